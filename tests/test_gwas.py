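"""GWAS post-processing: filters, consensus sets, gene annotation, network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sheathpheno import gwas as gw
from sheathpheno.simulate import simulate_association_tables

GFF = """\
##gff-version 3
chr1\ttest\tgene\t100\t900\t.\t+\t.\tID=geneA;description=kinase A
chr1\ttest\tgene\t2000\t2500\t.\t-\t.\tID=geneB;description=factor B
chr1\ttest\tgene\t2600\t3000\t.\t+\t.\tID=geneC;description=enzyme C
chr2\ttest\tgene\t500\t1500\t.\t+\t.\tID=geneD;description=channel D
chr2\ttest\tgene\t40000\t41000\t.\t-\t.\tID=geneE;description=pump E
"""


@pytest.fixture(scope="module")
def genes(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "genes.gff3"
    path.write_text(GFF)
    return gw.load_genes(path)


class TestSnpSummaries:
    def test_monomorphic_fully_called(self):
        g = pd.DataFrame([[0] * 10], index=["s1"])
        (s,) = gw.snp_summaries(g)
        assert (s.maf, s.call_rate) == (0.0, 1.0)

    def test_hand_counted_alt_frequency(self):
        g = pd.DataFrame([[0] * 9 + [2]], index=["s1"])
        (s,) = gw.snp_summaries(g)
        assert s.maf == pytest.approx(0.1)

    def test_call_rate_with_missing(self):
        g = pd.DataFrame([[0, 1, 2, np.nan, np.nan, 0, 1, 2, 0, 1]], index=["s1"])
        (s,) = gw.snp_summaries(g)
        assert s.call_rate == pytest.approx(0.8)

    def test_all_missing_excluded_with_warning(self):
        g = pd.DataFrame([[np.nan] * 4, [0, 1, 2, 1]], index=["s1", "s2"])
        with pytest.warns(UserWarning, match="all calls missing"):
            out = gw.snp_summaries(g)
        assert [s.snp_id for s in out] == ["s2"]


class TestFilterSnps:
    def test_exact_cutoffs_are_exclusive(self):
        s = [gw.SnpSummary("a", "1", 1, maf=0.05, call_rate=1.0),
             gw.SnpSummary("b", "1", 2, maf=0.3, call_rate=0.95),
             gw.SnpSummary("c", "1", 3, maf=0.2, call_rate=0.9)]
        assert gw.filter_snps(s) == ["b"]

    def test_toy_panel_equals_bruteforce(self):
        rng = np.random.default_rng(3)
        summaries = [
            gw.SnpSummary(f"s{i}", "1", i, maf=float(rng.uniform(0, 0.5)),
                          call_rate=float(rng.uniform(0.8, 1.0)))
            for i in range(10)
        ]
        expected = [s.snp_id for s in summaries
                    if s.maf > 0.05 and s.call_rate > 0.9]
        assert gw.filter_snps(summaries) == expected

    @given(maf_min=hst.floats(0.0, 0.5), callrate_min=hst.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_thresholds_never_adds_snps(self, maf_min, callrate_min):
        rng = np.random.default_rng(11)
        summaries = [
            gw.SnpSummary(f"s{i}", "1", i, maf=float(rng.uniform(0, 0.5)),
                          call_rate=float(rng.uniform(0, 1)))
            for i in range(30)
        ]
        base = set(gw.filter_snps(summaries, 0.05, 0.9))
        tight = set(gw.filter_snps(summaries, max(0.05, maf_min),
                                   max(0.9, callrate_min)))
        assert tight <= base


class TestSignificance:
    def test_effective_stage1_cutoff_at_genome_scale(self):
        records = pd.DataFrame({"p_value": [1e-8], "snp_id": ["s"],
                                "chrom": ["1"], "pos": [1],
                                "trait": ["t"], "method": ["m"]})
        kept, cutoff = gw.significance_filter(records, 794722)
        # 0.5 / 794722, the screen reported as ~6.3e-7 genome-wide
        assert cutoff == pytest.approx(6.2915e-7, rel=1e-4)
        assert len(kept) == 1

    @pytest.mark.parametrize("p, survives", [(1e-8, True), (1e-5, False),
                                             (1e-3, False)])
    def test_two_stage_screen(self, p, survives):
        records = pd.DataFrame({"p_value": [p], "snp_id": ["s"],
                                "chrom": ["1"], "pos": [1],
                                "trait": ["t"], "method": ["m"]})
        kept, _ = gw.significance_filter(records, 794722)
        assert (len(kept) == 1) is survives

    def test_final_defeat_threshold_binds_for_small_panels(self):
        # with few SNPs stage 1 is loose and the 2e-4 stage decides
        records = pd.DataFrame({"p_value": [1e-3], "snp_id": ["s"],
                                "chrom": ["1"], "pos": [1],
                                "trait": ["t"], "method": ["m"]})
        kept, cutoff = gw.significance_filter(records, 100)
        assert cutoff == pytest.approx(5e-3)
        assert kept.empty

    def test_nonpositive_p_rejected(self):
        records = pd.DataFrame({"p_value": [0.0], "snp_id": ["s"],
                                "chrom": ["1"], "pos": [1],
                                "trait": ["t"], "method": ["m"]})
        with pytest.raises(ValueError):
            gw.significance_filter(records, 10)


def rec(snp, method, p, trait="t1", chrom="1", pos=None):
    return {"snp_id": snp, "chrom": chrom, "pos": pos or 1,
            "trait": trait, "method": method, "p_value": p,
            "effect": 0.0, "pve": 1.0}


class TestConsensus:
    def test_single_method_single_snp(self):
        sets = gw.consensus(pd.DataFrame([rec("x", "m1", 1e-8)]))["t1"]
        assert sets.top1 == {"m1": "x"}
        assert sets.multi == set()
        assert sets.high_confidence == {"x"}

    def test_multi_method_snp_and_top1_union(self):
        rows = [rec("X", m, 1e-8) for m in ("m1", "m2", "m3")]
        rows.append(rec("Y", "m4", 1e-9))
        sets = gw.consensus(pd.DataFrame(rows))["t1"]
        assert sets.multi == {"X"}
        assert sets.high_confidence == {"X", "Y"}
        assert sets.both == {"X"}

    def test_top1_tie_breaks_to_lower_coordinate(self):
        rows = [rec("far", "m1", 1e-8, pos=5000),
                rec("near", "m1", 1e-8, pos=10)]
        sets = gw.consensus(pd.DataFrame(rows))["t1"]
        assert sets.top1 == {"m1": "near"}

    def test_set_inclusion_invariants(self):
        tab = simulate_association_tables(
            2000, 4,
            planted=[(3, ["mrMLM", "FASTmrMLM"], 1e-9),
                     (10, ["FASTmrEMMA"], 1e-8),
                     (11, ["mrMLM", "ISIS EM-BLASSO", "FASTmrMLM"], 1e-10)],
            seed=5)
        sig, _ = gw.significance_filter(tab, 794722)
        sets = gw.consensus(sig)["trait1"]
        top = set(sets.top1.values())
        assert sets.both <= top and sets.both <= sets.multi
        assert sets.high_confidence == top | sets.multi


class TestAnnotate:
    def test_within_gene_is_first_hit(self, genes):
        snps = pd.DataFrame([{"snp_id": "s", "chrom": "chr1", "pos": 500}])
        hits = gw.annotate(snps, genes)["s"]
        # geneA contains the snp; geneB/geneC also fall in the 10 kb window
        assert (hits[0].gene_id, hits[0].relation, hits[0].distance_bp) == (
            "geneA", "within", 0)
        assert [h.gene_id for h in hits] == ["geneA", "geneB", "geneC"]

    def test_upstream_within_window(self, genes):
        snps = pd.DataFrame([{"snp_id": "s", "chrom": "chr2", "pos": 39000}])
        (hit,) = gw.annotate(snps, genes, window_bp=10000)["s"]
        assert (hit.gene_id, hit.relation, hit.distance_bp) == ("geneE", "upstream", 1000)

    def test_toy_panel_equals_bruteforce_scan(self, genes):
        snps = pd.DataFrame([
            {"snp_id": f"s{i}", "chrom": c, "pos": p}
            for i, (c, p) in enumerate([
                ("chr1", 150), ("chr1", 1950), ("chr1", 2550),
                ("chr2", 100), ("chr2", 39500), ("chr3", 5)])
        ])
        window = 10000
        result = gw.annotate(snps, genes, window_bp=window)
        for _, snp in snps.iterrows():
            expected = []
            for _, g in genes.iterrows():
                if g["chrom"] != snp["chrom"]:
                    continue
                if g["start"] <= snp["pos"] <= g["end"]:
                    expected.append((g["gene_id"], "within", 0))
                elif 0 < g["start"] - snp["pos"] <= window:
                    expected.append((g["gene_id"], "upstream",
                                     g["start"] - snp["pos"]))
                elif 0 < snp["pos"] - g["end"] <= window:
                    expected.append((g["gene_id"], "downstream",
                                     snp["pos"] - g["end"]))
            expected.sort(key=lambda t: (t[2], t[0]))
            got = [(h.gene_id, h.relation, h.distance_bp)
                   for h in result[snp["snp_id"]]]
            assert got == expected

    def test_missing_chromosome_warns(self, genes):
        snps = pd.DataFrame([{"snp_id": "s", "chrom": "chr9", "pos": 1}])
        with pytest.warns(UserWarning, match="absent"):
            assert gw.annotate(snps, genes)["s"] == []

    def test_random_panel_equals_bruteforce(self, genes):
        rng = np.random.default_rng(17)
        big = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(100)],
            "description": "d",
            "chrom": rng.choice(["chr1", "chr2"], 100),
            "start": rng.integers(1, 100000, 100),
        })
        big["end"] = big["start"] + rng.integers(100, 5000, 100)
        snps = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(50)],
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "pos": rng.integers(1, 105000, 50),
        })
        res = gw.annotate(snps, big, window_bp=2000)
        for _, snp in snps.iterrows():
            brute = set()
            for _, g in big.iterrows():
                if g["chrom"] != snp["chrom"]:
                    continue
                d = max(g["start"] - snp["pos"], snp["pos"] - g["end"], 0)
                if d <= 2000:
                    brute.add(g["gene_id"])
            assert {h.gene_id for h in res[snp["snp_id"]]} == brute


class TestNetwork:
    def test_node_and_edge_counts(self):
        edges = pd.DataFrame({"trait": ["t1", "t1", "t2"],
                              "gene_id": ["g1", "g2", "g3"]})
        nodes, net = gw.export_network(edges)
        assert len(nodes) == 5
        assert (nodes["type"] == "trait").sum() == 2
        assert len(net) == 3

    def test_nodes_deduplicated_across_roles(self):
        edges = pd.DataFrame({"trait": ["t1", "t2"], "gene_id": ["g1", "g1"]})
        pathways = pd.DataFrame({"gene_id": ["g1"], "pathway": ["p1"]})
        nodes, net = gw.export_network(edges, pathways)
        assert len(nodes) == 4  # t1, t2, g1, p1
        assert len(net) == 3

    def test_sif_round_trip(self, tmp_path):
        edges = pd.DataFrame({"trait": ["t1", "t2"], "gene_id": ["g1", "g2"]})
        pathways = pd.DataFrame({"gene_id": ["g1", "g2"],
                                 "pathway": ["p1", "p1"]})
        _, net = gw.export_network(edges, pathways)
        path = tmp_path / "net.sif"
        gw.write_sif(net, path)
        back = gw.parse_sif(path)
        pd.testing.assert_frame_equal(back, net)


def test_pipeline_is_deterministic(genes, tmp_path):
    tab = simulate_association_tables(
        500, 3, planted=[(1, ["mrMLM", "FASTmrMLM"], 1e-9)], seed=9)
    outputs = []
    for run in range(2):
        sig, _ = gw.significance_filter(tab, 794722)
        cons = gw.consensus(sig)
        snps = sig[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
        snps = snps.assign(chrom="chr1")
        hits = gw.annotate(snps, genes)
        edges = gw.trait_gene_edges(cons, hits)
        nodes, net = gw.export_network(edges)
        p = tmp_path / f"run{run}.sif"
        gw.write_sif(net, p)
        outputs.append(p.read_bytes())
    assert outputs[0] == outputs[1]
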