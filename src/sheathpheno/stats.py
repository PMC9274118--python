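"""Phenotype statistics for replicated inbred-line trait tables.

Covers the downstream analysis of the 87-column phenotype matrix:
pairwise Pearson correlation, trait clustering by partition-around-medoids
with silhouette-selected k on the distance d = 1 - r, one-way ANOVA across
germplasm subpopulations with Tukey HSD post-hoc comparisons, standardized
PCA, broad-sense heritability from replicated lines, and the selection of
key traits (high-heritability morphology/biomass plus the first two color
principal components per object scope) for genetic mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TraitCorrelation", "TraitGrouping", "HeritabilityEstimate", "PCAResult",
    "KeyTraitSet", "correlation_matrix", "pam", "cluster_traits",
    "subpop_anova", "pca", "heritability", "heritability_table",
    "select_key_traits",
]


@dataclass
class TraitCorrelation:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


@dataclass
class TraitGrouping:
    k: int
    assignment: pd.Series  # trait -> group id (0-based)
    avg_silhouette: float
    medoids: list[str]
    silhouette_by_k: dict[int, float]
    linkage: np.ndarray | None = None  # average-linkage dendrogram on 1 - r


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability H2 = sigmaA2 / (sigmaA2 + sigmaE2).

    sigmaA2 is the between-line (genetic) variance component and sigmaE2
    the within-line (environmental) variance; V_A = sigmaA2 and
    V_P = sigmaA2 + sigmaE2.
    """

    sigmaA2: float
    sigmaE2: float
    H2: float

    @property
    def V_A(self) -> float:
        return self.sigmaA2

    @property
    def V_P(self) -> float:
        return self.sigmaA2 + self.sigmaE2


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x PCs
    loadings: pd.DataFrame     # traits x PCs, orthonormal columns
    variance_fractions: np.ndarray
    dropped: list[str]
    silhouette_2group: float | None = None
    labels_2group: np.ndarray | None = None


@dataclass
class KeyTraitSet:
    retained: list[str]
    pc_traits: pd.DataFrame         # score columns, e.g. Sum_PC1 ... Sixth_PC2
    loadings: dict[str, pd.DataFrame]

    @property
    def all_names(self) -> list[str]:
        return self.retained + list(self.pc_traits.columns)


def correlation_matrix(matrix: pd.DataFrame, min_n: int = 3) -> TraitCorrelation:
    """Pairwise-deletion Pearson correlation with two-sided p-values.

    Pairs with fewer than ``min_n`` complete rows, and pairs involving a
    constant column, are recorded as missing.
    """
    cols = list(matrix.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    X = matrix.to_numpy(dtype=float)
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < min_n:
                continue
            xi, xj = X[ok, i], X[ok, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # constant column: r undefined
            res = sps.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return TraitCorrelation(r=mk(r), p=mk(p), n=mk(n))


def pam(dist: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, list[int]]:
    """Partition around medoids (deterministic BUILD + SWAP).

    BUILD seeds with the point of minimal total distance and greedily adds
    the medoid that most reduces total cost; SWAP exchanges a medoid with a
    non-medoid while any exchange lowers the cost.  Ties resolve to the
    lowest index, so the fit is fully deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    m = dist.shape[0]
    if not 1 <= k < m:
        raise ValueError("k must be in [1, n_points)")
    medoids = [int(dist.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in list(medoids):
            for h in range(m):
                if h in medoids:
                    continue
                trial = sorted(set(medoids) - {mi} | {h})
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
                    break
            if improved:
                break
        if not improved:
            break
    labels = dist[:, medoids].argmin(axis=1)
    return labels, medoids


def cluster_traits(
    corr: TraitCorrelation, k_range: range | list[int] = range(2, 11)
) -> TraitGrouping:
    """Group traits by PAM on d = 1 - r, k chosen by average silhouette.

    Mirrors the pamk behaviour: fit each k in ``k_range``, keep the k with
    the highest average silhouette width.
    """
    r = corr.r
    if r.isna().any().any():
        raise ValueError("correlation matrix has missing entries; "
                         "drop undefined traits before clustering")
    names = list(r.columns)
    dist = 1.0 - r.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    n = len(names)
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    sil_by_k: dict[int, float] = {}
    best = None
    for k in ks:
        labels, medoids = pam(dist, k)
        if len(set(labels)) < 2:
            continue
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
        sil_by_k[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, labels, medoids)
    if best is None:
        raise ValueError("no k in range produced a valid partition")
    sil, k, labels, medoids = best
    from scipy.cluster.hierarchy import linkage as hclust
    from scipy.spatial.distance import squareform

    return TraitGrouping(
        k=k,
        assignment=pd.Series(labels, index=names, name="group"),
        avg_silhouette=sil,
        medoids=[names[i] for i in medoids],
        silhouette_by_k=sil_by_k,
        linkage=hclust(squareform(dist, checks=False), method="average"),
    )


def subpop_anova(
    matrix: pd.DataFrame,
    traits: list[str] | None = None,
    group_col: str = "subpopulation",
    alpha: float = 0.05,
    posthoc: bool = True,
) -> pd.DataFrame:
    """One-way ANOVA of each trait across subpopulations plus Tukey HSD.

    Returns one row per trait with the F statistic, p-value and, from the
    Tukey HSD comparisons, the number of subpopulations each group differs
    from.  Subpopulations with fewer than 2 samples are dropped with a
    warning.  ``posthoc=False`` skips the pairwise comparisons (useful for
    large simulation screens where only the F test matters).
    """
    if traits is None:
        traits = [c for c in matrix.columns
                  if c not in (group_col, "line_id", "replicate", "units")
                  and pd.api.types.is_numeric_dtype(matrix[c])]
    counts = matrix[group_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"dropping subpopulations with <2 samples: {small}",
                      stacklevel=2)
    keep = matrix[~matrix[group_col].isin(small)]
    groups = sorted(keep[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 subpopulations with >= 2 samples")
    rows = []
    for trait in traits:
        sub = keep[[trait, group_col]].dropna()
        samples = [sub.loc[sub[group_col] == g, trait].to_numpy() for g in groups]
        F, p = sps.f_oneway(*samples)
        sig_pairs: set[tuple[str, str]] = set()
        if posthoc and np.isfinite(p):
            tuk = pairwise_tukeyhsd(sub[trait].to_numpy(), sub[group_col].to_numpy(),
                                    alpha=alpha)
            res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
            for _, rrow in res.iterrows():
                if rrow["reject"] in (True, "True"):
                    sig_pairs.add((str(rrow["group1"]), str(rrow["group2"])))
        diff_counts = {
            g: sum(1 for pair in sig_pairs if g in pair) for g in groups
        }
        rows.append({
            "trait": trait, "F": float(F), "p": float(p),
            "significant_pairs": sorted(sig_pairs),
            "max_diff_count": max(diff_counts.values()) if diff_counts else 0,
            **{f"n_diff_{g}": diff_counts[g] for g in groups},
        })
    return pd.DataFrame(rows).set_index("trait")


def pca(
    matrix: pd.DataFrame,
    standardize: bool = True,
    two_group_silhouette: bool = False,
) -> PCAResult:
    """Standardized PCA of a trait block.

    Constant columns are dropped with a warning.  ``two_group_silhouette``
    additionally partitions the samples into 2 groups by PAM on the first
    two component scores and reports the average silhouette width.
    """
    X = matrix.dropna(axis=0)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("pca needs >= 2 columns and >= 3 complete rows")
    dropped = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    vals = X.to_numpy(dtype=float)
    if standardize:
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    fit = PCA(n_components=min(vals.shape), svd_solver="full").fit(vals)
    scores = fit.transform(vals)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    result = PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=pcs),
        loadings=pd.DataFrame(fit.components_.T, index=X.columns, columns=pcs),
        variance_fractions=fit.explained_variance_ratio_,
        dropped=dropped,
    )
    if two_group_silhouette:
        pts = scores[:, :2]
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        labels, _ = pam(d, 2)
        result.labels_2group = labels
        result.silhouette_2group = float(
            silhouette_score(d, labels, metric="precomputed"))
    return result


def heritability(values: np.ndarray, lines: np.ndarray) -> HeritabilityEstimate:
    """Broad-sense heritability from replicated line measurements.

    One-way random-effects decomposition with line as the random factor:
    sigmaE2 = MS_within; sigmaA2 = max(0, (MS_between - MS_within) / n0)
    where n0 = (N - sum n_i^2 / N) / (a - 1) is the effective replicate
    number for unbalanced designs.  H2 = sigmaA2 / (sigmaA2 + sigmaE2),
    clamped to [0, 1]; H2 = 0 when both components vanish.
    """
    values = np.asarray(values, dtype=float)
    lines = np.asarray(lines)
    ok = np.isfinite(values)
    values, lines = values[ok], lines[ok]
    uniq, idx = np.unique(lines, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need >= 2 lines")
    n_i = np.bincount(idx)
    N = int(n_i.sum())
    if N - a == 0:
        raise ValueError("all lines have a single replicate; "
                         "within-line variance is inestimable")
    grand = values.mean()
    means = np.bincount(idx, weights=values) / n_i
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[idx]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(n_i**2) / N) / (a - 1)
    sigmaA2 = max(0.0, (ms_between - ms_within) / n0)
    sigmaE2 = ms_within
    vp = sigmaA2 + sigmaE2
    H2 = min(1.0, sigmaA2 / vp) if vp > 0 else 0.0
    return HeritabilityEstimate(sigmaA2=sigmaA2, sigmaE2=sigmaE2, H2=H2)


def heritability_table(
    matrix: pd.DataFrame, traits: list[str], line_col: str = "line_id"
) -> pd.DataFrame:
    """Per-trait heritability estimates; rows indexed by trait name."""
    rows = []
    for t in traits:
        est = heritability(matrix[t].to_numpy(dtype=float), matrix[line_col].to_numpy())
        rows.append({"trait": t, "sigmaA2": est.sigmaA2,
                     "sigmaE2": est.sigmaE2, "H2": est.H2})
    return pd.DataFrame(rows).set_index("trait")


def select_key_traits(
    h2: pd.Series,
    matrix: pd.DataFrame,
    registry: pd.DataFrame,
    h2_min: float = 0.3,
    biomass_traits: tuple[str, str] = ("DryWeight", "FreshWeight"),
) -> KeyTraitSet:
    """Screen traits for genetic mapping by heritability.

    Non-color traits (morphology and biomass) with H2 above ``h2_min`` are
    retained as-is.  Color traits above the threshold are reduced per
    object scope by standardized PCA; the first two score vectors per scope
    are appended as pseudo-traits Sum_PC1/Sum_PC2 (whole plant) and
    Sixth_PC1/Sixth_PC2 (sixth sheath).
    """
    passing = set(h2[h2 > h2_min].index)
    color = {"whole_plant": [], "sixth": []}
    retained: list[str] = []
    for t in h2.index:
        if t not in passing:
            continue
        if t in biomass_traits or t not in registry.index:
            retained.append(t)
        elif registry.loc[t, "category"] == "color":
            color[registry.loc[t, "object_scope"]].append(t)
        else:
            retained.append(t)

    prefix = {"whole_plant": "Sum", "sixth": "Sixth"}
    pc_cols = {}
    loadings: dict[str, pd.DataFrame] = {}
    for scope, cols in color.items():
        if len(cols) < 2:
            if cols:
                warnings.warn(
                    f"<2 surviving color traits for {scope}; PCs omitted",
                    stacklevel=2)
            continue
        res = pca(matrix[cols], standardize=True)
        for i in (1, 2):
            pc_cols[f"{prefix[scope]}_PC{i}"] = res.scores[f"PC{i}"]
        loadings[prefix[scope]] = res.loadings[["PC1", "PC2"]]
    pc_traits = pd.DataFrame(pc_cols, index=matrix.index if not pc_cols else None)
    return KeyTraitSet(retained=retained, pc_traits=pc_traits, loadings=loadings)
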