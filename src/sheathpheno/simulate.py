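"""Synthetic data with analytic ground truth.

Three generators make the whole pipeline testable without any photograph
or genotype download:

* :func:`generate_scene` rasterizes a vector scene description (white
  board, circular marker, color-checker, tapered-quadrilateral sheaths)
  into an 8-bit RGB image, returning the exact vector geometry (shoelace
  areas, minimum-rectangle lengths, centroids, expected organ labels) as
  ground truth.  Rasterization uses a pixel-center coverage test and no
  anti-aliasing, so pixel counts track polygon areas closely.
* :func:`simulate_phenotypes` draws replicated line-structured phenotypes
  y_ij = mu + a_i + e_ij with a_i ~ N(0, sigmaA2), e_ij ~ N(0, sigmaE2) —
  the generating model under which broad-sense heritability is
  sigmaA2 / (sigmaA2 + sigmaE2).
* :func:`simulate_association_tables` builds per-method GWAS result
  tables with planted significant SNPs on a uniform p-value background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .dissection import DissectionParams
from .gwas import ASSOC_COLUMNS
from .traits import SUBPOPULATIONS

__all__ = [
    "SheathSpec", "MarkerSpec", "CheckerSpec", "SceneSpec", "GroundTruth",
    "generate_scene", "default_scene_spec", "simulate_phenotypes",
    "simulate_association_tables", "GWAS_METHODS",
]

GWAS_METHODS = ("mrMLM", "FASTmrMLM", "FASTmrEMMA",
                "ISIS EM-BLASSO", "pLARmEB", "pKWmEB")

#: subpopulation mixing proportions of a typical maize association panel
SUBPOP_WEIGHTS = {"NSS": 124 / 418, "SS": 31 / 418,
                  "TST": 164 / 418, "Mixed": 99 / 418}


@dataclass
class SheathSpec:
    """A tapered quadrilateral: length along the axis at ``angle_deg``,
    linearly varying width from ``width_bottom_px`` to ``width_top_px``."""

    center: tuple[float, float]
    length_px: float
    width_top_px: float
    width_bottom_px: float
    angle_deg: float
    fill: tuple[int, int, int]

    def polygon(self) -> Polygon:
        L = self.length_px / 2.0
        wt, wb = self.width_top_px / 2.0, self.width_bottom_px / 2.0
        local = np.array([[-L, -wb], [-L, wb], [L, wt], [L, -wt]])
        th = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = local @ rot.T + np.asarray(self.center)
        return Polygon(pts)


@dataclass
class MarkerSpec:
    center: tuple[float, float]
    radius_px: float
    fill: tuple[int, int, int] = (70, 70, 70)

    def polygon(self) -> Polygon:
        return Point(self.center).buffer(self.radius_px, quad_segs=90)


@dataclass
class CheckerSpec:
    origin: tuple[float, float]  # top-left (x, y)
    cell_px: int
    rows: int
    cols: int
    palette: tuple[tuple[int, int, int], ...] = (
        (25, 25, 25), (100, 100, 100), (45, 55, 45),
        (95, 75, 60), (30, 45, 60), (75, 60, 95),
    )

    def polygon(self) -> Polygon:
        x0, y0 = self.origin
        return box(x0, y0, x0 + self.cols * self.cell_px,
                   y0 + self.rows * self.cell_px)


@dataclass
class SceneSpec:
    width_px: int = 900
    height_px: int = 620
    background: tuple[int, int, int] = (245, 245, 245)
    marker: MarkerSpec | None = None
    checker: CheckerSpec | None = None
    sheaths: list[SheathSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    marker_diameter_cm: float = 2.0


@dataclass
class GroundTruth:
    """Exact vector-geometry answers for one generated scene."""

    sheaths: list[dict]
    marker_center: tuple[float, float] | None
    marker_radius_px: float | None
    px_per_cm: float | None
    expected_sixth: int | None
    expected_fifth: list[int]
    expected_other: list[int]


def _min_rect_sides(poly: Polygon) -> tuple[float, float]:
    rect = poly.minimum_rotated_rectangle
    pts = np.asarray(rect.exterior.coords)[:4]
    sides = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)[:2]
    return float(max(sides)), float(min(sides))


def _expected_labels(polys: list[Polygon], params: DissectionParams
                     ) -> tuple[int, list[int], list[int]]:
    """The organ labels the dissection rules imply on the vector geometry."""
    areas = [p.area for p in polys]
    order = sorted(range(len(polys)), key=lambda i: (-areas[i], i))
    sixth = order[0]
    six_len, _ = _min_rect_sides(polys[sixth])
    c6 = np.array(polys[sixth].centroid.coords[0])
    fifth, other = [], []
    for i in order[1:]:
        length, width = _min_rect_sides(polys[i])
        c = np.array(polys[i].centroid.coords[0])
        d = float(np.hypot(*(c - c6)))
        if length / width > params.ratio_min and d < params.dist_factor * six_len:
            fifth.append(i)
        else:
            other.append(i)
    return sixth, fifth, other


def _paint(canvas: np.ndarray, poly: Polygon, fill: tuple[int, int, int]) -> None:
    """Fill pixels whose center lies inside the polygon (no anti-aliasing)."""
    h, w = canvas.shape[:2]
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(int(minx) - 1, 0), min(int(maxx) + 2, w)
    r0, r1 = max(int(miny) - 1, 0), min(int(maxy) + 2, h)
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(poly, cols + 0.5, rows + 0.5)
    sub = canvas[r0:r1, c0:c1]
    sub[inside] = fill


def generate_scene(spec: SceneSpec,
                   dissection: DissectionParams | None = None
                   ) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a scene spec; return the image and its ground truth.

    Raises if any two foreground shapes overlap (the scene invariant) or
    if a sheath fill is not darker than the background.
    """
    if dissection is None:
        dissection = DissectionParams()
    shapes: list[Polygon] = []
    if spec.marker is not None:
        shapes.append(spec.marker.polygon())
    if spec.checker is not None:
        shapes.append(spec.checker.polygon())
    sheath_polys = [s.polygon() for s in spec.sheaths]
    shapes.extend(sheath_polys)
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            if shapes[i].intersects(shapes[j]):
                raise ValueError(f"scene shapes {i} and {j} overlap")
    bg_gray = float(np.dot(spec.background, [0.299, 0.587, 0.114]))
    for s in spec.sheaths:
        if float(np.dot(s.fill, [0.299, 0.587, 0.114])) >= bg_gray:
            raise ValueError("sheath fill must be darker than the background")

    canvas = np.empty((spec.height_px, spec.width_px, 3), dtype=np.float64)
    canvas[:] = spec.background
    if spec.marker is not None:
        _paint(canvas, spec.marker.polygon(), spec.marker.fill)
    if spec.checker is not None:
        ch = spec.checker
        x0, y0 = ch.origin
        for i in range(ch.rows):
            for j in range(ch.cols):
                fill = ch.palette[(i * ch.cols + j) % len(ch.palette)]
                cell = box(x0 + j * ch.cell_px, y0 + i * ch.cell_px,
                           x0 + (j + 1) * ch.cell_px, y0 + (i + 1) * ch.cell_px)
                _paint(canvas, cell, fill)
    for s, poly in zip(spec.sheaths, sheath_polys):
        _paint(canvas, poly, s.fill)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    truth_sheaths = []
    for s, poly in zip(spec.sheaths, sheath_polys):
        length, width = _min_rect_sides(poly)
        truth_sheaths.append({
            "area_px": poly.area,
            "perimeter_px": poly.length,
            "length_px": length,
            "width_px": width,
            "centroid": tuple(poly.centroid.coords[0]),
            "fill": s.fill,
        })
    if sheath_polys:
        sixth, fifth, other = _expected_labels(sheath_polys, dissection)
    else:
        sixth, fifth, other = None, [], []
    marker = spec.marker
    truth = GroundTruth(
        sheaths=truth_sheaths,
        marker_center=marker.center if marker else None,
        marker_radius_px=marker.radius_px if marker else None,
        px_per_cm=(2.0 * marker.radius_px / spec.marker_diameter_cm
                   if marker else None),
        expected_sixth=sixth,
        expected_fifth=fifth,
        expected_other=other,
    )
    return image, truth


def default_scene_spec(seed: int = 0, noise_sd: float = 2.0) -> SceneSpec:
    """A board-layout scene like a real acquisition: one marker, one
    checker, six sheaths with a single dominant (sixth) sheath."""
    green = (60, 130, 70)
    purple = (115, 70, 115)
    sheaths = [
        SheathSpec((450, 300), 430, 60, 48, 8, green),      # sixth (dominant)
        SheathSpec((400, 480), 240, 32, 26, -4, green),     # fifth: close, slim
        SheathSpec((180, 500), 220, 30, 24, 10, purple),    # far -> other
        SheathSpec((660, 500), 230, 34, 28, -8, green),     # far -> other
        SheathSpec((790, 300), 200, 28, 22, 85, purple),    # far -> other
        SheathSpec((150, 320), 100, 52, 48, 0, green),      # low ratio blob -> other
    ]
    return SceneSpec(
        width_px=900, height_px=620,
        marker=MarkerSpec((110, 110), 45.0),
        checker=CheckerSpec((700, 40), 20, 4, 6),
        sheaths=sheaths,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_phenotypes(
    n_lines: int,
    n_reps: int,
    sigmaA2: float,
    sigmaE2: float,
    trait_means: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated line-structured phenotypes under the random-line model.

    Each trait gets independent line effects a_i ~ N(0, sigmaA2) and
    residuals e_ij ~ N(0, sigmaE2).  Lines are assigned to the four
    germplasm subpopulations with panel-like proportions.  Returns a table
    indexed by sample_id with line_id / replicate / subpopulation metadata.
    """
    if n_lines < 2 or n_reps < 2:
        raise ValueError("need n_lines >= 2 and n_reps >= 2")
    if sigmaA2 < 0 or sigmaE2 < 0:
        raise ValueError("variances must be non-negative")
    trait_means = trait_means or {"y": 0.0}
    rng = np.random.default_rng(seed)
    lines = [f"L{i + 1:04d}" for i in range(n_lines)]
    subpops = rng.choice(list(SUBPOP_WEIGHTS), size=n_lines,
                         p=list(SUBPOP_WEIGHTS.values()))
    rows = {
        "line_id": np.repeat(lines, n_reps),
        "replicate": np.tile(np.arange(1, n_reps + 1), n_lines),
        "subpopulation": np.repeat(subpops, n_reps),
    }
    for trait, mu in trait_means.items():
        a = rng.normal(0.0, np.sqrt(sigmaA2), n_lines)
        e = rng.normal(0.0, np.sqrt(sigmaE2), n_lines * n_reps)
        rows[trait] = mu + np.repeat(a, n_reps) + e
    df = pd.DataFrame(rows)
    df.index = pd.Index(
        [f"{l}_r{r}" for l, r in zip(df["line_id"], df["replicate"])],
        name="sample_id")
    return df


def simulate_association_tables(
    n_snps: int,
    n_methods: int = 6,
    planted: list[tuple[int, list[str], float]] | None = None,
    trait: str = "trait1",
    background_keep: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-method GWAS result tables with planted significant SNPs.

    ``planted`` is a list of (snp index, methods, p-value) entries laid on
    top of a Uniform(0, 1) p-value background.  ``background_keep`` can
    subsample background rows to keep tables small.  The combined table
    follows the documented association schema (one row per snp, trait,
    method).
    """
    if n_methods > len(GWAS_METHODS):
        raise ValueError(f"at most {len(GWAS_METHODS)} methods")
    methods = GWAS_METHODS[:n_methods]
    planted = planted or []
    for idx, meths, _p in planted:
        if not 0 <= idx < n_snps:
            raise ValueError(f"planted snp index {idx} outside [0, {n_snps})")
        for m in meths:
            if m not in methods:
                raise ValueError(f"unknown method {m!r}")
    rng = np.random.default_rng(seed)
    snp_ids = np.array([f"snp{i + 1:06d}" for i in range(n_snps)])
    chrom = np.array(["1"] * n_snps)
    pos = (np.arange(n_snps) + 1) * 100
    frames = []
    for m in methods:
        p = rng.uniform(0.0, 1.0, n_snps)
        p = np.nextafter(p, 1.0)  # keep p strictly positive
        keep = np.ones(n_snps, dtype=bool)
        if background_keep < 1.0:
            keep = rng.uniform(size=n_snps) < background_keep
        for idx, meths, pv in planted:
            if m in meths:
                p[idx] = pv
                keep[idx] = True
        frames.append(pd.DataFrame({
            "snp_id": snp_ids[keep], "chrom": chrom[keep], "pos": pos[keep],
            "trait": trait, "method": m, "p_value": p[keep],
            "effect": rng.normal(0.0, 0.1, int(keep.sum())),
            "pve": rng.uniform(0.0, 10.0, int(keep.sum())),
        }))
    return pd.concat(frames, ignore_index=True)[ASSOC_COLUMNS]
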