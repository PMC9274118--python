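"""Trait extraction: the 85 image-derived leaf-sheath traits.

Two object scopes are measured per photograph: the *whole plant* (all
sheath contours pooled) and the *sixth sheath* (the largest contour).  The
roster is:

* whole plant, morphology (18): {Area, Length, Width, Perimeter} x
  {Avg, Sd, Sum} and {LWRatio, Compactness, Rectangularity} x {Avg, Sd},
  named ``T_<Measure>_<Agg>_SS``;
* whole plant, color (30): mean and pixel-level SD of R, G, B plus the 12
  comprehensive indices, named ``<Name>_SS`` / ``<Name>_S_SS``;
* sixth sheath, morphology (7): the raw measures, named ``T_<Measure>_S0``;
* sixth sheath, color (30): as above with suffix ``_S0``.

Together with manually weighed dry and fresh biomass this gives the
87-column phenotype table used by the downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import colorindex
from .dissection import DissectionParams, bounding_geometry, dissect
from .scene import Contour, ScaleCalibration, SegmentationConfig, segment_scene

__all__ = [
    "ShapeMeasures", "TraitVector", "ExtractionConfig",
    "shape_measures", "aggregate_whole_plant", "color_measures",
    "extract_traits", "assemble_table", "validate_against_biomass",
    "trait_registry", "SIZE_MEASURES", "SHAPE_MEASURES", "SUBPOPULATIONS",
]

SIZE_MEASURES = ("Area", "Length", "Width", "Perimeter")
SHAPE_MEASURES = ("LWRatio", "Compactness", "Rectangularity")
CHANNELS = ("R", "G", "B")
SUBPOPULATIONS = ("NSS", "SS", "TST", "Mixed")


@dataclass
class ShapeMeasures:
    """Morphology of one contour, in cm when calibrated else px."""

    area: float
    perimeter: float
    length: float
    width: float
    lw_ratio: float
    compactness: float
    rectangularity: float
    units: str  # "cm" | "px"

    def as_dict(self) -> dict[str, float]:
        return {
            "Area": self.area, "Length": self.length, "Width": self.width,
            "Perimeter": self.perimeter, "LWRatio": self.lw_ratio,
            "Compactness": self.compactness, "Rectangularity": self.rectangularity,
        }


@dataclass
class TraitVector:
    sample_id: str
    values: dict[str, float]
    units: str


@dataclass
class ExtractionConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dissection: DissectionParams = field(default_factory=DissectionParams)
    index_registry: dict = field(default_factory=lambda: dict(colorindex.INDEX_REGISTRY))

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        seg = SegmentationConfig.from_dict(d)
        dis = DissectionParams(
            ratio_min=d.get("ratio_min", 3.0),
            dist_factor=d.get("dist_factor", 0.5),
        )
        return cls(segmentation=seg, dissection=dis)


def shape_measures(contour: Contour, scale: ScaleCalibration | None = None) -> ShapeMeasures:
    """Shape descriptors of one contour.

    compactness = perimeter^2 / (4*pi*area): 1 for a disk, larger for
    elongated shapes.  rectangularity = area / min-area-rotated-rectangle
    area, 1 for a rectangle.  Both are dimensionless; the size measures
    convert to cm via the marker calibration when available.
    """
    geom = bounding_geometry(contour)
    s = 1.0 / scale.px_per_cm if scale is not None else 1.0
    area = contour.area_px * s * s
    perim = contour.perimeter_px * s
    length = geom.length_px * s
    width = geom.width_px * s
    return ShapeMeasures(
        area=area,
        perimeter=perim,
        length=length,
        width=width,
        lw_ratio=geom.lw_ratio,
        compactness=contour.perimeter_px**2 / (4.0 * np.pi * contour.area_px),
        rectangularity=contour.area_px / (geom.length_px * geom.width_px),
        units="cm" if scale is not None else "px",
    )


def _sd(x: np.ndarray) -> float:
    """Sample standard deviation; 0 for a single observation."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def aggregate_whole_plant(measures: list[ShapeMeasures]) -> dict[str, float]:
    """The 18 whole-plant morphology traits from per-sheath measures."""
    if not measures:
        raise ValueError("no sheath measures to aggregate")
    out: dict[str, float] = {}
    for name in SIZE_MEASURES:
        vals = np.array([m.as_dict()[name] for m in measures])
        out[f"T_{name}_Avg_SS"] = float(vals.mean())
        out[f"T_{name}_Sd_SS"] = _sd(vals)
        out[f"T_{name}_Sum_SS"] = float(vals.sum())
    for name in SHAPE_MEASURES:
        vals = np.array([m.as_dict()[name] for m in measures])
        out[f"T_{name}_Avg_SS"] = float(vals.mean())
        out[f"T_{name}_Sd_SS"] = _sd(vals)
    return out


def color_measures(rgb: np.ndarray, registry: dict | None = None) -> dict[str, float]:
    """The 30 color traits of one pixel region.

    ``rgb`` is an (n, 3) array of 8-bit RGB values.  Returns the mean and
    pixel-level sample SD (suffix ``_S``) of the three raw channels and of
    each comprehensive index in the registry (default 12).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 2 or rgb.shape[1] != 3 or len(rgb) == 0:
        raise ValueError("rgb must be a non-empty (n, 3) array")
    registry = registry or colorindex.INDEX_REGISTRY
    out: dict[str, float] = {}
    for i, ch in enumerate(CHANNELS):
        out[ch] = float(rgb[:, i].mean())
        out[f"{ch}_S"] = _sd(rgb[:, i])
    for name in colorindex.index_names(registry):
        vals = colorindex.compute_index(name, rgb, registry)
        out[name] = float(vals.mean())
        out[f"{name}_S"] = _sd(vals)
    return out


def _color_names(registry: dict | None = None) -> list[str]:
    names = []
    for ch in CHANNELS:
        names += [ch, f"{ch}_S"]
    for name in colorindex.index_names(registry):
        names += [name, f"{name}_S"]
    return names


def trait_registry(index_registry: dict | None = None) -> pd.DataFrame:
    """The full 85-trait roster with scope/category/aggregation metadata."""
    rows = []
    for name in SIZE_MEASURES:
        for agg in ("Avg", "Sd", "Sum"):
            rows.append((f"T_{name}_{agg}_SS", "whole_plant", "morphology", agg))
    for name in SHAPE_MEASURES:
        for agg in ("Avg", "Sd"):
            rows.append((f"T_{name}_{agg}_SS", "whole_plant", "morphology", agg))
    for base in _color_names(index_registry):
        rows.append((f"{base}_SS", "whole_plant", "color", "none"))
    for name in SIZE_MEASURES + SHAPE_MEASURES:
        rows.append((f"T_{name}_S0", "sixth", "morphology", "none"))
    for base in _color_names(index_registry):
        rows.append((f"{base}_S0", "sixth", "color", "none"))
    return pd.DataFrame(rows, columns=["trait", "object_scope", "category", "aggregation"]).set_index("trait")


def extract_traits(
    image: np.ndarray,
    config: ExtractionConfig | None = None,
    sample_id: str = "sample",
) -> TraitVector:
    """Run segmentation + dissection + measurement on one photograph.

    Returns the 85 named trait values.  Without a detectable scale marker
    the size traits stay in pixel units and the vector's ``units`` flag is
    ``"px"``.
    """
    if config is None:
        config = ExtractionConfig()
    scene, scale, used = segment_scene(image, config.segmentation)
    if not scene.sheaths:
        raise ValueError(f"{sample_id}: no sheath contour found")
    labels, _ = dissect(scene.sheaths, config.dissection)
    sixth = scene.sheaths[labels.sixth]

    measures = [shape_measures(c, scale) for c in scene.sheaths]
    values = aggregate_whole_plant(measures)

    pooled = np.vstack([c.pixel_values(used) for c in scene.sheaths])
    for base, v in color_measures(pooled, config.index_registry).items():
        values[f"{base}_SS"] = v

    sixth_sm = shape_measures(sixth, scale)
    for name, v in sixth_sm.as_dict().items():
        values[f"T_{name}_S0"] = v
    for base, v in color_measures(sixth.pixel_values(used), config.index_registry).items():
        values[f"{base}_S0"] = v

    order = trait_registry(config.index_registry).index
    values = {name: values[name] for name in order}
    return TraitVector(sample_id=sample_id, values=values,
                       units="cm" if scale is not None else "px")


def assemble_table(
    vectors: list[TraitVector],
    biomass: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join image traits with biomass and line metadata into one table.

    ``biomass`` has columns sample_id, DryWeight, FreshWeight (grams);
    ``metadata`` has sample_id, line_id, replicate, subpopulation.  Missing
    biomass becomes NaN; an unknown subpopulation label is assigned
    "Mixed" with a warning; a duplicate sample_id is an error.
    """
    if not vectors:
        raise ValueError("no trait vectors")
    ids = [v.sample_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among trait vectors")
    df = pd.DataFrame([v.values for v in vectors], index=pd.Index(ids, name="sample_id"))
    df["units"] = [v.units for v in vectors]

    if biomass is not None:
        biomass = biomass.set_index("sample_id") if "sample_id" in biomass.columns else biomass
        if biomass.index.duplicated().any():
            raise ValueError("duplicate sample_id in biomass table")
        df = df.join(biomass[["DryWeight", "FreshWeight"]], how="left")
    else:
        df["DryWeight"] = np.nan
        df["FreshWeight"] = np.nan

    if metadata is not None:
        metadata = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        if metadata.index.duplicated().any():
            raise ValueError("duplicate sample_id in metadata table")
        df = df.join(metadata[["line_id", "replicate", "subpopulation"]], how="left")
        bad = ~df["subpopulation"].isin(SUBPOPULATIONS) & df["subpopulation"].notna()
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} samples with unknown subpopulation label; "
                "assigned 'Mixed'", stacklevel=2,
            )
            df.loc[bad, "subpopulation"] = "Mixed"
    return df


def validate_against_biomass(matrix: pd.DataFrame) -> dict[str, dict[str, float]]:
    """OLS of manual dry/fresh weight on image-derived total sheath area.

    The R-squared measures how well the image pipeline's area tracks true
    biomass; a high value validates the automated measurement.
    """
    out: dict[str, dict[str, float]] = {}
    for weight in ("DryWeight", "FreshWeight"):
        sub = matrix[["T_Area_Sum_SS", weight]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 complete rows for {weight} regression")
        X = sm.add_constant(sub["T_Area_Sum_SS"].to_numpy())
        fit = sm.OLS(sub[weight].to_numpy(), X).fit()
        out[weight] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared),
            "n": int(len(sub)),
        }
    return out
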