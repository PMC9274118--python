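"""File I/O helpers: images, configs, and JSON serialization of scene
objects and dissection results."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from PIL import Image

from .dissection import DissectionTrace, OrganLabels
from .scene import Contour, SceneObjects

__all__ = [
    "read_image", "write_image", "load_config",
    "scene_to_dict", "scene_from_dict", "labels_to_dict",
    "read_genotypes",
]


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/JPEG/TIFF photograph as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def load_config(path: str | os.PathLike | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return json.load(fh)


def _contour_to_dict(c: Contour) -> dict:
    return {
        "boundary": np.asarray(c.boundary).tolist(),
        "coords": np.asarray(c.coords).tolist(),
        "area_px": c.area_px,
        "perimeter_px": c.perimeter_px,
        "centroid": list(c.centroid),
    }


def _contour_from_dict(d: dict) -> Contour:
    return Contour(
        boundary=np.asarray(d["boundary"], dtype=float),
        coords=np.asarray(d["coords"], dtype=int).reshape(-1, 2),
        area_px=float(d["area_px"]),
        perimeter_px=float(d["perimeter_px"]),
        centroid=tuple(d["centroid"]),
    )


def scene_to_dict(scene: SceneObjects) -> dict:
    return {
        "marker": _contour_to_dict(scene.marker) if scene.marker else None,
        "checker": _contour_to_dict(scene.checker) if scene.checker else None,
        "sheaths": [_contour_to_dict(c) for c in scene.sheaths],
        "marker_center": list(scene.marker_center) if scene.marker_center else None,
        "marker_radius_px": scene.marker_radius_px,
    }


def scene_from_dict(d: dict) -> SceneObjects:
    return SceneObjects(
        marker=_contour_from_dict(d["marker"]) if d.get("marker") else None,
        checker=_contour_from_dict(d["checker"]) if d.get("checker") else None,
        sheaths=[_contour_from_dict(c) for c in d.get("sheaths", [])],
        marker_center=tuple(d["marker_center"]) if d.get("marker_center") else None,
        marker_radius_px=d.get("marker_radius_px"),
    )


def labels_to_dict(labels: OrganLabels, trace: DissectionTrace) -> dict:
    return {
        "sixth": labels.sixth,
        "fifth": labels.fifth,
        "other": labels.other,
        "trace": {
            "C_six": list(trace.C_six),
            "sixth_length_px": trace.sixth_length_px,
            "records": [
                {"index": r.index, "C_cdit": list(r.C_cdit), "D_cent": r.D_cent,
                 "ratio": r.ratio, "decision": r.decision}
                for r in trace.records
            ],
        },
    }


def read_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Biallelic dosage matrix (rows = SNPs, cols = lines, values 0/1/2/NaN).

    Accepts a TSV with an snp_id index column, or a VCF whose GT fields are
    converted to alternate-allele dosages (missing calls become NaN).
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        vcf = VCF(path)
        rows, ids = [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            dosage = []
            for gt in var.genotypes:
                alleles = [a for a in gt[:-1] if a >= 0]
                dosage.append(float(sum(alleles)) if alleles else np.nan)
            rows.append(dosage)
        return pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"),
                            columns=vcf.samples)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    df.index.name = "snp_id"
    return df.astype(float)
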