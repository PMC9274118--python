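"""Organ dissection: label sheath contours as sixth, fifth or other.

The dissection rule works on the segmented sheath contours of one plant
photographed at the V6 stage.  The largest contour is the sixth (newest
fully emerged) leaf sheath.  Every other contour is a fifth-sheath
candidate: it must be elongated (length/width ratio of its minimum-area
rotated bounding rectangle above ``ratio_min``) and its centroid must lie
within ``dist_factor`` times the sixth sheath's bounding-box length of the
sixth sheath's centroid.  Candidates failing either test keep a generic
"other sheath" label and still count toward whole-plant aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .scene import Contour

__all__ = ["BoxGeom", "DissectionParams", "CandidateRecord", "DissectionTrace",
           "OrganLabels", "bounding_geometry", "dissect"]


@dataclass
class BoxGeom:
    """Minimum-area rotated bounding rectangle of a contour."""

    length_px: float
    width_px: float
    centroid: tuple[float, float]
    corners: np.ndarray  # (4, 2) rectangle vertices, (x, y)

    @property
    def lw_ratio(self) -> float:
        return self.length_px / self.width_px


@dataclass
class DissectionParams:
    ratio_min: float = 3.0
    dist_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.ratio_min <= 1:
            raise ValueError("ratio_min must exceed 1")
        if not 0 < self.dist_factor <= 1:
            raise ValueError("dist_factor must be in (0, 1]")


@dataclass
class CandidateRecord:
    index: int
    C_cdit: tuple[float, float]
    D_cent: float
    ratio: float
    decision: str  # accepted | rejected_ratio | rejected_distance


@dataclass
class DissectionTrace:
    C_six: tuple[float, float]
    sixth_length_px: float
    records: list[CandidateRecord] = field(default_factory=list)


@dataclass
class OrganLabels:
    sixth: int
    fifth: list[int]
    other: list[int]


def bounding_geometry(contour: Contour) -> BoxGeom:
    """Minimum-area rotated rectangle; length is the longer side.

    For rasterized contours the rectangle is fitted to the convex hull of
    the pixel centers; the underlying continuous shape lies between that
    support and its Minkowski sum with the unit pixel square, so each side
    is widened by half the square's support (|cos phi| + |sin phi|)/2 at
    the fitted orientation phi.  The estimate depends only on the pixel
    set, hence is exactly equivariant under 90-degree image rotations,
    with worst-case half-pixel error per side.  Contours carrying only a
    boundary polygon use the polygon vertices directly.
    """
    raster = bool(len(contour.coords))
    if raster:
        from scipy.spatial import ConvexHull

        rc = contour.coords.astype(float)
        if len(rc) >= 3 and np.ptp(rc[:, 0]) > 0 and np.ptp(rc[:, 1]) > 0:
            pts = rc[ConvexHull(rc).vertices][:, ::-1]  # (row,col)->(x,y)
        else:
            pts = rc[:, ::-1]
    else:
        pts = contour.boundary
    rect = MultiPoint(pts).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) contour has no bounding rectangle")
    corners = np.asarray(rect.exterior.coords)[:4]
    vecs = np.diff(np.vstack([corners, corners[:1]]), axis=0)[:2]
    sides = np.hypot(*vecs.T)
    margin = 0.0
    if raster:
        phi = np.arctan2(vecs[0, 1], vecs[0, 0])
        margin = (abs(np.cos(phi)) + abs(np.sin(phi))) / 2.0
    length = float(max(sides)) + margin
    width = float(min(sides)) + margin
    if width <= 0 or not np.isfinite(length):
        raise ValueError("degenerate contour: zero-width bounding rectangle")
    return BoxGeom(length_px=length, width_px=width,
                   centroid=contour.centroid, corners=corners)


def dissect(
    sheaths: list[Contour], params: DissectionParams | None = None
) -> tuple[OrganLabels, DissectionTrace]:
    """Assign sixth / fifth / other labels to sheath contours.

    The sweep visits non-sixth contours in descending area order; ties in
    the maximal area break to the lower index.  Thresholds are strict as
    stated: ratio must exceed ``ratio_min``, centroid distance must be
    strictly below ``dist_factor`` times the sixth box length.
    """
    if params is None:
        params = DissectionParams()
    if not sheaths:
        raise ValueError("dissect requires at least one sheath contour")

    order = sorted(range(len(sheaths)), key=lambda i: (-sheaths[i].area_px, i))
    sixth_idx = order[0]
    sixth = sheaths[sixth_idx]
    c_six = np.asarray(sixth.centroid, dtype=float)
    sixth_len = bounding_geometry(sixth).length_px

    trace = DissectionTrace(C_six=tuple(c_six), sixth_length_px=sixth_len)
    fifth: list[int] = []
    other: list[int] = []
    for i in order[1:]:
        cand = sheaths[i]
        geom = bounding_geometry(cand)
        c_cdit = np.asarray(cand.centroid, dtype=float)
        d_cent = float(np.hypot(*(c_cdit - c_six)))
        if geom.lw_ratio <= params.ratio_min:
            decision = "rejected_ratio"
            other.append(i)
        elif d_cent < params.dist_factor * sixth_len:
            decision = "accepted"
            fifth.append(i)
        else:
            decision = "rejected_distance"
            other.append(i)
        trace.records.append(
            CandidateRecord(index=i, C_cdit=tuple(c_cdit), D_cent=d_cent,
                            ratio=geom.lw_ratio, decision=decision)
        )
    return OrganLabels(sixth=sixth_idx, fifth=fifth, other=other), trace
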