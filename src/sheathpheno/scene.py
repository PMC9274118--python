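"""Scene segmentation: turn a raw photograph into classified foreground objects.

A leaf-sheath photograph contains, on a near-white board, three kinds of
foreground object: a circular scale marker, a color-checker board and the
leaf sheaths themselves.  This module segments the foreground (dark objects
on a light board) with an adaptive local-mean threshold, traces the
connected components into :class:`Contour` objects, and classifies each
contour into one of the three roles using shape (circularity), inner
composition (checker grid pattern) and chromatic uniformity cues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_local

__all__ = [
    "Contour",
    "SceneObjects",
    "ScaleCalibration",
    "MissingMarkerError",
    "to_grayscale",
    "adaptive_threshold",
    "extract_components",
    "classify_scene",
    "compute_scale",
    "segment_scene",
]

#: ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


class MissingMarkerError(ValueError):
    """Raised when a scale calibration is requested but no marker was found."""


@dataclass
class Contour:
    """A single foreground component.

    ``boundary`` is a closed polygon (first vertex repeated last) of
    sub-pixel ``(x, y)`` coordinates traced around the component;
    ``coords`` are the integer ``(row, col)`` pixel coordinates of the
    component interior.  ``area_px`` is the interior pixel count and
    ``perimeter_px`` the length of the traced boundary polygon.
    """

    boundary: np.ndarray
    coords: np.ndarray
    area_px: float
    perimeter_px: float
    centroid: tuple[float, float]

    @property
    def circularity(self) -> float:
        """4*pi*area / perimeter**2; 1 for a disk, < 1 otherwise."""
        return 4.0 * np.pi * self.area_px / self.perimeter_px**2

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), max-exclusive."""
        r, c = self.coords[:, 0], self.coords[:, 1]
        return int(r.min()), int(c.min()), int(r.max()) + 1, int(c.max()) + 1

    def pixel_values(self, image: np.ndarray) -> np.ndarray:
        """Values of ``image`` at the interior pixels (n,) or (n, 3)."""
        return image[self.coords[:, 0], self.coords[:, 1]]

    def contains(self, x: float, y: float) -> bool:
        r, c = int(round(y)), int(round(x))
        return bool(np.any((self.coords[:, 0] == r) & (self.coords[:, 1] == c)))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass
class SceneObjects:
    """Classified foreground of one photograph."""

    marker: Contour | None
    checker: Contour | None
    sheaths: list[Contour]
    marker_center: tuple[float, float] | None = None
    marker_radius_px: float | None = None

    @property
    def contours(self) -> list[Contour]:
        out = list(self.sheaths)
        if self.marker is not None:
            out.append(self.marker)
        if self.checker is not None:
            out.append(self.checker)
        return out


@dataclass
class ScaleCalibration:
    """Pixel-to-physical conversion derived from the circular marker."""

    px_per_cm: float
    marker_diameter_cm: float

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass
class SegmentationConfig:
    """Tunables for the segmentation stage (JSON-serialisable)."""

    window_px: int = 101
    offset: float = 10.0
    min_area_px: float = 500.0
    circ_min: float = 0.85
    grid_min: int = 6
    marker_diameter_cm: float = 2.0
    fill_holes: bool = True
    white_balance: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) 8-bit RGB image to 8-bit luminance.

    Uses the BT.601 weights 0.299 R + 0.587 G + 0.114 B, rounded to the
    nearest integer.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {image.shape}")
    gray = np.rint(image.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def adaptive_threshold(gray: np.ndarray, window_px: int = 101, offset: float = 10.0) -> np.ndarray:
    """Dark-foreground adaptive threshold.

    A pixel is foreground iff its value is below the local mean over a
    ``window_px`` x ``window_px`` neighbourhood minus ``offset``.  Sheaths,
    marker and checker are all darker than the white board, so the
    dark-foreground convention is fixed.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("gray image must be 2-D")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > min(gray.shape):
        raise ValueError(
            f"window_px={window_px} exceeds image size {gray.shape}"
        )
    local = threshold_local(gray, block_size=window_px, method="mean", offset=offset)
    return gray < local


def extract_components(
    mask: np.ndarray, min_area_px: float = 500.0, fill_holes: bool = True
) -> list[Contour]:
    """Trace 8-connected foreground components into contours.

    Components smaller than ``min_area_px`` pixels (pins, dust) are
    dropped.  The result is sorted by area, largest first.  Hole filling
    is applied per component by default: the adaptive threshold only
    guarantees the rim of large uniform objects, and interior holes would
    corrupt area-based traits.
    """
    mask = np.asarray(mask, dtype=bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labeled = measure.label(mask, connectivity=2)
    out: list[Contour] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area_px:
            continue
        out.append(_region_to_contour(region))
    out.sort(key=lambda c: -c.area_px)
    return out


def _region_to_contour(region) -> Contour:
    rmin, cmin, rmax, cmax = region.bbox
    sub = np.pad(region.image, 1)
    rings = measure.find_contours(sub.astype(float), 0.5)
    ring = max(rings, key=len)  # outer boundary of the component
    # Douglas-Peucker at 1 px removes the rasterization staircase, whose
    # diagonal steps otherwise inflate the perimeter of smooth shapes ~5%
    ring = measure.approximate_polygon(ring, tolerance=1.0)
    # find_contours yields (row, col) in the padded frame; convert to (x, y)
    xy = np.column_stack([ring[:, 1] + cmin - 1.0, ring[:, 0] + rmin - 1.0])
    perim = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
    cy, cx = region.centroid
    return Contour(
        boundary=xy,
        coords=region.coords,
        area_px=float(region.area),
        perimeter_px=perim,
        centroid=(float(cx), float(cy)),
    )


def _interior_uniformity(contour: Contour, gray: np.ndarray) -> float:
    return float(np.std(contour.pixel_values(gray).astype(np.float64)))


def _checker_score(
    contour: Contour, gray: np.ndarray, grid_min: int, min_spread: float
) -> tuple[int, float]:
    """Best qualifying (uniform-cell count, inter-cell std) over grid splits.

    A checker board splits into cells that are individually near-uniform
    but mutually different; a plain sheath or disk fails the inter-cell
    variance requirement, a textured region fails the within-cell one.
    A grid qualifies when at least ``grid_min`` covered cells are uniform
    and the spread of their means exceeds ``min_spread``; returns (0, 0)
    when no grid qualifies.
    """
    rmin, cmin, rmax, cmax = contour.bbox
    m = contour.mask(gray.shape)
    best = (0, 0.0)
    for rows in range(2, 7):
        for cols in range(2, 7):
            redges = np.linspace(rmin, rmax, rows + 1).astype(int)
            cedges = np.linspace(cmin, cmax, cols + 1).astype(int)
            means = []
            for i in range(rows):
                for j in range(cols):
                    cell = np.s_[redges[i]: redges[i + 1], cedges[j]: cedges[j + 1]]
                    inside = m[cell]
                    if inside.size == 0 or inside.mean() < 0.9:
                        continue
                    vals = gray[cell][inside].astype(np.float64)
                    if vals.std() < 12.0:
                        means.append(vals.mean())
            if len(means) >= grid_min:
                score = (len(means), float(np.std(means)))
                if score[1] > min_spread and score > best:
                    best = score
    return best


def classify_scene(
    contours: list[Contour],
    image: np.ndarray,
    circ_min: float = 0.85,
    grid_min: int = 6,
    uniform_max_std: float = 25.0,
    checker_intercell_min_std: float = 20.0,
) -> SceneObjects:
    """Assign marker / checker / sheath roles to foreground contours.

    The marker is the most circular contour (circularity >= ``circ_min``)
    with a near-uniform interior; the checker is the contour whose bounding
    box splits into at least ``grid_min`` internally uniform grid cells with
    high inter-cell variance.  Everything else is a sheath.  Each role is
    assigned at most once; ambiguity resolves to the best score with a
    warning.
    """
    gray = to_grayscale(image)
    marker_candidates = []
    for i, c in enumerate(contours):
        if c.circularity >= circ_min and _interior_uniformity(c, gray) <= uniform_max_std:
            marker_candidates.append((c.circularity, i))
    marker_idx = None
    if marker_candidates:
        if len(marker_candidates) > 1:
            warnings.warn(
                f"{len(marker_candidates)} contours qualify as marker; "
                "keeping the most circular",
                stacklevel=2,
            )
        marker_idx = max(marker_candidates)[1]

    checker_idx = None
    checker_best = (0, 0.0)
    for i, c in enumerate(contours):
        if i == marker_idx:
            continue
        n_cells, spread = _checker_score(c, gray, grid_min,
                                         checker_intercell_min_std)
        if n_cells >= grid_min and (n_cells, spread) > checker_best:
            checker_best = (n_cells, spread)
            checker_idx = i

    marker = contours[marker_idx] if marker_idx is not None else None
    checker = contours[checker_idx] if checker_idx is not None else None
    sheaths = [c for i, c in enumerate(contours) if i not in (marker_idx, checker_idx)]

    center = radius = None
    if marker is not None:
        center = marker.centroid
        radius = float(np.sqrt(marker.area_px / np.pi))
    return SceneObjects(
        marker=marker,
        checker=checker,
        sheaths=sheaths,
        marker_center=center,
        marker_radius_px=radius,
    )


def compute_scale(scene: SceneObjects, marker_diameter_cm: float) -> ScaleCalibration:
    """Pixel density from the circular marker of known physical diameter."""
    if marker_diameter_cm <= 0:
        raise ValueError("marker_diameter_cm must be positive")
    if scene.marker is None or scene.marker_radius_px is None:
        raise MissingMarkerError("no circular marker found; traits stay in pixel units")
    return ScaleCalibration(
        px_per_cm=2.0 * scene.marker_radius_px / marker_diameter_cm,
        marker_diameter_cm=marker_diameter_cm,
    )


def white_balance(image: np.ndarray, checker: Contour) -> np.ndarray:
    """Optional white balance from the brightest near-gray checker patch."""
    px = checker.pixel_values(image).astype(np.float64)
    grayish = px[np.ptp(px, axis=1) < 30]
    if len(grayish) == 0:
        return image
    ref = grayish[grayish.sum(axis=1).argmax()]
    gains = ref.mean() / np.maximum(ref, 1.0)
    out = np.clip(image.astype(np.float64) * gains, 0, 255)
    return out.astype(np.uint8)


def segment_scene(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[SceneObjects, ScaleCalibration | None, np.ndarray]:
    """Full segmentation stage: threshold, trace, classify, calibrate.

    Returns the classified scene, the scale calibration (``None`` when the
    marker is absent — downstream traits then stay in pixel units), and the
    possibly white-balanced image used for color traits.
    """
    if config is None:
        config = SegmentationConfig()
    gray = to_grayscale(image)
    mask = adaptive_threshold(gray, config.window_px, config.offset)
    contours = extract_components(mask, config.min_area_px, config.fill_holes)
    scene = classify_scene(
        contours, image, circ_min=config.circ_min, grid_min=config.grid_min
    )
    try:
        scale = compute_scale(scene, config.marker_diameter_cm)
    except MissingMarkerError:
        warnings.warn("no marker found; traits will be reported in pixel units",
                      stacklevel=2)
        scale = None
    used = image
    if config.white_balance and scene.checker is not None:
        used = white_balance(image, scene.checker)
    return scene, scale, used
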