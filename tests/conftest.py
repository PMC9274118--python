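import numpy as np
import pytest

from sheathpheno.scene import Contour, segment_scene
from sheathpheno.simulate import default_scene_spec, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """The board-layout scene (marker + checker + 6 sheaths) with truth."""
    spec = default_scene_spec(seed=1)
    image, truth = generate_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def segmented_default(default_scene):
    _, image, _ = default_scene
    return segment_scene(image)


def synthetic_contour(center, length, width, angle_deg=0.0):
    """A Contour built directly from an exact rotated rectangle.

    Used where a test needs controlled geometry (area, centroid, box)
    without going through rasterization.
    """
    L, W = length / 2.0, width / 2.0
    local = np.array([[-L, -W], [-L, W], [L, W], [L, -W], [-L, -W]], float)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    boundary = local @ rot.T + np.asarray(center, float)
    return Contour(
        boundary=boundary,
        coords=np.empty((0, 2), dtype=int),
        area_px=float(length * width),
        perimeter_px=float(2 * (length + width)),
        centroid=(float(center[0]), float(center[1])),
    )
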