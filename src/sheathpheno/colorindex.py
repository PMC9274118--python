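"""Comprehensive vegetation color indices.

Each index maps per-pixel (R, G, B) values in [0, 255] to a scalar.  The
excess-channel family (ExG, ExR, ExB, ExGR) operates on chromatic
coordinates r = R/(R+G+B) etc.; CIVE operates on the raw 8-bit channels;
the remaining ratio indices operate on raw channels with a 0-denominator
guard that returns 0 (counted, see :data:`zero_division_count`).

The default roster of 12 indices is a registry so that alternative
formulations can be swapped in from configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["INDEX_REGISTRY", "compute_index", "index_names", "zero_division_count"]

#: running count of guarded 0-denominator evaluations (diagnostic only)
zero_division_count: int = 0


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    global zero_division_count
    den = np.asarray(den, dtype=np.float64)
    bad = den == 0
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        zero_division_count += n_bad
    out = np.divide(num, np.where(bad, 1.0, den))
    return np.where(bad, 0.0, out)


def _chromatic(R, G, B):
    total = R + G + B
    return (_safe_div(R, total), _safe_div(G, total), _safe_div(B, total))


def _exg(R, G, B):
    r, g, b = _chromatic(R, G, B)
    return 2.0 * g - r - b


def _exr(R, G, B):
    r, g, b = _chromatic(R, G, B)
    return 1.4 * r - g


def _exb(R, G, B):
    r, g, b = _chromatic(R, G, B)
    return 1.4 * b - g


def _exgr(R, G, B):
    return _exg(R, G, B) - _exr(R, G, B)


def _cive(R, G, B):
    return 0.441 * R - 0.811 * G + 0.385 * B + 18.78745


def _vari(R, G, B):
    return _safe_div(G - R, G + R - B)


def _ngrdi(R, G, B):
    return _safe_div(G - R, G + R)


def _gli(R, G, B):
    return _safe_div(2.0 * G - R - B, 2.0 * G + R + B)


def _mgrvi(R, G, B):
    return _safe_div(G**2 - R**2, G**2 + R**2)


def _rgbvi(R, G, B):
    return _safe_div(G**2 - R * B, G**2 + R * B)


def _ikaw(R, G, B):
    return _safe_div(R - B, R + B)


def _rgri(R, G, B):
    return _safe_div(R, G)


INDEX_REGISTRY: dict = {
    "ExG": _exg,
    "ExR": _exr,
    "ExB": _exb,
    "ExGR": _exgr,
    "CIVE": _cive,
    "VARI": _vari,
    "NGRDI": _ngrdi,
    "GLI": _gli,
    "MGRVI": _mgrvi,
    "RGBVI": _rgbvi,
    "IKAW": _ikaw,
    "RGRI": _rgri,
}


def index_names(registry: dict | None = None) -> list[str]:
    return list((registry or INDEX_REGISTRY).keys())


def compute_index(name: str, rgb: np.ndarray, registry: dict | None = None) -> np.ndarray:
    """Evaluate one index over an (n, 3) float array of RGB pixels."""
    registry = registry or INDEX_REGISTRY
    rgb = np.asarray(rgb, dtype=np.float64)
    R, G, B = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    return np.asarray(registry[name](R, G, B), dtype=np.float64)
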