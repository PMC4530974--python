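"""Directional edge-likelihood (gradient) maps.

Boundaries in a flattened B-scan are near-horizontal, so only two edge
orientations matter: dark-to-bright (intensity increasing with depth, e.g.
the ILM and IS-OS) and bright-to-dark (e.g. the outer RNFL boundary).  Each
orientation has a fixed 11x5 matched-filter kernel for an axial step edge:
five identical columns of ``[1,1,1,1,1,0,-1,-1,-1,-1,-1]^T`` (dark-to-bright
is the negation of bright-to-dark).  The 5-column lateral extent averages
out speckle; the zero centre row makes the response symmetric about the
transition.

After convolution, negative responses are clamped to zero and the frame is
min-max normalized to [0, 1]; a constant frame therefore yields an all-zero
gradient.  Borders are handled by edge replication so the output has the
input's shape and image borders do not produce spurious maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError

#: axial taps of the dark-to-bright kernel, top to bottom
_L_D2B = np.array([1, 1, 1, 1, 1, 0, -1, -1, -1, -1, -1], dtype=float)

ORIENTATIONS = ("dark_to_bright", "bright_to_dark")


def edge_kernel(orientation: str) -> np.ndarray:
    """Return the 11x5 convolution kernel for the given edge orientation."""
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}")
    k = np.tile(_L_D2B[:, None], (1, 5))
    return k if orientation == "dark_to_bright" else -k


@dataclass
class GradientImage:
    """A [0, 1] edge-likelihood map of one B-scan."""

    values: np.ndarray
    orientation: str


def compute_gradient(frame: np.ndarray, orientation: str) -> GradientImage:
    """Convolve a B-scan with a directional edge kernel and normalize.

    The convolution uses edge-replication padding; negative responses are
    set to zero and the whole frame is then min-max rescaled to [0, 1].
    If the clamped response is identically zero (e.g. a constant frame) the
    all-zero map is returned unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InputError("frame must be 2-D")
    if not np.isfinite(frame).all():
        raise InputError("frame intensities must be finite")
    k = edge_kernel(orientation)
    if frame.shape[0] < k.shape[0] or frame.shape[1] < k.shape[1]:
        raise InputError(
            f"frame {frame.shape} smaller than the {k.shape} edge kernel")
    g = ndimage.convolve(frame, k, mode="nearest")
    np.clip(g, 0.0, None, out=g)
    lo, hi = g.min(), g.max()
    if hi > lo:
        g = (g - lo) / (hi - lo)
    else:
        g = np.zeros_like(g)
    return GradientImage(values=g, orientation=orientation)


def normalize_columns(values: np.ndarray, region=None) -> np.ndarray:
    """Min-max rescale each column of a gradient region to [0, 1].

    Used inside restricted search regions where biasing or masking has
    reduced the dynamic range.  A constant (featureless) column maps to all
    zeros so that it does not attract the path.  With ``region`` given (an
    object with ``crop``, e.g. a search region), only that axial band of the
    image is normalized and the full-size image is returned with the band
    replaced.
    """
    if region is not None:
        values = np.array(values, dtype=float, copy=True)
        band = region.crop(values)
        values[region.z_top:region.z_bottom + 1] = normalize_columns(band)
        return values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InputError("empty region")
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(values)
    np.divide(values - lo, span, out=out, where=span > 0)
    return out
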