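"""Pre/post-processing around each graph search.

Every boundary detection follows the same recipe: flatten the frame against
a reference boundary, compute a directional gradient, restrict it to a
search region, optionally bias/mask/normalize, run the shortest-path search
on a laterally down-sampled region, then interpolate, smooth and map the
result back to raw image coordinates.  This module provides those wrapping
operations.

Flattening shifts whole A-scans (columns) by integer amounts so the
reference boundary becomes a horizontal line at the row of its deepest
point; shifts are therefore downward-or-zero and nothing is cropped off the
top.  Vacated pixels are filled by edge replication, which introduces no
artificial edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .graph_search import DEFAULT_W_MIN, shortest_path_boundary


@dataclass
class Boundary:
    """A per-frame polyline: one (fractional) axial position per column."""

    z: np.ndarray
    label: str = ""
    frame_index: int = 0

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1 or self.z.size == 0:
            raise InputError("boundary z must be a non-empty 1-D array")


@dataclass
class SearchRegion:
    """An axial band [z_top, z_bottom] (inclusive), optionally curve-bounded.

    ``col_top``/``col_bottom`` carry per-column bounds for band-mode regions;
    graph construction always uses the rectangular hull, with pixels outside
    the per-column bounds zeroed by masking.
    """

    z_top: int
    z_bottom: int
    col_top: np.ndarray | None = None
    col_bottom: np.ndarray | None = None

    def __post_init__(self):
        if not (0 <= self.z_top <= self.z_bottom):
            raise InputError(
                f"invalid search region [{self.z_top}, {self.z_bottom}]")

    @property
    def n_rows(self) -> int:
        return self.z_bottom - self.z_top + 1

    def crop(self, image: np.ndarray) -> np.ndarray:
        if self.z_bottom >= image.shape[0]:
            raise InputError("search region exceeds the frame height")
        return image[self.z_top:self.z_bottom + 1]


@dataclass
class FlattenRecord:
    """Integer per-column shifts that made a reference boundary flat."""

    shifts: np.ndarray
    target_row: int

    def apply_to(self, z: np.ndarray) -> np.ndarray:
        """Map boundary positions from raw to flattened coordinates."""
        z = np.asarray(z, dtype=float)
        if z.shape != self.shifts.shape:
            raise InputError("boundary length does not match flatten record")
        return z + self.shifts

    def invert(self, z: np.ndarray) -> np.ndarray:
        """Map boundary positions from flattened back to raw coordinates."""
        z = np.asarray(z, dtype=float)
        if z.shape != self.shifts.shape:
            raise InputError("boundary length does not match flatten record")
        return z - self.shifts


def flatten(frame: np.ndarray, reference: Boundary | np.ndarray
            ) -> tuple[np.ndarray, FlattenRecord]:
    """Shift each A-scan down so the reference boundary becomes flat.

    The target row is the rounded maximum of the reference, so every shift
    is >= 0; vacated top pixels replicate the original first row.
    """
    frame = np.asarray(frame, dtype=float)
    z_ref = reference.z if isinstance(reference, Boundary) else np.asarray(reference, float)
    if z_ref.shape[0] != frame.shape[1]:
        raise InputError("reference must be defined on every column")
    if z_ref.min() < 0 or z_ref.max() > frame.shape[0] - 1:
        raise InputError("reference boundary lies outside the frame")
    target = int(np.round(z_ref.max()))
    shifts = np.round(target - z_ref).astype(int)
    shifts[shifts < 0] = 0
    out = np.empty_like(frame)
    for x in range(frame.shape[1]):
        s = shifts[x]
        if s == 0:
            out[:, x] = frame[:, x]
        else:
            out[s:, x] = frame[:frame.shape[0] - s, x]
            out[:s, x] = frame[0, x]
    return out, FlattenRecord(shifts=shifts, target_row=target)


def unflatten_boundary(b: Boundary, rec: FlattenRecord) -> Boundary:
    """Exact inverse of flattening on boundary coordinates."""
    return Boundary(z=rec.invert(b.z), label=b.label, frame_index=b.frame_index)


def interframe_region(prev: Boundary | np.ndarray, frame_height: int,
                      margin: int = 10) -> SearchRegion:
    """Axial band around a boundary from the adjacent frame.

    Assumes adjacent-frame boundary positions differ by less than ``margin``
    pixels, so the band [min(z) - margin, max(z) + margin] (clamped to the
    image) must contain the boundary in the current frame.
    """
    z = prev.z if isinstance(prev, Boundary) else np.asarray(prev, float)
    if z.size == 0:
        raise InputError("previous boundary is empty")
    z_top = max(0, int(np.floor(z.min())) - margin)
    z_bottom = min(frame_height - 1, int(np.ceil(z.max())) + margin)
    return SearchRegion(z_top=z_top, z_bottom=z_bottom)


def intraframe_region(upper, lower, mode: str, *, height: int | None = None,
                      frame_height: int | None = None) -> SearchRegion:
    """Search region from boundaries already detected in the same frame.

    mode='rect_between_extremes': rectangle from the *lowest* point of the
    upper curve down to the *highest* point of the lower curve (scalar
    extremes, matching a rectangular ROI between two curved boundaries).
    mode='rect_below': rectangle of ``height`` rows starting at the scalar
    reference row ``upper``.
    mode='band': per-column curve bounds (rectangular hull retained for
    graph construction).
    """

    def as_z(b):
        if isinstance(b, Boundary):
            return b.z
        return np.asarray(b, dtype=float)

    if mode == "rect_below":
        if height is None or height < 1:
            raise InputError("rect_below requires a positive height")
        ref = int(np.round(np.max(as_z(upper))))
        z_bottom = ref + height - 1
        if frame_height is not None:
            z_bottom = min(z_bottom, frame_height - 1)
        return SearchRegion(z_top=ref, z_bottom=z_bottom)

    zu, zl = as_z(upper), as_z(lower)
    if mode == "rect_between_extremes":
        z_top = int(np.round(zu.max()))
        z_bottom = int(np.round(zl.min()))
        if z_bottom < z_top:
            raise InputError("upper bound lies below lower bound")
        return SearchRegion(z_top=z_top, z_bottom=z_bottom)
    if mode == "band":
        if np.any(zl < zu):
            raise InputError("upper bound lies below lower bound")
        return SearchRegion(z_top=int(np.floor(zu.min())),
                            z_bottom=int(np.ceil(zl.max())),
                            col_top=zu.copy(), col_bottom=zl.copy())
    raise InputError(f"unknown intra-frame region mode {mode!r}")


def apply_lower_bias(g_roi: np.ndarray) -> np.ndarray:
    """Multiply each row by its relative depth in the region.

    Row ``z`` (0-based) of an ``M``-row region is scaled by ``z / (M - 1)``,
    so the top row vanishes and the bottom row is unchanged.  Used to favour
    the lowest of several same-orientation edges in one region.
    """
    g_roi = np.asarray(g_roi, dtype=float)
    m = g_roi.shape[0]
    if m < 2:
        raise InputError("bias map requires at least 2 rows")
    bias = (np.arange(m) / (m - 1))[:, None]
    return g_roi * bias


def mask_relative(g_roi: np.ndarray, b, side: str, upper=None) -> np.ndarray:
    """Zero the gradient strictly on one side of a boundary (region-local z).

    ``side='below'`` zeroes pixels strictly below ``b``; ``'above'`` strictly
    above; ``'outside_pair'`` takes ``upper`` and ``b`` (the lower curve) and
    zeroes everything strictly above the upper and strictly below the lower.
    """
    g_roi = np.asarray(g_roi, dtype=float)
    rows = np.arange(g_roi.shape[0])[:, None]

    def as_z(x):
        z = x.z if isinstance(x, Boundary) else np.asarray(x, dtype=float)
        if z.shape[0] != g_roi.shape[1]:
            raise InputError("boundary length does not match the region width")
        if z.min() < 0 or z.max() > g_roi.shape[0] - 1:
            raise InputError("boundary lies outside the region")
        return z[None, :]

    if side == "below":
        keep = rows <= as_z(b)
    elif side == "above":
        keep = rows >= as_z(b)
    elif side == "outside_pair":
        if upper is None:
            raise InputError("outside_pair requires the upper boundary")
        keep = (rows >= as_z(upper)) & (rows <= as_z(b))
    else:
        raise InputError(f"unknown mask side {side!r}")
    return np.where(keep, g_roi, 0.0)


def moving_average(z: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shrinking window)."""
    if window < 1:
        raise InputError("window must be >= 1")
    if window == 1:
        return np.asarray(z, dtype=float).copy()
    z = np.asarray(z, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(z, kernel, mode="same")
    den = np.convolve(np.ones_like(z), kernel, mode="same")
    return num / den


def downsample_search_upsample(g_roi: np.ndarray, w_min: float = DEFAULT_W_MIN,
                               factor: int = 2, smooth_window: int = 5
                               ) -> np.ndarray:
    """Search on a laterally down-sampled region; interpolate and smooth.

    Keeps columns 0, factor, 2*factor, ...; runs the shortest-path search;
    linearly interpolates the detected rows back to full width (nearest-value
    extrapolation at the right edge) and applies a centered moving average.
    Returns fractional region-local axial positions, one per column.
    """
    g_roi = np.asarray(g_roi, dtype=float)
    n = g_roi.shape[1]
    factor = int(factor)
    if factor < 1:
        raise InputError("factor must be >= 1")
    if factor > 1 and n < 2 * factor:
        raise InputError("region too narrow for the down-sampling factor")
    idx = np.arange(0, n, factor)
    res = shortest_path_boundary(g_roi[:, idx], w_min)
    z = np.interp(np.arange(n), idx, res.rows.astype(float))
    return moving_average(z, smooth_window)
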