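"""Agreement statistics between two surface sets.

Errors are signed differences ``a - b`` in pixels, pooled per boundary and
overall:

* MSE — mean signed error (bias),
* SSE — standard deviation of the signed error (population, n denominator),
* MUE — mean unsigned (absolute) error,
* E95 — 95th-percentile unsigned error, taken as the order statistic at
  ``ceil(0.95 n)``: the largest unsigned error remaining after the top 5%
  of values are removed (no interpolation between order statistics).

Pixel errors convert to microns by multiplying with the axial resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import SurfaceSet


@dataclass
class BoundaryErrors:
    mse: float
    sse: float
    mue: float
    e95: float
    n: int


@dataclass
class ErrorStats:
    """Pooled and per-boundary error statistics of ``a`` versus ``b``."""

    mse: float
    sse: float
    mue: float
    e95: float
    n: int
    per_boundary: dict[str, BoundaryErrors] = field(default_factory=dict)
    axial_res_um: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lab, st in self.per_boundary.items():
            rows.append({"boundary": lab, "mse_px": st.mse, "sse_px": st.sse,
                         "mue_px": st.mue, "e95_px": st.e95, "n": st.n})
        rows.append({"boundary": "overall", "mse_px": self.mse,
                     "sse_px": self.sse, "mue_px": self.mue,
                     "e95_px": self.e95, "n": self.n})
        df = pd.DataFrame(rows)
        if self.axial_res_um is not None:
            for col in ("mse", "sse", "mue", "e95"):
                df[f"{col}_um"] = df[f"{col}_px"] * self.axial_res_um
        return df


def e95_unsigned(unsigned: np.ndarray) -> float:
    """95th-percentile unsigned error (lower empirical order statistic)."""
    unsigned = np.sort(np.asarray(unsigned, dtype=float).ravel())
    n = unsigned.size
    if n == 0:
        raise InputError("no errors to summarize")
    k = max(1, math.ceil(0.95 * n))
    return float(unsigned[k - 1])


def _stats(diff: np.ndarray) -> BoundaryErrors:
    diff = np.asarray(diff, dtype=float).ravel()
    unsigned = np.abs(diff)
    return BoundaryErrors(
        mse=float(diff.mean()),
        sse=float(diff.std()),  # population denominator
        mue=float(unsigned.mean()),
        e95=e95_unsigned(unsigned),
        n=diff.size,
    )


def _overlap(a: SurfaceSet, b: SurfaceSet):
    """Common (frame, column) window of two sets in absolute coordinates."""
    f0 = max(a.frame_offset, b.frame_offset)
    f1 = min(a.frame_offset + a.n_frames, b.frame_offset + b.n_frames)
    c0 = max(a.column_offset, b.column_offset)
    c1 = min(a.column_offset + a.n_cols, b.column_offset + b.n_cols)
    if f1 <= f0 or c1 <= c0:
        raise InputError("surface sets have disjoint grids")
    sl_a = (slice(f0 - a.frame_offset, f1 - a.frame_offset),
            slice(c0 - a.column_offset, c1 - a.column_offset))
    sl_b = (slice(f0 - b.frame_offset, f1 - b.frame_offset),
            slice(c0 - b.column_offset, c1 - b.column_offset))
    return sl_a, sl_b


def compare_surfaces(a: SurfaceSet, b: SurfaceSet) -> ErrorStats:
    """Error statistics of ``a`` against ``b`` on their common grid cells.

    Boundaries are compared by label on the intersection of the two label
    sets; differences are pooled per boundary and across all boundaries.
    """
    labels = [lab for lab in a.labels if lab in b.surfaces]
    if not labels:
        raise InputError("surface sets share no boundary labels")
    sl_a, sl_b = _overlap(a, b)
    per = {}
    pooled = []
    for lab in labels:
        diff = a.surfaces[lab][sl_a] - b.surfaces[lab][sl_b]
        per[lab] = _stats(diff)
        pooled.append(diff.ravel())
    overall = _stats(np.concatenate(pooled))
    res_a = a.axial_res_um
    return ErrorStats(mse=overall.mse, sse=overall.sse, mue=overall.mue,
                      e95=overall.e95, n=overall.n, per_boundary=per,
                      axial_res_um=res_a)
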