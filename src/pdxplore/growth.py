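"""Tumor doubling-time estimation in the exponential growth window.

Subcutaneous tumor volumes grow exponentially between roughly 200 and
400 mm^3; within that window log2(volume) is linear in time and the
doubling time Td is the reciprocal of the fitted slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DoublingTimeFit:
    td_days: float | None
    slope: float | None
    r_squared: float | None
    n_points: int
    flag: str  # "", "too_few_points", "non_positive_slope"


def doubling_time(
    times,
    volumes,
    window: tuple[float, float] = (200.0, 400.0),
    n_refine: int = 3,
) -> DoublingTimeFit:
    """Least-squares line on (t, log2 V) restricted to the volume window.

    Window membership starts from the observed volumes (bounds
    inclusive) and is then refined against the fitted curve: selecting
    points by their own noisy volume correlates measurement error with
    inclusion near the window edges and attenuates the slope, so after
    each fit membership is recomputed from the fitted volumes and the
    line refit (up to ``n_refine`` rounds, stopping at a fixed point).
    ``n_refine=0`` gives the plain observed-volume window.

    Fewer than two in-window points yields an undefined Td; a
    non-positive slope (shrinking or flat tumor) is flagged.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    lo, hi = window
    log2v = np.log2(v)
    mask = (v >= lo) & (v <= hi)
    if mask.sum() < 2:
        return DoublingTimeFit(None, None, None, int(mask.sum()), "too_few_points")
    res = stats.linregress(t[mask], log2v[mask])
    for _ in range(n_refine):
        vhat = 2.0 ** (res.intercept + res.slope * t)
        new = (vhat >= lo) & (vhat <= hi)
        if new.sum() < 2 or np.array_equal(new, mask):
            break
        mask = new
        res = stats.linregress(t[mask], log2v[mask])
    n = int(mask.sum())
    if res.slope <= 0:
        return DoublingTimeFit(None, float(res.slope), float(res.rvalue**2), n,
                               "non_positive_slope")
    return DoublingTimeFit(1.0 / res.slope, float(res.slope), float(res.rvalue**2), n, "")


def doubling_time_table(measurements: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-animal Td from a long table (mouse_id, day, volume_mm3)."""
    rows = []
    for mouse, grp in measurements.groupby("mouse_id", sort=True):
        grp = grp.sort_values("day")
        fit = doubling_time(grp["day"], grp["volume_mm3"], **kwargs)
        rows.append(
            {
                "mouse_id": mouse,
                "td_days": fit.td_days,
                "r2": fit.r_squared,
                "n_points": fit.n_points,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows, columns=["mouse_id", "td_days", "r2", "n_points", "flag"])
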