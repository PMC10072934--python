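"""Between-individual variability as a moving-window MAD per group.

For each day, all displacements of a group's individuals within a centred
3-day window are pooled and summarised by the median absolute deviation
(MAD), a robust spread measure.  A fixed-df regression spline on the log
MAD then captures the temporal trend per group, with pointwise Gaussian
95% confidence intervals, and groups are compared day-by-day through CI
overlap with a reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

from .preprocessing import DisplacementSeries, cohort_to_frame

__all__ = [
    "MAD_CONSTANT",
    "MADSeries",
    "SmoothFit",
    "moving_mad",
    "smooth_mad",
    "compare_mad",
]

#: Consistency constant making the MAD estimate the Gaussian sd; set to 1.0
#: for the raw median absolute deviation.
MAD_CONSTANT = 1.4826


@dataclass
class MADSeries:
    """Per-group moving-window MAD over day since fledging/release."""

    group: str
    day: np.ndarray
    mad_km: np.ndarray
    n_values: np.ndarray
    window_days: int
    scale_constant: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "day": self.day,
                "mad_km": self.mad_km,
                "n_values": self.n_values,
            }
        )


@dataclass
class SmoothFit:
    """Spline-smoothed MAD trend with pointwise 95% CI.

    Values are stored on the log-MAD scale; the ``*_km`` properties
    back-transform to kilometres.
    """

    group: str
    day: np.ndarray
    fit_log: np.ndarray
    ci_low_log: np.ndarray
    ci_high_log: np.ndarray
    df: int

    @property
    def fit_km(self) -> np.ndarray:
        return np.exp(self.fit_log)

    @property
    def ci_low_km(self) -> np.ndarray:
        return np.exp(self.ci_low_log)

    @property
    def ci_high_km(self) -> np.ndarray:
        return np.exp(self.ci_high_log)


def moving_mad(
    cohort: Iterable[DisplacementSeries] | pd.DataFrame,
    window_days: int = 3,
    scale_constant: float = MAD_CONSTANT,
    min_values: int = 3,
    group: Optional[str] = None,
) -> MADSeries:
    """Pooled moving-window MAD of displacement for one group.

    For each day ``t`` between the first and last observed day, all
    displacements (km) of all individuals on days ``[t-w, t+w]``
    (``w = (window_days-1)//2``) are pooled; the MAD is
    ``scale_constant * median(|x - median(x)|)``.  Windows with fewer than
    ``min_values`` pooled values are omitted.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError("window_days must be an odd integer >= 1")
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if frame.empty:
        raise ValueError("empty cohort")
    if group is None:
        groups = frame["group"].unique()
        if len(groups) != 1:
            raise ValueError(
                "cohort spans several groups; pass group= to pick one"
            )
        group = str(groups[0])
    else:
        frame = frame[frame["group"] == group]
        if frame.empty:
            raise ValueError(f"no rows for group {group!r}")
    w = (window_days - 1) // 2
    days = frame["day"].to_numpy()
    kms = frame["km"].to_numpy()
    out_day, out_mad, out_n = [], [], []
    for t in range(int(days.min()), int(days.max()) + 1):
        mask = (days >= t - w) & (days <= t + w)
        n = int(mask.sum())
        if n < min_values:
            continue
        x = kms[mask]
        med = np.median(x)
        out_day.append(t)
        out_mad.append(scale_constant * float(np.median(np.abs(x - med))))
        out_n.append(n)
    return MADSeries(
        group=group,
        day=np.asarray(out_day, dtype=int),
        mad_km=np.asarray(out_mad, dtype=float),
        n_values=np.asarray(out_n, dtype=int),
        window_days=window_days,
        scale_constant=scale_constant,
    )


def _basis(day: np.ndarray, df: int) -> np.ndarray:
    """Intercept plus ``df`` smooth basis columns (spline for df >= 3)."""
    day = np.asarray(day, dtype=float)
    if df >= 3:
        X = np.asarray(dmatrix("bs(day, df=df, degree=3) - 1",
                               {"day": day, "df": df}))
    else:
        scaled = (day - day.mean()) / max(day.std(), 1.0)
        X = np.column_stack([scaled**p for p in range(1, df + 1)])
    return np.column_stack([np.ones(len(day)), X])


def smooth_mad(mad: MADSeries, df: int = 4, floor_km: float = 1e-6) -> SmoothFit:
    """Fixed-df regression-spline smooth of log MAD with pointwise 95% CI.

    ``df`` counts smooth basis functions in addition to the intercept
    (cubic B-splines for ``df >= 3``, low-order polynomials otherwise).
    Zero MAD values are floored at ``floor_km`` before the log transform.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    n = len(mad.day)
    if n < df + 3:
        raise ValueError(f"need at least {df + 3} MAD values to smooth with df={df}")
    y = np.log(np.maximum(mad.mad_km, floor_km))
    X = _basis(mad.day, df)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    return SmoothFit(
        group=mad.group,
        day=mad.day.copy(),
        fit_log=pred["mean"].to_numpy(),
        ci_low_log=pred["mean_ci_lower"].to_numpy(),
        ci_high_log=pred["mean_ci_upper"].to_numpy(),
        df=df,
    )


def compare_mad(
    groups: Sequence[SmoothFit] | Mapping[str, SmoothFit],
    reference: str,
) -> pd.DataFrame:
    """Per-day CI overlap of each group's smoothed MAD with a reference.

    Returns a tidy frame (day, group, overlap) for the days common to the
    reference and each comparison group; raises if a group's day grid is
    disjoint from the reference's.
    """
    if isinstance(groups, Mapping):
        fits = dict(groups)
    else:
        fits = {f.group: f for f in groups}
    if reference not in fits:
        raise ValueError(f"reference group {reference!r} not among fits")
    ref = fits[reference]
    ref_idx = {int(d): i for i, d in enumerate(ref.day)}
    rows = []
    for name, f in fits.items():
        if name == reference:
            continue
        common = [d for d in f.day if int(d) in ref_idx]
        if not common:
            raise ValueError(
                f"day grids of {name!r} and reference {reference!r} are disjoint"
            )
        for d in common:
            i = int(np.nonzero(f.day == d)[0][0])
            j = ref_idx[int(d)]
            overlap = (
                f.ci_low_log[i] <= ref.ci_high_log[j]
                and f.ci_high_log[i] >= ref.ci_low_log[j]
            )
            rows.append({"day": int(d), "group": name, "overlap": bool(overlap)})
    return pd.DataFrame(rows)
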