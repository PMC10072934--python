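"""Competing performance-curve fits, BIC parsimony selection, crossings.

Five functional forms (see :mod:`ontopace.families`) are fitted to log
daily displacement versus day since fledging/release and compared by BIC.
Two objectives are supported:

``L2``
    least squares on the mean — used for individual-level curves, where
    residuals are roughly symmetric;
``L1``
    least absolute deviations on the median — used for population-level
    curves pooled across individuals, which are heavily scattered.

BIC values are only comparable within one objective.  The likelihood
behind the BIC is the Gaussian profile likelihood for L2 and the Laplace
likelihood (scale = mean absolute residual) for L1; in both cases the
scale counts as one extra parameter, uniformly across families, so the
ranking is unaffected by the convention.

The parsimony rule: among converged fits whose BIC lies within ``delta``
(default 2) of the minimum, select the one with fewest parameters,
breaking ties in the fixed order null < linear < exponential < asymptotic
< weibull4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .families import (
    FAMILY_ORDER,
    PARAM_NAMES,
    CurveParams,
    eval_curve,
)
from .preprocessing import DisplacementSeries, cohort_to_frame

__all__ = [
    "CurveFit",
    "SelectionResult",
    "CrossingResult",
    "BootstrapResult",
    "fit_curve",
    "fit_all_families",
    "compute_bic",
    "select_family",
    "crossing_time",
    "bootstrap_curve",
    "classify_individuals",
]


@dataclass
class CurveFit:
    """One family fitted to one dataset under one objective.

    ``n_params`` includes the residual scale (+1 over the curve's own
    parameter count), so ``bic == -2*log_likelihood + n_params*log(n_obs)``
    holds exactly.
    """

    family: str
    params: CurveParams
    objective: str  # "L2" or "L1"
    n_obs: int
    n_params: int
    objective_value: float  # RSS for L2, sum |resid| for L1
    log_likelihood: float
    bic: float
    converged: bool

    @property
    def theta(self) -> Tuple[float, ...]:
        return self.params.theta


@dataclass
class SelectionResult:
    """Outcome of the BIC parsimony rule over a set of fits."""

    entity: str
    fits: dict  # family -> CurveFit
    selected: str
    delta_bic: float

    @property
    def selected_fit(self) -> CurveFit:
        return self.fits[self.selected]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in FAMILY_ORDER:
            if fam not in self.fits:
                continue
            f = self.fits[fam]
            rows.append(
                {
                    "entity": self.entity,
                    "family": fam,
                    "theta": ";".join(f"{v:.10g}" for v in f.theta),
                    "n_obs": f.n_obs,
                    "bic": f.bic,
                    "converged": f.converged,
                    "selected": fam == self.selected,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CrossingResult:
    """Day on which a fitted curve first reaches a threshold displacement."""

    threshold_km: float
    crossing_day: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class BootstrapResult:
    """Percentile band of a refitted curve plus crossing-time CI."""

    day_grid: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    crossing: CrossingResult
    n_boot: int
    n_failed: int


# --------------------------------------------------------------------------
# model predictions (overflow-guarded for use inside optimizers)

def _predict(family: str, x: np.ndarray, day: np.ndarray) -> np.ndarray:
    if family == "null":
        return np.full_like(day, x[0], dtype=float)
    if family == "linear":
        return x[0] + x[1] * day
    if family == "exponential":
        return x[0] * np.exp(np.clip(x[1] * day, -700.0, 50.0))
    if family == "asymptotic":
        init, gap, k = x  # gap = plateau - init >= 0
        return init + gap * (1.0 - np.exp(np.clip(-k * day, -700.0, 0.0)))
    # weibull4 in (lower, gap, slope, inflection) coordinates, gap >= 0
    lower, gap, slope, infl = x
    z = slope * (np.log(day) - np.log(infl))
    return lower + gap * np.exp(-np.exp(np.clip(z, -700.0, 50.0)))


def _jacobian(family: str, x: np.ndarray, day: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`_predict` w.r.t. the fitting coordinates."""
    if family == "exponential":
        e = np.exp(np.clip(x[1] * day, -700.0, 50.0))
        return np.column_stack([e, x[0] * day * e])
    if family == "asymptotic":
        init, gap, k = x
        e = np.exp(np.clip(-k * day, -700.0, 0.0))
        return np.column_stack([np.ones_like(day), 1.0 - e, gap * day * e])
    # weibull4: f = lower + gap * exp(-u), u = exp(slope*(log day - log infl))
    lower, gap, slope, infl = x
    ldt = np.log(day) - np.log(infl)
    u = np.exp(np.clip(slope * ldt, -700.0, 50.0))
    eu = np.exp(-u)
    return np.column_stack(
        [
            np.ones_like(day),
            eu,
            -gap * eu * u * ldt,
            gap * eu * u * slope / infl,
        ]
    )


def _to_theta(family: str, x: np.ndarray) -> Tuple[float, ...]:
    x = tuple(float(v) for v in x)
    if family == "asymptotic":
        return (x[0], x[0] + x[1], x[2])
    if family == "weibull4":
        return (x[0], x[0] + x[1], x[2], x[3])
    return x


def _from_theta(family: str, theta: Sequence[float]) -> np.ndarray:
    theta = list(theta)
    if family == "asymptotic":
        return np.array([theta[0], theta[1] - theta[0], theta[2]])
    if family == "weibull4":
        return np.array([theta[0], theta[1] - theta[0], theta[2], theta[3]])
    return np.array(theta, dtype=float)


_BOUNDS = {
    "exponential": ([0.0, 0.0], [np.inf, np.inf]),
    "asymptotic": ([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
    "weibull4": ([-np.inf, 0.0, -np.inf, 1e-6], [np.inf, np.inf, 0.0, np.inf]),
}


# --------------------------------------------------------------------------
# self-start heuristics

def _start_exponential(day: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos = y > 0
    if pos.sum() >= 2:
        b = np.polyfit(day[pos], np.log(y[pos]), 1)
        a0, k0 = math.exp(b[1]), max(b[0], 0.0)
    else:
        a0, k0 = max(float(np.mean(y)), 1e-3), 1e-3
    return np.array([max(a0, 1e-8), k0])


def _start_asymptotic(day: np.ndarray, y: np.ndarray) -> np.ndarray:
    order = np.argsort(day)
    ds, ys = day[order], y[order]
    head = float(np.mean(ys[: max(1, len(ys) // 10)]))
    plateau0 = float(np.mean(ys[-max(1, len(ys) // 5):]))
    gap0 = max(plateau0 - head, 1e-3)
    # rate from the day the (smoothed) rise first passes 63% of the gap
    smooth = pd.Series(ys).rolling(max(3, len(ys) // 20), center=True,
                                   min_periods=1).mean().to_numpy()
    idx = np.nonzero(smooth >= head + (1.0 - math.exp(-1.0)) * gap0)[0]
    t63 = float(ds[idx[0]]) if idx.size else float(ds[-1])
    k0 = 1.0 / max(t63, 0.5)
    return np.array([head, gap0, k0])


def _start_weibull4(day: np.ndarray, y: np.ndarray) -> np.ndarray:
    order = np.argsort(day)
    ds, ys = day[order], y[order]
    m = max(1, len(ys) // 10)
    lower0 = float(np.mean(ys[:m]))
    upper0 = float(np.mean(ys[-m:]))
    gap0 = max(upper0 - lower0, 1e-3)
    # days at which a smoothed series crosses quartiles of the rise
    smooth = pd.Series(ys).rolling(max(3, len(ys) // 20), center=True,
                                   min_periods=1).mean().to_numpy()

    def _cross(q: float) -> float:
        target = lower0 + q * gap0
        idx = np.nonzero(smooth >= target)[0]
        return float(ds[idx[0]]) if idx.size else float(ds[-1])

    t50 = max(_cross(0.5), float(ds[0]) + 1e-3)
    t25, t75 = _cross(0.25), _cross(0.75)
    # Weibull fraction q at day t: q = exp(-exp(slope*(log t - log e)))
    # so slope = log(-log q) / (log t_q - log e); average the two quartiles
    slopes = []
    for q, tq in ((0.25, t25), (0.75, t75)):
        dt = math.log(max(tq, 1e-6)) - math.log(t50)
        if abs(dt) > 1e-9:
            slopes.append(math.log(-math.log(q)) / dt)
    slope0 = float(np.clip(np.mean(slopes) if slopes else -3.0, -50.0, -0.1))
    return np.array([lower0, gap0, slope0, t50])


# --------------------------------------------------------------------------
# fitting

def _series_to_xy(series) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(series, DisplacementSeries):
        return series.day.astype(float), series.log_km
    if isinstance(series, pd.DataFrame):
        return (
            series["day"].to_numpy(dtype=float),
            np.log(series["km"].to_numpy(dtype=float)),
        )
    day, logy = series
    return np.asarray(day, dtype=float), np.asarray(logy, dtype=float)


def _l2_closed_form(family: str, day: np.ndarray, y: np.ndarray):
    """Exact solutions for the families that admit them."""
    if family == "null":
        return np.array([float(np.mean(y))]), True
    if family == "linear":
        X = np.column_stack([np.ones_like(day), day])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if beta[1] < 0:  # nondecreasing constraint binds
            return np.array([float(np.mean(y)), 0.0]), True
        return beta, True
    return None, False


def _fit_l2(family: str, day: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool]:
    x, done = _l2_closed_form(family, day, y)
    if done:
        return x, True
    lo, hi = _BOUNDS[family]

    def resid(x):
        return _predict(family, x, day) - y

    starts = [
        {
            "exponential": _start_exponential,
            "asymptotic": _start_asymptotic,
            "weibull4": _start_weibull4,
        }[family](day, y)
    ]
    if family == "asymptotic":
        # deterministic rate-scaled alternatives guard against the k -> 0
        # quasi-linear ridge when the self-start underestimates the rate
        for fac in (5.0, 0.2):
            alt = starts[0].copy()
            alt[2] *= fac
            starts.append(alt)
    # multi-start: jitter the self-start (fixed sub-seeds, data-independent)
    rng = np.random.default_rng(20230412)
    n_extra = 5 if family == "weibull4" else 0
    lo_arr = np.asarray(lo, dtype=float)
    hi_arr = np.asarray(hi, dtype=float)
    for _ in range(n_extra):
        jit = starts[0] * np.exp(rng.normal(0.0, 0.3, size=len(starts[0])))
        jit = np.maximum(jit, lo_arr + 1e-9)
        jit = np.where(np.isfinite(hi_arr), np.minimum(jit, hi_arr - 1e-9), jit)
        starts.append(jit)
    best, best_obj, ok = None, np.inf, False
    for x0 in starts:
        x0 = np.maximum(x0, lo_arr + 1e-12)
        x0 = np.where(np.isfinite(hi_arr), np.minimum(x0, hi_arr), x0)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi),
                                jac=lambda x: _jacobian(family, x, day),
                                xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                max_nfev=500)
        except Exception:
            continue
        obj = 2.0 * res.cost
        if np.isfinite(obj) and obj < best_obj:
            # status 0 = iteration budget exhausted (ridge-like surfaces)
            best, best_obj, ok = res.x, obj, res.status > 0
    if best is None:
        return starts[0], False
    return best, ok


def _fit_l1(family: str, day: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool]:
    if family == "null":
        return np.array([float(np.median(y))]), True
    if family == "linear":
        from statsmodels.regression.quantile_regression import QuantReg

        X = np.column_stack([np.ones_like(day), day])
        try:
            fit = QuantReg(y, X).fit(q=0.5)
            beta = np.asarray(fit.params, dtype=float)
        except Exception:
            beta = np.array([np.median(y), 0.0])
        if beta[1] < 0:
            return np.array([float(np.median(y)), 0.0]), True
        return beta, True
    # nonlinear: polish the L2 solution under the L1 objective
    x2, ok2 = _fit_l2(family, day, y)
    lo, hi = _BOUNDS[family]
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)

    def obj(x):
        if np.any(x < lo) or np.any(x > hi):
            return np.inf
        return float(np.sum(np.abs(_predict(family, x, day) - y)))

    best, best_val, ok = x2, obj(x2), ok2
    rng = np.random.default_rng(20230413)
    starts = [x2] + [
        x2 * np.exp(rng.normal(0.0, 0.15, size=len(x2))) for _ in range(3)
    ]
    for x0 in starts:
        x0 = np.minimum(np.maximum(x0, lo + 1e-12), np.where(np.isfinite(hi), hi, x0))
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val, ok = res.x, float(res.fun), True
    return best, ok


def _loglik(objective: str, n: int, objective_value: float) -> float:
    """Profile log-likelihood; +inf sentinel for a (numerically) perfect fit."""
    if objective_value <= 1e-10:
        return np.inf
    if objective == "L2":
        return -0.5 * (n * math.log(objective_value / n) + n * (1.0 + math.log(2.0 * math.pi)))
    mae = objective_value / n
    return -0.5 * (2.0 * n * (1.0 + math.log(2.0 * mae)))


def fit_curve(series, family: str, objective: str = "L2") -> CurveFit:
    """Fit one family to a displacement series (or pooled frame).

    ``series`` may be a :class:`DisplacementSeries`, a tidy frame with
    ``day``/``km`` columns, or a ``(day, log_km)`` pair.  The response is
    log displacement.  Monotone-direction bounds are enforced; the
    ``converged`` flag is honest and non-converged fits should be excluded
    from selection.
    """
    if objective not in ("L2", "L1"):
        raise ValueError("objective must be 'L2' or 'L1'")
    if family not in PARAM_NAMES:
        raise ValueError(f"unknown family {family!r}")
    day, y = _series_to_xy(series)
    n = len(y)
    n_theta = len(PARAM_NAMES[family])
    if n < n_theta + 2:
        raise ValueError(
            f"need at least {n_theta + 2} observations to fit {family}, got {n}"
        )
    if objective == "L2":
        x, ok = _fit_l2(family, day, y)
    else:
        x, ok = _fit_l1(family, day, y)
    theta = _to_theta(family, x)
    resid = _predict(family, x, day) - y
    if objective == "L2":
        obj_val = float(np.sum(resid**2))
    else:
        obj_val = float(np.sum(np.abs(resid)))
    ll = _loglik(objective, n, obj_val)
    n_params = n_theta + 1  # + residual scale
    bic = -np.inf if np.isinf(ll) else -2.0 * ll + n_params * math.log(n)
    try:
        params = CurveParams(family, theta)
    except ValueError:
        # numerically at a constraint edge: clamp into the feasible set
        lo_arr, hi_arr = (np.asarray(b, dtype=float) for b in _BOUNDS[family])
        x = np.maximum(x, lo_arr)
        x = np.where(np.isfinite(hi_arr), np.minimum(x, hi_arr), x)
        params = CurveParams(family, _to_theta(family, x))
        ok = False
    return CurveFit(
        family=family,
        params=params,
        objective=objective,
        n_obs=n,
        n_params=n_params,
        objective_value=obj_val,
        log_likelihood=ll,
        bic=bic,
        converged=bool(ok and np.isfinite(obj_val)),
    )


def fit_all_families(series, objective: str = "L2",
                     families: Iterable[str] = FAMILY_ORDER) -> dict:
    """Fit every family, skipping those with too few observations."""
    fits = {}
    for fam in families:
        try:
            fits[fam] = fit_curve(series, fam, objective=objective)
        except ValueError:
            continue
    return fits


def compute_bic(fit: CurveFit) -> float:
    """BIC of a converged fit: ``-2 logL + n_params * log(n_obs)``.

    A perfect (zero-residual) fit returns ``-inf``, which sorts as the
    best possible fit.
    """
    if not fit.converged:
        raise ValueError("BIC is only defined for converged fits")
    ll = _loglik(fit.objective, fit.n_obs, fit.objective_value)
    if np.isinf(ll):
        return -np.inf
    return -2.0 * ll + fit.n_params * math.log(fit.n_obs)


def select_family(fits, delta: float = 2.0, entity: str = "") -> SelectionResult:
    """Apply the BIC parsimony rule to a ``family -> CurveFit`` mapping.

    Candidates are the converged fits with BIC within ``delta`` of the
    minimum; the winner has the fewest parameters, ties broken by the
    fixed simplicity order.
    """
    if isinstance(fits, dict):
        fit_map = dict(fits)
    else:
        fit_map = {f.family: f for f in fits}
    conv = {fam: f for fam, f in fit_map.items() if f.converged}
    if not conv:
        raise ValueError("no converged fits to select from")
    best_bic = min(f.bic for f in conv.values())
    if np.isinf(best_bic):  # perfect fits: candidates are exactly those
        cands = [fam for fam, f in conv.items() if np.isinf(f.bic)]
    else:
        cands = [fam for fam, f in conv.items() if f.bic <= best_bic + delta]
    cands.sort(key=lambda fam: (conv[fam].n_params, FAMILY_ORDER.index(fam)))
    return SelectionResult(entity=entity, fits=fit_map, selected=cands[0],
                           delta_bic=delta)


def crossing_time(
    fit: Union[CurveFit, CurveParams],
    threshold_km: float,
    horizon_days: float,
    resolution: float = 0.01,
) -> CrossingResult:
    """Smallest day in ``(0, horizon]`` where the curve reaches a threshold.

    Works on a fitted curve or raw parameters.  The curve is nondecreasing
    under the sign constraints, so a bracket-and-bisect search to the
    requested resolution finds the first crossing; a curve already at or
    above the threshold from day 0 crosses at the resolution step, and a
    curve never reaching it returns an absent crossing (a valid outcome).
    Ties at the threshold count as reached.
    """
    if threshold_km <= 0:
        raise ValueError("threshold_km must be > 0")
    params = fit.params if isinstance(fit, CurveFit) else fit
    target = math.log(threshold_km)
    if eval_curve(params, float(horizon_days)) < target:
        return CrossingResult(threshold_km, None)
    lo, hi = 0.0, float(horizon_days)
    if eval_curve(params, resolution) >= target:
        return CrossingResult(threshold_km, resolution)
    while hi - lo > resolution / 2.0:
        mid = 0.5 * (lo + hi)
        if eval_curve(params, mid) >= target:
            hi = mid
        else:
            lo = mid
    # hi is within resolution/2 above the true crossing and satisfies
    # f(hi) >= target, f(hi - resolution) < target
    return CrossingResult(threshold_km, min(hi, float(horizon_days)))


def bootstrap_curve(
    cohort,
    family: str,
    n_boot: int = 1000,
    resample_unit: str = "individual",
    seed: int = 0,
    objective: str = "L1",
    day_grid: Optional[np.ndarray] = None,
    threshold_km: Optional[float] = None,
    horizon_days: Optional[float] = None,
) -> BootstrapResult:
    """Percentile bootstrap band for a pooled curve fit.

    ``resample_unit='individual'`` resamples whole birds with replacement
    (a cluster bootstrap respecting within-individual dependence, the
    default for population curves); ``'row'`` resamples day-rows.  Each
    replicate refits ``family`` and is evaluated on ``day_grid``;
    non-converged replicates are dropped and counted.  If more than half
    fail, an error is raised.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if resample_unit not in ("individual", "row"):
        raise ValueError("resample_unit must be 'individual' or 'row'")
    if isinstance(cohort, DisplacementSeries):
        cohort = [cohort]
    if isinstance(cohort, pd.DataFrame):
        frame = cohort
        units = list(frame["individual"].unique())
    else:
        frame = cohort_to_frame(cohort)
        units = [s.individual for s in cohort]
    if frame.empty:
        raise ValueError("empty cohort")
    max_day = float(frame["day"].max())
    if day_grid is None:
        day_grid = np.arange(1.0, max_day + 1.0)
    day_grid = np.asarray(day_grid, dtype=float)
    if horizon_days is None:
        horizon_days = max_day
    rng = np.random.default_rng(seed)
    by_ind = {k: v for k, v in frame.groupby("individual", sort=False)}
    curves = []
    crossings = []
    n_failed = 0
    for _ in range(n_boot):
        if resample_unit == "individual":
            pick = rng.choice(len(units), size=len(units), replace=True)
            rep = pd.concat([by_ind[units[i]] for i in pick], ignore_index=True)
        else:
            idx = rng.integers(0, len(frame), size=len(frame))
            rep = frame.iloc[idx]
        try:
            fit = fit_curve(rep, family, objective=objective)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        curves.append(eval_curve(fit.params, day_grid))
        if threshold_km is not None:
            c = crossing_time(fit, threshold_km, horizon_days)
            crossings.append(np.nan if c.crossing_day is None else c.crossing_day)
    if n_failed > n_boot / 2:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{n_boot} replicates failed to "
            f"converge for family {family!r}"
        )
    arr = np.asarray(curves)
    lo_band = np.percentile(arr, 2.5, axis=0)
    hi_band = np.percentile(arr, 97.5, axis=0)
    if threshold_km is not None and crossings:
        finite = np.asarray([c for c in crossings if np.isfinite(c)])
        if finite.size:
            cross = CrossingResult(
                threshold_km,
                float(np.median(finite)),
                float(np.percentile(finite, 2.5)),
                float(np.percentile(finite, 97.5)),
            )
        else:
            cross = CrossingResult(threshold_km, None)
    else:
        cross = CrossingResult(threshold_km or np.nan, None)
    return BootstrapResult(
        day_grid=day_grid,
        band_low=lo_band,
        band_high=hi_band,
        crossing=cross,
        n_boot=n_boot,
        n_failed=n_failed,
    )


def classify_individuals(
    cohort: Sequence[DisplacementSeries],
    benchmark_km: float = 8.1,
    delta: float = 2.0,
    objective: str = "L2",
) -> pd.DataFrame:
    """Select a family and benchmark latency for every individual.

    Returns a frame with columns ``individual``, ``group``, ``family``,
    ``crossing_day`` (NaN when the fitted curve never reaches the
    benchmark before the individual's last observed day) and ``error``
    (empty when classification succeeded).  Per-individual failures are
    flagged rows, not exceptions.
    """
    rows = []
    for s in cohort:
        row = {"individual": s.individual, "group": s.group,
               "family": None, "crossing_day": np.nan, "error": ""}
        try:
            fits = fit_all_families(s, objective=objective)
            sel = select_family(fits, delta=delta, entity=s.individual)
            row["family"] = sel.selected
            horizon = float(s.day.max())
            cross = crossing_time(sel.selected_fit, benchmark_km, horizon)
            row["crossing_day"] = (
                np.nan if cross.crossing_day is None else cross.crossing_day
            )
        except (ValueError, RuntimeError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
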