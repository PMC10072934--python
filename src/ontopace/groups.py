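"""Group comparisons: 20-day window mixed model and latency tests.

Two 20-day windows summarise each bird's movement: the first 20 days after
fledging/release (``post_fledge``) and the last 20 days before migration
departure (``pre_migration``).  Log displacement in each window is
modelled as

    y_ij = beta_g(i) . [1, P1(t_ij), P2(t_ij)] + u_0i + u_1i P1(t_ij) + e_ij

with group-specific fixed quadratic day trends (P1, P2 are polynomials
orthogonalized over days 1-20), per-individual random intercepts and day
slopes whose 2x2 covariance is grouped by rearing type, and residual
variance also grouped by rearing type.  Estimation is by maximum marginal
Gaussian likelihood with the fixed effects profiled out; confidence
intervals are Wald intervals from the observed information.

Benchmark-latency distributions (days until an individual's fitted curve
first reaches the wild-bird reference displacement) are compared across
groups with a Brown-Forsythe (median-centred Levene) test for equality of
variances and a Kruskal-Wallis test for equality of medians; birds that
never reach the benchmark are counted separately and excluded from both
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve
from scipy.optimize import minimize

from .preprocessing import DisplacementSeries, cohort_to_frame

__all__ = [
    "WINDOW_DAYS",
    "build_windows",
    "WindowModelFit",
    "fit_window_model",
    "LatencyTestResult",
    "latency_tests",
]

WINDOW_DAYS = 20
WINDOWS = ("post_fledge", "pre_migration")


def build_windows(
    cohort: Iterable[DisplacementSeries] | pd.DataFrame,
    migration_days: Mapping[str, int],
    min_days: int = 9,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Slice each individual's series into the two 20-day windows.

    ``migration_days`` maps individual to the day index of migration
    departure.  The ``post_fledge`` window covers days ``1..window_days``
    and ``pre_migration`` the ``window_days`` days ending at departure,
    re-indexed so ``window_day`` runs 1..20 in both.  For short stays the
    two windows may overlap; both slices are kept.  Individuals observed
    on fewer than ``min_days`` days in a window are excluded from that
    window (independently per window); individuals without a migration
    date are excluded from ``pre_migration`` with a warning.

    Returns a tidy frame with columns ``individual``, ``group``,
    ``window``, ``window_day``, ``day``, ``log_km``.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    rows = []
    for ind, sub in frame.groupby("individual", sort=False):
        group = str(sub["group"].iloc[0])
        day = sub["day"].to_numpy()
        log_km = np.log(sub["km"].to_numpy())
        post = (day >= 1) & (day <= window_days)
        if post.sum() >= min_days:
            rows.append(
                pd.DataFrame(
                    {
                        "individual": str(ind),
                        "group": group,
                        "window": "post_fledge",
                        "window_day": day[post],
                        "day": day[post],
                        "log_km": log_km[post],
                    }
                )
            )
        if str(ind) not in migration_days:
            warnings.warn(f"individual {ind!r}: no migration date; "
                          "excluded from pre_migration window")
            continue
        mday = int(migration_days[str(ind)])
        pre = (day > mday - window_days) & (day <= mday)
        if pre.sum() >= min_days:
            rows.append(
                pd.DataFrame(
                    {
                        "individual": str(ind),
                        "group": group,
                        "window": "pre_migration",
                        "window_day": day[pre] - (mday - window_days),
                        "day": day[pre],
                        "log_km": log_km[pre],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["individual", "group", "window", "window_day", "day", "log_km"]
        )
    return pd.concat(rows, ignore_index=True)


def _orth_poly_transform(window_days: int = WINDOW_DAYS) -> np.ndarray:
    """3x3 matrix C such that [1, t, t^2] @ C gives orthonormal P0, P1, P2."""
    t = np.arange(1, window_days + 1, dtype=float)
    V = np.column_stack([np.ones_like(t), t, t * t])
    Q, _ = np.linalg.qr(V)
    # sign convention: P1 increasing, P2 positive at the ends
    for j in range(3):
        if Q[-1, j] < Q[0, j]:
            Q[:, j] *= -1.0
    C, *_ = np.linalg.lstsq(V, Q, rcond=None)
    return C


@dataclass
class WindowModelFit:
    """ML estimates of the group x time^2 heteroscedastic mixed model."""

    window: str
    groups: Tuple[str, ...]
    beta: pd.Series  # fixed effects, named "<group>:<P0|P1|P2>"
    cov_beta: np.ndarray
    psi: Dict[str, np.ndarray]  # per-group 2x2 random-effect covariance
    sigma: Dict[str, float]  # per-group residual sd
    sigma_ci: Dict[str, Tuple[float, float]]
    group_means: pd.DataFrame  # group, mean_km, ci_low_km, ci_high_km
    log_likelihood: float
    converged: bool
    intercept_only_refit: bool
    n_individuals: Dict[str, int]


def _nll_and_beta(theta: np.ndarray, blocks, groups, p_fixed,
                  intercept_only: bool):
    """Profile negative log likelihood; returns (nll, beta, XtVinvX).

    ``blocks`` groups individuals sharing a (group, day-pattern) so the
    20x20 covariance is factored once per block: each block is
    ``(group, X, Z, Y)`` with ``Y`` holding one column per individual.
    """
    psi = {}
    sig2 = {}
    for gi, g in enumerate(groups):
        a, b, c, ls = theta[4 * gi: 4 * gi + 4]
        if intercept_only:
            L = np.array([[np.exp(a), 0.0], [0.0, 1e-8]])
        else:
            L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        psi[g] = L @ L.T
        sig2[g] = np.exp(2.0 * ls)
    XtVX = np.zeros((p_fixed, p_fixed))
    XtVy = np.zeros(p_fixed)
    logdet_sum = 0.0
    n_total = 0
    cache = []
    for g, X, Z, Y in blocks:
        m = Y.shape[1]
        V = Z @ psi[g] @ Z.T + sig2[g] * np.eye(Z.shape[0])
        try:
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet_sum += m * 2.0 * float(np.sum(np.log(np.diag(cf))))
        Vi_X = cho_solve((cf, True), X)
        Vi_Y = cho_solve((cf, True), Y)
        XtVX += m * (X.T @ Vi_X)
        XtVy += X.T @ Vi_Y.sum(axis=1)
        n_total += Y.size
        cache.append((X, Y, Vi_Y, cf))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = 0.0
    for X, Y, Vi_Y, cf in cache:
        R = Y - (X @ beta)[:, None]
        quad += float(np.sum(R * cho_solve((cf, True), R)))
    nll = 0.5 * (logdet_sum + quad + n_total * np.log(2.0 * np.pi))
    return nll, beta, XtVX


def fit_window_model(
    data: pd.DataFrame,
    window: str,
    window_days: int = WINDOW_DAYS,
) -> WindowModelFit:
    """Fit the heteroscedastic random-slope model to one window's data.

    Requires at least two groups with at least three individuals each.
    On a singular random-effect covariance or failed optimisation, the
    model is re-fitted with intercept-only random effects and flagged.
    Group mean daily displacement over the window (back-transformed km) is
    the day-average of the fitted group curve, with a delta-method 95% CI.
    """
    sub = data[data["window"] == window]
    if sub.empty:
        raise ValueError(f"no rows for window {window!r}")
    groups = tuple(sorted(sub["group"].unique()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = sub.groupby("group")["individual"].nunique()
    if (counts < 3).any():
        raise ValueError("need at least 3 individuals per group")
    C = _orth_poly_transform(window_days)

    def poly(t: np.ndarray) -> np.ndarray:
        V = np.column_stack([np.ones_like(t), t, t * t])
        return V @ C  # columns P0, P1, P2

    G = len(groups)
    p_fixed = 3 * G
    n_ind: Dict[str, int] = {g: 0 for g in groups}
    by_pattern: Dict[tuple, list] = {}
    for (ind, g), d in sub.groupby(["individual", "group"], sort=False):
        t = d["window_day"].to_numpy(dtype=float)
        key = (g, tuple(t))
        by_pattern.setdefault(key, []).append(d["log_km"].to_numpy(dtype=float))
        n_ind[g] += 1
    blocks = []
    for (g, t_key), ys in by_pattern.items():
        t = np.asarray(t_key, dtype=float)
        P = poly(t)
        X = np.zeros((len(t), p_fixed))
        gi = groups.index(g)
        X[:, 3 * gi: 3 * gi + 3] = P
        Z = P[:, :2]  # random intercept + orthogonal linear slope
        blocks.append((g, X, Z, np.column_stack(ys)))

    resid = sub["log_km"] - sub.groupby("individual")["log_km"].transform("mean")
    pooled_sd = float(resid.std())
    if not np.isfinite(pooled_sd) or pooled_sd <= 0:
        pooled_sd = 0.5
    x0 = np.tile([np.log(0.5), 0.0, np.log(0.1), np.log(max(pooled_sd, 0.05))], G)

    def run(intercept_only: bool):
        res = minimize(
            lambda th: _nll_and_beta(th, blocks, groups, p_fixed,
                                     intercept_only)[0],
            x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res

    intercept_only = False
    res = run(False)
    if not np.isfinite(res.fun):
        intercept_only = True
        res = run(True)
        if not np.isfinite(res.fun):
            raise RuntimeError("window model failed to converge; "
                               f"gradient norm {np.linalg.norm(res.jac):.3g}")
    nll, beta, XtVX = _nll_and_beta(res.x, blocks, groups, p_fixed,
                                    intercept_only)
    cov_beta = np.linalg.inv(XtVX)
    psi, sigma = {}, {}
    for gi, g in enumerate(groups):
        a, b, c, ls = res.x[4 * gi: 4 * gi + 4]
        if intercept_only:
            L = np.array([[np.exp(a), 0.0], [0.0, 0.0]])
        else:
            L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        psi[g] = L @ L.T
        sigma[g] = float(np.exp(ls))

    # Wald CI for log sigma_g from the observed information of the profile
    # likelihood over the variance parameters (finite differences)
    sigma_ci = {}
    try:
        H = _fd_hessian(
            lambda th: _nll_and_beta(th, blocks, groups, p_fixed,
                                     intercept_only)[0],
            res.x,
        )
        cov_theta = np.linalg.pinv(H)
        for gi, g in enumerate(groups):
            i = 4 * gi + 3
            se = float(np.sqrt(max(cov_theta[i, i], 0.0)))
            ls = res.x[i]
            sigma_ci[g] = (float(np.exp(ls - 1.96 * se)),
                           float(np.exp(ls + 1.96 * se)))
    except Exception:
        sigma_ci = {g: (np.nan, np.nan) for g in groups}

    # group mean over the window, back-transformed, delta-method CI
    t_grid = np.arange(1, window_days + 1, dtype=float)
    P_grid = poly(t_grid)
    mean_rows = []
    for gi, g in enumerate(groups):
        Xg = np.zeros((window_days, p_fixed))
        Xg[:, 3 * gi: 3 * gi + 3] = P_grid
        mu = Xg @ beta
        m = float(np.mean(np.exp(mu)))
        grad = (np.exp(mu)[:, None] * Xg).mean(axis=0)
        se = float(np.sqrt(max(grad @ cov_beta @ grad, 0.0)))
        mean_rows.append(
            {"group": g, "mean_km": m,
             "ci_low_km": m - 1.96 * se, "ci_high_km": m + 1.96 * se}
        )

    names = [f"{g}:P{j}" for g in groups for j in range(3)]
    return WindowModelFit(
        window=window,
        groups=groups,
        beta=pd.Series(beta, index=names),
        cov_beta=cov_beta,
        psi=psi,
        sigma=sigma,
        sigma_ci=sigma_ci,
        group_means=pd.DataFrame(mean_rows),
        log_likelihood=float(-nll),
        converged=bool(res.success),
        intercept_only_refit=intercept_only,
        n_individuals=n_ind,
    )


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


@dataclass
class LatencyTestResult:
    """Group comparison of days-to-benchmark distributions."""

    per_group: pd.DataFrame  # group, n, n_never, median, range, variance
    levene_F: float
    levene_p: float
    kruskal_H: float
    kruskal_p: float


def latency_tests(latencies: pd.DataFrame) -> LatencyTestResult:
    """Brown-Forsythe and Kruskal-Wallis tests on benchmark latencies.

    ``latencies`` has columns ``individual``, ``group``, ``days`` (NaN for
    birds that never reached the benchmark; these are counted per group
    and excluded from both tests).  Groups left with fewer than two finite
    latencies are dropped with a warning.
    """
    samples, rows = [], []
    for g, sub in latencies.groupby("group", sort=True):
        days = sub["days"].to_numpy(dtype=float)
        finite = days[np.isfinite(days)]
        rows.append(
            {
                "group": g,
                "n": int(finite.size),
                "n_never": int(np.sum(~np.isfinite(days))),
                "median": float(np.median(finite)) if finite.size else np.nan,
                "range": float(np.ptp(finite)) if finite.size else np.nan,
                "variance": float(np.var(finite, ddof=1)) if finite.size > 1 else np.nan,
            }
        )
        if finite.size >= 2:
            samples.append(finite)
        else:
            warnings.warn(f"group {g!r}: fewer than 2 finite latencies; dropped")
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 finite latencies")
    if all(np.array_equal(s, samples[0]) for s in samples[1:]):
        # identical groups: zero spread difference, no evidence either way
        lev_F, lev_p = 0.0, 1.0
    else:
        lev_F, lev_p = stats.levene(*samples, center="median")
    try:
        kw_H, kw_p = stats.kruskal(*samples)
    except ValueError:  # every observation identical: no rank information
        kw_H, kw_p = 0.0, 1.0
    return LatencyTestResult(
        per_group=pd.DataFrame(rows),
        levene_F=float(lev_F),
        levene_p=float(lev_p),
        kruskal_H=float(kw_H),
        kruskal_p=float(kw_p),
    )
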