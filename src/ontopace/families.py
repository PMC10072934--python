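"""Performance-curve families on the log-displacement scale.

Five competing functional forms describe how log daily maximum displacement
(log km) changes with day since fledging/release:

``null``
    constant ``c`` — no change in performance.
``linear``
    ``a + b*day`` — steady improvement.
``exponential``
    ``a * exp(k*day)`` — slow start, accelerating improvement.
``asymptotic``
    ``plateau - (plateau - init) * exp(-k*day)`` — monomolecular
    rise-to-limit: fast early gains that level off.
``weibull4``
    ``lower + (upper - lower) * exp(-exp(slope*(log(day) - log(inflection))))``
    — a type-1 Weibull sigmoid: a delay, then rapid improvement, then a
    plateau.  With the convention ``slope < 0`` the curve increases from
    ``lower`` (the ``day -> 0`` limit) to ``upper``.

All families are nondecreasing in ``day`` under the sign constraints
enforced by :class:`CurveParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "FAMILY_ORDER",
    "CurveParams",
    "eval_curve",
    "n_params",
]

#: Fixed family order, simplest first; also the tie-break order in selection.
FAMILY_ORDER: Tuple[str, ...] = (
    "null",
    "linear",
    "exponential",
    "asymptotic",
    "weibull4",
)

PARAM_NAMES = {
    "null": ("c",),
    "linear": ("a", "b"),
    "exponential": ("a", "k"),
    "asymptotic": ("init", "plateau", "k"),
    "weibull4": ("lower", "upper", "slope", "inflection_day"),
}

FAMILIES = tuple(PARAM_NAMES)


def n_params(family: str) -> int:
    """Number of curve parameters of *family* (excluding any scale)."""
    return len(PARAM_NAMES[family])


@dataclass(frozen=True)
class CurveParams:
    """A curve family together with its parameter vector.

    Parameters are on the log-km response scale where they describe levels
    (``c``, ``a`` of the linear family, ``init``/``plateau``,
    ``lower``/``upper``); rates (``b``, ``k``) are per day and
    ``inflection_day`` is in days.

    Raises
    ------
    ValueError
        If the family is unknown, the parameter count does not match, a
        parameter is non-finite, or the sign constraints that guarantee a
        nondecreasing curve are violated (``b >= 0``, ``k >= 0``,
        ``a >= 0`` for the exponential, ``plateau >= init``,
        ``upper >= lower``, ``slope <= 0``, ``inflection_day > 0``).
    """

    family: str
    theta: Tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.family not in PARAM_NAMES:
            raise ValueError(f"unknown curve family {self.family!r}")
        theta = tuple(float(v) for v in self.theta)
        object.__setattr__(self, "theta", theta)
        names = PARAM_NAMES[self.family]
        if len(theta) != len(names):
            raise ValueError(
                f"{self.family} expects {len(names)} parameters "
                f"{names}, got {len(theta)}"
            )
        if not all(np.isfinite(theta)):
            raise ValueError(f"non-finite parameters for {self.family}: {theta}")
        p = dict(zip(names, theta))
        if self.family == "linear" and p["b"] < 0:
            raise ValueError("linear slope b must be >= 0 for a nondecreasing curve")
        if self.family == "exponential" and (p["a"] < 0 or p["k"] < 0):
            raise ValueError("exponential requires a >= 0 and k >= 0")
        if self.family == "asymptotic":
            if p["k"] < 0:
                raise ValueError("asymptotic rate k must be >= 0")
            if p["plateau"] < p["init"]:
                raise ValueError("asymptotic requires plateau >= init")
        if self.family == "weibull4":
            if p["upper"] < p["lower"]:
                raise ValueError("weibull4 requires upper >= lower")
            if p["slope"] > 0:
                raise ValueError(
                    "weibull4 slope must be <= 0 (increasing-sigmoid convention)"
                )
            if p["inflection_day"] <= 0:
                raise ValueError("weibull4 inflection_day must be > 0")

    @property
    def named(self) -> dict:
        """Parameters as a ``name -> value`` mapping."""
        return dict(zip(PARAM_NAMES[self.family], self.theta))

    def __iter__(self):
        return iter(self.theta)


def eval_curve(params: CurveParams, day) -> np.ndarray | float:
    """Evaluate the curve at ``day`` (scalar or array, days >= 0).

    Returns log displacement (log km).  The weibull4 family takes its
    continuous ``day -> 0`` limit (``lower`` under the ``slope < 0``
    convention), so day 0 is well defined for every family.
    """
    day_arr = np.asarray(day, dtype=float)
    if np.any(day_arr < 0):
        raise ValueError("day must be >= 0")
    t = params.theta
    if params.family == "null":
        out = np.full_like(day_arr, t[0])
    elif params.family == "linear":
        out = t[0] + t[1] * day_arr
    elif params.family == "exponential":
        out = t[0] * np.exp(t[1] * day_arr)
    elif params.family == "asymptotic":
        init, plateau, k = t
        out = plateau - (plateau - init) * np.exp(-k * day_arr)
    else:  # weibull4
        lower, upper, slope, infl = t
        out = np.empty_like(day_arr)
        pos = day_arr > 0
        with np.errstate(over="ignore"):
            z = np.exp(slope * (np.log(day_arr[pos]) - np.log(infl)))
        out[pos] = lower + (upper - lower) * np.exp(-z)
        # day -> 0+ limit: slope < 0 sends the inner exponent to +inf,
        # hence exp(-inf) -> 0 and the curve starts at `lower`;
        # slope == 0 degenerates to the constant lower + (upper-lower)/e.
        limit = lower if slope < 0 else lower + (upper - lower) * np.exp(-1.0)
        out[~pos] = limit
    if np.isscalar(day) or np.ndim(day) == 0:
        return float(out)
    return out
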