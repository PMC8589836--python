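"""Hetero-pentamer composition statistics and coordination activity models.

When a ring motor assembles from a pool containing a fraction ``p`` of
ATPase-dead monomers, the number of active subunits per motor is binomial:
f(k, p) = C(n, k) (1-p)^k p^(n-k).  Under the assumption that packaging
requires at least ``k_min`` active subunits and that each active subunit
contributes 1/n of the total activity, the predicted ensemble activity
(normalised to the undoped condition) is

    Activity(k_min, p) = (1/n) * sum_{k = k_min}^{n} k f(k, p).

``k_min = 1`` is a completely uncoordinated motor (activity = 1 - p),
``k_min = n`` a strictly coordinated one (activity = (1-p)^n).  Observed
activities are assumed pre-normalised to the p = 0 condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "ActivityCurve",
    "KminFitResult",
    "DegenerateDesignError",
    "composition_pmf",
    "doping_fraction",
    "predicted_activity",
    "activity_curve",
    "fit_kmin",
]


class DegenerateDesignError(ValueError):
    """Raised when observations span a single doping fraction."""


@dataclass
class ActivityCurve:
    doping_grid: np.ndarray
    activity: np.ndarray
    k_min: int


@dataclass
class KminFitResult:
    k_min: int
    residual_sums: dict[int, float]
    n_subunits: int


def composition_pmf(doping_p: float, n: int = 5) -> np.ndarray:
    """Probability vector over k = 0..n ACTIVE subunits at inactive fraction p."""
    if not 0.0 <= doping_p <= 1.0:
        raise ValueError("doping_p must be in [0, 1]")
    return binom.pmf(np.arange(n + 1), n, 1.0 - doping_p)


def doping_fraction(inactive_amount: float, active_amount: float) -> float:
    """Per-subunit inactive probability from molar amounts in the assembly pool."""
    if inactive_amount < 0 or active_amount < 0:
        raise ValueError("amounts must be non-negative")
    total = inactive_amount + active_amount
    if total == 0:
        raise ValueError("at least one amount must be positive")
    return inactive_amount / total


def predicted_activity(k_min: int, doping_p, n: int = 5):
    """Normalised ensemble activity when >= k_min active subunits are required."""
    if not 1 <= k_min <= n:
        raise ValueError("k_min must be in [1, n]")
    p = np.asarray(doping_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("doping_p must be in [0, 1]")
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, 1.0 - p[..., None])
    contrib = np.where(k >= k_min, k, 0)
    act = np.sum(contrib * pmf, axis=-1) / n
    return float(act) if act.ndim == 0 else act


def activity_curve(k_min: int, doping_grid=None, n: int = 5) -> ActivityCurve:
    grid = np.linspace(0.0, 1.0, 101) if doping_grid is None else np.asarray(doping_grid, float)
    return ActivityCurve(grid, predicted_activity(k_min, grid, n), k_min)


def fit_kmin(observations, n: int = 5) -> KminFitResult:
    """Least-squares selection of the coordination level from activity data.

    ``observations`` is a sequence of (doping_fraction, normalised activity)
    pairs.  Ties in residual sum break toward larger k_min (the more
    coordinated model).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 2:
        raise ValueError("need >= 2 (doping, activity) observations")
    p, a = obs[:, 0], obs[:, 1]
    if np.unique(p).size < 2:
        raise DegenerateDesignError("observations span a single doping fraction")

    residual_sums: dict[int, float] = {}
    best_k, best_rss = None, np.inf
    for k_min in range(1, n + 1):
        rss = float(np.sum((a - predicted_activity(k_min, p, n)) ** 2))
        residual_sums[k_min] = rss
        if rss <= best_rss:  # <= so equal fits prefer the larger k_min
            best_k, best_rss = k_min, rss
    return KminFitResult(best_k, residual_sums, n)
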