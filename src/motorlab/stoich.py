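"""Photobleaching step counting and binomial stoichiometry inference.

The number of dye-labelled subunits per motor is read out by counting
discrete downward photobleaching steps in donor-channel intensity
trajectories.  Traces are first smoothed with an edge-preserving nonlinear
forward-backward filter, then segmented into a piecewise-constant staircase
by penalized changepoint detection, and the pooled per-trace step counts
are fitted with a (optionally zero-truncated) binomial model

    s(k) = C(n, k) p^k (1-p)^(n-k)

over candidate ring sizes n, where p is the labelling efficiency.  The n
maximising the likelihood is the inferred stoichiometry; candidates smaller
than any observed count are infeasible and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import binom, chi2

__all__ = [
    "FilterParams",
    "StepCountResult",
    "BinomialFitResult",
    "NoFeasibleModelError",
    "nonlinear_fb_filter",
    "filter_intensity_matrix",
    "count_steps",
    "count_steps_dataset",
    "binomial_pmf",
    "zero_truncated_binomial_pmf",
    "fit_binomial_stoichiometry",
    "stoichiometry_report",
]

DEFAULT_CANDIDATE_N = (3, 4, 5, 6, 7, 8)


class NoFeasibleModelError(ValueError):
    """Raised when every candidate stoichiometry is excluded by the data."""


@dataclass(frozen=True)
class FilterParams:
    """Nonlinear forward-backward filter parameters.

    ``window_count`` is the base predictor window (frames), ``bank_size``
    the number of window sizes in each predictor bank (windows
    window_count * 2^i), and ``weight_exponent`` the power applied to the
    inverse prediction variance when mixing predictors.
    """

    window_count: int = 4
    bank_size: int = 3
    weight_exponent: int = 20

    def __post_init__(self) -> None:
        if min(self.window_count, self.bank_size, self.weight_exponent) < 1:
            raise ValueError("all filter parameters must be positive integers")

    @property
    def max_window(self) -> int:
        return self.window_count * 2 ** (self.bank_size - 1)


@dataclass
class StepCountResult:
    n_steps: int
    step_times: np.ndarray
    step_amplitudes: np.ndarray
    trace_id: str = ""
    segment_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    unit_amplitude: float = float("nan")  # fitted single-bleach step size


@dataclass
class BinomialFitResult:
    n_hat: int
    p_hat: float
    per_n_statistic: dict[int, dict]
    truncated: bool


# ---------------------------------------------------------------------------
# Nonlinear forward-backward filter
# ---------------------------------------------------------------------------

def _running_past_mean(y: np.ndarray, w: int) -> np.ndarray:
    """Mean of up to ``w`` samples strictly before each index (2-D, last axis)."""
    n = y.shape[-1]
    csum = np.concatenate([np.zeros(y.shape[:-1] + (1,)), np.cumsum(y, axis=-1)], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    counts = np.maximum(idx - lo, 1)
    mean = (csum[..., idx] - csum[..., lo]) / counts
    mean[..., 0] = y[..., 0]  # no past at the first frame
    return mean


def filter_intensity_matrix(Y: np.ndarray, params: FilterParams = FilterParams()) -> np.ndarray:
    """Apply the nonlinear forward-backward filter along the last axis.

    Each point is predicted by banks of forward (past) and backward
    (future) running means with window sizes window_count * 2^i.  Predictor
    weights are the mean squared prediction error over each predictor's own
    window raised to ``-weight_exponent``, so in flat regions all
    predictors contribute while at a step the predictors that straddle the
    edge are suppressed, preserving edge position.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[-1]
    if n <= 2 * params.max_window:
        raise ValueError("trace shorter than twice the maximum filter window")
    windows = [params.window_count * 2**i for i in range(params.bank_size)]

    preds, errs = [], []
    for w in windows:
        fwd = _running_past_mean(Y, w)
        bwd = _running_past_mean(Y[..., ::-1], w)[..., ::-1]
        preds.extend([fwd, bwd])
        # mean squared prediction residual over the predictor's own window
        errs.append(_running_past_mean((Y - fwd) ** 2, w))
        errs.append(_running_past_mean(((Y - bwd) ** 2)[..., ::-1], w)[..., ::-1])
    preds = np.stack(preds)
    errs = np.stack(errs)

    tiny = 1e-12 * max(float(np.var(Y)), 1e-30)
    log_w = -params.weight_exponent * np.log(errs + tiny)
    log_w -= logsumexp(log_w, axis=0, keepdims=True)
    return np.sum(np.exp(log_w) * preds, axis=0)


def nonlinear_fb_filter(trace, params: FilterParams = FilterParams()):
    """Edge-preserving smoothing of one intensity trace (same length and grid)."""
    from .synth import IntensityTrace

    smoothed = filter_intensity_matrix(trace.intensities[None, :], params)[0]
    return IntensityTrace(trace.times, smoothed, trace.channel, trace.trace_id)


# ---------------------------------------------------------------------------
# Step counting
# ---------------------------------------------------------------------------

def _binary_segmentation(y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Changepoint indices by recursive binary splitting of the L2 cost."""
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def sse(i: int, j: int) -> float:
        s = csum[j] - csum[i]
        return csum2[j] - csum2[i] - s * s / (j - i)

    changepoints: list[int] = []
    stack = [(0, y.size)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_size:
            continue
        ks = np.arange(i + min_size, j - min_size + 1)
        s_l = csum[ks] - csum[i]
        s_r = csum[j] - csum[ks]
        sse_l = csum2[ks] - csum2[i] - s_l**2 / (ks - i)
        sse_r = csum2[j] - csum2[ks] - s_r**2 / (j - ks)
        gains = sse(i, j) - sse_l - sse_r
        best = int(np.argmax(gains))
        if gains[best] > penalty:
            k = int(ks[best])
            changepoints.append(k)
            stack.append((i, k))
            stack.append((k, j))
    return sorted(changepoints)


def _refine_boundaries(y: np.ndarray, bounds: list[int], min_size: int, sweeps: int = 3) -> list[int]:
    """Coordinate-descent polish of changepoint positions.

    Greedy binary splitting can misplace a boundary between two nearby
    steps, leaving a segment that mixes two levels; each sweep re-optimizes
    every internal boundary between its neighbours at fixed segment count.
    """
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y**2)])
    bounds = list(bounds)
    for _ in range(sweeps):
        moved = False
        for b in range(1, len(bounds) - 1):
            i, j = bounds[b - 1], bounds[b + 1]
            ks = np.arange(i + min_size, j - min_size + 1)
            if ks.size == 0:
                continue
            s_l = csum[ks] - csum[i]
            s_r = csum[j] - csum[ks]
            sse = (
                csum2[ks] - csum2[i] - s_l**2 / (ks - i)
                + csum2[j] - csum2[ks] - s_r**2 / (j - ks)
            )
            k_best = int(ks[np.argmin(sse)])
            if k_best != bounds[b]:
                bounds[b] = k_best
                moved = True
        if not moved:
            break
    return bounds


def count_steps(
    trace,
    min_amplitude: float,
    penalty: float | None = None,
    min_segment_frames: int = 2,
    unit_amplitude: float | None = None,
) -> StepCountResult:
    """Count downward photobleaching steps in a (raw or filtered) trace.

    The trace is segmented into a piecewise-constant staircase; adjacent
    segments whose mean difference is upward or smaller than
    ``min_amplitude`` are merged, leaving monotone-decreasing levels.
    Segment levels are then snapped to an integer ladder of a common unit
    amplitude, so labels bleaching within the same frame window (one
    transition of twice the unit drop) are counted as two steps.  When the
    dataset-wide single-bleach amplitude is known (``unit_amplitude``, see
    :func:`count_steps_dataset`), the ladder is constrained near it, which
    resolves ladders that a single noisy level would otherwise alias.  The
    default penalty assumes frame-independent noise, i.e. a raw trace;
    pass an explicit penalty when counting on filter output, whose
    residual noise is correlated between frames.
    """
    if min_amplitude <= 0:
        raise ValueError("min_amplitude must be positive")
    y = np.asarray(trace.intensities, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if penalty is None:
        # BIC-style penalty from the robust frame-to-frame noise scale;
        # appropriate for raw traces whose noise is independent per frame
        sigma = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2.0)
        penalty = max(2.0 * sigma**2 * np.log(y.size), 1e-12)

    bounds = [0] + _binary_segmentation(y, penalty, min_segment_frames) + [y.size]
    bounds = _refine_boundaries(y, bounds, min_segment_frames)
    means = [float(np.mean(y[i:j])) for i, j in zip(bounds[:-1], bounds[1:])]
    lengths = [j - i for i, j in zip(bounds[:-1], bounds[1:])]

    # merge until all transitions are downward steps of at least min_amplitude
    while len(means) > 1:
        diffs = np.diff(means)  # negative = downward
        worst = int(np.argmax(diffs))  # least-downward transition
        if diffs[worst] <= -min_amplitude:
            break
        n_l, n_r = lengths[worst], lengths[worst + 1]
        means[worst] = (means[worst] * n_l + means[worst + 1] * n_r) / (n_l + n_r)
        lengths[worst] = n_l + n_r
        del means[worst + 1], lengths[worst + 1]
        del bounds[worst + 1]
    if len(bounds) > 2:
        bounds = _refine_boundaries(y, bounds, min_segment_frames)
        means = [float(np.mean(y[i:j])) for i, j in zip(bounds[:-1], bounds[1:])]
        lengths = [j - i for i, j in zip(bounds[:-1], bounds[1:])]

    drops = -np.diff(means)
    step_idx = np.array(bounds[1:-1], dtype=int)
    levels, unit = _fit_intensity_ladder(
        np.asarray(means), np.asarray(lengths), min_amplitude, unit_amplitude
    )
    return StepCountResult(
        n_steps=int(levels[0]),  # rungs are relative to the bleached baseline
        step_times=t[step_idx] if step_idx.size else np.empty(0),
        step_amplitudes=drops,
        trace_id=getattr(trace, "trace_id", ""),
        segment_means=np.asarray(means),
        unit_amplitude=unit,
    )


def count_steps_dataset(
    traces,
    min_amplitude: float,
    penalty: float | None = None,
    min_segment_frames: int = 2,
) -> list[StepCountResult]:
    """Two-pass step counting over a pooled dataset of traces.

    All traces share the same dye, hence the same single-bleach step
    amplitude.  A first per-trace pass estimates that unit amplitude; the
    median estimate is then fed back so each trace's level ladder is
    constrained to the dataset-wide unit, which disambiguates counts that
    one noisy level would otherwise alias toward a finer ladder.
    """
    first = [count_steps(tr, min_amplitude, penalty, min_segment_frames) for tr in traces]
    units = np.array([r.unit_amplitude for r in first if np.isfinite(r.unit_amplitude)])
    if units.size == 0:
        return first
    global_unit = float(np.median(units))
    return [
        count_steps(tr, min_amplitude, penalty, min_segment_frames, unit_amplitude=global_unit)
        for tr in traces
    ]


def _fit_intensity_ladder(
    means: np.ndarray,
    lengths: np.ndarray,
    min_amplitude: float,
    unit_amplitude: float | None = None,
) -> tuple[np.ndarray, float]:
    """Assign each segment level to an integer rung of a common step ladder.

    Labels bleaching within the same frame window merge into one transition
    of a multiple of the unit step amplitude, so segment means are modelled
    as ``baseline + m * a`` for integer rung m.  The rung count of the
    first segment is scanned, the amplitude refitted by weighted least
    squares, and the best-scoring ladder (ties toward fewer steps) decides
    the multiplicities.  Returns (rungs, fitted unit amplitude).
    """
    if means.size == 1:
        return np.zeros(1, dtype=int), float("nan")
    # anchor the ladder on the last long-lived level: a short terminal
    # segment can be a noise dip rather than the bleached baseline
    long_enough = np.flatnonzero(lengths >= 5)
    base_idx = int(long_enough[-1]) if long_enough.size else means.size - 1
    heights = means - means[base_idx]
    top = heights[0]
    w = lengths.astype(float)  # long clean levels pin the unit amplitude
    n_max = max(int(np.floor(top / min_amplitude + 0.5)), 1)
    best_levels, best_score, best_unit = None, np.inf, float("nan")
    for n_top in range(1, n_max + 1):
        a = top / n_top
        if a < min_amplitude:
            break
        if unit_amplitude is not None and not (
            0.75 * unit_amplitude <= a <= 1.3 * unit_amplitude
        ):
            continue
        m = np.round(heights / a).astype(int)
        m[0], m[base_idx] = n_top, 0
        denom = float(np.sum(w * m * m))
        if denom > 0:
            a = float(np.sum(w * m * heights) / denom)  # refit unit amplitude
            m = np.round(heights / a).astype(int)
            m[0], m[base_idx] = n_top, 0
        score = float(np.sum(w * (heights - m * a) ** 2))
        # a finer ladder (larger n_top) always fits at least as well as a
        # coarser one whose rungs it contains, so demand a decisive
        # improvement before accepting more steps
        if score < 0.35 * best_score - 1e-12:
            best_levels, best_score, best_unit = m, score, a
    if best_levels is None and unit_amplitude is not None:
        # no candidate near the dataset unit; fall back to the free scan
        return _fit_intensity_ladder(means, lengths, min_amplitude, None)
    if best_levels is None:
        return np.zeros_like(means, dtype=int), float("nan")
    return best_levels, best_unit


# ---------------------------------------------------------------------------
# Binomial stoichiometry fitting
# ---------------------------------------------------------------------------

def binomial_pmf(k, n: int, p: float) -> np.ndarray:
    """s(k) = C(n,k) p^k (1-p)^(n-k): probability of k labelled subunits."""
    return binom.pmf(k, n, p)


def zero_truncated_binomial_pmf(k, n: int, p: float) -> np.ndarray:
    """Binomial pmf conditioned on k >= 1 (unlabelled motors are invisible)."""
    k = np.asarray(k)
    norm = 1.0 - (1.0 - p) ** n
    return np.where(k >= 1, binom.pmf(k, n, p) / norm, 0.0)


def _log_likelihood(counts: np.ndarray, n: int, p: float, truncated: bool) -> float:
    if np.max(counts) > n:
        return -np.inf
    ll = float(np.sum(binom.logpmf(counts, n, p)))
    if truncated:
        ll -= counts.size * np.log(1.0 - (1.0 - p) ** n)
    return ll


def _fit_p(counts: np.ndarray, n: int, truncated: bool) -> float:
    if not truncated:
        return float(np.mean(counts) / n)
    res = minimize_scalar(
        lambda p: -_log_likelihood(counts, n, p, truncated=True),
        bounds=(1e-9, 1.0 - 1e-9),
        method="bounded",
    )
    return float(res.x)


def fit_binomial_stoichiometry(
    counts,
    candidate_n=DEFAULT_CANDIDATE_N,
    truncate_zero: bool = True,
) -> BinomialFitResult:
    """Maximum-likelihood stoichiometry from pooled per-trace step counts.

    For each candidate n the labelling efficiency p is fitted by maximum
    likelihood under the (optionally zero-truncated) binomial pmf; the
    candidate with the highest likelihood wins, ties breaking toward
    smaller n.  Candidates with any observed count > n are infeasible.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if truncate_zero and np.any(counts < 1):
        raise ValueError("zero counts present; zero-truncated fit requires counts >= 1")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")

    per_n: dict[int, dict] = {}
    best_n, best_ll = None, -np.inf
    for n in sorted(candidate_n):
        feasible = int(np.max(counts)) <= n
        if feasible:
            p_hat = _fit_p(counts, n, truncate_zero)
            ll = _log_likelihood(counts, n, p_hat, truncate_zero)
        else:
            p_hat, ll = np.nan, -np.inf
        per_n[n] = {"feasible": feasible, "p_hat": p_hat, "log_likelihood": ll}
        if feasible and ll > best_ll:
            best_n, best_ll = n, ll
    if best_n is None:
        raise NoFeasibleModelError("all candidate stoichiometries are excluded by the data")
    return BinomialFitResult(
        n_hat=best_n,
        p_hat=per_n[best_n]["p_hat"],
        per_n_statistic=per_n,
        truncated=truncate_zero,
    )


def stoichiometry_report(
    counts,
    candidate_n=DEFAULT_CANDIDATE_N,
    truncate_zero: bool = True,
) -> dict:
    """Per-candidate fit statistics and predicted-vs-observed histograms.

    For each candidate n the table reports the fitted p, log-likelihood,
    Pearson chi-square against the observed count histogram, and the number
    of traces with counts exceeding that candidate expected under the
    overall best-fit model (a candidate is untenable when the best model
    predicts many counts above it, or infeasible when such counts were
    observed).
    """
    counts = np.asarray(counts, dtype=int)
    fit = fit_binomial_stoichiometry(counts, candidate_n, truncate_zero)
    n_traces = counts.size
    k_lo = 1 if truncate_zero else 0

    rows = []
    histograms: dict[int, pd.DataFrame] = {}
    for n in sorted(candidate_n):
        stats = fit.per_n_statistic[n]
        if stats["feasible"]:
            ks = np.arange(k_lo, n + 1)
            pmf = (
                zero_truncated_binomial_pmf(ks, n, stats["p_hat"])
                if truncate_zero
                else binomial_pmf(ks, n, stats["p_hat"])
            )
            observed = np.array([np.sum(counts == k) for k in ks], dtype=float)
            expected = n_traces * pmf
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2_stat = float(np.nansum((observed - expected) ** 2 / expected))
            dof = max(ks.size - 2, 1)
            chi2_p = float(chi2.sf(chi2_stat, dof))
            histograms[n] = pd.DataFrame({"k": ks, "observed": observed, "expected": expected})
        else:
            chi2_stat, chi2_p = np.nan, np.nan
        # expected count of traces exceeding this candidate's n under the
        # overall best-fit stoichiometry
        ks_best = np.arange(k_lo, fit.n_hat + 1)
        pmf_best = (
            zero_truncated_binomial_pmf(ks_best, fit.n_hat, fit.p_hat)
            if truncate_zero
            else binomial_pmf(ks_best, fit.n_hat, fit.p_hat)
        )
        expected_exceeding = float(n_traces * np.sum(pmf_best[ks_best > n]))
        rows.append(
            {
                "n": n,
                "feasible": stats["feasible"],
                "p_hat": stats["p_hat"],
                "log_likelihood": stats["log_likelihood"],
                "chi2": chi2_stat,
                "chi2_pvalue": chi2_p,
                "expected_exceeding": expected_exceeding,
                "observed_exceeding": int(np.sum(counts > n)),
            }
        )

    low_sample = n_traces < 30
    if low_sample:
        warnings.warn(
            f"only {n_traces} trace(s); stoichiometry report is unreliable",
            UserWarning,
            stacklevel=2,
        )
    return {
        "table": pd.DataFrame(rows).set_index("n"),
        "histograms": histograms,
        "fit": fit,
        "low_sample_warning": low_sample,
    }
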