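"""Synthetic single-molecule data with recorded ground truth.

Three generators emulate the raw material of the analysis pipeline:

* donor-channel (Cy3) intensity trajectories with stepwise photobleaching of
  up to ``n_subunits`` labels, for stoichiometry step counting;
* acceptor-channel (Cy5) trajectories with upward engagement spikes, gap
  times drawn from a two-exponential mixture (engaging-state bursts vs the
  quiescent state), a three-class engagement-lifetime mixture and
  exponential photobleach censoring (~40 s);
* constant-force optical-trap extension traces for a 3400-bp tether with
  Poisson-placed pauses (plateaus or unpackaging) and worm-like-chain
  bp-to-nm conversion.

Every generator takes a seed (or :class:`numpy.random.Generator`) and
returns exact ground truth, so downstream detection and fitting stages can
be scored without any external recordings.  Baseline intensity is 0 a.u.
and noise is i.i.d. Gaussian per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engagements import (
    EndReason,
    EngagementClass,
    EngagementEvent,
    classify_engagement,
)
from .trap import ExtensionTrace, PauseAnnotation, PauseType, WLCParams, extension_from_bp

__all__ = [
    "MotorComposition",
    "IntensityTrace",
    "EngagementKinetics",
    "TrapSimParams",
    "PhotobleachTruth",
    "TrueEngagement",
    "TrapTruth",
    "sample_motor_composition",
    "sample_zero_truncated_binomial",
    "gen_photobleach_trace",
    "gen_engagement_trajectory",
    "gen_extension_trace",
]

DEFAULT_FRAME_INTERVAL_S = 0.1  # 100-ms camera resolution


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotorComposition:
    """Subunit composition and labelling state of a single ring motor."""

    n_subunits: int = 5
    n_inactive: int = 0
    labeled_role: str = "active"  # which subunit species carries the dye
    per_subunit_label_prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_inactive <= self.n_subunits:
            raise ValueError("n_inactive must be in [0, n_subunits]")
        if not 0.0 <= self.per_subunit_label_prob <= 1.0:
            raise ValueError("per_subunit_label_prob must be in [0, 1]")
        if self.labeled_role not in ("active", "inactive"):
            raise ValueError("labeled_role must be 'active' or 'inactive'")

    @property
    def n_labelable(self) -> int:
        return self.n_inactive if self.labeled_role == "inactive" else (
            self.n_subunits - self.n_inactive
        )


@dataclass
class IntensityTrace:
    """Uniformly sampled fluorescence intensity for one channel of one spot."""

    times: np.ndarray
    intensities: np.ndarray
    channel: str = "Cy3"
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be strictly increasing with constant spacing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class EngagementKinetics:
    """Gap-time mixture, engagement-lifetime mixture and photobleach lifetime.

    Defaults reproduce an unimpaired motor: gap mixture 0.8 x 5 s + 0.2 x
    40 s (amplitude-weighted mean 12 s); lifetime classes dominated by
    transient events; acceptor photobleach lifetime 40 s.
    """

    amp_short: float = 0.8
    tau_short: float = 5.0
    amp_long: float = 0.2
    tau_long: float = 40.0
    lifetime_weights: tuple[float, float, float] = (0.75, 0.15, 0.10)
    lifetime_taus: tuple[float, float, float] = (0.8, 4.0, 25.0)
    bleach_lifetime: float = 40.0

    def __post_init__(self) -> None:
        if self.amp_short < 0 or self.amp_long < 0 or abs(
            self.amp_short + self.amp_long - 1.0
        ) > 1e-9:
            raise ValueError("gap amplitudes must be non-negative and sum to 1")
        if any(w < 0 for w in self.lifetime_weights) or abs(
            sum(self.lifetime_weights) - 1.0
        ) > 1e-9:
            raise ValueError("lifetime weights must be non-negative and sum to 1")
        taus = (self.tau_short, self.tau_long, *self.lifetime_taus, self.bleach_lifetime)
        if any(tau <= 0 for tau in taus):
            raise ValueError("all lifetimes must be positive")
        if self.tau_long <= self.tau_short:
            raise ValueError("tau_long must exceed tau_short")

    @property
    def mean_gap(self) -> float:
        return self.amp_short * self.tau_short + self.amp_long * self.tau_long


@dataclass(frozen=True)
class TrapSimParams:
    """Ground-truth kinematics for synthetic constant-force packaging traces."""

    pause_free_velocity_bp_s: float = 960.0
    pause_rate_per_kb: float = 1.2
    pause_duration_mean_s: float = 0.8
    unpackaging_fraction: float = 0.2
    unpackaging_velocity_bp_s: float = -300.0
    noise_sd_nm: float = 2.0
    force_pN: float = 5.0
    dna_length_bp: float = 3400.0
    frame_interval_s: float = 0.001
    start_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pause_free_velocity_bp_s <= 0:
            raise ValueError("pause_free_velocity must be positive")
        if self.pause_rate_per_kb < 0:
            raise ValueError("pause_rate must be non-negative")
        if self.unpackaging_velocity_bp_s > 0:
            raise ValueError("unpackaging_velocity must be <= 0")


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class PhotobleachTruth:
    n_labels: int
    step_times: np.ndarray  # sorted bleach times of every label, seconds
    detectable: bool  # False for zero-label motors (no visible spot)


@dataclass
class TrueEngagement:
    """Ground-truth engagement: observed event plus the hidden quantities."""

    event: EngagementEvent
    gap_before_s: float  # gap from previous event end to this start
    gap_component: str  # 'short' (engaging-state burst) or 'long' (quiescent)
    intrinsic_lifetime_s: float
    bleach_time_s: float


@dataclass
class TrapTruth:
    pauses: PauseAnnotation
    pause_free_velocity_bp_s: float
    bp_clean: np.ndarray
    failure: bool = False  # DNA fully unpackaged before completion


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def sample_motor_composition(
    doping_fraction: float,
    n_subunits: int = 5,
    n_motors: int = 1,
    seed=None,
    labeled_role: str = "active",
    per_subunit_label_prob: float = 1.0,
) -> list[MotorComposition]:
    """Assemble motors from a pool with the given inactive-monomer fraction.

    Each subunit is independently inactive with probability
    ``doping_fraction`` (the molar ratio of inactive to total monomers), so
    the number of inactive subunits per motor is binomial.
    """
    if not 0.0 <= doping_fraction <= 1.0:
        raise ValueError("doping_fraction must be in [0, 1]")
    rng = _rng(seed)
    n_inactive = rng.binomial(n_subunits, doping_fraction, size=n_motors)
    return [
        MotorComposition(n_subunits, int(k), labeled_role, per_subunit_label_prob)
        for k in n_inactive
    ]


def sample_zero_truncated_binomial(n: int, p: float, size: int, seed=None) -> np.ndarray:
    """Draw from a binomial(n, p) conditioned on being >= 1 (visible spots only)."""
    rng = _rng(seed)
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = rng.binomial(n, p, size=max(size - filled, 16))
        draw = draw[draw > 0][: size - filled]
        out[filled : filled + draw.size] = draw
        filled += draw.size
    return out


def gen_photobleach_trace(
    composition: MotorComposition,
    step_amplitude: float = 100.0,
    bleach_mean_s: float = 20.0,
    noise_sd: float = 30.0,
    duration_s: float = 150.0,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    seed=None,
    trace_id: str = "",
    n_labels: int | None = None,
) -> tuple[IntensityTrace, PhotobleachTruth]:
    """Donor-channel staircase: each label bleaches at an exponential time.

    Intensity starts at ``n_labels * step_amplitude`` above a zero baseline
    and drops by one step amplitude per bleach event, plus Gaussian noise.
    ``n_labels`` is drawn binomially from the labelable subunits unless
    given explicitly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if step_amplitude <= 0:
        raise ValueError("step_amplitude must be positive")
    rng = _rng(seed)
    if n_labels is None:
        n_labels = int(rng.binomial(composition.n_labelable, composition.per_subunit_label_prob))
    bleach_times = np.sort(rng.exponential(bleach_mean_s, size=n_labels))
    times = np.arange(0.0, duration_s, frame_interval_s)
    surviving = (times[:, None] < bleach_times[None, :]).sum(axis=1) if n_labels else np.zeros(
        times.size
    )
    intensities = step_amplitude * surviving
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=times.size)
    trace = IntensityTrace(times, intensities, channel="Cy3", trace_id=trace_id)
    return trace, PhotobleachTruth(n_labels, bleach_times, detectable=n_labels > 0)


def gen_engagement_trajectory(
    kinetics: EngagementKinetics,
    duration_s: float = 240.0,
    spike_amplitude: float = 100.0,
    noise_sd: float = 20.0,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    seed=None,
    trace_id: str = "",
) -> tuple[IntensityTrace, list[TrueEngagement]]:
    """Acceptor-channel trajectory with engagement spikes and ground truth.

    Gaps between events are drawn directly from the two-component mixture
    (the observable the dwell-time analysis fits); each engagement's
    observed end is min(intrinsic lifetime, photobleach time) and events
    clipped by the trace end are marked censored.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if spike_amplitude <= 0:
        raise ValueError("spike_amplitude must be positive")
    rng = _rng(seed)
    lifetime_weights = np.asarray(kinetics.lifetime_weights, dtype=float)
    lifetime_taus = np.asarray(kinetics.lifetime_taus, dtype=float)

    truths: list[TrueEngagement] = []
    t = 0.0
    while True:
        if rng.random() < kinetics.amp_short:
            gap_component, gap = "short", rng.exponential(kinetics.tau_short)
        else:
            gap_component, gap = "long", rng.exponential(kinetics.tau_long)
        start = t + gap
        if start >= duration_s:
            break
        comp = rng.choice(3, p=lifetime_weights)
        intrinsic = rng.exponential(lifetime_taus[comp])
        bleach = rng.exponential(kinetics.bleach_lifetime)
        end = start + min(intrinsic, bleach)
        if end >= duration_s:
            end, reason = duration_s, EndReason.CENSORED_AT_TRACE_END
        elif bleach < intrinsic:
            reason = EndReason.PHOTOBLEACH
        else:
            reason = EndReason.DISSOCIATION
        event = EngagementEvent(start, end, classify_engagement(end - start), reason)
        truths.append(TrueEngagement(event, gap, gap_component, intrinsic, bleach))
        if end >= duration_s:
            break
        t = end

    times = np.arange(0.0, duration_s, frame_interval_s)
    intensities = np.zeros(times.size)
    for truth in truths:
        mask = (times >= truth.event.start) & (times < truth.event.end)
        intensities[mask] += spike_amplitude
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=times.size)
    trace = IntensityTrace(times, intensities, channel="Cy5", trace_id=trace_id)
    return trace, truths


def gen_extension_trace(
    params: TrapSimParams = TrapSimParams(),
    wlc: WLCParams = WLCParams(),
    seed=None,
    pauses: list[tuple[float, float, str]] | None = None,
    trace_id: str = "",
) -> tuple[ExtensionTrace, TrapTruth]:
    """Constant-force extension trace with injected pauses and ground truth.

    Packaging proceeds at the pause-free velocity, interrupted by pauses
    placed as a homogeneous Poisson process in packaged length (matching the
    per-kb pause-frequency statistic) unless an explicit list of
    ``(position_bp, duration_s, type)`` pauses is supplied.  A pause is a
    plateau or, with probability ``unpackaging_fraction``, a gradual
    negative-velocity release.  Base pairs are converted to nm through the
    worm-like chain at the trace force.
    """
    rng = _rng(seed)
    v = params.pause_free_velocity_bp_s
    total_bp = params.dna_length_bp

    if pauses is None:
        n_pauses = rng.poisson(params.pause_rate_per_kb * total_bp / 1000.0)
        positions = np.sort(rng.uniform(0.0, total_bp, size=n_pauses))
        pause_list = []
        for pos in positions:
            duration = rng.exponential(params.pause_duration_mean_s)
            kind = (
                PauseType.UNPACKAGING
                if rng.random() < params.unpackaging_fraction
                else PauseType.PLATEAU
            )
            pause_list.append((float(pos), float(duration), kind))
    else:
        pause_list = [(float(p), float(d), PauseType(k)) for p, d, k in pauses]

    # piecewise-linear bp(t): (time, bp_unpackaged) breakpoints
    failure = False
    break_t, break_bp = [0.0], [total_bp]
    truth_pauses = PauseAnnotation()
    t_now, bp_now, packaged = 0.0, total_bp, 0.0
    if params.start_delay_s > 0:
        t_now += params.start_delay_s
        break_t.append(t_now)
        break_bp.append(bp_now)
    for pos, duration, kind in pause_list:
        seg_bp = pos - packaged
        if seg_bp < 0:
            continue
        t_now += seg_bp / v
        bp_now -= seg_bp
        packaged = pos
        break_t.append(t_now)
        break_bp.append(bp_now)
        v_pause = params.unpackaging_velocity_bp_s if kind is PauseType.UNPACKAGING else 0.0
        released = -v_pause * duration
        if bp_now + released > params.dna_length_bp:
            failure = True
            released = params.dna_length_bp - bp_now
            duration = released / max(-v_pause, 1e-12)
        truth_pauses.intervals.append((t_now, t_now + duration))
        truth_pauses.pause_types.append(kind)
        truth_pauses.pause_velocities_bp_s.append(v_pause)
        t_now += duration
        bp_now += released
        packaged -= released  # released DNA must be repackaged
        break_t.append(t_now)
        break_bp.append(bp_now)
        if failure:
            break
    if not failure:
        t_now += bp_now / v
        break_t.append(t_now)
        break_bp.append(0.0)

    times = np.arange(0.0, t_now, params.frame_interval_s)
    bp_clean = np.interp(times, break_t, break_bp)
    extension = extension_from_bp(bp_clean, params.force_pN, wlc)
    if params.noise_sd_nm > 0:
        extension = extension + rng.normal(0.0, params.noise_sd_nm, size=times.size)
    trace = ExtensionTrace(times, extension, params.force_pN, trace_id=trace_id)
    return trace, TrapTruth(truth_pauses, v, bp_clean, failure)
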