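"""Engagement idealization, classification, censored mixtures and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorlab import engagements as eng
from motorlab import synth

C = eng.EngagementClass


def _event(start, end):
    return eng.EngagementEvent(start, end, eng.classify_engagement(end - start),
                               eng.EndReason.DISSOCIATION)


class TestClassification:
    @pytest.mark.parametrize(
        "lifetime,expected",
        [
            (0.0, C.TRANSIENT),
            (1.5, C.TRANSIENT),
            (1.999, C.TRANSIENT),
            (2.0, C.SEMI_TRANSIENT),
            (5.0, C.SEMI_TRANSIENT),
            (10.0, C.SEMI_TRANSIENT),
            (10.001, C.LONG_LIVED),
            (15.0, C.LONG_LIVED),
        ],
    )
    def test_class_boundaries(self, lifetime, expected):
        assert eng.classify_engagement(lifetime) is expected

    def test_negative_lifetime_raises(self):
        with pytest.raises(ValueError):
            eng.classify_engagement(-0.1)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    def test_classification_is_total(self, lifetime):
        assert eng.classify_engagement(lifetime) in list(C)


class TestIdealization:
    def test_noiseless_spikes_recovered_exactly(self):
        times = np.arange(0.0, 60.0, 0.1)
        y = np.zeros(times.size)
        y[(times >= 10.0) & (times < 13.0)] = 100.0
        y[(times >= 30.0) & (times < 30.5)] = 100.0
        trace = synth.IntensityTrace(times, y, channel="Cy5")
        events = eng.idealize_engagements(trace)
        assert len(events) == 2
        assert events[0].start == pytest.approx(10.0) and events[0].end == pytest.approx(13.0)
        assert events[1].start == pytest.approx(30.0) and events[1].end == pytest.approx(30.5)

    def test_flat_trace_yields_no_events(self, rng):
        trace = synth.IntensityTrace(np.arange(0, 30, 0.1), rng.normal(0, 5, 300), "Cy5")
        assert eng.idealize_engagements(trace) == []

    def test_saturated_trace_raises(self, rng):
        trace = synth.IntensityTrace(
            np.arange(0, 30, 0.1), 100.0 + rng.normal(0, 5, 300), "Cy5"
        )
        with pytest.raises(eng.NoBaselineError):
            eng.idealize_engagements(trace, baseline=0.0)

    def test_trace_end_events_marked_censored(self):
        times = np.arange(0.0, 20.0, 0.1)
        y = np.zeros(times.size)
        y[times >= 15.0] = 100.0
        events = eng.idealize_engagements(synth.IntensityTrace(times, y, channel="Cy5"))
        assert events[-1].end_reason is eng.EndReason.CENSORED_AT_TRACE_END

    def test_generator_events_recovered(self):
        """>=90% of resolvable true events found with <=1 frame boundary error."""
        kin = synth.EngagementKinetics()
        rng = np.random.default_rng(41)
        total = matched = 0
        for _ in range(40):
            trace, truths = synth.gen_engagement_trajectory(kin, 240.0, 100.0, 20.0, seed=rng)
            events = eng.idealize_engagements(trace)
            for truth in truths:
                if truth.event.lifetime < 0.25:
                    continue  # below the two-frame detection resolution
                total += 1
                matched += any(
                    abs(e.start - truth.event.start) <= 0.101
                    and abs(e.end - truth.event.end) <= 0.101
                    for e in events
                )
        assert matched / total >= 0.90


class TestExponentialMixture:
    def test_tau_avg_is_amplitude_weighted_mean(self):
        fit = eng.MixtureFit(2, np.array([0.8, 0.2]), np.array([5.0, 40.0]), 0.0, {}, 100, 0)
        assert fit.tau_avg == pytest.approx(12.0)

    def test_single_exponential_rate_recovery(self, rng):
        x = rng.exponential(7.0, 10_000)
        fit = eng.fit_exponential_mixture(x, candidate_orders=(1,))
        assert fit.taus[0] == pytest.approx(7.0, rel=0.05)

    def test_censored_likelihood_reduces_to_uncensored(self, rng):
        x = rng.exponential(5.0, 500)
        f1 = eng.fit_exponential_mixture(x, candidate_orders=(2,))
        f2 = eng.fit_exponential_mixture(x, np.zeros(500, dtype=bool), candidate_orders=(2,))
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-9)

    def test_two_component_selection_and_tau_avg(self):
        rng = np.random.default_rng(2)
        comp = rng.random(2000) < 0.8
        gaps = np.where(comp, rng.exponential(5.0, 2000), rng.exponential(40.0, 2000))
        fit = eng.fit_exponential_mixture(gaps, candidate_orders=(1, 2))
        assert fit.n_components == 2
        assert fit.model_selection_scores[2] < fit.model_selection_scores[1]
        assert fit.tau_avg == pytest.approx(12.0, rel=0.10)

    def test_survival_ls_and_mle_agree(self, rng):
        """Survival-curve least squares and MLE give the same lifetime."""
        x = rng.exponential(6.0, 10_000)
        mle = eng.fit_exponential_mixture(x, candidate_orders=(1,))
        ls = eng.fit_exponential_survival_ls(x, 1)
        assert ls.taus[0] == pytest.approx(mle.taus[0], rel=0.10)

    def test_degenerate_data_raises(self):
        with pytest.raises(eng.DegenerateFitError):
            with pytest.warns(UserWarning):
                eng.fit_exponential_mixture([3.0, 3.0, 3.0], candidate_orders=(2,))

    def test_small_sample_warns(self, rng):
        with pytest.warns(UserWarning):
            eng.fit_exponential_mixture(rng.exponential(1.0, 10), candidate_orders=(1,))


class TestEventStatistics:
    def test_frequencies_per_minute(self):
        events = [_event(i * 10.0, i * 10.0 + 0.5) for i in range(6)]
        freqs = eng.engagement_frequencies(events, observation_time_s=180.0)
        assert freqs["per_minute"]["transient"] == pytest.approx(2.0)

    def test_empty_events_all_zero(self):
        freqs = eng.engagement_frequencies([], 60.0)
        assert all(v == 0.0 for v in freqs["per_minute"].values())

    def test_fractions_sum_to_one(self):
        events = [_event(0, 1), _event(5, 10), _event(20, 40)]
        freqs = eng.engagement_frequencies(events, 60.0)
        assert sum(freqs["fraction"].values()) == pytest.approx(1.0)

    def test_zero_observation_time_raises(self):
        with pytest.raises(ValueError):
            eng.engagement_frequencies([], 0.0)

    def test_transition_matrix_direct_count(self):
        seq = [_event(0, 1), _event(2, 3), _event(4, 5), _event(6, 11)]  # T,T,T,S
        probs, counts = eng.class_transition_matrix([seq])
        assert probs[0, 0] == pytest.approx(2 / 3)
        assert probs[0, 1] == pytest.approx(1 / 3)
        assert counts[0].sum() == 3

    def test_single_event_sequences_undefined(self):
        probs, _ = eng.class_transition_matrix([[_event(0, 1)], [_event(0, 5)]])
        assert np.all(np.isnan(probs))

    def test_markov_probability_recovery(self, rng):
        """P(T->T) = 0.9 estimated within +/-0.02 from 10^4 transitions."""
        states = [0]
        for _ in range(10_000):
            if states[-1] == 0:
                states.append(0 if rng.random() < 0.9 else 1)
            else:
                states.append(0 if rng.random() < 0.5 else 1)
        lifetimes = {0: 1.0, 1: 5.0}
        t0, seq = 0.0, []
        for s in states:
            seq.append(_event(t0, t0 + lifetimes[s]))
            t0 += lifetimes[s] + 1.0
        probs, _ = eng.class_transition_matrix([seq])
        assert probs[0, 0] == pytest.approx(0.9, abs=0.02)

    def test_count_packaged_dna(self):
        events = [_event(0, 1), _event(2, 7), _event(10, 25), _event(30, 60)]
        assert eng.count_packaged_dna(events) == 2
        assert eng.count_packaged_dna([]) == 0

    def test_mean_packaged_count_matches_renewal_oracle(self):
        """Per-motor long-lived counts match a renewal-equation oracle."""
        kin = synth.EngagementKinetics()
        duration = 240.0
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(500):
            _, truths = synth.gen_engagement_trajectory(kin, duration, seed=rng)
            counts.append(
                sum(1 for t in truths if t.event.event_class is C.LONG_LIVED)
            )
        counts = np.asarray(counts, dtype=float)

        # oracle: renewal equation on exact per-bin probability masses of
        # the gap and observed-lifetime distributions, times P(long-lived)
        dt = 0.02
        edges = np.arange(0.0, duration + dt, dt)
        w = np.array(kin.lifetime_weights)
        taus = np.array(kin.lifetime_taus)

        def gap_cdf(t):
            return kin.amp_short * (1 - np.exp(-t / kin.tau_short)) + kin.amp_long * (
                1 - np.exp(-t / kin.tau_long)
            )

        def life_surv(t):
            return np.sum(w * np.exp(-t[:, None] / taus), axis=1) * np.exp(-t / 40.0)

        gap_mass = np.diff(gap_cdf(edges))
        life_mass = -np.diff(life_surv(edges))
        cycle_mass = np.convolve(gap_mass, life_mass)[: gap_mass.size]
        renewal = np.zeros_like(gap_mass)
        for i in range(renewal.size):
            renewal[i] = gap_mass[i] + np.sum(renewal[:i] * cycle_mass[i:0:-1])
        p_long = float(np.sum(w * np.exp(-10.0 / taus)) * np.exp(-10.0 / 40.0))
        # long-lived class requires >10 s of observed signal before trace end
        usable = edges[:-1] <= duration - 10.0
        expected = float(np.sum(renewal[usable]) * p_long)

        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3 * se + 0.02
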