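"""Event synchronization, downsampling control, and spike coherence."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import brute_force_q, no_coincidence_pair
from cortistri import (
    UndefinedResultError,
    ValidationError,
    event_synchronization,
    gen_common_modulated_pair,
    gen_poisson_train,
    gen_synchronized_pair,
    group_coherence,
    local_tau,
    spike_coherence,
    subsample_spikes,
)


class TestLocalTau:
    def test_interior_uses_smallest_of_four_isis(self, make_train):
        x = make_train([0.0, 0.4, 1.0])  # ISIs 0.4, 0.6 around index 1
        y = make_train([0.0, 0.5, 0.8], unit_id="y")  # ISIs 0.5, 0.3
        assert local_tau(x, y, 1, 1) == pytest.approx(0.15)

    def test_regular_trains_give_half_min_isi(self, make_train):
        x = make_train(np.arange(1.0, 20.0, 1.0))
        y = make_train(np.arange(1.0, 5.0, 0.2), unit_id="y")
        assert local_tau(x, y, 5, 5) == pytest.approx(0.1)

    def test_boundary_spike_uses_one_sided_isis(self, make_train):
        x = make_train([0.0, 0.4, 1.0])
        y = make_train([0.0, 0.5, 0.8], unit_id="y")
        # first x spike: only its right ISI (0.4) exists
        assert local_tau(x, y, 0, 1) == pytest.approx(0.15)
        assert local_tau(x, y, 0, 2) == pytest.approx(0.15)  # y right edge: 0.3

    def test_too_few_spikes_rejected(self, make_train):
        with pytest.raises(ValidationError):
            local_tau(make_train([1.0]), make_train([1.0, 2.0]), 0, 0)


class TestEventSynchronization:
    def test_identical_trains_give_q_of_one(self):
        x = gen_poisson_train(2.0, 180.0, 0)
        assert event_synchronization(x, x).Q == 1.0

    def test_no_coincidences_give_q_of_zero(self, make_train):
        x, y = no_coincidence_pair(make_train)
        assert event_synchronization(x, y).Q == 0.0

    def test_matches_brute_force_double_loop(self, make_train):
        rng = np.random.default_rng(0)
        for _ in range(200):
            nx, ny = rng.integers(2, 31, size=2)
            x = make_train(np.sort(rng.uniform(0, 60, nx)))
            y = make_train(np.sort(rng.uniform(0, 60, ny)), unit_id="y")
            assert event_synchronization(x, y).Q == pytest.approx(
                brute_force_q(x, y), abs=1e-12
            )

    def test_worked_small_example_against_oracle(self, make_train):
        x = make_train([1.0, 2.0, 3.0])
        y = make_train([1.05, 2.5], unit_id="y")
        assert event_synchronization(x, y).Q == pytest.approx(
            brute_force_q(x, y), abs=1e-12
        )

    def test_symmetric_in_arguments(self, make_train):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = make_train(np.sort(rng.uniform(0, 60, 20)))
            y = make_train(np.sort(rng.uniform(0, 60, 25)), unit_id="y")
            assert event_synchronization(x, y).Q == pytest.approx(
                event_synchronization(y, x).Q, abs=1e-12
            )

    def test_invariant_under_common_time_shift(self, make_train):
        rng = np.random.default_rng(2)
        x0 = np.sort(rng.uniform(0, 60, 30))
        y0 = np.sort(rng.uniform(0, 60, 30))
        q0 = event_synchronization(make_train(x0), make_train(y0, unit_id="y")).Q
        q1 = event_synchronization(
            make_train(x0 + 50.0), make_train(y0 + 50.0, unit_id="y")
        ).Q
        assert q1 == pytest.approx(q0, abs=1e-12)

    def test_exact_ties_count_half(self, make_train):
        # sparse trains sharing one spike time and nothing else nearby
        x = make_train([10.0, 50.0, 90.0])
        y = make_train([30.0, 50.0, 70.0], unit_id="y")
        res = event_synchronization(x, y)
        assert res.Q == pytest.approx(1.0 / 3.0)  # (0.5 + 0.5) / sqrt(9)

    @given(st.integers(0, 2**31 - 1))
    def test_q_bounded_in_unit_interval(self, seed):
        from cortistri import SpikeTrain

        rng = np.random.default_rng(seed)

        def train(uid):
            times = np.sort(rng.uniform(0, 30, rng.integers(2, 40)))
            return SpikeTrain(uid, "a", "saline", "mPFC", "pre_exposure", times, 180.0)

        q = event_synchronization(train("x"), train("y")).Q
        assert 0.0 <= q <= 1.0

    def test_cumulative_curve_nondecreasing_and_ends_at_q(self):
        x, y = gen_synchronized_pair(1.1, 1.9, 0.3, seed=5)
        res = event_synchronization(x, y)
        assert np.all(np.diff(res.curve_values) >= 0)
        assert res.curve_values[-1] == pytest.approx(res.Q)
        assert np.all(np.diff(res.curve_times) >= 0)

    def test_degenerate_trains_signal_undefined(self, make_train):
        with pytest.raises(UndefinedResultError):
            event_synchronization(make_train([1.0]), make_train([1.0, 2.0]))


class TestSubsample:
    def test_full_fraction_is_identity(self):
        x = gen_poisson_train(2.0, 180.0, 0)
        assert subsample_spikes(x, 1.0) is x

    def test_half_of_100_spikes_is_exactly_50(self, make_train):
        x = make_train(np.linspace(0.5, 170, 100))
        y = subsample_spikes(x, 0.5, seed=3)
        assert y.n_spikes == 50
        assert np.isin(y.times, x.times).all()
        assert np.all(np.diff(y.times) > 0)

    def test_fraction_out_of_range_rejected(self):
        x = gen_poisson_train(2.0, 180.0, 0)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValidationError):
                subsample_spikes(x, bad)

    def test_downsampled_saline_synchrony_still_exceeds_pcp(self):
        # rate-matched control: halving saline NAc spikes must not abolish
        # the injected synchrony difference
        wins = 0
        for seed in range(20):
            xs, ys = gen_synchronized_pair(1.1, 1.9, 0.15, seed=seed)
            xp, yp = gen_synchronized_pair(1.1, 0.93, 0.03, seed=seed + 500)
            q_sal = event_synchronization(
                xs, subsample_spikes(ys, 0.5, seed=seed)
            ).Q
            q_pcp = event_synchronization(xp, yp).Q
            wins += q_sal > q_pcp
        assert wins >= 15


class TestCoherence:
    def test_self_coherence_is_one(self):
        x = gen_poisson_train(2.0, 180.0, 1)
        res = spike_coherence(x, x)
        assert np.all(res.coherence > 0.999)

    def test_independent_pairs_sit_at_segment_bias_floor(self):
        n_seg = 180_000 // 1024
        vals = [
            spike_coherence(
                gen_poisson_train(1.5, 180.0, 2 * s),
                gen_poisson_train(1.5, 180.0, 2 * s + 1),
            ).coherence.mean()
            for s in range(50)
        ]
        assert abs(np.mean(vals) - 1.0 / n_seg) / (1.0 / n_seg) < 0.2

    def test_shared_rhythm_peaks_at_modulation_frequency(self):
        c4, c20 = [], []
        for seed in range(10):
            x, y = gen_common_modulated_pair(2.0, 2.0, 4.0, 0.8, seed=seed)
            res = spike_coherence(x, y)
            c4.append(res.coherence[np.argmin(np.abs(res.frequencies - 4.0))])
            c20.append(res.coherence[np.argmin(np.abs(res.frequencies - 20.0))])
        assert np.mean(c4) > 3 * np.mean(c20)

    def test_empty_train_signals_undefined(self, make_train):
        x = gen_poisson_train(2.0, 180.0, 0)
        with pytest.raises(UndefinedResultError):
            spike_coherence(x, make_train([]))

    def test_short_trial_rejected(self, make_train):
        x = make_train([0.5, 1.0, 1.5], duration=4.0)
        with pytest.raises(ValidationError):
            spike_coherence(x, x)


class TestGroupCoherence:
    def test_identical_pairs_give_zero_width_band(self):
        x = gen_poisson_train(2.0, 180.0, 2)
        y = gen_poisson_train(2.0, 180.0, 3)
        pc = spike_coherence(x, y)
        res = group_coherence([pc, pc, pc], n_boot=200, seed=0)
        assert np.allclose(res.lower, res.mean)
        assert np.allclose(res.upper, res.mean)

    def test_band_contains_mean_everywhere(self):
        pairs = [
            spike_coherence(
                gen_poisson_train(2.0, 180.0, 10 + 2 * s),
                gen_poisson_train(2.0, 180.0, 11 + 2 * s),
            )
            for s in range(5)
        ]
        res = group_coherence(pairs, n_boot=500, seed=1)
        assert np.all(res.lower <= res.mean)
        assert np.all(res.mean <= res.upper)

    def test_single_pair_rejected(self):
        x = gen_poisson_train(2.0, 180.0, 0)
        with pytest.raises(ValidationError):
            group_coherence([spike_coherence(x, x)])

    def test_low_replicate_count_warns_but_computes(self, caplog):
        x = gen_poisson_train(2.0, 180.0, 2)
        pc = spike_coherence(x, x)
        with caplog.at_level(logging.WARNING, logger="cortistri"):
            res = group_coherence([pc, pc], n_boot=50, seed=0)
        assert res.n_pairs == 2
        assert any("n_boot" in r.message for r in caplog.records)
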