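"""Tests of the delta-modulation spike encoder and reconstruction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memspike.encoder import (EncoderParams, EventTrain, delta_from_circuit,
                              encode, encode_circuit,
                              encode_with_threshold_noise, read_events_csv,
                              reconstruct, reconstruction_mse,
                              write_events_csv)
from memspike.memristor import MemristorParams

FS = 1000.0


def sine(n=1001, amp=1.0, periods=1):
    t = np.arange(n) / (n - 1)
    return amp * np.sin(2 * np.pi * periods * t)


class TestDeltaFormula:
    def test_unity_gain_when_r2_equals_r1(self):
        p = EncoderParams(delta=None, r1=1e4, r2=1e4)
        assert p.gain_alpha == 1.0

    def test_r3_to_zero_limit(self):
        p = EncoderParams(delta=None, r1=1e4, r2=1e5, r3=1e-6)
        assert delta_from_circuit(p) == pytest.approx(
            p.memristor.v_th / 10.0, rel=1e-9)

    def test_reference_component_values(self):
        mem = MemristorParams(r_off=1e6)
        p = EncoderParams(delta=None, r1=1e4, r2=1e5, r3=1e5, memristor=mem)
        assert delta_from_circuit(p) == pytest.approx(0.374, abs=1e-6)

    def test_delta_decreases_with_gain(self):
        deltas = [delta_from_circuit(EncoderParams(delta=None, r1=1e4, r2=g * 1e4))
                  for g in (2, 5, 10, 20)]
        assert all(a > b for a, b in zip(deltas, deltas[1:]))


class TestEncode:
    def test_constant_signal_emits_nothing(self):
        ev = encode(np.full(500, 0.3), FS, EncoderParams(delta=0.1))
        assert len(ev) == 0

    def test_linear_ramp_counts(self):
        ev = encode(np.linspace(0, 1.0, 1001), FS, EncoderParams(delta=0.2))
        assert ev.counts() == (5, 0)

    def test_full_sine_period_counts(self):
        ev = encode(sine(), FS, EncoderParams(delta=0.2))
        assert ev.counts() == (10, 10)
        # UP events concentrated on rising phases
        rising = (ev.times * FS % 1000 < 250) | (ev.times * FS % 1000 > 750)
        assert np.all(ev.polarity[rising] == 1)

    def test_sign_flip_swaps_channels_exactly(self):
        p = EncoderParams(delta=0.13)
        s = sine(periods=3)
        a, b = encode(s, FS, p), encode(-s, FS, p)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.polarity, -b.polarity)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            encode(np.empty(0), FS, EncoderParams())

    def test_jump_carries_over_one_event_per_sample(self):
        sig = np.concatenate([np.zeros(5), np.full(20, 1.0)])
        ev = encode(sig, FS, EncoderParams(delta=0.25))
        # a 4-delta jump spreads over 4 consecutive samples
        np.testing.assert_array_equal((ev.times * FS).astype(int), [5, 6, 7, 8])
        assert np.all(ev.polarity == 1)


class TestReconstruct:
    def test_empty_train_is_constant(self):
        ev = EventTrain(times=np.empty(0), polarity=np.empty(0, dtype=np.int8),
                        delta=0.1, initial_value=0.4, duration=1.0)
        np.testing.assert_allclose(reconstruct(ev, np.linspace(0, 1, 11)), 0.4)

    def test_up_then_down_cancels(self):
        ev = EventTrain(times=np.array([0.2, 0.6]),
                        polarity=np.array([1, -1], dtype=np.int8),
                        delta=0.1, initial_value=0.0, duration=1.0)
        vals = reconstruct(ev, [0.1, 0.4, 0.9])
        np.testing.assert_allclose(vals, [0.0, 0.1, 0.0])

    def test_tracking_error_bounded_by_delta(self):
        p = EncoderParams(delta=0.07)
        s = sine(2001, periods=2)
        ev = encode(s, FS, p)
        rec = reconstruct(ev, np.arange(s.size) / FS)
        assert np.max(np.abs(rec - s)) <= p.delta + 1e-12

    def test_mse_trivial_cases(self):
        a = sine()
        assert reconstruction_mse(a, a) == 0.0
        assert reconstruction_mse(a, a + 0.3) == pytest.approx(0.09)
        with pytest.raises(ValueError):
            reconstruction_mse(a, a[:-1])

    def test_sine_mse_below_delta_squared(self):
        p = EncoderParams(delta=0.05)
        s = sine(2001)
        rec = reconstruct(encode(s, FS, p), np.arange(s.size) / FS)
        assert reconstruction_mse(s, rec) <= p.delta ** 2


class TestThresholdNoise:
    def test_zero_cv_identical_to_noiseless(self):
        p = EncoderParams(delta=0.1, threshold_cv=0.0, seed=5)
        s = sine()
        a, b = encode(s, FS, p), encode_with_threshold_noise(s, FS, p)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.polarity, b.polarity)

    def test_same_seed_is_deterministic(self):
        p = EncoderParams(delta=0.1, threshold_cv=0.1, seed=5)
        s = sine()
        a = encode_with_threshold_noise(s, FS, p)
        b = encode_with_threshold_noise(s, FS, p)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.polarity, b.polarity)

    def test_mean_mse_non_decreasing_in_cv(self):
        s = sine(1501, periods=2)
        grid = np.arange(s.size) / FS
        means = []
        for cv in (0.0, 0.05, 0.15):
            mses = []
            for seed in range(40):
                p = EncoderParams(delta=0.05, threshold_cv=cv, seed=seed)
                ev = encode_with_threshold_noise(s, FS, p)
                mses.append(reconstruction_mse(s, reconstruct(ev, grid)))
            means.append(np.mean(mses))
        assert means[0] <= means[1] <= means[2]


class TestCircuitEncoder:
    def test_constant_input_no_events(self):
        ev = encode_circuit(np.full(300, 0.2), FS, EncoderParams(delta=0.1))
        assert len(ev) == 0

    def test_counts_match_behavioral_on_smooth_signals(self):
        p = EncoderParams(delta=0.08)
        for s in (sine(), sine(2001, periods=3), np.linspace(0, 1, 501)):
            assert encode_circuit(s, FS, p).counts() == encode(s, FS, p).counts()

    def test_sign_flip_swaps_channels(self):
        p = EncoderParams(delta=0.08)
        s = sine(periods=2)
        a, b = encode_circuit(s, FS, p), encode_circuit(-s, FS, p)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.polarity, -b.polarity)


class TestEventTrainIO:
    def test_round_trip_bit_exact(self, tmp_path):
        ev = encode(sine(periods=2), FS, EncoderParams(delta=0.07))
        path = tmp_path / "events.csv"
        write_events_csv(ev, path)
        back = read_events_csv(path)
        np.testing.assert_array_equal(ev.times, back.times)
        np.testing.assert_array_equal(ev.polarity, back.polarity)
        assert (ev.delta, ev.initial_value, ev.duration) == \
               (back.delta, back.initial_value, back.duration)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EventTrain(times=np.array([0.2, 0.1]),
                       polarity=np.array([1, 1], dtype=np.int8),
                       delta=0.1, initial_value=0.0, duration=1.0)
        with pytest.raises(ValueError):
            EventTrain(times=np.array([0.1]),
                       polarity=np.array([2], dtype=np.int8),
                       delta=0.1, initial_value=0.0, duration=1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_encode_reconstruct_idempotent_and_sparse(seed):
    """Re-encoding a reconstruction yields the same event counts, and the
    event count is bounded by total variation / delta (+1 per segment)."""
    rng = np.random.default_rng(seed)
    # smooth random signal: integrated, low-pass-ish noise
    steps = rng.normal(0, 0.01, 800)
    s = np.cumsum(steps)
    p = EncoderParams(delta=0.05)
    ev = encode(s, FS, p)
    rec = reconstruct(ev, np.arange(s.size) / FS)
    ev2 = encode(rec, FS, p)
    assert ev2.counts() == ev.counts()
    tv = np.sum(np.abs(np.diff(s)))
    n_seg = 1 + np.sum(np.diff(np.sign(np.diff(s))) != 0)
    assert len(ev) <= tv / p.delta + n_seg


def test_spike_density_tracks_slope():
    """Faster-changing windows of a chirp carry more events."""
    t = np.arange(4000) / FS
    chirp = np.sin(2 * np.pi * (0.5 + 2.0 * t) * t)
    ev = encode(chirp, FS, EncoderParams(delta=0.05))
    idx = (ev.times * FS).astype(int)
    counts = np.histogram(idx, bins=4, range=(0, 4000))[0]
    assert all(a < b for a, b in zip(counts, counts[1:]))
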