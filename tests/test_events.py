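"""Bilevel state-level estimation and gait-event detection.

The histogram oracle here is an independent brute-force implementation
(explicit loops, no shared code with the package) used to freeze expected
state levels.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaitdnd import (
    BilevelEstimate,
    condition_presets,
    detect_events,
    durations_from_events,
    estimate_bilevels,
    extract_all_signals,
    scott_bin_width,
    simulate_record,
)
from gaitdnd.events import EventSequence
from gaitdnd.preprocess import SignalWindow


def brute_force_bilevels(x):
    """Independent oracle: loop-based histogram, Scott width, mode levels."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    a_min, a_max = min(x), max(x)
    width = 3.49 * sd / n ** (1.0 / 3.0)
    m = max(2, math.ceil((a_max - a_min) / width))
    counts = [0] * m
    for v in x:
        b = int((v - a_min) / (a_max - a_min) * m)
        counts[min(b, m - 1)] += 1
    occ = [i for i, c in enumerate(counts) if c]
    i_low, i_high = occ[0], occ[-1]
    split = i_low + (i_high - i_low) // 2
    low_bins = list(range(i_low, split + 1))
    high_bins = list(range(split + 1, i_high + 1))
    best_low = max(low_bins, key=lambda i: (counts[i], -i))
    best_high = max(high_bins, key=lambda i: (counts[i], -i))
    center = lambda i: a_min + (i + 0.5) * (a_max - a_min) / m
    return center(best_low), center(best_high), m


class TestBilevelEstimation:
    def test_square_wave_levels_match_brute_force_oracle(self):
        x = np.tile([0.0] * 5 + [10.0] * 5, 100)  # equal dwell, n = 1000
        est = estimate_bilevels(x)
        s_low, s_high, m = brute_force_bilevels(x)
        assert est.n_bins == m
        assert est.lower == pytest.approx(s_low, abs=1e-12)
        assert est.upper == pytest.approx(s_high, abs=1e-12)
        # state levels sit within half a bin of the true 0/10 states
        assert abs(est.lower - 0.0) <= est.amp_range / est.n_bins / 2 + 1e-12
        assert abs(est.upper - 10.0) <= est.amp_range / est.n_bins / 2 + 1e-12
        assert est.reference == pytest.approx(
            est.lower + 0.10 * (est.upper - est.lower), abs=1e-15
        )

    def test_scott_width_closed_form(self):
        # sigma-hat = 1, n = 1000 -> 3.49 / 10
        assert scott_bin_width(1.0, 1000) == pytest.approx(0.349, abs=1e-15)

    def test_noisy_bimodal_levels_match_oracle(self, rng):
        x = np.concatenate(
            [rng.normal(0.0, 0.3, 400), rng.normal(8.0, 0.5, 600)]
        )
        rng.shuffle(x)
        est = estimate_bilevels(x)
        s_low, s_high, _ = brute_force_bilevels(x)
        assert est.lower == pytest.approx(s_low, abs=1e-9)
        assert est.upper == pytest.approx(s_high, abs=1e-9)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="no bilevel structure"):
            estimate_bilevels(np.full(100, 3.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_bilevels(np.array([0.0, 1.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=hst.floats(-1000, 1000), scale=hst.floats(0.01, 100))
    def test_shift_and_scale_covariance(self, shift, scale):
        rng = np.random.default_rng(99)
        x = np.concatenate([rng.normal(0, 0.2, 300), rng.normal(5, 0.2, 300)])
        base = estimate_bilevels(x)
        shifted = estimate_bilevels(x + shift)
        assert shifted.lower == pytest.approx(base.lower + shift, abs=1e-8)
        assert shifted.upper == pytest.approx(base.upper + shift, abs=1e-8)
        assert shifted.reference == pytest.approx(
            base.reference + shift, abs=1e-8
        )
        scaled = estimate_bilevels(x * scale)
        assert scaled.amp_range == pytest.approx(
            base.amp_range * scale, rel=1e-9
        )
        assert scaled.lower == pytest.approx(base.lower * scale, rel=1e-9)
        assert scaled.reference == pytest.approx(
            base.reference * scale, rel=1e-9
        )


def _square_wave(period_s=1.0, duty=0.6, fs=100.0, n_periods=10):
    high = int(period_s * fs * duty)
    low = int(period_s * fs) - high
    return np.tile([10.0] * high + [0.0] * low, n_periods)


class TestDetection:
    def test_square_wave_duty_cycle_recovered(self):
        # strides are exact (edges interpolate identically cycle to cycle);
        # stance/swing are exact up to the sub-sample interpolation offset,
        # since each step transition is localized within one sample interval
        fs = 100.0
        x = np.tile([0.0] * 40 + [10.0] * 60, 10)
        seq = detect_events(x, estimate_bilevels(x), fs)
        stance = seq.toe_offs[: seq.heel_strikes.size] - seq.heel_strikes[
            : seq.toe_offs.size
        ]
        strides = np.diff(seq.heel_strikes)
        np.testing.assert_allclose(strides, 1.0, atol=1e-9)
        np.testing.assert_allclose(stance, 0.6, atol=1.0 / fs)
        assert np.ptp(stance) < 1e-9  # all stances identical

    def test_signal_below_reference_yields_empty_sequence(self):
        bl = BilevelEstimate(0.0, 10.0, 1.0, 10.0, 1.0, 10, 0, 9)
        seq = detect_events(np.zeros(100), bl, 100.0)
        assert seq.heel_strikes.size == 0 and seq.toe_offs.size == 0

    def test_sequence_starts_with_heel_strike_and_alternates(self):
        # start mid-stance: leading toe-off must be trimmed
        x = np.concatenate([[10.0] * 30, np.tile([0.0] * 40 + [10.0] * 60, 5)])
        seq = detect_events(x, estimate_bilevels(x), 100.0)
        assert seq.heel_strikes[0] < seq.toe_offs[0]
        merged = np.sort(np.concatenate([seq.heel_strikes, seq.toe_offs]))
        labels = [
            "hs" if t in seq.heel_strikes else "to" for t in merged
        ]
        assert labels == ["hs", "to"] * (len(labels) // 2) + (
            ["hs"] if len(labels) % 2 else []
        )

    def test_debounce_removes_chatter(self):
        fs = 100.0
        x = np.tile([0.0] * 40 + [10.0] * 60, 5)
        # inject one-sample chatter dips near a rising edge
        x[141] = 0.0
        seq_clean = detect_events(
            np.tile([0.0] * 40 + [10.0] * 60, 5), estimate_bilevels(x), fs
        )
        seq = detect_events(x, estimate_bilevels(x), fs)
        assert seq.heel_strikes.size == seq_clean.heel_strikes.size
        assert seq.toe_offs.size == seq_clean.toe_offs.size


class TestDurations:
    def test_hand_example(self):
        seq = EventSequence(
            "left", np.array([0.0, 1.0, 2.0]), np.array([0.6, 1.6])
        )
        d = durations_from_events(seq)
        np.testing.assert_allclose(d.stride_s, [1.0, 1.0])
        np.testing.assert_allclose(d.stance_s, [0.6, 0.6])
        np.testing.assert_allclose(d.swing_s, [0.4, 0.4])

    def test_stride_identity_on_detected_events(self, noisy_als_record):
        record, _ = noisy_als_record
        est = estimate_bilevels(record.left)
        seq = detect_events(record.left, est, record.fs_hz)
        d = durations_from_events(seq)
        assert d.n_cycles > 50
        np.testing.assert_allclose(
            d.stride_s, d.stance_s + d.swing_s, atol=1e-9
        )
        assert np.all(d.stance_s > 0) and np.all(d.swing_s > 0)

    def test_als_preset_mean_stride_recovered_within_two_percent(
        self, noisy_als_record
    ):
        record, _ = noisy_als_record
        config = condition_presets("ALS")
        est = estimate_bilevels(record.left)
        d = durations_from_events(
            detect_events(record.left, est, record.fs_hz)
        )
        assert np.mean(d.stride_s) == pytest.approx(
            config.stride_mean_s, rel=0.02
        )

    def test_single_heel_strike_gives_empty_series(self):
        seq = EventSequence("left", np.array([0.5]), np.array([]))
        d = durations_from_events(seq)
        assert d.n_cycles == 0


class TestExtractAllSignals:
    def _window(self, record, condition="CON"):
        return SignalWindow(
            subject_id="s", condition=condition, window_index=0,
            fs_hz=record.fs_hz, left=record.left, right=record.right,
        )

    def test_thirty_second_window_yields_expected_cycle_count(self):
        config = condition_presets("CON", duration_s=30.0, spike_rate_per_min=0.0)
        record, _ = simulate_record(config, seed=8)
        signals = extract_all_signals(self._window(record))
        for foot in ("left", "right"):
            assert abs(signals.durations[foot].n_cycles - 30.0 / 1.05) <= 3

    def test_feet_are_processed_independently(self):
        config = condition_presets("CON", duration_s=30.0, spike_rate_per_min=0.0)
        record, _ = simulate_record(config, seed=8)
        base = extract_all_signals(self._window(record))
        perturbed_record, _ = simulate_record(config, seed=8)
        perturbed_record.right[:] = np.random.default_rng(0).normal(
            size=record.n_samples
        )
        perturbed = extract_all_signals(self._window(perturbed_record))
        np.testing.assert_array_equal(
            base.events["left"].heel_strikes,
            perturbed.events["left"].heel_strikes,
        )

    def test_all_zero_channel_keeps_vgrf_but_no_durations(self):
        config = condition_presets("CON", duration_s=30.0, spike_rate_per_min=0.0)
        record, _ = simulate_record(config, seed=8)
        record.left[:] = 0.0
        signals = extract_all_signals(self._window(record))
        assert signals.vgrf["left"].size == record.n_samples
        assert signals.durations["left"].n_cycles == 0
        assert signals.durations["right"].n_cycles > 20

    def test_series_accessor_matches_components(self):
        config = condition_presets("CON", duration_s=30.0, spike_rate_per_min=0.0)
        record, _ = simulate_record(config, seed=8)
        signals = extract_all_signals(self._window(record))
        np.testing.assert_array_equal(
            signals.series("stride", "left"),
            signals.durations["left"].stride_s,
        )
        np.testing.assert_array_equal(
            signals.series("vgrf", "right"), record.right
        )
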