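"""Feature oracles: closed forms, brute-force DTW, spectral identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogstep.features import (
    FEATURE_COLUMNS,
    FeatureError,
    angular_jerk,
    basic_stats,
    dtw_distance,
    low_power_frequency,
    normalized_jerk,
    peak_geometry,
    power_spectral_entropy,
    principal_harmonic,
    spectrum,
    stride_similarity,
    trial_feature_table,
)
from fogstep.segmentation import StepSegment


def _dtw_bruteforce(a, b):
    """Independent recursive DTW oracle (exponential, tiny inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return abs(a[0] - b[0])
        if i < 0 or j < 0:
            return math.inf
        return abs(a[i] - b[j]) + min(rec(i - 1, j), rec(i, j - 1), rec(i - 1, j - 1))

    return rec(len(a) - 1, len(b) - 1)


class TestBasicStats:
    def test_alternating_unit_sequence(self):
        sd, rng_, rms = basic_stats([1, -1, 1, -1])
        assert (sd, rng_, rms) == (1.0, 2.0, 1.0)

    def test_constant_slice_degenerate(self):
        sd, rng_, rms = basic_stats([3.0] * 8)
        assert (sd, rng_) == (0.0, 0.0)
        assert rms == 3.0

    def test_unit_sine_rms_analytic_limit(self):
        t = np.linspace(0, 1, 10000, endpoint=False)
        _, _, rms = basic_stats(np.sin(2 * np.pi * t))
        assert rms == pytest.approx(1 / math.sqrt(2), abs=0.01)

    def test_too_short_slice_rejected(self):
        with pytest.raises(FeatureError):
            basic_stats([1.0])


class TestJerk:
    def test_quadratic_velocity_closed_form(self):
        # omega = t^2 on [0, 1] s: second derivative 2, so 0.5 * int 4 dt = 2
        fs = 600.0
        t = np.arange(0, 1 + 1 / fs, 1 / fs)
        assert angular_jerk(t**2, fs) == pytest.approx(2.0, rel=0.01)

    def test_linear_ramp_is_zero(self):
        fs = 60.0
        t = np.arange(0, 1, 1 / fs)
        assert angular_jerk(3.0 * t, fs) == pytest.approx(0.0, abs=1e-6 * 9.0)

    def test_sine_closed_form(self):
        # omega = sin(2 pi t): int of (2pi)^4 sin^2 over 1 s = (2pi)^4 / 2
        fs = 600.0
        t = np.arange(0, 1 + 1 / fs, 1 / fs)
        expected = (2 * np.pi) ** 4 / 4
        assert angular_jerk(np.sin(2 * np.pi * t), fs) == pytest.approx(
            expected, rel=0.01
        )

    def test_normalized_jerk_divides_by_duration(self):
        fs = 600.0
        t = np.arange(0, 1 + 1 / fs, 1 / fs)
        assert normalized_jerk(t**2, fs) == pytest.approx(2.0, rel=0.01)
        # half-duration slice with the same curvature: value doubles per
        # second of duration removed from the denominator
        half = t[: t.size // 2 + 1] ** 2
        ratio = normalized_jerk(half, fs) / angular_jerk(half, fs)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_zero_input_gives_zero(self):
        assert normalized_jerk(np.zeros(30), 60.0) == 0.0


class TestDTW:
    def test_identical_slices_cost_zero(self):
        x = np.sin(np.linspace(0, 3, 40))
        assert stride_similarity(x, x.copy()) == 0.0

    def test_three_by_three_lattice(self):
        assert dtw_distance([0, 0, 0], [1, 1, 1]) == 3.0

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_bruteforce_oracle(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(_dtw_bruteforce(tuple(a), tuple(b)))

    @given(
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=12),
        st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=12),
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetric(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))


class TestPeakGeometry:
    def test_half_sine_width_is_half_duration(self):
        fs = 600.0
        dur = 0.4
        t = np.arange(0, dur, 1 / fs)
        lobe = 2.0 * np.sin(np.pi * t / dur)
        height, width = peak_geometry(lobe, fs)
        assert height == pytest.approx(2.0, rel=1e-3)
        assert width == pytest.approx(0.2, abs=1 / fs)

    def test_rectangular_lobe_width_is_duration(self):
        fs = 60.0
        height, width = peak_geometry(np.ones(30), fs)
        assert height == 1.0
        assert width == pytest.approx(29 / fs)

    def test_scaling_changes_height_not_width(self):
        fs = 600.0
        t = np.arange(0, 0.4, 1 / fs)
        lobe = np.sin(np.pi * t / 0.4)
        h1, w1 = peak_geometry(lobe, fs)
        h2, w2 = peak_geometry(5.0 * lobe, fs)
        assert h2 == pytest.approx(5 * h1)
        assert w2 == pytest.approx(w1)


class TestSpectrum:
    def test_pure_tone_argmax_bin(self):
        fs = 60.0
        t = np.arange(0, 1, 1 / fs)
        P, freqs = spectrum(np.sin(2 * np.pi * 3 * t), fs)
        df = freqs[1] - freqs[0]
        assert freqs[np.argmax(P)] == pytest.approx(3.0, abs=df)

    def test_unit_sum_normalization(self):
        rng = np.random.default_rng(1)
        P, _ = spectrum(rng.normal(size=55), 60.0)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_parseval_total_power_tracks_variance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=64)
        x = x - x.mean()
        raw = np.abs(np.fft.rfft(x, 512)) ** 2
        # two-sided energy from the one-sided spectrum (interior bins twice)
        twosided = raw.copy()
        twosided[1:-1] *= 2
        assert twosided.sum() / 512 == pytest.approx(np.sum(x**2), rel=0.01)

    def test_all_zero_slice_rejected(self):
        with pytest.raises(FeatureError):
            spectrum(np.full(32, 2.0), 60.0)


class TestSpectralScalars:
    def test_single_bin_entropy_slightly_negative(self):
        P = np.zeros(64)
        P[0] = 1.0
        val = power_spectral_entropy(P)
        assert val == pytest.approx(-math.log(1.001), abs=1e-9)

    def test_flat_spectrum_entropy_near_log_n(self):
        P = np.full(64, 1 / 64)
        assert power_spectral_entropy(P) == pytest.approx(math.log(64), abs=0.07)

    def test_flat_exceeds_single_bin(self):
        flat = np.full(64, 1 / 64)
        single = np.zeros(64)
        single[5] = 1.0
        assert power_spectral_entropy(flat) > power_spectral_entropy(single)

    def test_unnormalized_spectrum_rejected(self):
        with pytest.raises(FeatureError):
            power_spectral_entropy(np.ones(8))

    def test_principal_harmonic_of_tone(self):
        fs = 60.0
        t = np.arange(0, 2, 1 / fs)
        P, freqs = spectrum(np.sin(2 * np.pi * 2 * t), fs)
        freq, amp, width, weighted = principal_harmonic(P, freqs)
        df = freqs[1] - freqs[0]
        assert freq == pytest.approx(2.0, abs=df)
        assert weighted == pytest.approx(amp * freq)

    def test_principal_harmonic_picks_stronger_tone(self):
        freqs = np.linspace(0, 30, 257)
        P = np.zeros(257)
        i1 = np.argmin(np.abs(freqs - 1.0))
        i4 = np.argmin(np.abs(freqs - 4.0))
        P[i1], P[i4] = 0.6, 0.4
        freq, amp, width, _ = principal_harmonic(P, freqs)
        assert freq == pytest.approx(1.0, abs=freqs[1])
        # isolated single-bin peak: interpolated width at most two bins
        assert width <= 2 * (freqs[1] - freqs[0]) + 1e-12

    def test_low_power_frequency_tones(self):
        fs = 60.0
        t = np.arange(0, 1, 1 / fs)
        P1, f1 = spectrum(np.sin(2 * np.pi * 1 * t), fs)
        P5, f5 = spectrum(np.sin(2 * np.pi * 5 * t), fs)
        assert low_power_frequency(P1, f1) >= 0.95
        assert low_power_frequency(P5, f5) <= 0.05

    def test_low_power_frequency_equal_mixture(self):
        fs = 60.0
        t = np.arange(0, 2, 1 / fs)
        x = np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 5 * t)
        P, freqs = spectrum(x, fs)
        assert low_power_frequency(P, freqs) == pytest.approx(0.5, abs=0.05)


class TestFeatureTable:
    def test_steady_gait_step_properties(self, clean_recording):
        table = trial_feature_table(clean_recording)
        assert (table["low_power_frequency"] > 0.8).all()
        assert (table["stride_similarity"] < 0.5).all()

    def test_schema_and_no_missing_values(self, clean_recording):
        table = trial_feature_table(clean_recording)
        assert list(table.columns[:16]) == FEATURE_COLUMNS
        assert not table[FEATURE_COLUMNS].isna().any().any()

    def test_first_steps_dropped_by_missing_data_policy(
        self, clean_trial, clean_recording
    ):
        table = trial_feature_table(clean_recording)
        truth_total = clean_trial.truth.n_steps()
        # each leg loses its first peak (no stride) and its first segment
        # (no previous stride for DTW); left additionally lacks an earlier
        # contralateral peak for its first retained step
        assert len(table) < truth_total
        assert truth_total - len(table) <= 5

    def test_scale_covariance_through_normalization(self, clean_trial):
        """Scaling the raw signal leaves every feature unchanged."""
        import copy

        from fogstep.pipeline import recording_from_synthetic

        scaled = copy.deepcopy(clean_trial)
        scaled.left_raw.samples = scaled.left_raw.samples * 7.3
        scaled.right_raw.samples = scaled.right_raw.samples * 7.3
        base = trial_feature_table(recording_from_synthetic(clean_trial))
        after = trial_feature_table(recording_from_synthetic(scaled))
        np.testing.assert_allclose(
            base[FEATURE_COLUMNS].to_numpy(),
            after[FEATURE_COLUMNS].to_numpy(),
            rtol=1e-9,
            atol=1e-12,
        )

    def test_step_time_half_stride_for_alternating_gait(self, clean_recording):
        table = trial_feature_table(clean_recording)
        ratio = table["step_time_s"] / table["stride_time_s"]
        assert np.abs(ratio - 0.5).max() <= 0.1
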