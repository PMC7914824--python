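import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from neopcg import FEATURE_NAMES, PointContext, SimulationParams, simulate_cycle
from neopcg.features import (
    DB_EPS,
    SUB_BANDS,
    WIDE_BAND,
    bandpass_filter,
    derivative_discontinuity_count,
    energy_and_rms,
    envelope_poly_coeffs,
    extract_cycle_features,
    extrema_timing_stats,
    frq_zero,
    octave_deviation,
    position_skewness,
    quarter_profile,
    spectral_centroid_0_200,
    zero_crossing_count,
)

RATE = 2000.0


def _tone(freq, duration=1.0, amplitude=1.0, rate=RATE):
    t = np.arange(int(rate * duration)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


def _ctx():
    return PointContext(mean_cycle_duration=0.42,
                        mean_fc={"S1": 90.0, "m1": 50.0, "S2": 110.0, "m2": 50.0})


def _cycle(label="healthy", gain=3.0, seed=0):
    params = SimulationParams(murmur_gain=gain)
    return simulate_cycle(label, params, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# primitive operators against brute-force oracles
# ---------------------------------------------------------------------------

class TestBandpass:
    def test_zeros_in_zeros_out(self):
        out = bandpass_filter(np.zeros(500), RATE, 80, 200)
        np.testing.assert_array_equal(out, np.zeros(500))

    def test_passband_tone_preserved(self):
        x = _tone(100)
        out = bandpass_filter(x, RATE, 80, 200)
        assert np.sqrt(np.mean(out**2)) >= 0.9 * np.sqrt(np.mean(x**2))

    def test_stopband_tone_attenuated(self):
        x = _tone(20)
        out = bandpass_filter(x, RATE, 80, 200)
        assert np.sqrt(np.mean(out**2)) <= 0.1 * np.sqrt(np.mean(x**2))

    def test_band_to_nyquist_becomes_highpass(self):
        x = _tone(700)
        out = bandpass_filter(x, RATE, 400, 1000)
        assert np.sqrt(np.mean(out**2)) >= 0.9 * np.sqrt(np.mean(x**2))
        low = bandpass_filter(_tone(100), RATE, 400, 1000)
        assert np.sqrt(np.mean(low**2)) <= 0.1

    def test_output_length_matches_input(self):
        for n in (40, 103, 500):
            assert len(bandpass_filter(np.random.default_rng(0).normal(size=n),
                                       RATE, 25, 45)) == n


class TestEnergyRms:
    def test_three_four(self):
        energy, rms, _, _ = energy_and_rms(np.array([3.0, 4.0]))
        assert energy == 25.0
        assert rms == pytest.approx(np.sqrt(12.5), abs=1e-12)

    def test_zero_floor(self):
        energy, rms, en_db, rms_db = energy_and_rms(np.zeros(10))
        assert energy == 0.0 and rms == 0.0
        assert en_db == pytest.approx(10 * np.log10(DB_EPS))
        assert en_db == pytest.approx(-120.0)

    def test_matches_direct_summation(self, rng):
        x = rng.normal(size=256)
        energy, rms, en_db, rms_db = energy_and_rms(x)
        brute = sum(float(v) ** 2 for v in x)
        assert energy == pytest.approx(brute, rel=1e-12)
        assert rms == pytest.approx(np.sqrt(brute / 256), rel=1e-12)
        assert en_db == pytest.approx(10 * np.log10(brute + DB_EPS), rel=1e-12)


class TestZeroCrossings:
    @pytest.mark.parametrize("x,expected", [
        ([1, -1, 1, -1], 3),
        ([1, 2, 3, 4], 0),
        ([1, 0, -1], 1),       # zero separates opposite signs: one crossing
        ([1, 0, 1], 0),        # zero without a sign change: none
        ([-1, 0, 0, 2, -3], 2),
    ])
    def test_convention(self, x, expected):
        assert zero_crossing_count(np.array(x, dtype=float)) == expected

    def test_matches_linear_scan(self, rng):
        x = rng.normal(size=300)
        count = 0
        last = 0.0
        for v in x:
            s = np.sign(v)
            if s == 0:
                continue
            if last != 0 and s != last:
                count += 1
            last = s
        assert zero_crossing_count(x) == count

    def test_frq_zero_of_tone(self):
        x = _tone(100, duration=1.0)
        assert frq_zero(x, RATE) == pytest.approx(200, abs=2)

    def test_frq_zero_formula(self):
        assert frq_zero(np.array([1.0, -1.0]), 2.0) == 1.0
        assert frq_zero(np.ones(10), RATE) == 0.0


class TestSpectralCentroid:
    def test_dc_returns_zero(self):
        assert spectral_centroid_0_200(np.ones(64), RATE) == 0.0

    def test_pure_tone(self):
        assert spectral_centroid_0_200(_tone(100), RATE) == pytest.approx(100, abs=1)

    def test_two_tone_mean(self):
        x = _tone(50) + _tone(150)
        assert spectral_centroid_0_200(x, RATE) == pytest.approx(100, abs=2)

    def test_matches_explicit_dft_oracle(self, rng):
        x = rng.normal(size=512)
        n = len(x)
        num = den = 0.0
        for k in range(1, n // 2 + 1):
            f = k * RATE / n
            if f > 200:
                break
            mag = abs(np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)))
            num += f * mag
            den += mag
        assert spectral_centroid_0_200(x, RATE) == pytest.approx(num / den, rel=1e-9)


class TestOctaveDeviation:
    @pytest.mark.parametrize("fc,ref,expected", [(200, 100, 1.0), (100, 100, 0.0),
                                                 (50, 100, -1.0), (0, 100, 0.0)])
    def test_values(self, fc, ref, expected):
        assert octave_deviation(fc, ref) == pytest.approx(expected)

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            octave_deviation(100, 0)


class TestEnvelopePoly:
    def test_constant_signal(self):
        a0, a1, a2 = envelope_poly_coeffs(np.full(400, 0.7) * np.sin(
            2 * np.pi * 100 * np.arange(400) / RATE + np.pi / 3) + 0j.real
        ) if False else envelope_poly_coeffs(0.7 * np.sin(
            2 * np.pi * 100 * np.arange(400) / RATE))
        # envelope of a pure tone is its amplitude
        assert a0 + a1 * 0.5 + a2 * 0.25 == pytest.approx(0.7, abs=0.05)

    def test_zeros(self):
        assert envelope_poly_coeffs(np.zeros(100)) == (0.0, 0.0, 0.0)

    def test_linear_ramp_slope(self):
        n = 2000
        t = np.arange(n) / RATE
        x = (np.arange(n) / n) * np.sin(2 * np.pi * 100 * t)
        a0, a1, a2 = envelope_poly_coeffs(x)
        # least-squares fit on the true ramp envelope has slope 1
        assert a1 == pytest.approx(1.0, abs=0.1)


class TestExtremaTiming:
    def test_three_sine_periods(self):
        t = np.arange(600) / 600
        x = np.sin(2 * np.pi * 3 * t)
        stats = extrema_timing_stats(x)
        assert stats["n_max"] == 3 and stats["n_min"] == 3

    def test_constant_is_degenerate(self):
        stats = extrema_timing_stats(np.ones(50))
        assert stats["n_max"] == 0 and stats["n_min"] == 0
        for key in ("mean_t_max", "std_dt_min", "mean_t_zero", "std_dt_zero"):
            assert stats[key] == 0.0

    def test_absolute_extrema_against_scan(self, rng):
        x = rng.normal(size=173)
        stats = extrema_timing_stats(x)
        assert stats["a_max"] == x.max()
        assert stats["t_max"] == list(x).index(x.max()) / 172
        assert stats["a_min"] == x.min()
        assert stats["max_a"] == np.abs(x).max()

    def test_local_extrema_match_bruteforce_scan(self, rng):
        x = rng.normal(size=211)
        stats = extrema_timing_stats(x)
        maxima = [i for i in range(1, 210) if x[i] > x[i - 1] and x[i] > x[i + 1]]
        minima = [i for i in range(1, 210) if x[i] < x[i - 1] and x[i] < x[i + 1]]
        assert stats["n_max"] == len(maxima)
        assert stats["n_min"] == len(minima)
        t = np.array(maxima) / 211
        assert stats["mean_t_max"] == pytest.approx(t.mean(), rel=1e-12)
        assert stats["std_t_max"] == pytest.approx(t.std(), rel=1e-12)
        dt = np.diff(t)
        assert stats["mean_dt_max"] == pytest.approx(dt.mean(), rel=1e-12)
        assert stats["std_dt_max"] == pytest.approx(dt.std(), rel=1e-12)

    def test_plateau_counts_once(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -2.0, 0.0])
        stats = extrema_timing_stats(x)
        assert stats["n_max"] == 1
        assert stats["n_min"] == 1


class TestQuarterProfile:
    def test_all_ones_length8(self):
        prof = quarter_profile(np.ones(8))
        for k in range(1, 5):
            assert prof[f"en_q{k}"] == 2.0
            assert prof[f"mean_q{k}"] == 1.0
            assert prof[f"std_q{k}"] == 0.0

    def test_impulse_first_quarter(self):
        x = np.zeros(8)
        x[0] = 1.0
        prof = quarter_profile(x)
        assert [prof[f"en_q{k}"] for k in range(1, 5)] == [1.0, 0.0, 0.0, 0.0]

    def test_remainder_goes_to_last_quarter(self, rng):
        x = rng.normal(size=103)
        prof = quarter_profile(x)
        q = 103 // 4  # 25; last quarter gets 28 samples
        segments = [x[:q], x[q:2 * q], x[2 * q:3 * q], x[3 * q:]]
        assert len(segments[3]) == 28
        for k, seg in enumerate(segments, start=1):
            assert prof[f"en_q{k}"] == pytest.approx(np.sum(seg**2), rel=1e-12)
            assert prof[f"mean_q{k}"] == pytest.approx(seg.mean(), rel=1e-12)
            assert prof[f"std_q{k}"] == pytest.approx(seg.std(), rel=1e-12)
        assert prof["mean"] == pytest.approx(x.mean(), rel=1e-12)
        assert prof["std"] == pytest.approx(x.std(), rel=1e-12)


class TestPositionSkewness:
    def test_midpoint_zero(self):
        x = np.zeros(11)
        x[5] = 2.0
        assert position_skewness(x) == 0.0

    def test_edges(self):
        x = np.zeros(10)
        x[-1] = -3.0
        assert position_skewness(x) == 1.0
        x = np.zeros(10)
        x[0] = 3.0
        assert position_skewness(x) == -1.0


class TestDerivativeDiscontinuities:
    def test_line_and_constant(self):
        assert derivative_discontinuity_count(np.linspace(0, 1, 50)) == 0
        assert derivative_discontinuity_count(np.full(50, 3.0)) == 0

    def test_smooth_sine_has_none(self):
        assert derivative_discontinuity_count(_tone(30, duration=0.5)) == 0

    def test_injected_kink_detected_once(self):
        x = _tone(10, duration=0.5, amplitude=0.1)
        x[500:] += 50 * 0.002 * np.arange(len(x) - 500)  # slope break at 500
        assert derivative_discontinuity_count(x) == 1


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

class TestFullVector:
    def test_census(self):
        assert len(FEATURE_NAMES) == 200
        assert len(set(FEATURE_NAMES)) == 200
        per_interval = {iv: sum(n.startswith(iv + "_") for n in FEATURE_NAMES)
                        for iv in ("S1", "m1", "S2", "m2")}
        assert per_interval == {"S1": 29 + 22, "S2": 29 + 22,
                                "m1": 29 + 19, "m2": 29 + 19}
        assert "bpm" in FEATURE_NAMES and "cycle_trel" in FEATURE_NAMES

    def test_any_valid_cycle_yields_200(self):
        x, cyc = _cycle("PDA")
        vec = extract_cycle_features(x, cyc, _ctx())
        assert list(vec) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in vec.values())

    def test_all_zero_audio(self):
        x, cyc = _cycle()
        vec = extract_cycle_features(np.zeros_like(x), cyc, _ctx())
        for name, value in vec.items():
            if name.endswith(("en_lin", "rms_lin")) or name.endswith("_energy"):
                assert value == 0.0
            if name.endswith("_db"):
                assert value == pytest.approx(-120.0)

    def test_determinism(self):
        x, cyc = _cycle("CHD", seed=5)
        v1 = extract_cycle_features(x, cyc, _ctx())
        v2 = extract_cycle_features(x, cyc, _ctx())
        assert v1 == v2

    def test_db_linear_consistency(self):
        x, cyc = _cycle("PDA", seed=2)
        vec = extract_cycle_features(x, cyc, _ctx())
        for name, value in vec.items():
            if name.endswith("en_db"):
                lin = vec[name.replace("en_db", "en_lin")]
                assert value == pytest.approx(10 * np.log10(lin + DB_EPS), rel=1e-12)
            if name.endswith("rms_db"):
                lin = vec[name.replace("rms_db", "rms_lin")]
                assert value == pytest.approx(10 * np.log10(lin + DB_EPS), rel=1e-12)

    def test_energy_equals_n_rms_squared(self):
        x, cyc = _cycle(seed=3)
        slices = cyc.interval_slices()
        vec = extract_cycle_features(x, cyc, _ctx())
        for iv in ("S1", "m1", "S2", "m2"):
            n = slices[iv].stop - slices[iv].start
            en, rms = vec[f"{iv}_bw_en_lin"], vec[f"{iv}_bw_rms_lin"]
            assert en == pytest.approx(n * rms**2, rel=1e-9)

    def test_subband_parseval_sanity(self, rng):
        """Sub-band energies must roughly partition the wide-band energy."""
        for _ in range(100):
            x = rng.normal(size=300)
            wide = np.sum(bandpass_filter(x, RATE, *WIDE_BAND) ** 2)
            total = sum(np.sum(bandpass_filter(x, RATE, *band) ** 2)
                        for band in SUB_BANDS)
            assert total <= 1.1 * wide

    def test_short_interval_rejected(self):
        # the cycle type itself refuses sub-2-sample intervals ...
        from neopcg.io import SegmentedCycle
        with pytest.raises(ValueError):
            SegmentedCycle(0, 140, 141, 241, 840)
        # ... and extraction names the interval when the audio is truncated
        x, cyc = _cycle()
        with pytest.raises(ValueError, match="m2"):
            extract_cycle_features(x[:cyc.m2_start + 1], cyc, _ctx())

    def test_murmur_effect_visible_in_m1_b4_energy(self):
        """Systolic 200-400 Hz energy separates CHD from healthy cycles."""
        rng = np.random.default_rng(8)
        params = SimulationParams(murmur_gain=3.0)
        chd, healthy = [], []
        for _ in range(200):
            for label, store in (("CHD", chd), ("healthy", healthy)):
                x, cyc = simulate_cycle(label, params, rng)
                vec = extract_cycle_features(x, cyc, _ctx())
                store.append(vec["m1_b4_en_lin"])
        assert mannwhitneyu(chd, healthy, alternative="greater").pvalue < 0.01
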