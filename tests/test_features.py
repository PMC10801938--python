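"""Expert-feature oracles: closed forms, brute-force loops, spectral checks."""

import numpy as np
import pytest

from fhrfusion.features import (
    FEATURE_NAMES,
    FREQUENCY_DOMAIN_NAMES,
    NONLINEAR_NAMES,
    TIME_DOMAIN_NAMES,
    BaselineEstimate,
    RRSeries,
    estimate_baseline,
    extract_features,
    fhr_to_rr,
    frequency_domain_features,
    nonlinear_features,
    time_domain_features,
)
from fhrfusion.records import FHRRecord, SAMPLING_RATE_HZ, WINDOW_SAMPLES
from fhrfusion.simulate import make_fixture

FS = SAMPLING_RATE_HZ


# --------------------------------------------------------------------------
# brute-force oracles (direct-definition loops, independent of the library)
# --------------------------------------------------------------------------


def brute_force_hrv(rr):
    nn = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
    mean_nn = sum(nn) / len(nn)
    sdnn = (sum((d - mean_nn) ** 2 for d in nn) / len(nn)) ** 0.5
    rmssd = (sum(d * d for d in nn) / len(nn)) ** 0.5
    nn50 = sum(1 for d in nn if abs(d) > 50.0)
    sd1 = (sum(d * d for d in nn) / len(nn) / 2.0) ** 0.5
    s = [(rr[i + 1] + rr[i]) / 2**0.5 for i in range(len(rr) - 1)]
    mean_s = sum(s) / len(s)
    sd2 = (sum((v - mean_s) ** 2 for v in s) / len(s)) ** 0.5
    return {
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / len(nn),
        "SD1": sd1,
        "SD2": sd2,
    }


def _tdf(rr_values):
    rr = RRSeries(np.asarray(rr_values, dtype=float))
    base = BaselineEstimate(baseline=np.full(len(rr_values), 140.0), events=[])
    return time_domain_features(rr, base)


class TestRRConversion:
    def test_samplewise_formula(self):
        rr = fhr_to_rr(np.array([120.0]))
        np.testing.assert_allclose(rr.rr, [500.0])

    def test_nn_is_successive_difference(self):
        rr = fhr_to_rr(np.array([150.0, 100.0]))
        np.testing.assert_allclose(rr.rr, [400.0, 600.0])
        np.testing.assert_allclose(rr.nn, [200.0])

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            fhr_to_rr(np.array([120.0, 0.0]))


class TestBaseline:
    def test_constant_signal(self):
        est = estimate_baseline(np.full(2400, 140.0))
        np.testing.assert_allclose(est.baseline, 140.0)
        assert est.events == []

    @pytest.mark.parametrize("sign,acc,dec", [(+1, 1, 0), (-1, 0, 1)])
    def test_single_event_detected(self, sign, acc, dec):
        x = np.full(4800, 140.0)
        x[2000:2120] += sign * 20.0  # 30 s excursion, 20 bpm
        est = estimate_baseline(x)
        assert est.n_accelerations == acc
        assert est.n_decelerations == dec
        assert abs(est.baseline.mean() - 140.0) < 1.0

    def test_subthreshold_excursions_ignored(self):
        x = np.full(4800, 140.0)
        x[1000:1120] += 10.0          # too small (10 < 15 bpm)
        x[3000:3040] += 20.0          # too short (10 s < 15 s)
        est = estimate_baseline(x)
        assert est.events == []

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.full(100, 140.0))


class TestTimeDomain:
    def test_constant_rr_zero_variability(self):
        out = _tdf(np.full(300, 500.0))
        for key in ("SDNN", "RMSSD", "NN50", "pNN50", "STV", "LTV"):
            assert out[key] == 0.0

    def test_alternating_closed_form(self):
        rr = np.tile([500.0, 560.0], 100)
        out = _tdf(rr)
        assert out["RMSSD"] == pytest.approx(60.0)
        assert out["pNN50"] == pytest.approx(100.0)

    def test_symmetric_series_zero_skew(self, rng):
        sym = np.concatenate([[400, 500, 600]] * 50).astype(float)
        assert _tdf(sym)["skew_rr"] == pytest.approx(0.0, abs=1e-9)

    def test_brute_force_agreement(self, rng):
        for _ in range(5):
            rr = rng.uniform(350, 650, size=50)
            out = _tdf(rr)
            expect = brute_force_hrv(list(rr))
            for key in ("SDNN", "RMSSD", "NN50", "pNN50"):
                assert out[key] == pytest.approx(expect[key], abs=1e-9)

    def test_stv_epoch_definition(self):
        # rr constant within each 2.5 s epoch, stepping by 8 ms per epoch
        rr = np.repeat(np.arange(480.0, 480.0 + 8 * 24, 8.0), 10)
        out = _tdf(rr)
        assert out["STV"] == pytest.approx(8.0)

    def test_tri_bounds(self, rng):
        rr = rng.uniform(350, 650, size=1000)
        out = _tdf(rr)
        assert out["Tri"] >= 1.0
        assert out["TINN"] >= 0.0


def sinusoid_rr(freqs_amps, n=WINDOW_SAMPLES, mean=430.0):
    """rr series whose spectrum (in cumulative-rr time) holds given tones."""
    rr = np.empty(n)
    t = 0.0
    for i in range(n):
        rr[i] = mean + sum(
            a * np.sin(2 * np.pi * f * t + ph) for f, a, ph in freqs_amps
        )
        t += rr[i] / 1000.0
    return rr


class TestFrequencyDomain:
    def _features_for_rr(self, rr):
        return frequency_domain_features(RRSeries(rr))

    @pytest.mark.parametrize(
        "freq,band", [(0.01, "VLF"), (0.1, "LF"), (0.25, "MF"), (0.7, "HF")]
    )
    def test_sinusoid_peak_recovered_in_band(self, freq, band):
        rr = sinusoid_rr([(freq, 40.0, 0.0)])
        out = self._features_for_rr(rr)
        assert out[f"rr_peak_{band}"] == pytest.approx(freq, abs=0.005)
        assert out[f"rr_percent_{band}"] > 90.0

    def test_percentages_sum_to_100(self, rng):
        rr = 430.0 + rng.normal(0, 20, size=WINDOW_SAMPLES)
        out = self._features_for_rr(rr)
        total = sum(out[f"rr_percent_{b}"] for b in ("VLF", "LF", "MF", "HF"))
        assert total == pytest.approx(100.0)

    def test_two_sinusoids_band_split(self):
        rr = sinusoid_rr([(0.25, 30.0, 0.0), (0.7, 30.0, 1.0)])
        out = self._features_for_rr(rr)
        assert out["rr_peak_MF"] == pytest.approx(0.25, abs=0.01)
        assert out["rr_peak_HF"] == pytest.approx(0.7, abs=0.01)
        # LF nearly empty relative to MF+HF
        assert out["rr_ratio"] < 0.1

    def test_band_powers_nonnegative(self, rng):
        rr = 430.0 + rng.normal(0, 15, size=WINDOW_SAMPLES)
        out = self._features_for_rr(rr)
        for b in ("VLF", "LF", "MF", "HF"):
            assert out[f"rr_{b}"] >= 0.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            self._features_for_rr(np.full(100, 430.0))


class TestNonlinear:
    def test_sd1_equals_rmssd_over_sqrt2(self, rng):
        rr = rng.uniform(350, 650, size=300)
        out = nonlinear_features(RRSeries(rr))
        rmssd = np.sqrt(np.mean(np.diff(rr) ** 2))
        assert out["SD1"] == pytest.approx(rmssd / np.sqrt(2), rel=1e-12)

    def test_sd1_sd2_brute_force(self, rng):
        rr = rng.uniform(350, 650, size=120)
        out = nonlinear_features(RRSeries(rr))
        expect = brute_force_hrv(list(rr))
        assert out["SD1"] == pytest.approx(expect["SD1"], abs=1e-9)
        assert out["SD2"] == pytest.approx(expect["SD2"], abs=1e-9)

    def test_constant_series_degenerate_values(self):
        out = nonlinear_features(RRSeries(np.full(500, 430.0)))
        assert out["ShannEn"] == 0.0
        assert out["ApEn"] == 0.0 and out["SampEn"] == 0.0
        assert out["SD_Ratio"] == 0.0
        # LZ parsing of a constant sequence has exactly 2 phrases
        n = 500
        assert out["LZC"] == pytest.approx(2.0 * np.log2(n) / n)

    def test_white_noise_hurst_near_half(self):
        vals = []
        for seed in range(20):
            rr = 430.0 + np.random.default_rng(seed).normal(0, 20, size=4096)
            vals.append(nonlinear_features(RRSeries(rr))["Hurst"])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_entropies_nonnegative(self, rng):
        rr = 430.0 + rng.normal(0, 20, size=400)
        out = nonlinear_features(RRSeries(rr))
        for key in ("ApEn", "SampEn", "FuzzyEn", "ShannEn"):
            assert out[key] >= 0.0


class TestExtractFeatures:
    def test_group_sizes(self):
        assert len(TIME_DOMAIN_NAMES) == 21
        assert len(FREQUENCY_DOMAIN_NAMES) == 14
        assert len(NONLINEAR_NAMES) == 10
        assert len(FEATURE_NAMES) == 45

    def test_vector_is_finite_and_ordered(self):
        rec = make_fixture("white_noise", seed=5)
        vec = extract_features(rec)
        assert vec.shape == (45,)
        assert np.all(np.isfinite(vec))

    def test_deterministic(self):
        rec = make_fixture("white_noise", seed=7)
        np.testing.assert_array_equal(extract_features(rec), extract_features(rec))

    def test_sensitive_to_perturbation(self):
        rec = make_fixture("white_noise", seed=7)
        bumped = FHRRecord(fhr=rec.fhr.copy())
        bumped.fhr[-1] += 1.0
        assert np.any(extract_features(rec) != extract_features(bumped))

    def test_constant_fixture_known_values(self):
        vec = extract_features(make_fixture("constant", bpm=140.0))
        named = dict(zip(FEATURE_NAMES, vec))
        for key in ("SDNN", "RMSSD", "nACC", "nDEC", "STV", "ShannEn"):
            assert named[key] == 0.0
        assert named["mean_baseline"] == pytest.approx(140.0)

    def test_time_shift_invariance(self, rng):
        # periodic signal: rolling by whole periods leaves features unchanged
        rec = make_fixture("alternating_rr", a=500.0, b=560.0)
        rolled = FHRRecord(fhr=np.roll(rec.fhr, 2))
        np.testing.assert_allclose(
            extract_features(rec), extract_features(rolled), rtol=1e-9
        )

    def test_scaling_rr_scales_dispersion_features(self, rng):
        rr = 430.0 + rng.normal(0, 20, size=300)
        base = nonlinear_features(RRSeries(rr))
        scaled = nonlinear_features(RRSeries(2.0 * rr))
        for key in ("SD1", "SD2"):
            assert scaled[key] == pytest.approx(2.0 * base[key], rel=1e-9)
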