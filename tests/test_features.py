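import numpy as np
import pytest
from scipy import signal

import wingradar as wr
from wingradar.detection import MicroDopplerSegment
from wingradar.features import (
    DEFAULT_BANDS,
    RegistryError,
    SPECTRAL_TEMPORAL_NAMES,
)

from conftest import wingbeat_with_noise

FS = 1000.0


def make_segment(x, eta=0.8, species="", fs=FS):
    return MicroDopplerSegment(
        samples=np.asarray(x, dtype=float),
        fs=fs,
        start_s=0.0,
        duration_s=len(x) / fs,
        eta_hr=eta,
        species_name=species,
    )


class TestRegistry:
    def test_default_registry_emits_exactly_70_unique_names(self):
        reg = wr.default_registry()
        assert len(reg.names) == 70
        assert len(set(reg.names)) == 70

    def test_canonical_feature_names_present(self):
        names = set(wr.default_registry().names)
        for name in wr.CANONICAL_NAMES:
            assert name in names, name

    def test_misconfigured_registry_rejected(self):
        bad = wr.FeatureRegistry(mel=wr.MelSpec(n_coeffs=13))
        with pytest.raises(RegistryError):
            bad.validate()


class TestMfcc:
    def test_stationary_tone_has_zero_deltas(self):
        t = np.arange(2000) / FS
        out = wr.mfcc_block(np.cos(2 * np.pi * 150 * t), FS, wr.MelSpec())
        # phase-dependent leakage makes per-subframe cepstra oscillate, but
        # the aggregated deltas cancel; delta-deltas keep a small residual
        for i in range(14):
            assert abs(out[f"mfccDelta{i}"]) < 1e-6
            assert abs(out[f"mfccDeltaDelta{i}"]) < 0.1

    def test_amplitude_scale_moves_only_zeroth_coefficient(self):
        x = wingbeat_with_noise(150.0, (1.0, 0.5), 20.0, seed=1)
        a = wr.mfcc_block(x, FS, wr.MelSpec())
        b = wr.mfcc_block(5.0 * x, FS, wr.MelSpec())
        assert abs(a["mfcc0"] - b["mfcc0"]) > 0.1
        for i in range(1, 14):
            assert a[f"mfcc{i}"] == pytest.approx(b[f"mfcc{i}"], abs=1e-9)

    def test_chirp_raises_delta_magnitude_over_stationary(self):
        t = np.arange(2000) / FS
        stationary = np.cos(2 * np.pi * 150 * t)
        chirp = signal.chirp(t, f0=120.0, f1=280.0, t1=2.0)
        ms = wr.MelSpec()
        d_stat = np.array([wr.mfcc_block(stationary, FS, ms)[f"mfccDelta{i}"] for i in range(14)])
        d_chirp = np.array([wr.mfcc_block(chirp, FS, ms)[f"mfccDelta{i}"] for i in range(14)])
        assert np.abs(d_chirp).mean() > np.abs(d_stat).mean()

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            wr.mfcc_block(np.zeros(2), FS, wr.MelSpec())


class TestF0Estimators:
    SPEC = wr.F0SearchSpec()

    @pytest.mark.parametrize(
        "fn", [wr.estimate_f0_pef, wr.estimate_f0_wavelet, wr.estimate_f0_ncf]
    )
    def test_recovers_150hz_three_harmonics(self, fn):
        x = wingbeat_with_noise(150.0, (1.0, 0.5, 0.25), 20.0, seed=2)
        assert fn(x, FS, self.SPEC) == pytest.approx(150.0, abs=2.5)

    @pytest.mark.parametrize(
        "fn", [wr.estimate_f0_pef, wr.estimate_f0_wavelet, wr.estimate_f0_ncf]
    )
    def test_recovers_pure_fundamental(self, fn):
        t = np.arange(2000) / FS
        assert fn(np.cos(2 * np.pi * 220 * t), FS, self.SPEC) == pytest.approx(220.0, abs=2.5)

    @pytest.mark.parametrize(
        "fn", [wr.estimate_f0_pef, wr.estimate_f0_wavelet, wr.estimate_f0_ncf]
    )
    def test_white_noise_flagged_missing(self, fn):
        x = np.random.default_rng(3).normal(size=2000)
        assert np.isnan(fn(x, FS, self.SPEC))

    def test_ncf_integer_period_exact(self):
        t = np.arange(2000) / FS
        x = np.cos(2 * np.pi * 200 * t)  # lag 5 samples exactly
        assert wr.estimate_f0_ncf(x, FS, self.SPEC) == pytest.approx(200.0, abs=0.5)

    def test_estimators_agree_on_clean_segments(self):
        rng = np.random.default_rng(4)
        for i in range(20):
            f_w = float(rng.uniform(100, 300))
            n_h = max(1, min(3, int(480 // f_w)))
            x = wingbeat_with_noise(f_w, (1.0, 0.5, 0.25)[:n_h], 25.0, seed=100 + i)
            ests = [
                fn(x, FS, self.SPEC)
                for fn in (wr.estimate_f0_pef, wr.estimate_f0_wavelet, wr.estimate_f0_ncf)
            ]
            assert np.all(np.isfinite(ests))
            assert max(ests) - min(ests) <= 5.0


class TestBandPower:
    def test_tone_concentrates_in_its_band(self):
        t = np.arange(2000) / FS
        out = wr.band_power_ratios(np.cos(2 * np.pi * 120 * t), FS)
        assert out["bandPower_100_150"] > 0.95
        assert out["bandPower_300_350"] < 0.01

    def test_fractions_sum_at_most_one(self):
        x = np.random.default_rng(5).normal(size=2000)
        out = wr.band_power_ratios(x, FS)
        total = sum(out.values())
        assert 0.0 < total <= 1.0 + 1e-12

    def test_two_equal_tones_split_evenly(self):
        t = np.arange(2000) / FS
        x = np.cos(2 * np.pi * 120 * t) + np.cos(2 * np.pi * 320 * t)
        out = wr.band_power_ratios(x, FS)
        assert out["bandPower_100_150"] == pytest.approx(0.5, abs=0.05)
        assert out["bandPower_300_350"] == pytest.approx(0.5, abs=0.05)

    def test_scale_invariance(self):
        x = np.random.default_rng(6).normal(size=1000)
        a = wr.band_power_ratios(x, FS)
        b = wr.band_power_ratios(13.7 * x, FS)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestSpectralTemporal:
    def test_flatness_extremes(self):
        noise = np.random.default_rng(7).normal(size=2000)
        t = np.arange(2000) / FS
        tone = np.cos(2 * np.pi * 200 * t)
        assert wr.spectral_temporal_block(noise, FS)["spectralFlatness"] > 0.9
        assert wr.spectral_temporal_block(tone, FS)["spectralFlatness"] < 0.1

    def test_tone_centroid_near_tone_frequency(self):
        t = np.arange(2000) / FS
        out = wr.spectral_temporal_block(np.cos(2 * np.pi * 250 * t), FS)
        assert out["spectralCentroid"] == pytest.approx(250.0, abs=5.0)
        assert out["peakFrequency"] == pytest.approx(250.0, abs=5.0)

    def test_moments_match_psd_moment_oracle(self):
        x = np.random.default_rng(8).normal(size=2000)
        out = wr.spectral_temporal_block(x, FS)
        L = len(x)
        f, P = signal.welch(x, fs=FS, nperseg=min(L, max(L // 4, 32)))
        f, P = f[1:], P[1:]
        # explicit-loop oracle for the first two spectral moments
        tot = c = 0.0
        for fi, pi in zip(f, P):
            tot += pi
            c += fi * pi
        c /= tot
        s = 0.0
        for fi, pi in zip(f, P):
            s += (fi - c) ** 2 * pi / tot
        assert out["spectralCentroid"] == pytest.approx(c, abs=1e-9)
        assert out["spectralSpread"] == pytest.approx(np.sqrt(s), abs=1e-9)

    def test_all_descriptors_emitted(self):
        out = wr.spectral_temporal_block(np.random.default_rng(9).normal(size=500), FS)
        assert set(out) == set(SPECTRAL_TEMPORAL_NAMES)


class TestExtractFeatures:
    def test_valid_segment_yields_70_finite_features(self):
        seg = make_segment(wingbeat_with_noise(160.0, (1.0, 0.4), 15.0, seed=10), eta=0.9)
        fv = wr.extract_features(seg)
        assert len(fv) == 70
        assert all(np.isfinite(v) for v in fv.values.values())
        assert fv.values["HarmonicRatio"] == 0.9

    def test_deterministic(self):
        seg = make_segment(wingbeat_with_noise(160.0, (1.0, 0.4), 15.0, seed=11))
        a = wr.extract_features(seg)
        b = wr.extract_features(seg)
        assert a.values == b.values

    def test_noise_segment_imputes_f0(self):
        seg = make_segment(np.random.default_rng(12).normal(size=2000), eta=0.1)
        fv = wr.extract_features(seg)
        spec = wr.F0SearchSpec()
        assert fv.values["NCF_F0"] == spec.f_min
        assert np.isfinite(fv.values["PEF_F0"]) and np.isfinite(fv.values["WT_F0"])

    def test_f0_features_order_species_by_fundamental(self):
        low = make_segment(wingbeat_with_noise(120.0, (1.0, 0.5), 18.0, seed=13))
        high = make_segment(wingbeat_with_noise(300.0, (1.0,), 18.0, seed=14))
        a, b = wr.extract_features(low), wr.extract_features(high)
        for name in ("PEF_F0", "WT_F0", "NCF_F0"):
            assert a.values[name] < b.values[name]

    def test_band_cover_sums_for_default_bands(self):
        # nine 50 Hz bands cover 50-500 of the 0-500 Hz spectrum
        assert len(DEFAULT_BANDS) == 9
        assert DEFAULT_BANDS[0] == (50, 100) and DEFAULT_BANDS[-1] == (450, 500)
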