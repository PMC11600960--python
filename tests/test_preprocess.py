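"""Cleaning chain: resampling, line-noise removal, artifact rejection,
ICA, spherical interpolation, epoching."""

import numpy as np
import pytest
from scipy import signal as sps

from blasteeg.preprocess import (
    ComponentRules,
    detect_artifact_segments,
    epoch,
    flag_components,
    ica_decompose,
    interpolate_channels,
    reject_artifacts,
    remove_line_noise,
    resample,
)
from blasteeg.recording import MultichannelRecording, default_electrode_coords


def psd_at(x, fs, f):
    freqs, p = sps.welch(x, fs=fs, nperseg=int(4 * fs))
    return p[np.argmin(np.abs(freqs - f))]


class TestResample:
    def test_sinusoid_content_preserved(self, make_recording):
        fs = 2000.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(data=np.column_stack([x, x]), sfreq=fs)
        out = resample(rec, 1000.0)
        assert out.sfreq == 1000.0
        assert abs(out.duration - rec.duration) <= 1 / 1000.0
        ref = np.sin(2 * np.pi * 10 * np.arange(out.n_samples) / 1000.0)
        core = slice(100, -100)  # ignore filter edge effects
        err = np.sqrt(np.mean((out.data[core, 0] - ref[core]) ** 2))
        assert err < 1e-3 * np.sqrt(np.mean(ref[core] ** 2)) * 10  # 0.1 % RMS-ish

    def test_identity_and_upsampling_rejected(self, make_recording):
        rec = make_recording(sfreq=1000.0)
        assert np.array_equal(resample(rec, 1000.0).data, rec.data)
        with pytest.raises(ValueError):
            resample(rec, 2000.0)

    def test_sub_nyquist_content_retained(self, make_recording):
        fs = 2000.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 480 * t)
        rec = make_recording(data=x[:, None], sfreq=fs)
        out = resample(rec, 1000.0)
        assert psd_at(out.data[:, 0], 1000.0, 480) > 100 * psd_at(
            out.data[:, 0], 1000.0, 250
        )


class TestLineNoise:
    def test_pure_tone_suppressed_20db(self, make_recording):
        fs = 500.0
        rng = np.random.default_rng(0)
        t = np.arange(0, 30, 1 / fs)
        x = rng.standard_normal(t.size) + 5 * np.sin(2 * np.pi * 50 * t + 0.3)
        rec = make_recording(data=x[:, None], sfreq=fs)
        out = remove_line_noise(rec, base=50.0, n_harmonics=1)
        before = psd_at(rec.data[:, 0], fs, 50)
        after = psd_at(out.data[:, 0], fs, 50)
        assert 10 * np.log10(before / after) >= 20

    def test_no_tone_near_identity(self, make_recording):
        rec = make_recording(seed=1, duration=30.0)
        out = remove_line_noise(rec)
        rms = np.sqrt(np.mean(rec.data**2))
        assert np.sqrt(np.mean((out.data - rec.data) ** 2)) < 0.005 * rms

    def test_harmonics_all_suppressed(self, make_recording):
        fs = 500.0
        rng = np.random.default_rng(2)
        t = np.arange(0, 30, 1 / fs)
        x = rng.standard_normal(t.size)
        for f, a in ((50, 4), (100, 3), (150, 2)):
            x = x + a * np.sin(2 * np.pi * f * t + f)
        rec = make_recording(data=x[:, None], sfreq=fs)
        out = remove_line_noise(rec, base=50.0, n_harmonics=3)
        for f in (50, 100, 150):
            drop = 10 * np.log10(
                psd_at(rec.data[:, 0], fs, f) / psd_at(out.data[:, 0], fs, f)
            )
            assert drop >= 20

    def test_idempotent(self, make_recording):
        fs = 500.0
        t = np.arange(0, 30, 1 / fs)
        x = np.random.default_rng(3).standard_normal((t.size, 2))
        x[:, 0] += 5 * np.sin(2 * np.pi * 50 * t)
        rec = make_recording(data=x, sfreq=fs)
        once = remove_line_noise(rec)
        twice = remove_line_noise(once)
        rms = np.sqrt(np.mean(once.data**2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 1e-3 * rms


class TestArtifacts:
    def test_clean_recording_fully_retained(self, make_recording):
        rec = make_recording(seed=4, duration=60.0)
        segs = detect_artifact_segments(rec, z_threshold=5.0, window_s=1.0)
        assert sum(e - s for s, e in segs) == rec.n_samples

    def test_injected_transients_excised(self, make_recording):
        rec = make_recording(seed=5, duration=120.0, sfreq=500.0)
        data = rec.data.copy()
        rms = data.std()
        starts = (np.arange(10) * 11 + 3) * 500  # every 11 s
        for s in starts:
            data[s : s + 500] += 20 * rms * np.hanning(500)[:, None]
        dirty = make_recording(data=data, sfreq=500.0)
        segs = detect_artifact_segments(dirty, z_threshold=5.0, window_s=1.0)
        kept = np.zeros(dirty.n_samples, bool)
        for a, b in segs:
            kept[a:b] = True
        n_hit = sum((~kept[s : s + 500]).any() for s in starts)
        assert n_hit >= 9
        clean_mask = np.ones(dirty.n_samples, bool)
        for s in starts:
            clean_mask[s : s + 500] = False
        lost = (~kept & clean_mask).sum() / clean_mask.sum()
        assert lost < 0.05

    def test_infinite_threshold_keeps_everything(self, make_recording):
        rec = make_recording(seed=6, duration=20.0)
        segs = detect_artifact_segments(rec, z_threshold=np.inf, window_s=1.0)
        assert segs == [(0, rec.n_samples)]

    def test_reject_artifacts_logs(self, make_recording):
        rec = make_recording(seed=7, duration=20.0)
        out = reject_artifacts(rec)
        assert any("reject_artifacts" in line for line in out.log)


class TestICA:
    def test_known_mixture_recovered(self, make_recording):
        rng = np.random.default_rng(8)
        n = 4000
        t = np.arange(n) / 500.0
        sources = np.column_stack(
            [
                sps.sawtooth(2 * np.pi * 3 * t),
                np.sign(np.sin(2 * np.pi * 5 * t)),
                rng.laplace(size=n),
            ]
        )
        A = rng.normal(size=(3, 4))
        rec = make_recording(data=sources @ A, sfreq=500.0)
        decomp = ica_decompose(rec, seed=0)
        corr = np.abs(np.corrcoef(sources.T, decomp.activations.T)[:3, 3:])
        assert (corr.max(axis=1) > 0.95).all()

    def test_reconstruction_accuracy(self, make_recording):
        rec = make_recording(seed=9, duration=2.0, n_channels=3, sfreq=500.0)
        # 2 s of 3 channels < 20 * 9 samples? 1000 > 180, fine
        decomp = ica_decompose(rec)
        recon = decomp.reconstruct()
        rel = np.linalg.norm(recon - rec.data) / np.linalg.norm(rec.data)
        assert rel < 1e-6

    def test_rank_deficient_input_reduced_rank(self, make_recording):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((4000, 2))
        data = np.column_stack([x, x[:, 0]])  # duplicated channel
        rec = make_recording(data=data, sfreq=500.0)
        decomp = ica_decompose(rec)
        assert decomp.n_components == 2
        recon = decomp.reconstruct()
        assert np.allclose(recon, rec.data, atol=1e-8)

    def test_too_short_input_rejected(self, make_recording):
        rec = make_recording(seed=11, duration=0.2, n_channels=4, sfreq=500.0)
        with pytest.raises(ValueError, match="retained samples"):
            ica_decompose(rec)


class TestComponentFlags:
    def _decomp_from(self, activations, sfreq=500.0):
        from blasteeg.preprocess import ICADecomposition

        k = activations.shape[1]
        return ICADecomposition(
            unmixing=np.eye(k),
            mixing=np.eye(k),
            mean=np.zeros(k),
            activations=activations,
            ch_names=[f"ch{i}" for i in range(k)],
            sfreq=sfreq,
        )

    def test_line_residual_flagged(self):
        t = np.arange(10000) / 500.0
        acts = np.column_stack(
            [np.sin(2 * np.pi * 50 * t), np.random.default_rng(0).standard_normal(t.size)]
        )
        flags = flag_components(self._decomp_from(acts))
        assert 0 in flags and "line" in flags[0]
        assert 1 not in flags

    def test_oscillatory_component_not_flagged(self):
        rng = np.random.default_rng(1)
        t = np.arange(10000) / 500.0
        alpha = np.sin(2 * np.pi * 10 * t) + 0.5 * rng.standard_normal(t.size)
        flags = flag_components(self._decomp_from(alpha[:, None]))
        assert flags == {}

    def test_all_rules_off_no_flags(self):
        t = np.arange(5000) / 500.0
        acts = np.sin(2 * np.pi * 50 * t)[:, None]
        rules = ComponentRules(line_ratio=None, kurtosis=None, drift_fraction=None)
        assert flag_components(self._decomp_from(acts), rules) == {}


class TestInterpolation:
    def _smooth_field_recording(self, n_channels=32, n_samples=200):
        coords = default_electrode_coords(n_channels)
        # low-order spherical-harmonic-like smooth field, time-modulated
        field = 1.5 * coords[:, 2] + 0.8 * coords[:, 0] - 0.4 * coords[:, 1]
        t = np.linspace(0, 1, n_samples)
        data = np.outer(np.sin(2 * np.pi * 3 * t) + 2.0, field)
        return MultichannelRecording(
            data=data, sfreq=200.0,
            ch_names=[f"ch{i:02d}" for i in range(n_channels)], coords=coords,
        )

    def test_spherical_recovers_smooth_field(self):
        rec = self._smooth_field_recording()
        truth = rec.data[:, 5].copy()
        corrupted = rec.data.copy()
        corrupted[:, 5] = 999.0
        rec2 = MultichannelRecording(
            data=corrupted, sfreq=rec.sfreq, ch_names=rec.ch_names, coords=rec.coords
        )
        out = interpolate_channels(rec2, {"ch05"}, method="spherical")
        err = np.sqrt(np.mean((out.data[:, 5] - truth) ** 2))
        assert err < 0.05 * np.sqrt(np.mean(truth**2))

    def test_no_bad_channels_identity(self, make_recording):
        rec = make_recording(seed=12)
        out = interpolate_channels(rec, set())
        assert np.array_equal(out.data, rec.data)

    @pytest.mark.parametrize("method", ["spherical", "inverse_distance"])
    def test_constant_field_reproduced(self, method):
        coords = default_electrode_coords(8)
        data = np.full((50, 8), 3.7)
        rec = MultichannelRecording(
            data=data, sfreq=100.0,
            ch_names=[f"ch{i:02d}" for i in range(8)], coords=coords,
        )
        out = interpolate_channels(rec, {"ch03"}, method=method)
        assert out.data[:, 3] == pytest.approx(3.7, rel=1e-6)

    def test_good_channels_untouched(self, make_recording):
        rec = make_recording(seed=13, n_channels=8)
        out = interpolate_channels(rec, {"ch02"}, method="spherical")
        others = [i for i in range(8) if i != 2]
        assert np.array_equal(out.data[:, others], rec.data[:, others])

    def test_too_many_bad_rejected(self, make_recording):
        rec = make_recording(seed=14, n_channels=5)
        with pytest.raises(ValueError, match="too many"):
            interpolate_channels(rec, {"ch00", "ch01", "ch02"}, method="spherical")

    def test_missing_coords_rejected(self, make_recording):
        rec = make_recording(seed=15)
        rec.coords = None
        with pytest.raises(ValueError, match="coordinates"):
            interpolate_channels(rec, {"ch00"})


class TestEpoch:
    def test_clean_300s_gives_100_epochs(self, make_recording):
        rec = make_recording(seed=16, duration=300.0, sfreq=100.0, n_channels=2)
        assert epoch(rec, 3.0).shape == (100, 300, 2)

    def test_epochs_never_span_gaps(self, make_recording):
        rec = make_recording(seed=17, duration=10.0, sfreq=100.0, n_channels=2)
        rec.retained_segments = [(0, 300), (700, 1000)]
        eps = epoch(rec, 3.0)
        assert eps.shape[0] == 2
        assert np.array_equal(eps[0], rec.data[0:300])
        assert np.array_equal(eps[1], rec.data[700:1000])

    def test_half_overlap_window_count(self, make_recording):
        rec = make_recording(seed=18, duration=10.0, sfreq=100.0, n_channels=2)
        assert epoch(rec, 2.0, overlap_fraction=0.5).shape[0] == 9

    def test_nothing_fits_is_error(self, make_recording):
        rec = make_recording(seed=19, duration=1.0, sfreq=100.0, n_channels=2)
        with pytest.raises(ValueError, match="no epoch"):
            epoch(rec, 3.0)


class TestEqualDuration:
    def test_cohort_truncated_to_minimum_retained(self, make_recording):
        from blasteeg.pipeline import enforce_equal_duration

        a = make_recording(seed=20, duration=10.0, sfreq=100.0, n_channels=2)
        b = make_recording(seed=21, duration=10.0, sfreq=100.0, n_channels=2)
        b.retained_segments = [(0, 300), (500, 900)]  # 7 s retained
        out = enforce_equal_duration([a, b])
        assert all(
            sum(e - s for s, e in r.retained_segments) == 700 for r in out
        )
        # truncation takes the earliest retained samples
        assert out[0].retained_segments == [(0, 700)]
        assert out[1].retained_segments == [(0, 300), (500, 900)]

    def test_truncate_beyond_retained_rejected(self, make_recording):
        rec = make_recording(seed=22, duration=2.0, sfreq=100.0, n_channels=2)
        with pytest.raises(ValueError, match="beyond"):
            rec.truncate_retained(500)
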