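import numpy as np
import pytest
from scipy.signal import butter, periodogram, sosfilt

from dusqa.annotation import QualityClass, consensus_track, build_windows, fleiss_kappa
from dusqa.synthetic import (
    SynthConfig,
    acoustic_features,
    classify_by_statistics,
    gen_dataset,
    gen_good,
    gen_interference,
    gen_labeled_recording,
    gen_poor,
    gen_silent,
    gen_talking,
)

Q = QualityClass


def _envelope_autocorr_peak_lag(samples, rate=4000):
    sos = butter(2, 20.0, btype="lowpass", fs=rate, output="sos")
    env = sosfilt(sos, np.abs(samples))
    env = env - env.mean()
    lags = np.arange(int(0.25 * rate), int(0.7 * rate))
    ac = np.array([np.dot(env[:-l], env[l:]) for l in lags])
    return lags[ac.argmax()] / rate, ac.max() / np.dot(env, env)


class TestGenGood:
    def test_envelope_periodicity_at_heart_rate(self, synth_config):
        rec = gen_good(7.5, 140.0, synth_config, seed=0)
        lag, _ = _envelope_autocorr_peak_lag(rec.samples)
        assert lag == pytest.approx(60 / 140, rel=0.10)

    def test_spectral_centroid_inside_carrier_band(self, synth_config):
        rec = gen_good(3.75, 130.0, synth_config, seed=1)
        f, pxx = periodogram(rec.samples, fs=4000)
        centroid = (f * pxx).sum() / pxx.sum()
        lo, hi = synth_config.carrier_band_hz
        assert lo < centroid < hi

    def test_seed_determinism(self, synth_config):
        a = gen_good(3.75, 120.0, synth_config, seed=9)
        b = gen_good(3.75, 120.0, synth_config, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestGenPoor:
    def test_periodicity_weaker_than_matched_good(self, synth_config):
        _, good_peak = _envelope_autocorr_peak_lag(
            gen_good(7.5, 130.0, synth_config, seed=5).samples
        )
        _, poor_peak = _envelope_autocorr_peak_lag(
            gen_poor(7.5, synth_config, seed=5).samples
        )
        assert poor_peak < 0.5 * good_peak

    def test_nonzero_rms_distinguishes_from_silent(self, synth_config):
        assert np.sqrt(np.mean(gen_poor(3.75, synth_config, 2).samples ** 2)) > 0.01

    def test_seed_determinism(self, synth_config):
        assert np.array_equal(
            gen_poor(3.75, synth_config, 7).samples,
            gen_poor(3.75, synth_config, 7).samples,
        )


class TestGenInterference:
    def test_power_concentrated_on_buzz_harmonics(self, synth_config):
        rec = gen_interference(3.75, synth_config, seed=0)
        assert acoustic_features(rec.samples, synth_config)["buzz_share"] >= 0.8

    def test_no_heart_rate_envelope_periodicity(self, synth_config):
        _, peak = _envelope_autocorr_peak_lag(
            gen_interference(7.5, synth_config, seed=1).samples
        )
        assert peak < 0.3

    def test_seed_determinism(self, synth_config):
        assert np.array_equal(
            gen_interference(3.75, synth_config, 3).samples,
            gen_interference(3.75, synth_config, 3).samples,
        )


class TestGenTalking:
    def test_syllabic_modulation_dominates(self, synth_config):
        """Envelope-spectrum mass in the syllabic 2-8 Hz band exceeds the
        share the heartbeat generator puts there."""

        def mod_fraction(samples):
            sos = butter(2, 20.0, btype="lowpass", fs=4000, output="sos")
            env = sosfilt(sos, np.abs(samples))
            f, pxx = periodogram(env - env.mean(), fs=4000)
            band = pxx[(f >= 2) & (f <= 8)].sum()
            return band / pxx[f >= 0.5].sum()

        talk = mod_fraction(gen_talking(7.5, synth_config, seed=0).samples)
        good = mod_fraction(gen_good(7.5, 130.0, synth_config, seed=0).samples)
        assert talk > good

    def test_formant_resonances_present(self, synth_config):
        rec = gen_talking(7.5, synth_config, seed=2)
        f, pxx = periodogram(rec.samples, fs=4000)
        for formant in synth_config.formants_hz:
            band = pxx[np.abs(f - formant) < 0.1 * formant].sum()
            assert band / pxx.sum() > 0.1

    def test_seed_determinism(self, synth_config):
        assert np.array_equal(
            gen_talking(3.75, synth_config, 4).samples,
            gen_talking(3.75, synth_config, 4).samples,
        )


class TestGenSilent:
    def test_rms_and_peak_bounds(self, synth_config):
        rec = gen_silent(3.75, synth_config, seed=0)
        assert np.sqrt(np.mean(rec.samples**2)) <= 1e-3
        assert np.max(np.abs(rec.samples)) < 0.01

    def test_seed_determinism(self, synth_config):
        assert np.array_equal(
            gen_silent(3.75, synth_config, 5).samples,
            gen_silent(3.75, synth_config, 5).samples,
        )


class TestGenLabeledRecording:
    def test_noise_free_annotators_agree_perfectly(self):
        cfg = SynthConfig(annotator_flip=0.0, annotator_unsure=0.0)
        rec = gen_labeled_recording([(Q.GOOD, 10), (Q.SILENT, 10)], cfg, seed=0)
        matrix = np.array([[int(l) for l in t.labels] for t in rec.tracks]).T
        assert fleiss_kappa(matrix) == pytest.approx(1.0)
        for track in rec.tracks:
            assert tuple(track.labels) == rec.truth

    def test_block_boundaries_on_segment_grid(self):
        rec = gen_labeled_recording([(Q.POOR, 4), (Q.GOOD, 6)], seed=1)
        assert len(rec.recording.samples) == 10 * 3000
        assert rec.truth[:4] == (Q.POOR,) * 4
        assert rec.truth[4:] == (Q.GOOD,) * 6

    def test_moderate_noise_consensus_recovers_truth(self):
        """With 5% flips, consensus windows almost always carry the
        ground-truth class.  Unanimity on a 5-segment window survives with
        probability about (0.95**3)**5 = 0.46, so roughly 90 of the 196
        candidate windows should remain."""
        cfg = SynthConfig(annotator_flip=0.05, annotator_unsure=0.0)
        rec = gen_labeled_recording([(Q.GOOD, 100), (Q.POOR, 100)], cfg, seed=2)
        segments = consensus_track(list(rec.tracks))
        windows = build_windows(segments)
        assert len(windows) > 50
        hits = sum(
            w.label == rec.truth[w.start_segment_index] for w in windows
        )
        assert hits / len(windows) >= 0.95


class TestGenDataset:
    def test_covers_all_classes_deterministically(self, synth_config):
        recs = gen_dataset(10, None, synth_config, seed=3, segments_per_recording=5)
        classes = {r.truth[0] for r in recs}
        assert classes == set(Q) - {Q.UNSURE}
        again = gen_dataset(10, None, synth_config, seed=3, segments_per_recording=5)
        for a, b in zip(recs, again):
            assert np.array_equal(a.recording.samples, b.recording.samples)


class TestDiscriminability:
    def test_statistic_bank_separates_classes(self, synth_recordings, synth_config):
        """The fixed acoustic statistics classify generated 3.75 s windows
        with >= 99% accuracy, so downstream learnability runs probe the
        neural model rather than generator artefacts."""
        total = correct = 0
        for rec in synth_recordings:
            truth = rec.truth[0]
            samples = rec.recording.samples
            for start in range(0, len(samples) - 15000 + 1, 15000):
                pred = classify_by_statistics(samples[start : start + 15000], synth_config)
                correct += pred == truth
                total += 1
        assert total >= 200
        assert correct / total >= 0.99
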