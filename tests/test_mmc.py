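import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pbbm.cohort import (
    CohortConfig,
    ManometryConfig,
    generate_manometry,
    label_windows,
    train_default_classifier,
)
from pbbm.mmc import (
    ManometryTrace,
    band_energy_fraction,
    detect_phase3,
    extract_features,
    train_phase3_classifier,
)

FS = 4.0


def _sinusoid(freq_cpm, minutes, fs=FS, amp=1.0):
    t = np.arange(int(minutes * 60 * fs)) / fs
    return amp * np.sin(2 * np.pi * (freq_cpm / 60.0) * t)


class TestBandEnergyFraction:
    def test_in_band_tone_concentrates_energy(self):
        assert band_energy_fraction(_sinusoid(11.0, 4), FS) >= 0.95

    def test_out_of_band_tone_excluded(self):
        assert band_energy_fraction(_sinusoid(2.5, 4), FS) <= 0.05

    def test_white_noise_matches_flat_spectrum(self):
        """For white noise the expected band fraction is the band width
        over the Nyquist bandwidth."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=2**14)
        frac = band_energy_fraction(x, FS)
        expected = (12.0 - 9.0) / 60.0 / (FS / 2.0)
        assert frac == pytest.approx(expected, rel=0.2)

    def test_amplitude_invariance(self):
        x = _sinusoid(10.0, 4) + 0.3 * np.random.default_rng(1).normal(size=int(4 * 60 * FS))
        assert band_energy_fraction(x, FS) == pytest.approx(
            band_energy_fraction(100.0 * x, FS), rel=1e-9)

    def test_constant_window_is_zero(self):
        assert band_energy_fraction(np.full(int(4 * 60 * FS), 7.0), FS) == 0.0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            band_energy_fraction(np.zeros(10), FS)


class TestFeatures:
    def test_duodenal_burst_contraction_count_and_amplitude(self):
        """A synthetic duodenal phase-III burst reads as 11-12
        contractions/min at ~33 mmHg."""
        burst = 33.0 * 0.5 * (1.0 + _sinusoid(11.5, 4))
        trace = ManometryTrace(FS, {"duodenum": burst})
        feats = extract_features(trace, window_min=2.0, hop_min=2.0)
        assert feats["contractions_per_min"].iloc[0] == pytest.approx(11.5, abs=0.5)
        assert feats["contraction_amplitude_mmhg"].iloc[0] == pytest.approx(33.0, rel=0.1)

    def test_flat_trace_has_no_contractions(self):
        trace = ManometryTrace(FS, {"duodenum": np.zeros(int(10 * 60 * FS))})
        feats = extract_features(trace)
        assert (feats["contractions_per_min"] == 0).all()
        assert (feats["band_fraction"] == 0).all()


class TestClassifier:
    def _labeled_features(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        pos = pd.DataFrame({
            "band_fraction": rng.uniform(0.6, 0.95, n),
            "log_amplitude": rng.uniform(2.5, 3.5, n),
            "contractions_per_min": rng.uniform(10, 12, n),
        })
        neg = pd.DataFrame({
            "band_fraction": rng.uniform(0.0, 0.2, n),
            "log_amplitude": rng.uniform(0.5, 1.5, n),
            "contractions_per_min": rng.uniform(0, 3, n),
        })
        x = pd.concat([pos, neg], ignore_index=True)
        y = np.r_[np.ones(n, int), np.zeros(n, int)]
        return x, y

    def test_separable_data_high_accuracy(self):
        x, y = self._labeled_features()
        clf = train_phase3_classifier(x, y, l2_penalty=0.01)
        acc = np.mean((clf.predict_proba(x) >= 0.5).astype(int) == y)
        assert acc >= 0.95

    def test_infinite_penalty_collapses_to_prevalence(self):
        x, y = self._labeled_features()
        y = np.r_[np.ones(30, int), np.zeros(90, int)]  # 25% prevalence
        clf = train_phase3_classifier(x, y, l2_penalty=1e9)
        assert np.allclose(clf.weights, 0.0, atol=1e-4)
        assert clf.predict_proba(x) == pytest.approx(0.25, abs=0.02)

    def test_permuted_labels_carry_no_signal(self):
        x, y = self._labeled_features(seed=2)
        rng = np.random.default_rng(7)
        y_perm = rng.permutation(y)
        clf = train_phase3_classifier(x, y_perm, l2_penalty=1.0)
        auc = roc_auc_score(y_perm, clf.predict_proba(x))
        assert auc == pytest.approx(0.5, abs=0.1)


@pytest.fixture(scope="module")
def classifier():
    return train_default_classifier(seed=0)


class TestDetection:
    def test_embedded_burst_onset_recovered(self, classifier):
        cfg = CohortConfig(seed=21)
        mano = ManometryConfig(duration_h=2.0)
        trace, _ = generate_manometry(cfg, 1.1, mano)
        call = detect_phase3(trace, classifier)
        assert call.found
        assert call.tmmc_h == pytest.approx(1.1, abs=0.5 / 60 + 1e-9)
        assert call.tmmc_post_dose_h == call.tmmc_h  # dosed at t=0

    def test_quiescent_trace_yields_no_calls(self, classifier):
        rng = np.random.default_rng(3)
        n = int(1.0 * 3600 * FS)
        trace = ManometryTrace(FS, {"duodenum": rng.normal(0, 2.0, n),
                                    "antrum": rng.normal(0, 2.0, n)})
        call = detect_phase3(trace, classifier)
        assert not call.found
        assert call.tmmc_h is None
        assert call.intervals == []

    def test_sub_minimum_duration_burst_rejected(self, classifier):
        """A 1-minute duodenal run of phase-III-like activity is below the
        3-minute duodenal rule and must not be called."""
        rng = np.random.default_rng(4)
        n = int(1.0 * 3600 * FS)
        x = rng.normal(0, 2.0, n)
        burst = 33.0 * 0.5 * (1.0 + _sinusoid(11.5, 1.0))
        start = int(0.5 * 3600 * FS)
        x[start : start + burst.size] += burst
        call = detect_phase3(ManometryTrace(FS, {"duodenum": x}), classifier)
        assert call.intervals == []

    def test_intervals_non_overlapping_per_region(self, classifier):
        cfg = CohortConfig(seed=8)
        trace, _ = generate_manometry(cfg, 0.7, ManometryConfig(duration_h=1.5))
        call = detect_phase3(trace, classifier)
        by_region = {}
        for start, end, region in call.intervals:
            by_region.setdefault(region, []).append((start, end))
        for spans in by_region.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2


def test_generator_labels_align_with_embedded_segments():
    cfg = CohortConfig(seed=5)
    trace, labels = generate_manometry(cfg, 0.8, ManometryConfig(duration_h=1.5))
    assert set(labels["region"]) == {"antrum", "duodenum"}
    assert (labels["phase"] == "III").all()
    assert labels["start_h"].iloc[0] == pytest.approx(0.8)
    # dominant periodogram frequency of the duodenal burst is 11-12 cpm
    fs = trace.sampling_rate_hz
    seg = trace.channels["duodenum"][int(0.8 * 3600 * fs): int(0.8 * 3600 * fs) + int(4 * 60 * fs)]
    seg = seg - seg.mean()
    freqs = np.fft.rfftfreq(seg.size, 1 / fs) * 60.0  # cycles/min
    peak = freqs[np.argmax(np.abs(np.fft.rfft(seg)))]
    assert 11.0 <= peak <= 12.0
    features = extract_features(trace)
    y = label_windows(features, labels)
    assert y.sum() > 0
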