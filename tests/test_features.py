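"""Spectral estimation, band powers, accelerometer features and the catalog."""

from __future__ import annotations

import numpy as np
import pytest

from ictalprint.features import (
    BANDS, TOTAL_BAND, FeatureCatalog, FeatureDef, SignalLengthError,
    estimate_psd, band_power, relative_band_power, emg_power,
    hjorth_parameters, acc_features, default_catalog, paper_feature_names,
    compute_feature_table, METADATA_COLUMNS,
)
from ictalprint.segmentation import AnalysisPeriod
from .conftest import make_recording

FS = 207.0


def sinusoid(freq, duration_s=60.0, amplitude=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestPSD:
    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * FS))
        f, p = estimate_psd(x, FS)
        total = np.trapezoid(p, f)
        assert abs(total - np.var(x)) < 0.05 * np.var(x)

    def test_sinusoid_band_power_closed_form(self):
        f, p = estimate_psd(sinusoid(5.0), FS)
        assert band_power(f, p, 4, 6) == pytest.approx(0.5, rel=0.05)
        assert band_power(f, p, 6, 8) < 0.01

    def test_zero_vector_zero_density(self):
        f, p = estimate_psd(np.zeros(int(10 * FS)), FS)
        assert np.all(p == 0.0)

    def test_too_short_input_names_minimum(self):
        with pytest.raises(SignalLengthError, match="414"):
            estimate_psd(np.zeros(100), FS)

    def test_band_partition_additivity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(60 * FS))
        f, p = estimate_psd(x, FS)
        partition = sum(band_power(f, p, lo, hi) for lo, hi in BANDS.values())
        total = band_power(f, p, 0, 0.5) + partition + band_power(f, p, 48, FS / 2)
        assert total == pytest.approx(np.trapezoid(p, f), rel=1e-9)

    def test_inverted_band_rejected(self):
        f, p = estimate_psd(sinusoid(5.0, 10.0), FS)
        with pytest.raises(ValueError):
            band_power(f, p, 6, 4)


class TestRelativePower:
    def test_concentrated_sinusoid(self):
        x = sinusoid(5.0) + 1e-4 * np.random.default_rng(2).standard_normal(int(60 * FS))
        f, p = estimate_psd(x, FS)
        assert relative_band_power(f, p, 4, 6) > 0.95

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(3)
        for x in (rng.standard_normal(int(30 * FS)), sinusoid(7.0, 30.0)):
            f, p = estimate_psd(x, FS)
            s = sum(relative_band_power(f, p, lo, hi) for lo, hi in BANDS.values())
            assert s == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_flat_spectrum_expectation(self):
        # E[relative delta power] = bandwidth ratio 3.5 / 47.5 for white noise
        vals = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(30 * FS))
            f, p = estimate_psd(x, FS)
            vals.append(relative_band_power(f, p, 0.5, 4.0))
        assert np.mean(vals) == pytest.approx(3.5 / 47.5, abs=0.03)

    def test_band_outside_total_rejected(self):
        f, p = estimate_psd(sinusoid(5.0, 10.0), FS)
        with pytest.raises(ValueError):
            relative_band_power(f, p, 40.0, 60.0)

    def test_zero_signal_gives_zero(self):
        f, p = estimate_psd(np.zeros(int(10 * FS)), FS)
        assert relative_band_power(f, p, 4, 6) == 0.0


class TestEMGPower:
    def test_in_band_sinusoid(self):
        assert emg_power(sinusoid(30.0), FS) == pytest.approx(0.5, rel=0.05)

    def test_low_frequency_rejected(self):
        assert emg_power(sinusoid(5.0), FS) < 0.01


class TestHjorth:
    def test_nonnegative_and_zero_for_constant(self):
        act, mob, comp = hjorth_parameters(np.full(1000, 3.0), FS)
        assert (act, mob, comp) == (0.0, 0.0, 0.0)
        act, mob, comp = hjorth_parameters(
            np.random.default_rng(0).standard_normal(2000), FS)
        assert act > 0 and mob > 0 and comp > 0


class TestAccFeatures:
    def test_static_posture(self):
        n = int(60 * 10)
        out = acc_features(np.zeros(n), np.zeros(n), np.ones(n), 10.0)
        assert out["acc_x_mean"] == 0.0
        assert out["acc_m_mean"] == pytest.approx(1.0)
        assert out["acc_pitch_deg"] == pytest.approx(0.0)
        for key in ("acc_x_sd", "acc_m_sd", "acc_x_madiff", "acc_move_frac"):
            assert out[key] == 0.0

    def test_pitch_closed_form(self):
        theta = np.radians(30.0)
        n = int(60 * 10)
        out = acc_features(np.full(n, np.sin(theta)), np.zeros(n),
                           np.full(n, np.cos(theta)), 10.0)
        assert out["acc_pitch_deg"] == pytest.approx(30.0, abs=1e-6)

    def test_mid_period_step(self):
        n = int(60 * 10)
        ax = np.zeros(n)
        ax[n // 2:] = 0.3
        out = acc_features(ax, np.zeros(n), np.ones(n), 10.0)
        assert out["acc_x_mean"] == pytest.approx(0.15, abs=1e-9)
        assert out["acc_x_madiff"] > 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            acc_features(np.zeros(100), np.zeros(99), np.zeros(100), 10.0)


class TestCatalog:
    def test_size_and_canonical_names(self):
        cat = default_catalog()
        assert 65 <= len(cat) <= 75
        assert len(cat) == 68
        for name in paper_feature_names():
            assert name in cat.names
        assert len(set(cat.names)) == len(cat.names)

    def test_duplicate_names_rejected(self):
        e = FeatureDef("x", "eeg", "EEG_prox", "d")
        with pytest.raises(ValueError, match="duplicate"):
            FeatureCatalog([e, e])

    def test_subset_preserves_requested_order(self):
        cat = default_catalog()
        sub = cat.subset(paper_feature_names())
        assert sub.names == paper_feature_names()
        with pytest.raises(KeyError):
            cat.subset(["not_a_feature"])

    def test_serialization_lists_all_entries(self, tmp_path):
        import json
        cat = default_catalog()
        text = cat.to_json(tmp_path / "cat.json")
        assert len(json.loads(text)) == len(cat)


class TestFeatureTable:
    def _periods(self, rec, n=2, kind="ictal"):
        return [AnalysisPeriod(rec.person_id, f"s{i}", kind, 2.0 + 4 * i, 6.0 + 4 * i)
                for i in range(n)]

    def test_shape_and_column_order(self, small_recording):
        cat = default_catalog()
        table, log = compute_feature_table(small_recording, self._periods(small_recording))
        assert table.shape == (2, 3 + 68)
        assert list(table.columns) == METADATA_COLUMNS + cat.names
        assert not table.isna().any().any()
        assert log == []

    def test_deterministic_rows(self, small_recording):
        t1, _ = compute_feature_table(small_recording, self._periods(small_recording))
        t2, _ = compute_feature_table(small_recording, self._periods(small_recording))
        assert t1.equals(t2)

    def test_restricted_catalog_in_canonical_order(self, small_recording):
        cat = default_catalog().subset(paper_feature_names())
        table, _ = compute_feature_table(small_recording, self._periods(small_recording), cat)
        assert list(table.columns)[3:] == paper_feature_names()

    def test_scale_covariance(self, small_recording):
        """x -> c*x multiplies absolute powers by c^2, leaves relative
        powers unchanged."""
        c = 3.0
        periods = self._periods(small_recording, n=1)
        t1, _ = compute_feature_table(small_recording, periods)
        for ch in small_recording.channels:
            if ch.role == "eeg":
                ch.samples = ch.samples * c
        t2, _ = compute_feature_table(small_recording, periods)
        for band in BANDS:
            assert t2[f"eeg_abspow_{band}"][0] == pytest.approx(
                c ** 2 * t1[f"eeg_abspow_{band}"][0], rel=1e-9)
            assert t2[f"eeg_relpow_{band}"][0] == pytest.approx(
                t1[f"eeg_relpow_{band}"][0], rel=1e-9)
        assert t2["emg_power_prox"][0] == pytest.approx(
            c ** 2 * t1["emg_power_prox"][0], rel=1e-9)

    def test_relative_powers_bounded(self, small_report):
        table = small_report.feature_table
        rel_cols = [c for c in table.columns if "relpow" in c]
        assert ((table[rel_cols] >= 0) & (table[rel_cols] <= 1)).all().all()
        assert (table[[c for c in table.columns if "hjorth_mobility" in c
                       or "hjorth_complexity" in c]] >= 0).all().all()

    def test_period_outside_recording_raises(self, small_recording):
        bad = [AnalysisPeriod("P1", "s", "ictal", 100.0, 110.0)]
        with pytest.raises(IndexError):
            compute_feature_table(small_recording, bad)

    def test_foreign_person_rejected(self, small_recording):
        bad = [AnalysisPeriod("someone_else", "s", "ictal", 2.0, 6.0)]
        with pytest.raises(ValueError, match="belongs"):
            compute_feature_table(small_recording, bad)
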