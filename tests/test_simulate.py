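"""Synthetic-cohort generator: determinism, planted signals, null behavior."""

from __future__ import annotations

import json

import numpy as np
import pytest
from scipy import stats

from ictalprint.io import read_annotations
from ictalprint.segmentation import extract_periods
from ictalprint.features import compute_feature_table, default_catalog
from ictalprint.simulate import (
    PersonProfile, CohortSpec, ConfigurationError,
    simulate_recording, simulate_cohort, archetype_cohort, null_cohort,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cohort = null_cohort(seed=7, n_seizures=10, n_persons=2)
        rec1, annos1 = simulate_recording(cohort.profiles[0], cohort)
        rec2, annos2 = simulate_recording(cohort.profiles[0], cohort)
        for c1, c2 in zip(rec1.channels, rec2.channels):
            assert np.array_equal(c1.samples, c2.samples)
        assert annos1 == annos2

    def test_cohort_files_identical_across_runs(self, tmp_path):
        cohort = null_cohort(seed=3, n_seizures=10, n_persons=2)
        m1 = simulate_cohort(cohort, tmp_path / "a")
        m2 = simulate_cohort(cohort, tmp_path / "b")
        assert m1["seeds"] == m2["seeds"]
        assert (tmp_path / "a" / "annotations.csv").read_bytes() == \
               (tmp_path / "b" / "annotations.csv").read_bytes()
        for pid, fname in m1["recordings"].items():
            assert (tmp_path / "a" / fname).read_bytes() == \
                   (tmp_path / "b" / fname).read_bytes()


class TestPlantedSignatures:
    def test_theta_gain_raises_ictal_low_theta_relpow(self):
        cohort = CohortSpec(profiles=[
            PersonProfile("T", seed=11, n_seizures=15,
                          eeg_band_gain={"low_theta": 4.0}),
            PersonProfile("N", seed=12, n_seizures=10),
        ])
        rec, annos = simulate_recording(cohort.profiles[0], cohort)
        periods, _ = extract_periods(rec, annos)
        table, _ = compute_feature_table(rec, periods)
        ictal = table[table["kind"] == "ictal"]["eeg_relpow_low_theta"]
        base = table[table["kind"] == "baseline"]["eeg_relpow_low_theta"]
        assert ictal.mean() > base.mean()
        assert stats.mannwhitneyu(ictal, base, alternative="greater").pvalue < 1e-4

    def test_emg_gain_raises_ictal_emg_power(self):
        cohort = CohortSpec(profiles=[
            PersonProfile("M", seed=21, n_seizures=12, emg_burst_gain=5.0),
            PersonProfile("N", seed=22, n_seizures=10),
        ])
        rec, annos = simulate_recording(cohort.profiles[0], cohort)
        periods, _ = extract_periods(rec, annos)
        table, _ = compute_feature_table(rec, periods)
        ictal = table[table["kind"] == "ictal"]["emg_power_prox"]
        base = table[table["kind"] == "baseline"]["emg_power_prox"]
        assert ictal.mean() > base.mean()

    def test_posture_shift_moves_x_mean_not_magnitude(self):
        cohort = CohortSpec(profiles=[
            PersonProfile("S", seed=31, n_seizures=12, acc_shift_g=0.4),
            PersonProfile("N", seed=32, n_seizures=10),
        ])
        rec, annos = simulate_recording(cohort.profiles[0], cohort)
        periods, _ = extract_periods(rec, annos)
        table, _ = compute_feature_table(rec, periods)
        ictal = table[table["kind"] == "ictal"]
        base = table[table["kind"] == "baseline"]
        assert ictal["acc_x_mean"].mean() > base["acc_x_mean"].mean() + 0.2
        # gravity rotation preserves the magnitude
        assert abs(ictal["acc_m_mean"].mean() - base["acc_m_mean"].mean()) < 0.02


class TestNullSignature:
    def test_null_profile_ictal_indistinguishable_from_baseline(self, null_recording_pair):
        """With all gains at 1 and no movement, no catalog feature may
        distinguish ictal from baseline periods (Bonferroni-corrected
        two-sample KS over the 68 features, n=20 per class)."""
        rec, annos, _ = null_recording_pair
        periods, _ = extract_periods(rec, annos)
        table, _ = compute_feature_table(rec, periods)
        ictal = table[table["kind"] == "ictal"]
        base = table[table["kind"] == "baseline"]
        assert len(ictal) == 20
        names = default_catalog().names
        pvals = {}
        for f in names:
            if ictal[f].var() == 0 and base[f].var() == 0:
                continue
            pvals[f] = stats.ks_2samp(ictal[f], base[f]).pvalue
        alpha = 0.01 / len(names)
        offenders = {f: p for f, p in pvals.items() if p < alpha}
        assert not offenders, f"features distinguish null ictal periods: {offenders}"


class TestCohortManifest:
    def test_study_scale_cohort(self, tmp_path):
        cohort = archetype_cohort(seed=5)
        manifest = simulate_cohort(cohort, tmp_path)
        assert len(manifest["recordings"]) == 4
        annos = read_annotations(tmp_path / manifest["annotations"])
        per_person = {p: sum(a.person_id == p for a in annos) for p in "BEGI"}
        assert per_person == {"B": 27, "E": 17, "G": 12, "I": 22}
        assert sum(a.label == "FBTCS" for a in annos) == 4
        assert {a.person_id for a in annos if a.label == "FBTCS"} == {"B", "E"}
        assert len(annos) == 78
        with open(tmp_path / "manifest.json") as fh:
            on_disk = json.load(fh)
        assert on_disk["seeds"] == manifest["seeds"]

    def test_single_profile_cohort(self, tmp_path):
        cohort = CohortSpec(profiles=[PersonProfile("solo", seed=1, n_seizures=10)])
        manifest = simulate_cohort(cohort, tmp_path)
        assert list(manifest["recordings"]) == ["solo"]

    def test_annotations_match_recording_extent(self, null_recording_pair):
        rec, annos, _ = null_recording_pair
        for a in annos:
            assert 0 <= a.onset_s and a.end_s <= rec.duration_s


class TestValidation:
    def test_profile_invariants(self):
        with pytest.raises(ConfigurationError, match="n_seizures"):
            PersonProfile("X", seed=1, n_seizures=9)
        with pytest.raises(ConfigurationError, match="durations"):
            PersonProfile("X", seed=1, seizure_duration_s=(5.0, 10.0))
        with pytest.raises(ConfigurationError, match="gains"):
            PersonProfile("X", seed=1, eeg_band_gain={"delta": -1.0})
        with pytest.raises(ConfigurationError, match="suppression"):
            PersonProfile("X", seed=1, emg_burst_gain=0.5)
        with pytest.raises(ConfigurationError, match="unknown EEG bands"):
            PersonProfile("X", seed=1, eeg_band_gain={"gamma": 2.0})

    def test_too_short_recording_budget_raises(self):
        cohort = CohortSpec(
            profiles=[PersonProfile("X", seed=1, n_seizures=10),
                      PersonProfile("Y", seed=2, n_seizures=10)],
            max_duration_s=1000.0,
        )
        with pytest.raises(ConfigurationError, match="max_duration_s"):
            simulate_recording(cohort.profiles[0], cohort)

    def test_foreign_profile_rejected(self):
        cohort = null_cohort(seed=1)
        other = PersonProfile("zz", seed=9, n_seizures=10)
        with pytest.raises(ConfigurationError, match="not in cohort"):
            simulate_recording(other, cohort)
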