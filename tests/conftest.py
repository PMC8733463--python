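"""Shared fixtures: tiny in-memory recordings and cached cohort runs.

The expensive artifacts (a simulated archetype cohort and its full
pipeline report) are session-scoped so the many tests that only
inspect them do not re-simulate.
"""

from __future__ import annotations

import numpy as np
import pytest

from ictalprint.io import ChannelSignal, Recording, SeizureAnnotation
from ictalprint.simulate import (
    archetype_cohort, null_cohort, simulate_cohort, simulate_recording,
)
from ictalprint.pipeline import run_pipeline, PipelineConfig


def make_recording(
    duration_s: float = 12.0,
    person_id: str = "P1",
    seed: int = 0,
    eeg_fs: float = 207.0,
    acc_fs: float = 10.0,
) -> Recording:
    """A small valid recording with reproducible noise content."""
    rng = np.random.default_rng(seed)
    n_eeg = int(duration_s * eeg_fs)
    n_acc = int(duration_s * acc_fs)
    channels = [
        ChannelSignal("EEG_prox", "eeg", eeg_fs, rng.normal(0, 30, n_eeg)),
        ChannelSignal("EEG_dist", "eeg", eeg_fs, rng.normal(0, 30, n_eeg)),
        ChannelSignal("ACC_x", "acc", acc_fs, 0.05 + rng.normal(0, 0.02, n_acc)),
        ChannelSignal("ACC_y", "acc", acc_fs, rng.normal(0, 0.02, n_acc)),
        ChannelSignal("ACC_z", "acc", acc_fs, 1.0 + rng.normal(0, 0.02, n_acc)),
    ]
    return Recording(person_id=person_id, channels=channels)


@pytest.fixture
def small_recording() -> Recording:
    return make_recording()


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A compact archetype cohort (10 seizures/person) on disk."""
    out = tmp_path_factory.mktemp("cohort")
    cohort = archetype_cohort(
        seed=1, n_seizures={"B": 11, "E": 10, "G": 10, "I": 11},
        fbtcs_extra={"B": 1},
    )
    manifest = simulate_cohort(cohort, out)
    return out, manifest


@pytest.fixture(scope="session")
def small_report(small_cohort_dir):
    """Full pipeline report for the compact cohort (seed 1)."""
    out, _ = small_cohort_dir
    return run_pipeline(out / "manifest.json", PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def null_recording_pair():
    """One zero-signature person's recording + annotations (20 seizures)."""
    cohort = null_cohort(seed=1, n_seizures=20, n_persons=2)
    rec, annos = simulate_recording(cohort.profiles[0], cohort)
    return rec, annos, cohort
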