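"""YAML run configuration for the command-line interface.

A run config bundles the cohort to simulate (or the manifest to load)
with the pipeline parameters. A single global seed fans out
deterministically to the per-person generator seeds and the selection
seed, so one integer reproduces a whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import (
    CohortSpec, PersonProfile, archetype_cohort, _person_seeds,
)
from .selection import SelectionConfig
from .pipeline import PipelineConfig

__all__ = ["RunConfig", "load_config", "demo_config_yaml"]


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run."""

    seed: int = 1
    cohort: CohortSpec | None = None     # None -> stock archetype cohort
    manifest: Path | None = None         # pre-simulated inputs, if any
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def resolve_cohort(self) -> CohortSpec:
        if self.cohort is not None:
            return self.cohort
        return archetype_cohort(seed=self.seed)


def _build_cohort(spec: dict, seed: int) -> CohortSpec:
    profiles_spec = spec["profiles"]
    ids = [p["person_id"] for p in profiles_spec]
    seeds = _person_seeds(seed, ids)
    profiles = []
    for p in profiles_spec:
        p = dict(p)
        pid = p.pop("person_id")
        p.setdefault("seed", seeds[pid])
        if "seizure_duration_s" in p:
            p["seizure_duration_s"] = tuple(p["seizure_duration_s"])
        profiles.append(PersonProfile(person_id=pid, **p))
    kwargs = {}
    for key in ("interictal_gap_s", "background_eeg", "background_acc",
                "fbtcs_extra", "max_duration_s"):
        if key in spec:
            val = spec[key]
            if key == "interictal_gap_s":
                val = tuple(val)
            if key == "background_acc" and "gravity_g" in val:
                val = dict(val, gravity_g=tuple(val["gravity_g"]))
            kwargs[key] = val
    return CohortSpec(profiles=profiles, **kwargs)


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load a YAML run configuration; ``--seed`` overrides the file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(seed_override if seed_override is not None else raw.get("seed", 1))
    pconf_raw = dict(raw.get("pipeline", {}))
    sel_raw = pconf_raw.pop("selection", None)
    selection = None
    if sel_raw is not None:
        sel_raw = dict(sel_raw)
        for grid_key in ("n_trees_grid", "min_split_grid"):
            if grid_key in sel_raw:
                sel_raw[grid_key] = tuple(sel_raw[grid_key])
        sel_raw.setdefault("seed", seed)
        selection = SelectionConfig(**sel_raw)
    pconf_raw.setdefault("seed", seed)
    pipeline = PipelineConfig(selection=selection, **pconf_raw)
    cohort = None
    if "cohort" in raw:
        cohort = _build_cohort(raw["cohort"], seed)
    manifest = Path(raw["manifest"]) if "manifest" in raw else None
    return RunConfig(seed=seed, cohort=cohort, manifest=manifest, pipeline=pipeline)


def demo_config_yaml() -> str:
    """A self-contained demo config (the stock archetype cohort)."""
    from .simulate import ARCHETYPE_SIGNATURES

    counts = {"B": 25, "E": 15, "G": 12, "I": 22}
    profiles = []
    for pid, sig in sorted(ARCHETYPE_SIGNATURES.items()):
        entry: dict = {"person_id": pid, "n_seizures": counts[pid]}
        for key, val in sig.items():
            if val and val != 1.0:
                entry[key] = val
        profiles.append(entry)
    demo = {
        "seed": 1,
        "pipeline": {"n_selected": 5, "n_components": 3, "ci_method": "wald"},
        "cohort": {"profiles": profiles, "fbtcs_extra": {"B": 2, "E": 2}},
    }
    return yaml.safe_dump(demo, sort_keys=False)
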