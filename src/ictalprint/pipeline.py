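"""End-to-end composition: manifest -> FingerprintReport directory.

Stages: cohort filter -> period extraction -> feature table ->
Gini-importance selection -> Z-score -> PCA -> nearest-centroid person
clustering -> radar fingerprints -> ictal-vs-preictal/baseline
separations. Every stage's artifacts are serialized into the output
directory with deterministic formatting, so a rerun with the same
inputs, config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import read_recording, read_annotations
from .segmentation import filter_cohort, extract_periods, Exclusion
from .features import default_catalog, compute_feature_table, FeatureCatalog, METADATA_COLUMNS
from .selection import SelectionConfig, select_features, reduce_table, ReducedFeatureSpace
from .fingerprint import (
    fit_zscore, apply_zscore, fit_pca, project,
    person_clustering, build_radar, state_separation,
    ZScoreModel, PCAModel, CentroidSet, RadarFingerprint, SeparationResult,
)

__all__ = ["FingerprintReport", "PipelineConfig", "run_pipeline"]

try:
    from importlib.metadata import version as _dist_version
    _pkg_version = _dist_version("ictalprint")
except Exception:  # pragma: no cover - uninstalled source tree
    _pkg_version = "unknown"

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline (defaults = the standard analysis)."""

    min_seizures: int = 10
    min_ictal_s: float = 2.0
    n_selected: int = 5
    n_components: int = 3
    ci_method: str = "wald"
    leave_one_out: bool = False
    seed: int = 0
    selection: SelectionConfig | None = None

    def selection_config(self) -> SelectionConfig:
        if self.selection is not None:
            return self.selection
        return SelectionConfig(seed=self.seed, n_selected=self.n_selected)


@dataclass
class FingerprintReport:
    """Bundle of every artifact of one pipeline run."""

    config: PipelineConfig
    catalog: FeatureCatalog
    feature_table: pd.DataFrame
    space: ReducedFeatureSpace
    zscore: ZScoreModel
    pca: PCAModel
    centroids: CentroidSet
    clustering: SeparationResult
    radar: RadarFingerprint
    separations: dict[str, SeparationResult]
    exclusions: list[Exclusion] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.catalog.to_json(out / "catalog.json")
        self.feature_table.to_csv(out / "features.csv", index=False,
                                  float_format=_FLOAT_FMT)
        self.space.to_json(out / "selected_features.json")
        self.zscore.to_json(out / "zscore.json")
        self.pca.to_json(out / "pca.json")
        self.centroids.to_json(out / "centroids.json")
        self.radar.to_frame().to_csv(out / "radar.csv", index=False,
                                     float_format=_FLOAT_FMT)
        assert self.clustering.assignments is not None
        self.clustering.assignments.to_csv(out / "clustering_assignments.csv",
                                           index=False, float_format=_FLOAT_FMT)
        summary = {
            "pipeline": {
                "version": _pkg_version,
                "seed": self.config.seed,
                "n_components": self.config.n_components,
                "n_selected": self.config.n_selected,
                "ci_method": self.config.ci_method,
                "leave_one_out": self.config.leave_one_out,
                "min_seizures": self.config.min_seizures,
                "min_ictal_s": self.config.min_ictal_s,
            },
            "selected_features": self.space.selected,
            "best_hyperparams": list(self.space.best_hyperparams),
            "person_clustering": self.clustering.summary_dict(),
            "separations": {k: v.summary_dict() for k, v in sorted(self.separations.items())},
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        # per-row cluster-average distances go with each separation CSV,
        # ready for the distance-to-cluster-average plot
        for name, sep in self.separations.items():
            assert sep.assignments is not None
            sep.assignments.to_csv(out / f"separation_{name}.csv", index=False,
                                   float_format=_FLOAT_FMT)
        with open(out / "run.log", "w") as fh:
            for exc in self.exclusions:
                fh.write(str(exc) + "\n")
        return out


def run_pipeline(
    manifest: dict | str | Path,
    config: PipelineConfig | None = None,
    catalog: FeatureCatalog | None = None,
    base_dir: str | Path | None = None,
) -> FingerprintReport:
    """Execute the full analysis described by a cohort manifest.

    ``manifest`` is the dict written by
    :func:`ictalprint.simulate.simulate_cohort` (or a path to its
    ``manifest.json``); relative paths resolve against ``base_dir`` or
    the manifest file's directory.
    """
    config = config or PipelineConfig()
    catalog = catalog or default_catalog()

    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        base = Path(base_dir) if base_dir else mpath.parent
        with open(mpath) as fh:
            manifest = json.load(fh)
    else:
        base = Path(base_dir) if base_dir else Path(".")

    def _stage(name):
        logger.info("stage: %s", name)

    _stage("filter")
    annos = read_annotations(base / manifest["annotations"])
    kept, cohort_log = filter_cohort(annos, min_seizures=config.min_seizures)

    _stage("segment+featurize")
    tables = []
    period_log: list[Exclusion] = list(cohort_log)
    for pid, fname in sorted(manifest["recordings"].items()):
        person_annos = [a for a in kept if a.person_id == pid]
        if not person_annos:
            continue
        rec = read_recording(base / fname)
        periods, plog = extract_periods(rec, person_annos, min_ictal_s=config.min_ictal_s)
        period_log.extend(plog)
        table, flog = compute_feature_table(rec, periods, catalog)
        period_log.extend(flog)
        tables.append(table)
    if not tables:
        raise ValueError("no person survived the cohort filter")
    feature_table = pd.concat(tables, ignore_index=True)

    _stage("select")
    ictal = feature_table[feature_table["kind"] == "ictal"].reset_index(drop=True)
    space = select_features(ictal, config.selection_config())
    red_ictal = reduce_table(ictal, space)

    _stage("zscore+pca")
    zmodel = fit_zscore(red_ictal)
    z_ictal = apply_zscore(zmodel, red_ictal)
    pca = fit_pca(z_ictal, n_components_used=config.n_components)
    scores = project(pca, z_ictal)

    _stage("clustering+radar")
    centroids, clustering = person_clustering(
        scores, n_components=config.n_components,
        leave_one_out=config.leave_one_out, ci_method=config.ci_method,
    )
    radar = build_radar(z_ictal)

    _stage("separations")
    separations: dict[str, SeparationResult] = {}
    for kind in ("preictal", "baseline"):
        other = feature_table[feature_table["kind"] == kind].reset_index(drop=True)
        if other.empty:
            continue
        z_other = apply_zscore(zmodel, reduce_table(other, space))
        separations[kind] = state_separation(z_ictal, z_other, other_kind=kind,
                                             ci_method=config.ci_method)

    return FingerprintReport(
        config=config, catalog=catalog, feature_table=feature_table,
        space=space, zscore=zmodel, pca=pca, centroids=centroids,
        clustering=clustering, radar=radar, separations=separations,
        exclusions=period_log,
    )
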