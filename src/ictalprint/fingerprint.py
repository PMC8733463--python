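"""Fingerprint construction and evaluation in the reduced feature space.

The reduced (5-feature) ictal table is Z-score normalized — means and
standard deviations are fit on the ictal rows and reused for pre-ictal
and baseline rows, anchoring every comparison to ictal statistics. A
PCA of the Z-scored ictal rows gives the visualization space; person
centroids over the first principal components drive a nearest-centroid
assignment of each seizure, whose accuracy measures how well seizures
cluster within persons. Radar summaries (per-person feature medians
and interquartile ranges) display the fingerprints, and person-specific
cluster-average distances in the Z-scored 5-dim space separate ictal
from pre-ictal / baseline periods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import METADATA_COLUMNS

__all__ = [
    "ZScoreModel", "PCAModel", "CentroidSet", "RadarFingerprint", "SeparationResult",
    "fit_zscore", "apply_zscore", "fit_pca", "project",
    "person_clustering", "build_radar", "state_separation",
    "binomial_halfwidth",
]


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreModel:
    """Per-feature location/scale estimated on ictal rows (sample sd)."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {f: {"mean": float(m), "sd": float(s)}
                   for f, m, s in zip(self.features, self.mean, self.sd)}
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_zscore(table: pd.DataFrame) -> ZScoreModel:
    """Fit per-feature mean/sd on a (reduced, ictal) table.

    Raises on single-row input (sd undefined) and on constant features.
    """
    feats = _feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate a standard deviation")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = [f for f, s in zip(feats, sd) if not s > 0]
    if bad:
        raise ValueError(f"constant feature(s), Z-score undefined: {bad}")
    return ZScoreModel(features=feats, mean=mean, sd=sd)


def apply_zscore(model: ZScoreModel, table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with model features standardized."""
    missing = [f for f in model.features if f not in table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing}")
    out = table.copy()
    X = out[model.features].to_numpy(dtype=float)
    out[model.features] = (X - model.mean) / model.sd
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Covariance-eigendecomposition PCA of the Z-scored ictal rows.

    Sign convention: the largest-magnitude loading of each component is
    positive, so loadings are reproducible across library versions.
    """

    features: list[str]
    mean: np.ndarray                      # of the fitted rows
    loadings: np.ndarray                  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components_used: int = 3

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": self.features,
            "mean": [float(v) for v in self.mean],
            "loadings": [[float(v) for v in row] for row in self.loadings],
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio],
            "n_components_used": self.n_components_used,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_pca(z_table: pd.DataFrame, n_components_used: int = 3) -> PCAModel:
    """Fit a full PCA on Z-scored ictal rows (components = features)."""
    feats = _feature_columns(z_table)
    X = z_table[feats].to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError(f"PCA needs at least as many rows ({n}) as features ({p})")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    loadings = evecs[:, order].T
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(
        features=feats, mean=mean, loadings=loadings,
        explained_variance=evals, explained_variance_ratio=ratio,
        n_components_used=min(n_components_used, p),
    )


def project(model: PCAModel, table: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Project rows onto the principal components (scores ``PC1..PCk``)."""
    k = model.loadings.shape[0] if n_components is None else n_components
    X = table[model.features].to_numpy(dtype=float)
    scores = (X - model.mean) @ model.loadings[:k].T
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    out = table[meta].copy() if meta else pd.DataFrame(index=table.index)
    for i in range(k):
        out[f"PC{i + 1}"] = scores[:, i]
    return out


# ---------------------------------------------------------------------------
# Nearest-centroid clustering of seizures by person
# ---------------------------------------------------------------------------

@dataclass
class CentroidSet:
    """Per-person mean vectors in a given space."""

    space_tag: str                        # "pca" | "reduced_z"
    columns: list[str]
    centroids: dict[str, np.ndarray]
    n: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "space": self.space_tag,
            "columns": self.columns,
            "centroids": {p: [float(v) for v in c] for p, c in sorted(self.centroids.items())},
            "n": {p: int(v) for p, v in sorted(self.n.items())},
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def binomial_halfwidth(p: float, n: int, method: str = "wald", level: float = 0.95) -> float:
    """Half-width of a binomial proportion CI (wald | wilson | clopper-pearson)."""
    if n <= 0:
        return float("nan")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "wald":
        return float(z * np.sqrt(p * (1.0 - p) / n))
    k = int(round(p * n))
    if method == "wilson":
        denom = 1.0 + z * z / n
        return float(z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom)
    if method == "clopper-pearson":
        lo = stats.beta.ppf((1 - level) / 2, k, n - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - (1 - level) / 2, k + 1, n - k) if k < n else 1.0
        return float((hi - lo) / 2.0)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class SeparationResult:
    """Classification summary of one separation task."""

    task: str           # "person_clustering" | "preictal_vs_ictal" | "baseline_vs_ictal"
    accuracy: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    ppv: float = float("nan")
    npv: float = float("nan")
    ci_halfwidths: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)
    assignments: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        def clean(v):
            return None if isinstance(v, float) and np.isnan(v) else float(v)
        return {
            "task": self.task,
            "accuracy": clean(self.accuracy),
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "ppv": clean(self.ppv),
            "npv": clean(self.npv),
            "ci_halfwidths": {k: clean(v) for k, v in sorted(self.ci_halfwidths.items())},
            "n": {k: int(v) for k, v in sorted(self.n.items())},
        }


def _nearest(point: np.ndarray, centroids: dict[str, np.ndarray],
             sizes: dict[str, int]) -> str:
    # tie at exactly equal distance -> person with more seizures, then lexicographic
    best: str | None = None
    best_d = np.inf
    for pid in sorted(centroids, key=lambda p: (-sizes[p], p)):
        d = float(np.linalg.norm(point - centroids[pid]))
        if d < best_d:
            best, best_d = pid, d
    assert best is not None
    return best


def person_clustering(
    scores: pd.DataFrame,
    n_components: int = 3,
    persons: Sequence[str] | None = None,
    leave_one_out: bool = False,
    ci_method: str = "wald",
) -> tuple[CentroidSet, SeparationResult]:
    """Assign every seizure to the person with the nearest centroid.

    ``scores`` holds per-seizure principal-component scores with a
    ``person_id`` column. Centroids are the per-person means over the
    first ``n_components`` scores, computed from all seizures; with
    ``leave_one_out`` the assigned seizure is removed from its own
    person's centroid first. ``persons`` restricts the task to a
    subset (the others' rows are dropped entirely).
    """
    df = scores if persons is None else scores[scores["person_id"].isin(persons)]
    if df.empty:
        raise ValueError("no rows to cluster")
    cols = [c for c in df.columns if c.startswith("PC")][:n_components]
    if len(cols) < n_components:
        raise ValueError(f"need {n_components} components, table has {len(cols)}")
    X = df[cols].to_numpy(dtype=float)
    y = df["person_id"].to_numpy()
    uniq = sorted(set(y))
    if len(uniq) < 2:
        raise ValueError("need at least 2 persons")
    sums = {p: X[y == p].sum(axis=0) for p in uniq}
    sizes = {p: int((y == p).sum()) for p in uniq}
    if min(sizes.values()) < 1:
        raise ValueError("every person needs at least one seizure")
    centroids = {p: sums[p] / sizes[p] for p in uniq}

    assigned = []
    for i in range(len(X)):
        if leave_one_out and sizes[y[i]] > 1:
            cents = dict(centroids)
            cents[y[i]] = (sums[y[i]] - X[i]) / (sizes[y[i]] - 1)
        else:
            cents = centroids
        assigned.append(_nearest(X[i], cents, sizes))
    assigned = np.array(assigned)
    correct = assigned == y
    acc = float(np.mean(correct))
    n_total = len(X)
    result = SeparationResult(
        task="person_clustering",
        accuracy=acc,
        ci_halfwidths={"accuracy": binomial_halfwidth(acc, n_total, ci_method)},
        n={**sizes, "total": n_total},
        assignments=pd.DataFrame({
            "person_id": y,
            "seizure_id": df["seizure_id"].to_numpy() if "seizure_id" in df else np.arange(n_total),
            "assigned": assigned,
            "correct": correct,
        }),
    )
    cset = CentroidSet(space_tag="pca", columns=cols, centroids=centroids, n=sizes)
    return cset, result


# ---------------------------------------------------------------------------
# Radar fingerprints
# ---------------------------------------------------------------------------

@dataclass
class RadarFingerprint:
    """Per-person medians and IQRs of the Z-scored ictal features."""

    features: list[str]
    median: dict[str, np.ndarray]
    iqr: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.median):
            for i, f in enumerate(self.features):
                rows.append({"person_id": pid, "feature": f, "order": i + 1,
                             "median": float(self.median[pid][i]),
                             "iqr": float(self.iqr[pid][i])})
        return pd.DataFrame(rows)


def build_radar(z_table: pd.DataFrame) -> RadarFingerprint:
    """Medians and interquartile ranges per person and feature.

    Percentiles use linear interpolation; every person needs >= 2 rows
    for the IQR to be meaningful.
    """
    feats = _feature_columns(z_table)
    median: dict[str, np.ndarray] = {}
    iqr: dict[str, np.ndarray] = {}
    for pid, grp in z_table.groupby("person_id"):
        X = grp[feats].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError(f"person {pid!r} has {X.shape[0]} row(s); IQR needs >= 2")
        median[pid] = np.median(X, axis=0)
        q75, q25 = np.percentile(X, [75, 25], axis=0)
        iqr[pid] = q75 - q25
    return RadarFingerprint(features=feats, median=median, iqr=iqr)


# ---------------------------------------------------------------------------
# Ictal vs pre-ictal / baseline separation
# ---------------------------------------------------------------------------

def state_separation(
    z_ictal: pd.DataFrame,
    z_other: pd.DataFrame,
    other_kind: str = "preictal",
    ci_method: str = "wald",
) -> SeparationResult:
    """Separate ictal from another period kind by cluster-average distance.

    For every person, the ictal cluster average and the other-kind
    cluster average are computed in the Z-scored reduced space; each
    period is classified as the class whose person-specific average is
    nearer (Euclidean norm; exact ties count as ictal). Metrics are
    pooled over persons with ictal as the positive class; 95% CIs use
    the pooled n. Persons missing either class are excluded.
    """
    feats = _feature_columns(z_ictal)
    if _feature_columns(z_other) != feats:
        raise ValueError("ictal and other tables must share feature columns")
    persons = sorted(set(z_ictal["person_id"]) & set(z_other["person_id"]))
    dropped = sorted((set(z_ictal["person_id"]) | set(z_other["person_id"])) - set(persons))
    if dropped:
        import warnings
        warnings.warn(f"persons missing one class excluded from separation: {dropped}",
                      stacklevel=2)
    if not persons:
        raise ValueError("no person has both classes")

    rows = []
    tp = tn = fp = fn = 0
    for pid in persons:
        Xi = z_ictal.loc[z_ictal["person_id"] == pid, feats].to_numpy(dtype=float)
        Xo = z_other.loc[z_other["person_id"] == pid, feats].to_numpy(dtype=float)
        ci = Xi.mean(axis=0)
        co = Xo.mean(axis=0)
        for X, true_kind, table in ((Xi, "ictal", z_ictal), (Xo, other_kind, z_other)):
            sub = table[table["person_id"] == pid]
            sids = sub["seizure_id"].to_numpy() if "seizure_id" in sub else np.arange(len(X))
            di = np.linalg.norm(X - ci, axis=1)
            do = np.linalg.norm(X - co, axis=1)
            pred = np.where(di <= do, "ictal", other_kind)   # tie -> ictal
            for k in range(len(X)):
                rows.append({"person_id": pid, "seizure_id": sids[k], "kind": true_kind,
                             "dist_ictal": float(di[k]), "dist_other": float(do[k]),
                             "predicted": pred[k]})
                if true_kind == "ictal":
                    tp += pred[k] == "ictal"
                    fn += pred[k] != "ictal"
                else:
                    tn += pred[k] != "ictal"
                    fp += pred[k] == "ictal"

    n_pos, n_neg = tp + fn, tn + fp
    n_total = n_pos + n_neg
    acc = (tp + tn) / n_total
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    ci_hw = {name: binomial_halfwidth(val, n_total, ci_method)
             for name, val in (("accuracy", acc), ("sensitivity", sens),
                               ("specificity", spec), ("ppv", ppv), ("npv", npv))
             if not np.isnan(val)}
    return SeparationResult(
        task=f"{other_kind}_vs_ictal",
        accuracy=float(acc), sensitivity=float(sens), specificity=float(spec),
        ppv=float(ppv), npv=float(npv),
        ci_halfwidths=ci_hw,
        n={"ictal": int(n_pos), other_kind: int(n_neg), "total": int(n_total)},
        assignments=pd.DataFrame(rows),
    )
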