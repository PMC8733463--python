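"""Optional rendering of radar fingerprints and PC pair plots (PNG).

Matplotlib is imported lazily; the analysis itself never needs it —
all plot coordinates are exported as CSV by the pipeline regardless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def render_report_plots(report, out_dir) -> list[Path]:
    """Write ``radar.png`` and ``pairplot.png`` for a FingerprintReport."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written: list[Path] = []

    radar = report.radar
    persons = sorted(radar.median)
    k = len(radar.features)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
    ncols = min(len(persons), 4)
    nrows = int(np.ceil(len(persons) / ncols))
    fig, axes = plt.subplots(nrows, ncols, subplot_kw={"projection": "polar"},
                             figsize=(3.2 * ncols, 3.4 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for ax, pid in zip(axes, persons):
        med = radar.median[pid]
        iqr = radar.iqr[pid]
        closed = np.concatenate([angles, angles[:1]])
        ax.plot(closed, np.concatenate([med, med[:1]]), lw=1.5)
        ax.fill_between(closed,
                        np.concatenate([med - iqr / 2, [med[0] - iqr[0] / 2]]),
                        np.concatenate([med + iqr / 2, [med[0] + iqr[0] / 2]]),
                        alpha=0.3)
        ax.set_xticks(angles)
        ax.set_xticklabels([f"F{i + 1}" for i in range(k)], fontsize=8)
        ax.set_title(f"person {pid}", fontsize=10)
    for ax in axes[len(persons):]:
        ax.set_visible(False)
    fig.suptitle("Ictal fingerprints (Z-scored medians ± IQR/2)")
    fig.tight_layout()
    p = out / "radar.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    assign = report.clustering.assignments
    scores_cols = report.centroids.columns
    # recompute scores for the plot from the stored assignments + centroids
    # is lossy; use the feature table through the saved models instead
    from .selection import reduce_table
    from .fingerprint import apply_zscore, project
    ictal = report.feature_table[report.feature_table["kind"] == "ictal"]
    z = apply_zscore(report.zscore, reduce_table(ictal, report.space))
    sc = project(report.pca, z)
    k = min(3, len(scores_cols))
    fig, axes = plt.subplots(k, k, figsize=(3.0 * k, 3.0 * k))
    colors = {pid: f"C{i}" for i, pid in enumerate(sorted(set(sc["person_id"])))}
    for i in range(k):
        for j in range(k):
            ax = axes[i, j] if k > 1 else axes
            for pid, grp in sc.groupby("person_id"):
                if i == j:
                    ax.hist(grp[f"PC{i + 1}"], bins=12, alpha=0.5,
                            color=colors[pid], label=pid)
                else:
                    ax.scatter(grp[f"PC{j + 1}"], grp[f"PC{i + 1}"], s=12,
                               color=colors[pid], label=pid)
            if i == k - 1:
                ax.set_xlabel(f"PC{j + 1}")
            if j == 0:
                ax.set_ylabel(f"PC{i + 1}")
    handles, labels = (axes[0, 0] if k > 1 else axes).get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    fig.legend(uniq.values(), uniq.keys(), loc="upper right", title="person")
    fig.suptitle("Seizures in the principal-component space")
    fig.tight_layout()
    p = out / "pairplot.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)
    return written
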