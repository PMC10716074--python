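"""Trajectory plots of the per-cycle comparison metrics."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .metrics import METRIC_COLUMNS

_LABELS = {
    "mean_hybrid_gv": "Mean hybrid genetic value",
    "best_hybrid_gv": "Best hybrid genetic value",
    "va_pool_A": "Additive variance, pool A",
    "va_pool_B": "Additive variance, pool B",
    "accuracy": "Selection / prediction accuracy",
    "fst": "Fixation index (FST) between pools",
}


def plot_metric(rows: pd.DataFrame, metric: str, path) -> None:
    """Replicate-mean trajectory of one metric, one line per scheme x size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    means = rows.groupby(["scheme", "size", "cycle"])[metric].mean().reset_index()
    for (scheme, size), grp in means.groupby(["scheme", "size"]):
        ax.plot(grp["cycle"], grp[metric], label=f"{scheme} ({size})")
    ax.set_xlabel("Breeding cycle")
    ax.set_ylabel(_LABELS.get(metric, metric))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_all_metrics(rows: pd.DataFrame, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for metric in METRIC_COLUMNS:
        if metric in rows.columns:
            path = out_dir / f"{metric}.png"
            plot_metric(rows, metric, path)
            written.append(path)
    return written
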