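"""Small plotting helpers for validation reports (matplotlib, Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_qq", "plot_station_abs_errors"]


def plot_qq(qq, path: str | Path, title: str = "") -> None:
    """Sorted-observed vs sorted-predicted Q-Q plot with the 1:1 line."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["observed"], qq["predicted"], s=12, alpha=0.7)
    lims = [
        min(qq["observed"].min(), qq["predicted"].min()),
        max(qq["observed"].max(), qq["predicted"].max()),
    ]
    ax.plot(lims, lims, color="red", lw=1)
    ax.set_xlabel("observed PM$_{2.5}$ (µg/m³)")
    ax.set_ylabel("predicted PM$_{2.5}$ (µg/m³)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_station_abs_errors(reports: dict, path: str | Path) -> None:
    """Per-station box plots of absolute errors, one panel per model."""
    n = len(reports)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.5), sharey=True,
                             squeeze=False)
    for ax, (model_id, report) in zip(axes[0], reports.items()):
        data = [report.abs_errors[c].to_numpy() for c in report.abs_errors]
        ax.boxplot(data, tick_labels=list(report.abs_errors.columns))
        ax.set_title(model_id, fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    axes[0][0].set_ylabel("absolute error (µg/m³)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
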