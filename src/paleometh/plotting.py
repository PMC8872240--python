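"""Diagnostic figures for coverage-titration experiments."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .precision import ExperimentResult

__all__ = ["plot_noncovered", "plot_sd_trend", "save_experiment_plots"]


def plot_noncovered(result: ExperimentResult, path: str | Path) -> None:
    """Non-covered CpG count versus down-sampled coverage."""
    t = result.table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t.levels, t.n_noncovered, "o-", color="#336699")
    ax.set_xlabel("coverage (fold)")
    ax.set_ylabel("non-covered CpGs")
    ax.set_title(f"{result.config.name}: uncovered CpGs vs coverage")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sd_trend(result: ExperimentResult, path: str | Path) -> None:
    """SD(Delta f) versus coverage with the fitted trendline."""
    t = result.table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t.levels, t.sd_delta_f, "o", color="#993333", label="SD(Δf)")
    grid = np.linspace(t.levels.min(), t.levels.max(), 200)
    ax.plot(
        grid,
        result.trend.predict(grid, result.config.full_cov),
        ":",
        color="gray",
        label=(
            f"{result.trend.form} fit "
            f"(R²={result.trend.r_squared:.3f})"
        ),
    )
    ax.axhline(
        result.recommendation.threshold,
        ls="--",
        color="#339933",
        label=f"{result.recommendation.factor:g}×SD threshold",
    )
    ax.set_xlabel("coverage (fold)")
    ax.set_ylabel("SD(Δf)")
    ax.set_title(f"{result.config.name}: precision vs coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_experiment_plots(result: ExperimentResult, outdir: str | Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plot_noncovered(result, outdir / "noncovered_vs_coverage.png")
    plot_sd_trend(result, outdir / "sd_trend.png")
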