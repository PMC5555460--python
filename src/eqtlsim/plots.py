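"""Figure rendering for scenario runs: RTC ECDFs, variance-decomposition
box plots, and bias-surface heatmaps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import bias_surface  # noqa: E402


def plot_rtc_ecdf(rtc: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for scenario, sub in rtc.groupby("scenario"):
        x = np.sort(sub["rtc"].to_numpy())
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=scenario)
    ax.set_xlabel("RTC score of the primary signal")
    ax.set_ylabel("cumulative probability")
    ax.legend(title="scenario")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ve_decomposition(replicates: pd.DataFrame, path: Path) -> None:
    cols = ["ve_simulated", "ve_joint", "ve_conditional_sum", "ve_top_peak"]
    labels = ["Simu", "Multi", "Uni", "Single"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([replicates[c].dropna() for c in cols], tick_labels=labels)
    ax.set_ylabel("proportion of trait variance explained")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bias_surface(scored_pairs: pd.DataFrame, path: Path) -> None:
    surf = bias_surface(scored_pairs.dropna(subset=["joint_dev"]))
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
    extent = (surf.r2_edges[0], surf.r2_edges[-1],
              surf.beta_edges[0], surf.beta_edges[-1])
    for ax, layer, title in zip(
        axes,
        (surf.conditional, surf.joint, surf.difference),
        ("conditional |deviation|", "joint |deviation|", "joint - conditional"),
    ):
        im = ax.imshow(layer, origin="lower", aspect="auto", extent=extent)
        ax.set_title(title)
        ax.set_xlabel("mean r$^2$ with co-causal sites")
        fig.colorbar(im, ax=ax)
    axes[0].set_ylabel(r"true $|\beta|$ (sdu)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(scenario_dir: Path, outdir: Path) -> list[Path]:
    written = []
    rtc = pd.read_csv(scenario_dir / "rtc.tsv", sep="\t")
    p = outdir / "rtc_ecdf.png"
    plot_rtc_ecdf(rtc, p)
    written.append(p)
    replicates = pd.read_csv(scenario_dir / "replicates.tsv", sep="\t")
    p = outdir / "ve_decomposition.png"
    plot_ve_decomposition(replicates, p)
    written.append(p)
    scored = pd.read_csv(scenario_dir / "scored_pairs.tsv", sep="\t")
    if len(scored):
        p = outdir / "bias_surface.png"
        plot_bias_surface(scored, p)
        written.append(p)
    return written
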