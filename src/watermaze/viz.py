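"""Figure helpers: learning curves, latency boxes, occupancy bars, heatmaps.

Figures are side-effects of CLI runs, never inputs to any computation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .arena import ArenaConfig, QUADRANTS

__all__ = [
    "plot_learning_curve",
    "plot_latency_boxes",
    "plot_occupancy_bars",
    "plot_heatmap",
    "plot_trajectory",
]


def plot_learning_curve(latencies: pd.DataFrame, path) -> None:
    """Mean escape latency per day with s.e.m. bars."""
    by_day = latencies.groupby("day")["latency"]
    days = by_day.mean().index.to_numpy()
    mean = by_day.mean().to_numpy()
    sem = by_day.sem().to_numpy()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(days, mean, yerr=sem, marker="o", capsize=3)
    ax.set_xlabel("day")
    ax.set_ylabel("mean escape latency (s)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_latency_boxes(latencies: pd.DataFrame, path, by: str = "trial") -> None:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    groups = [g["latency"].to_numpy() for _, g in latencies.groupby(by)]
    ax.boxplot(groups, showfliers=True)
    ax.set_xlabel(by)
    ax.set_ylabel("escape latency (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_occupancy_bars(occupancy: pd.DataFrame, path, title: str = "") -> None:
    """Mean quadrant occupancy fractions with sd bars."""
    means = [occupancy[q].mean() for q in QUADRANTS]
    sds = [occupancy[q].std() for q in QUADRANTS]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.bar(QUADRANTS, means, yerr=sds, capsize=3)
    ax.set_ylabel("occupancy fraction")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(density: np.ndarray, xedges, yedges, path, arena: ArenaConfig | None = None) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        density.T,
        origin="lower",
        extent=[xedges[0], xedges[-1], yedges[0], yedges[-1]],
        cmap="hot",
    )
    if arena is not None:
        ax.add_patch(
            plt.Circle((0, 0), arena.pool_radius, fill=False, color="w", lw=1)
        )
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(trajectory: np.ndarray, arena: ArenaConfig, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.add_patch(plt.Circle((0, 0), arena.pool_radius, fill=False, color="k"))
    ax.add_patch(
        plt.Circle(arena.platform_center, arena.platform_radius, color="0.6")
    )
    ax.plot(trajectory[:, 1], trajectory[:, 2], lw=0.8)
    ax.plot(trajectory[0, 1], trajectory[0, 2], "go", ms=4)
    ax.set_aspect("equal")
    ax.set_xlim(-arena.pool_radius * 1.05, arena.pool_radius * 1.05)
    ax.set_ylim(-arena.pool_radius * 1.05, arena.pool_radius * 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
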