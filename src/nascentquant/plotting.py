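"""Diagnostic figures: fit overlays, distance histograms, triangle plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .distances import DistanceDistribution
from .io import ImageStack

__all__ = ["spot_overlay", "distance_histogram_plot", "triangle_plot"]


def spot_overlay(stack: ImageStack, spots: pd.DataFrame, channel: str,
                 path: str | Path) -> None:
    """Max projection of a channel with fitted spot centres overlaid.

    Accepted spots are circled; rejected candidates are marked with crosses
    so fit failures remain visible during QC.
    """
    proj = stack.channel(channel).max(axis=0)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj, cmap="gray", origin="upper")
    sub = spots[spots["channel"] == channel] if "channel" in spots.columns else spots
    acc = sub[sub["accepted"].astype(bool)] if "accepted" in sub.columns else sub
    rej = sub[~sub["accepted"].astype(bool)] if "accepted" in sub.columns else sub.iloc[:0]
    ax.scatter(acc["x_px"], acc["y_px"], s=60, facecolors="none", edgecolors="lime",
               label=f"accepted ({len(acc)})")
    if len(rej):
        ax.scatter(rej["x_px"], rej["y_px"], s=30, marker="x", color="red",
                   label=f"rejected ({len(rej)})")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(f"{channel}: fitted spot centres")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def distance_histogram_plot(dist: DistanceDistribution, path: str | Path,
                            bin_width: float = 25.0) -> None:
    """2D amplitude-distance histogram plus the gated 1D fit."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.imshow(dist.histogram, aspect="auto", origin="lower",
               extent=[dist.dist_edges[0], dist.dist_edges[-1],
                       dist.amp_edges[0], dist.amp_edges[-1]], cmap="viridis")
    ax1.set_xlabel("distance (nm)")
    ax1.set_ylabel("amplitude")
    ax1.set_title(f"{dist.pair[0]}-{dist.pair[1]}")
    gated = dist.distances_nm[(dist.distances_nm >= dist.gate[0])
                              & (dist.distances_nm <= dist.gate[1])]
    edges = np.arange(dist.gate[0], dist.gate[1] + bin_width, bin_width)
    ax2.hist(gated, bins=edges, color="steelblue", alpha=0.7)
    if np.isfinite(dist.fit.peak):
        ax2.axvline(dist.fit.peak, color="crimson",
                    label=f"peak {dist.fit.peak:.0f} +- {dist.fit.se:.0f} nm")
        ax2.legend()
    ax2.set_xlabel("distance (nm)")
    ax2.set_ylabel("pairs")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def triangle_plot(triangle: Mapping, path: str | Path) -> None:
    """Peak inter-locus distances drawn as a triangle, gene 1 at the origin."""
    fig, ax = plt.subplots(figsize=(5, 5))
    names = [k for k in triangle if k != "peaks"]
    pts = np.array([triangle[k] for k in names], dtype=float)
    cycle = list(pts) + [pts[0]]
    ax.plot([p[0] for p in cycle], [p[1] for p in cycle], "o-", color="navy")
    for name, (x, y) in zip(names, pts):
        ax.annotate(name, (x, y), textcoords="offset points", xytext=(6, 6))
    ax.set_xlabel("nm")
    ax.set_ylabel("nm")
    ax.set_aspect("equal")
    ax.set_title("peak inter-locus distances")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
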