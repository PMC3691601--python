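"""Minimal plots: genome-wide LOD curves and per-genotype effect plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_lod(curve, threshold=None, path=None, ax=None):
    """Genome-wide LOD profile with alternating linkage-group shading."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    pos = curve.positions
    offset = 0.0
    ticks, labels = [], []
    for i, lg in enumerate(dict.fromkeys(pos["lg"])):
        m = (pos["lg"] == lg).to_numpy()
        cm = pos["cm"].to_numpy()[m]
        x = cm - cm.min() + offset
        ax.plot(x, curve.lod[m], color="C0" if i % 2 == 0 else "C1", lw=1)
        ticks.append(offset + (cm.max() - cm.min()) / 2)
        labels.append(str(lg))
        offset = x.max() + 5
    if threshold is not None:
        ax.axhline(threshold, color="red", ls="--", lw=1, label=f"threshold {threshold:.2f}")
        ax.legend(frameon=False)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("LOD")
    ax.set_title(curve.trait)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_effects(effects: dict, path=None, ax=None):
    """Phenotype means +- SE by genotype class at a peak marker."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    order = ["B", "H", "A"]
    xs, means, ses = [], [], []
    for i, cls in enumerate(order):
        info = effects["classes"].get(cls) or {}
        if info.get("mean") is None:
            continue
        xs.append(i)
        means.append(info["mean"])
        ses.append(info["se"] if np.isfinite(info.get("se", np.nan)) else 0.0)
    ax.errorbar(xs, means, yerr=ses, fmt="o-", capsize=4)
    ax.set_xticks(range(3))
    ax.set_xticklabels(["BB", "AB", "AA"])
    ax.set_ylabel("phenotype mean")
    ax.set_title(f"{effects['marker']} ({effects.get('dominance', '')})")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
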