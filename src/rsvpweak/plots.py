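"""Figures: ERP waveforms, montage selection-frequency maps, accuracy violins."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .erp import ErpWaveform
from .montage import MONTAGE_62, channel_positions


def plot_erp(target: ErpWaveform, nontarget: ErpWaveform, ax=None, title=""):
    """Target vs non-target averages with ±1 SE shading."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for wave, color, label in ((target, "tab:red", "target"),
                               (nontarget, "tab:blue", "non-target")):
        t = np.arange(len(wave.mean)) * (1000.0 / wave.rate)
        ax.plot(t, wave.mean, color=color, label=label)
        ax.fill_between(t, wave.mean - wave.stderr, wave.mean + wave.stderr,
                        color=color, alpha=0.25, linewidth=0)
    ax.set_xlabel("time post-stimulus (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.set_title(title or f"average ERP at {target.channel}")
    ax.legend(frameon=False)
    return ax


def plot_selection_map(counts: dict[str, int], ax=None, title="selection frequency"):
    """Top-view montage scatter colored by how often each channel was chosen."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    pos = channel_positions()
    xy = np.array([pos[c][:2] for c in MONTAGE_62])
    vals = np.array([counts.get(c, 0) for c in MONTAGE_62], dtype=float)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, s=160, cmap="YlOrRd",
                    edgecolors="k", linewidths=0.5)
    for (x, y), c in zip(xy, MONTAGE_62):
        ax.annotate(c, (x, y), ha="center", va="center", fontsize=4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7, label="times selected")
    return ax


def plot_accuracy_violin(acc_long, ax=None, value="accuracy"):
    """Violin of per-subject accuracies (or ITRs) by condition and set."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    groups, labels = [], []
    for (s, cond), grp in acc_long.groupby(["set", "condition"]):
        groups.append(grp[value].values)
        labels.append(f"set{s}\n{cond}")
    ax.violinplot(groups, showmeans=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7)
    ax.set_ylabel(value)
    return ax
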