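"""ERP averaging and P300 amplitude/latency statistics.

The P300 here is quantified on the across-epoch average waveform: amplitude
is the maximum of the average in the 200-900 ms post-stimulus window
(endpoints inclusive) and latency is the time of that maximum, ties broken
to the earliest sample. An alternative per-epoch mode (average of per-epoch
window maxima) is available for sensitivity analyses. Benchmark-versus-
condition comparisons use two-sided paired t-tests across subjects, reported
uncorrected with the usual star codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet

P300_WINDOW = (200.0, 900.0)


@dataclass
class ErpWaveform:
    """Pointwise mean and standard error of one class at one channel."""

    mean: np.ndarray
    stderr: np.ndarray
    rate: float
    class_label: str  # "target" | "non-target"
    channel: str


def average_erp(epochs: EpochSet, class_label: str, channel: str) -> ErpWaveform:
    """Across-epoch mean ± SE at one channel for targets or non-targets."""
    if class_label not in ("target", "non-target"):
        raise ValueError("class_label must be 'target' or 'non-target'")
    mask = epochs.labels if class_label == "target" else ~epochs.labels
    if not mask.any():
        raise ValueError(f"no {class_label} epochs present")
    ch = epochs.channels.index(channel)
    x = epochs.data[mask, ch, :]
    n = x.shape[0]
    mean = x.mean(axis=0)
    stderr = x.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ErpWaveform(mean=mean, stderr=stderr, rate=epochs.rate,
                       class_label=class_label, channel=channel)


def p300_features(wave: ErpWaveform, window=P300_WINDOW) -> tuple[float, float]:
    """(amplitude μV, latency ms): max of the average waveform in ``window``.

    Window endpoints are inclusive; the earliest sample wins ties.
    """
    lo, hi = window
    times = np.arange(len(wave.mean)) * (1000.0 / wave.rate)
    if lo < times[0] or hi > times[-1]:
        raise ValueError(f"window {window} outside epoch [0, {times[-1]:.1f}] ms")
    mask = (times >= lo) & (times <= hi)
    seg = wave.mean[mask]
    i = int(np.argmax(seg))  # argmax returns the first maximum
    return float(seg[i]), float(times[mask][i])


def p300_per_epoch(epochs: EpochSet, channel: str, window=P300_WINDOW) -> np.ndarray:
    """Per-epoch window maxima at one channel (sensitivity-analysis mode)."""
    ch = epochs.channels.index(channel)
    times = epochs.times_ms
    mask = (times >= window[0]) & (times <= window[1])
    return epochs.data[:, ch, mask].max(axis=-1)


def paired_t(benchmark, other) -> tuple[float, float]:
    """Two-sided paired t-test of benchmark vs another condition."""
    benchmark = np.asarray(benchmark, dtype=float)
    other = np.asarray(other, dtype=float)
    if benchmark.shape != other.shape:
        raise ValueError("paired samples must have equal length")
    if len(benchmark) < 2:
        raise ValueError("need at least two pairs")
    res = stats.ttest_rel(benchmark, other)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """'' / '*' / '**' / '***' for p < .05 / .01 / .001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def erp_summary_table(per_subject: pd.DataFrame, benchmark: str = "C1") -> pd.DataFrame:
    """Condition-level amplitude/latency summary with benchmark paired tests.

    ``per_subject`` needs columns subject, condition, amplitude, latency.
    Returns one row per condition: mean ± SE of both features plus the
    paired-t p-value and star code against the benchmark (blank for the
    benchmark itself).
    """
    rows = []
    bench = per_subject[per_subject.condition == benchmark].sort_values("subject")
    for cond, grp in per_subject.groupby("condition", sort=True):
        grp = grp.sort_values("subject")
        n = len(grp)
        row = {
            "condition": cond,
            "amplitude_mean": grp.amplitude.mean(),
            "amplitude_se": grp.amplitude.std(ddof=1) / np.sqrt(n),
            "latency_mean": grp.latency.mean(),
            "latency_se": grp.latency.std(ddof=1) / np.sqrt(n),
        }
        if cond != benchmark and len(bench) == n and n >= 2:
            _, p_amp = paired_t(bench.amplitude.values, grp.amplitude.values)
            _, p_lat = paired_t(bench.latency.values, grp.latency.values)
            row.update(
                amplitude_p=p_amp, amplitude_stars=significance_stars(p_amp),
                latency_p=p_lat, latency_stars=significance_stars(p_lat),
            )
        else:
            row.update(amplitude_p=np.nan, amplitude_stars="",
                       latency_p=np.nan, latency_stars="")
        rows.append(row)
    return pd.DataFrame(rows)
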