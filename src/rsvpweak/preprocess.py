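"""Continuous-EEG preprocessing: band-pass, epoching, decimation.

The pipeline filters the continuous recording 0.3-20 Hz with a zero-phase
Butterworth (4th order each pass, applied forward-backward so ERP latencies
are not shifted), cuts one epoch per stimulus from onset to 1000 ms
post-stimulus, and decimates by 8 to 125 Hz. The 20 Hz cutoff sits well below
the 62.5 Hz post-decimation Nyquist, so decimation is plain sample picking
with no second anti-alias stage. No baseline correction and no artifact
rejection are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import RawRecording

DEFAULT_BAND = (0.3, 20.0)
DEFAULT_FACTOR = 8
FILTER_ORDER = 4


@dataclass
class EpochSet:
    """Segmented trials: epochs x channels x samples with per-epoch labels.

    ``labels`` is boolean (True = target); ``condition`` holds the contrast
    label per epoch; the time axis starts at stimulus onset (0 ms).
    """

    data: np.ndarray
    labels: np.ndarray
    condition: np.ndarray
    rate: float
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.data)
        if not (len(self.labels) == len(self.condition) == n):
            raise ValueError("labels/condition length must match epoch count")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.data.shape[-1]) * (1000.0 / self.rate)

    def pick(self, channels) -> "EpochSet":
        idx = [self.channels.index(c) for c in channels]
        return replace(self, data=self.data[:, idx, :], channels=tuple(channels))

    def where(self, mask) -> "EpochSet":
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            condition=self.condition[mask],
        )


def design_bandpass(low: float, high: float, rate: float, order: int = FILTER_ORDER):
    """Second-order sections of the band-pass used throughout the pipeline."""
    if not 0 < low < high < rate / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at rate {rate} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def bandpass(recording: RawRecording, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> RawRecording:
    """Zero-phase band-pass of the continuous signal, per channel.

    Forward-backward application squares the magnitude response and cancels
    the phase, so component latencies are preserved; DC is removed by the
    high-pass edge.
    """
    sos = design_bandpass(low, high, recording.sampling_rate)
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=-1)
    filtered = filtered.astype(recording.signal.dtype, copy=False)
    return RawRecording(
        channel_labels=recording.channel_labels,
        sampling_rate=recording.sampling_rate,
        signal=filtered,
        schedules=recording.schedules,
    )


def segment(recording: RawRecording, events: pd.DataFrame,
            window_ms: float = 1000.0) -> EpochSet:
    """Cut one epoch per stimulus event: [onset, onset + window_ms).

    ``events`` rows must carry onset_ms, is_target and condition. An event
    whose epoch would run past the recording raises with the offending row.
    """
    rate = recording.sampling_rate
    n_keep = int(round(window_ms * rate / 1000.0))
    n_samples = recording.signal.shape[1]
    data = np.empty((len(events), len(recording.channel_labels), n_keep),
                    dtype=recording.signal.dtype)
    labels, conds = [], []
    for i, row in enumerate(events.itertuples(index=False)):
        start = int(round(row.onset_ms * rate / 1000.0))
        stop = start + n_keep
        if start < 0 or stop > n_samples:
            raise ValueError(
                f"epoch for event at {row.onset_ms} ms (session "
                f"{getattr(row, 'session', '?')}, trial {getattr(row, 'trial', '?')}) "
                f"extends past the recording ({n_samples} samples)"
            )
        data[i] = recording.signal[:, start:stop]
        labels.append(bool(row.is_target))
        conds.append(row.condition)
    return EpochSet(
        data=data,
        labels=np.array(labels, dtype=bool),
        condition=np.array(conds, dtype=object),
        rate=rate,
        channels=tuple(recording.channel_labels),
    )


def downsample(epochs: EpochSet, factor: int = DEFAULT_FACTOR) -> EpochSet:
    """Decimate every epoch by keeping every ``factor``-th sample.

    The preceding 20 Hz low-pass already provides anti-aliasing for the
    resulting 125 Hz rate. 1000 samples at 1000 Hz become 125.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if epochs.data.shape[-1] // factor < 2:
        raise ValueError("too few samples to decimate by this factor")
    return replace(
        epochs,
        data=np.ascontiguousarray(epochs.data[..., ::factor]),
        rate=epochs.rate / factor,
    )


def preprocess_recording(recording: RawRecording, events: pd.DataFrame,
                         band=DEFAULT_BAND, factor: int = DEFAULT_FACTOR) -> EpochSet:
    """filter -> segment -> decimate, the standard path for one recording."""
    return downsample(segment(bandpass(recording, *band), events), factor)
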