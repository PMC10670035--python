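"""On-disk formats: events TSV, config YAML, subset JSON, epoch archives."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import ChannelSubset
from .preprocess import EpochSet

EVENT_COLUMNS = ["onset_ms", "duration_ms", "digit", "is_target",
                 "condition", "session", "trial"]


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    df["is_target"] = df["is_target"].astype(bool)
    return df


def write_config(cfg, path) -> None:
    """Serialize a (dataclass) config as YAML; tuples become lists."""
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(plain(cfg), sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_subset(subset: ChannelSubset, path) -> None:
    Path(path).write_text(json.dumps(
        {"name": subset.name, "channels": list(subset.channels),
         "score": subset.score}, indent=2))


def read_subset(path) -> ChannelSubset:
    d = json.loads(Path(path).read_text())
    return ChannelSubset(name=d["name"], channels=tuple(d["channels"]),
                         score=d["score"])


def save_epochs(epochs: EpochSet, path) -> None:
    """Compressed archive of an EpochSet (data + labels + metadata)."""
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float32),
        labels=epochs.labels,
        condition=np.array([str(c) for c in epochs.condition]),
        rate=epochs.rate,
        channels=np.array(epochs.channels),
    )


def load_epochs(path) -> EpochSet:
    z = np.load(path, allow_pickle=False)
    return EpochSet(
        data=z["data"].astype(float),
        labels=z["labels"].astype(bool),
        condition=z["condition"].astype(object),
        rate=float(z["rate"]),
        channels=tuple(str(c) for c in z["channels"]),
    )


def save_recording(recording, path) -> None:
    """Continuous signal + labels + rate in a compressed array container."""
    np.savez_compressed(
        path,
        signal=recording.signal.astype(np.float32),
        channels=np.array(recording.channel_labels),
        rate=recording.sampling_rate,
    )


def load_recording(path):
    from .simulate import RawRecording

    z = np.load(path, allow_pickle=False)
    return RawRecording(
        channel_labels=tuple(str(c) for c in z["channels"]),
        sampling_rate=float(z["rate"]),
        signal=z["signal"].astype(np.float32),
        schedules=[],
    )


def load_edf(path, events_path) -> tuple["np.ndarray", list[str], float, pd.DataFrame]:
    """Read user-supplied continuous EEG (EDF) plus an events TSV.

    Returns (signal μV: channels x samples, channel labels, rate, events).
    Channel labels are uppercased to the montage convention.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> μV
    labels = [ch.upper().replace("FP", "FP") for ch in raw.ch_names]
    return signal, labels, float(raw.info["sfreq"]), read_events(events_path)
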