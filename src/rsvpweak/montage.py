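"""62-channel 10-10 scalp montage: labels, positions, and regional groupings.

The montage is a fixed 62-label subset of the extended 10-10 system, matching
a vertex-referenced NeuroScan-style cap. Positions come from the standard
10-05 template shipped with MNE and are used for distance-based topography
weights and for plotting selection-frequency maps.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Canonical channel order, anterior to posterior, left to right.
MONTAGE_62: tuple[str, ...] = (
    "FP1", "FPz", "FP2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Parietal-lobe channels (used for the default ERP topography and for
#: checking that selection frequency concentrates parietally).
PARIETAL = tuple(c for c in MONTAGE_62 if c.startswith(("P", "CP", "PO")))


def _mne_name(label: str) -> str:
    # our labels use "FP"/"FPz"; the MNE template spells them "Fp"/"Fpz"
    return label.replace("FP", "Fp")


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """Map each montage label to its 3-D head-frame position (meters)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        # the 10-05 template montage is being renamed across MNE versions
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    out = {}
    for label in MONTAGE_62:
        out[label] = np.asarray(pos[_mne_name(label)], dtype=float)
    return out


def channel_distances(reference: str = "Pz") -> dict[str, float]:
    """Euclidean scalp distance (m) from every channel to ``reference``."""
    pos = channel_positions()
    ref = pos[reference]
    return {c: float(np.linalg.norm(p - ref)) for c, p in pos.items()}


def gaussian_topography(center: str = "Pz", width_m: float = 0.07) -> dict[str, float]:
    """Spatial weight map exp(-d^2 / 2 width^2), normalized to max 1.

    ``width_m`` is the Gaussian scale in meters on the scalp; 0.07 m spreads a
    parietal-maximal field over neighboring centro-parietal and occipital
    sites, the classic P300 topography.
    """
    d = channel_distances(center)
    w = {c: float(np.exp(-(dist**2) / (2.0 * width_m**2))) for c, dist in d.items()}
    peak = max(w.values())
    return {c: v / peak for c, v in w.items()}


def validate_channels(labels) -> None:
    unknown = [c for c in labels if c not in MONTAGE_62]
    if unknown:
        raise ValueError(f"channels not in the 62-channel montage: {unknown}")
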