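"""Stimulus-contrast conditions and their ERP calibration.

Five equal-RGB gray levels define the weak-contrast ("hidden") conditions:
the benchmark C1 is pure white (RGB 255) and each subsequent level roughly
halves the gray value (127, 63, 31, 15) on a black background. The contrast
ratio of a condition is its gray value over 255.

Each condition carries a P300 calibration — the mean single-trial amplitude
(μV) and peak latency (ms) the simulator injects for target stimuli —
together with trial-to-trial jitter SDs. Defaults reproduce the grand-average
amplitude/latency profile of an 18-subject cohort: amplitudes
8.92/8.55/8.51/8.72/7.84 μV and latencies 582/572/576/595/644 ms for C1..C5,
with the cohort standard errors (×√18) supplying the between-subject spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

CONDITION_LABELS = ("C1", "C2", "C3", "C4", "C5")

DEFAULT_RGB = (255, 127, 63, 31, 15)

#: Cohort size behind the default calibration; the quoted standard errors
#: scale to subject-level SDs by sqrt of this.
N_SUBJECTS = 18

#: label -> (amplitude mean μV, amplitude SE μV, latency mean ms, latency SE ms)
P300_CALIBRATION = {
    "C1": (8.92, 1.24, 582.39, 25.02),
    "C2": (8.55, 1.27, 572.44, 25.72),
    "C3": (8.51, 1.32, 575.83, 23.57),
    "C4": (8.72, 1.33, 595.00, 21.15),
    "C5": (7.84, 1.40, 643.83, 26.16),
}

#: Single-trial latency jitter SD (ms). Trial-to-trial P300 latency scatter
#: within a subject is far smaller than the between-subject spread; 40 ms is
#: a typical single-trial value and keeps the average-waveform peak within a
#: few percent of the injected amplitude.
TRIAL_LATENCY_SD_MS = 40.0


@dataclass(frozen=True)
class ConditionSpec:
    """One contrast condition with its injected-ERP calibration.

    ``erp_amplitude_sd`` / ``erp_latency_sd`` are per-trial jitter SDs used by
    the simulator (amplitudes truncated at 0, latencies clipped to the epoch).
    """

    label: str
    rgb_value: int
    ratio_to_benchmark: float
    erp_amplitude_mean: float
    erp_amplitude_sd: float
    erp_latency_mean: float
    erp_latency_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.rgb_value <= 255:
            raise ValueError(f"rgb_value {self.rgb_value} outside 0-255")
        if self.erp_amplitude_sd < 0 or self.erp_latency_sd < 0:
            raise ValueError("jitter SDs must be nonnegative")
        if not 0 < self.erp_latency_mean < 1000:
            raise ValueError("latency mean must lie inside the 1000 ms epoch")
        expected = round(self.rgb_value / 255, 3)
        if abs(self.ratio_to_benchmark - expected) > 1e-9:
            raise ValueError(
                f"ratio_to_benchmark {self.ratio_to_benchmark} != rgb/255 = {expected}"
            )


def contrast_ratio(rgb_value: int) -> float:
    """Gray value over the 255 benchmark, rounded to 3 decimals."""
    if not 0 <= rgb_value <= 255:
        raise ValueError(f"rgb_value {rgb_value} outside 0-255")
    return round(rgb_value / 255, 3)


def make_condition_table(rgb_values=DEFAULT_RGB) -> list[ConditionSpec]:
    """Build the five ConditionSpecs for the given gray levels.

    Values must be strictly decreasing from the benchmark. The default ERP
    calibration (see module docstring) is attached per condition.
    """
    if len(rgb_values) != len(CONDITION_LABELS):
        raise ValueError(f"expected {len(CONDITION_LABELS)} gray levels")
    if any(b >= a for a, b in zip(rgb_values, rgb_values[1:])):
        raise ValueError("gray levels must strictly decrease from the benchmark")
    specs = []
    for label, rgb in zip(CONDITION_LABELS, rgb_values):
        amp, amp_se, lat, lat_se = P300_CALIBRATION[label]
        specs.append(
            ConditionSpec(
                label=label,
                rgb_value=rgb,
                ratio_to_benchmark=contrast_ratio(rgb),
                erp_amplitude_mean=amp,
                erp_amplitude_sd=amp_se * math.sqrt(N_SUBJECTS),
                erp_latency_mean=lat,
                erp_latency_sd=TRIAL_LATENCY_SD_MS,
            )
        )
    return specs


def subject_conditions(specs, rng) -> list[ConditionSpec]:
    """Draw one subject's condition means from the cohort calibration.

    Amplitude and latency means are offset by normal draws with SD = cohort
    SE × √N_SUBJECTS (the between-subject spread the SEs measure); jitter SDs
    are kept. Amplitudes are truncated at 0 and latencies clipped to stay
    inside the 200-900 ms measurement window.
    """
    out = []
    for s in specs:
        if s.label in P300_CALIBRATION:
            _, amp_se, _, lat_se = P300_CALIBRATION[s.label]
        else:
            amp_se, lat_se = 0.0, 0.0
        amp_sd = amp_se * math.sqrt(N_SUBJECTS)
        lat_sd = lat_se * math.sqrt(N_SUBJECTS)
        amp = max(0.0, s.erp_amplitude_mean + rng.normal(0.0, amp_sd))
        lat = float(np.clip(s.erp_latency_mean + rng.normal(0.0, lat_sd), 250.0, 850.0))
        out.append(replace(s, erp_amplitude_mean=amp, erp_latency_mean=lat))
    return out
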