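"""RSVP event schedules: per-trial stimulus timelines with target flags.

A trial shows a plus-sign cue for 1 s, a 0.5 s gap, then the ten digits 0-9
in pseudo-random order, each on screen for 200 ms with no inter-stimulus
interval. Exactly one digit per trial is the pre-instructed target. A session
interleaves 150 trials — 30 per contrast condition — in random order; the
full design is 10 sessions, i.e. 300 target and 2700 non-target stimuli per
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import ConditionSpec

CUE_MS = 1000
GAP_MS = 500
STIM_MS = 200
N_STIM = 10
TRIALS_PER_CONDITION = 30

#: Pause between the end of a trial's stimulus stream and the next trial's
#: cue. Not part of the stimulus timing proper; long enough that the last
#: 1000 ms epoch of a trial never runs past the recording.
DEFAULT_ITI_MS = 1000

#: Active stimulus span of one trial (cue onset to last stimulus offset).
TRIAL_SPAN_MS = CUE_MS + GAP_MS + N_STIM * STIM_MS


@dataclass(frozen=True)
class TrialEvents:
    """One trial: condition, absolute stimulus onsets, digit order, target."""

    condition: str
    stimulus_onsets: tuple[int, ...]  # ms from recording start
    stimulus_identities: tuple[int, ...]  # permutation of 0-9
    target_digit: int
    target_position: int  # 1-based index into the stream

    def __post_init__(self) -> None:
        if sorted(self.stimulus_identities) != list(range(N_STIM)):
            raise ValueError("stimulus_identities must be a permutation of 0-9")
        diffs = np.diff(self.stimulus_onsets)
        if len(self.stimulus_onsets) != N_STIM or not np.all(diffs == STIM_MS):
            raise ValueError("onsets must be 10 contiguous 200 ms steps")
        if self.stimulus_identities[self.target_position - 1] != self.target_digit:
            raise ValueError("target_position does not index target_digit")


@dataclass(frozen=True)
class EventSchedule:
    """All trials of one session, in presentation order."""

    session_index: int  # 1-based
    trials: tuple[TrialEvents, ...] = field(default_factory=tuple)

    @property
    def duration_ms(self) -> int:
        last = self.trials[-1].stimulus_onsets[-1]
        return last + STIM_MS + DEFAULT_ITI_MS


def generate_schedule(
    conditions: list[ConditionSpec],
    n_sessions: int = 10,
    seed: int = 0,
    iti_ms: int = DEFAULT_ITI_MS,
    trials_per_condition: int = TRIALS_PER_CONDITION,
) -> list[EventSchedule]:
    """Generate seeded session schedules for the full factorial design.

    Each session holds ``trials_per_condition`` trials of every condition in
    a uniformly shuffled order; digit order and target are drawn per trial.
    Deterministic for a given seed.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    sessions = []
    for s in range(1, n_sessions + 1):
        order = np.repeat([c.label for c in conditions], trials_per_condition)
        rng.shuffle(order)
        trials = []
        t0 = 0
        for label in order:
            digits = tuple(int(d) for d in rng.permutation(N_STIM))
            pos = int(rng.integers(1, N_STIM + 1))
            first = t0 + CUE_MS + GAP_MS
            onsets = tuple(first + i * STIM_MS for i in range(N_STIM))
            trials.append(
                TrialEvents(
                    condition=str(label),
                    stimulus_onsets=onsets,
                    stimulus_identities=digits,
                    target_digit=digits[pos - 1],
                    target_position=pos,
                )
            )
            t0 += TRIAL_SPAN_MS + iti_ms
        sessions.append(EventSchedule(session_index=s, trials=tuple(trials)))
    return sessions


def schedule_to_events(schedules: list[EventSchedule]) -> pd.DataFrame:
    """Flatten schedules to a long events table (one row per stimulus).

    Columns: onset_ms, duration_ms, digit, is_target, condition, session,
    trial — the on-disk TSV layout.
    """
    rows = []
    for sched in schedules:
        for k, tr in enumerate(sched.trials, start=1):
            for i, (onset, digit) in enumerate(
                zip(tr.stimulus_onsets, tr.stimulus_identities), start=1
            ):
                rows.append(
                    (onset, STIM_MS, digit, i == tr.target_position,
                     tr.condition, sched.session_index, k)
                )
    return pd.DataFrame(
        rows,
        columns=["onset_ms", "duration_ms", "digit", "is_target",
                 "condition", "session", "trial"],
    )
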