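"""Simulate the RSVP cohort and write the event schedules.

Generates the study design — sessions of 150 trials, 30 per contrast
condition, one target digit per trial — for a small simulated cohort and
writes the per-subject events tables. The continuous EEG itself is
regenerated on demand by the later stages (it is cheap to recompute and
expensive to store); this stage records the design and the per-subject
seeds so every later stage sees identical data.

Run from the repository root:  python analysis/01_simulate.py [--subjects N]
"""

import argparse
import json
from pathlib import Path

from rsvpweak import io as rio
from rsvpweak.conditions import make_condition_table
from rsvpweak.pipeline import subject_seed
from rsvpweak.schedule import generate_schedule, schedule_to_events

# Cohort scale for the desk-top analysis: 6 simulated subjects x 2 sessions
# keeps every later stage within minutes while preserving the trial
# structure; the full design (18 x 10) is a flag away.
DEF_SUBJECTS, DEF_SESSIONS, DEF_SEED = 6, 2, 0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--subjects", type=int, default=DEF_SUBJECTS)
    ap.add_argument("--sessions", type=int, default=DEF_SESSIONS)
    ap.add_argument("--seed", type=int, default=DEF_SEED)
    ap.add_argument("--out", default="results/design")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    conds = make_condition_table()
    manifest = {"seed": args.seed, "n_subjects": args.subjects,
                "n_sessions": args.sessions, "subject_seeds": {}}
    for subj in range(1, args.subjects + 1):
        s_seed = subject_seed(args.seed, subj)
        manifest["subject_seeds"][subj] = s_seed
        schedules = generate_schedule(conds, args.sessions, seed=s_seed)
        events = schedule_to_events(schedules)
        rio.write_events(events, out / f"subject{subj:02d}_events.tsv")
        targets = events.groupby("condition").is_target.sum().to_dict()
        print(f"subject {subj:2d}: {len(events):5d} stimulus events, "
              f"targets/condition {targets}")
    (out / "design.json").write_text(json.dumps(manifest, indent=2))
    print(f"design written to {out}/ "
          f"({args.subjects} subjects x {args.sessions} sessions)")


if __name__ == "__main__":
    main()
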