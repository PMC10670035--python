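"""P300 amplitude/latency per subject and condition, with benchmark tests.

Simulates each subject of the cohort (seeds from results/design/design.json),
preprocesses (0.3-20 Hz, epoch 0-1000 ms, decimate to 125 Hz), measures the
P300 of the target average at the topography peak channel as the maximum in
200-900 ms, and writes a condition-level summary with paired t-tests of
every condition against the C1 benchmark.

Run after 01_simulate.py:  python analysis/02_erp_stats.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rsvpweak.conditions import make_condition_table, subject_conditions
from rsvpweak.erp import erp_summary_table
from rsvpweak.pipeline import erp_features_by_condition, subject_epochs
from rsvpweak.simulate import SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--design", default="results/design/design.json")
    ap.add_argument("--out", default="results/erp")
    args = ap.parse_args()

    design = json.loads(Path(args.design).read_text())
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    base = make_condition_table()
    rows = []
    for subj, s_seed in design["subject_seeds"].items():
        rng = np.random.default_rng(s_seed)
        conds = subject_conditions(base, rng)
        cfg = SimulationConfig(seed=s_seed, n_sessions=design["n_sessions"],
                               conditions=conds)
        epochs = subject_epochs(cfg)
        feats = erp_features_by_condition(epochs, cfg.peak_channel())
        for cond, (amp, lat) in sorted(feats.items()):
            rows.append({"subject": int(subj), "condition": cond,
                         "amplitude": amp, "latency": lat})
            print(f"subject {subj}: {cond} amplitude {amp:5.2f} μV, "
                  f"latency {lat:5.0f} ms")

    per_subject = pd.DataFrame(rows)
    per_subject.to_csv(out / "p300_per_subject.tsv", sep="\t", index=False)
    summary = erp_summary_table(per_subject)
    summary.to_csv(out / "p300_summary.tsv", sep="\t", index=False)
    print("\ncondition-level summary (mean ± SE, paired t vs C1):")
    for r in summary.itertuples(index=False):
        print(f"  {r.condition}: {r.amplitude_mean:5.2f} ± {r.amplitude_se:4.2f} μV"
              f" {r.amplitude_stars:3s} | {r.latency_mean:6.1f} ±"
              f" {r.latency_se:5.1f} ms {r.latency_stars}")


if __name__ == "__main__":
    main()
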