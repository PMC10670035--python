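"""Floating-forward channel selection per subject and condition.

For every subject x condition, selects 6 of the 62 channels by SFFS under
the bias-corrected, PCA-compressed Fisher criterion (on a balanced epoch
subsample), then aggregates how often each montage channel was chosen and
renders the selection-frequency scalp map. On the planted parietal-maximal
topography the counts concentrate over parietal sites.

Run after 01_simulate.py:  python analysis/03_channel_selection.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rsvpweak import io as rio
from rsvpweak.channels import selection_frequency, sffs_select
from rsvpweak.conditions import make_condition_table, subject_conditions
from rsvpweak.pipeline import balanced_subsample, subject_epochs
from rsvpweak.plots import plot_selection_map
from rsvpweak.simulate import SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--design", default="results/design/design.json")
    ap.add_argument("--out", default="results/selection")
    ap.add_argument("--per-class", type=int, default=200,
                    help="balanced epochs per class fed to the criterion")
    args = ap.parse_args()

    design = json.loads(Path(args.design).read_text())
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    base = make_condition_table()
    subsets = []
    rows = []
    for subj, s_seed in design["subject_seeds"].items():
        rng = np.random.default_rng(s_seed)
        conds = subject_conditions(base, rng)
        cfg = SimulationConfig(seed=s_seed, n_sessions=design["n_sessions"],
                               conditions=conds)
        epochs = subject_epochs(cfg)
        for cond in sorted({str(c) for c in epochs.condition}):
            sub = epochs.where(epochs.condition.astype(str) == cond)
            small = balanced_subsample(sub, args.per_class, rng)
            chosen = sffs_select(small, k=6)
            subsets.append(chosen)
            rio.write_subset(chosen, out / f"subject{int(subj):02d}_{cond}.json")
            rows.append({"subject": int(subj), "condition": cond,
                         "channels": " ".join(chosen.channels),
                         "score": chosen.score})
            print(f"subject {subj} {cond}: {', '.join(chosen.channels)} "
                  f"(score {chosen.score:.3g})")

    pd.DataFrame(rows).to_csv(out / "selected_sets.tsv", sep="\t", index=False)
    counts = selection_frequency(subsets)
    pd.DataFrame(sorted(counts.items()), columns=["channel", "count"]).to_csv(
        out / "selection_frequency.tsv", sep="\t", index=False)
    ax = plot_selection_map(counts)
    ax.figure.savefig(out / "selection_map.png", dpi=150, bbox_inches="tight")
    top = sorted(counts.items(), key=lambda kv: -kv[1])[:8]
    print("\nmost-selected channels:", ", ".join(f"{c} ({n})" for c, n in top))


if __name__ == "__main__":
    main()
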