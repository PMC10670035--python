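"""Cross-validated decoding and information transfer rate by channel set.

Decodes target vs non-target epochs per subject x condition with LDA and
RBF-SVM under repeated stratified 6-fold cross-validation, across the fixed
channel sets and the subject's selected 6-channel set (from stage 03), and
converts accuracies to information transfer rates (10 commands, one 2 s
stimulus stream per command). Writes long-format fold results and the
set x condition summary tables.

Run after 03_channel_selection.py:  python analysis/04_decode.py
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rsvpweak import io as rio
from rsvpweak.channels import fixed_sets
from rsvpweak.conditions import make_condition_table, subject_conditions
from rsvpweak.decode import cross_validate, itr
from rsvpweak.pipeline import subject_epochs
from rsvpweak.simulate import SimulationConfig

DEFAULT_SETS = ("1", "4", "5", "6")  # all, midline, classic 8, selected


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--design", default="results/design/design.json")
    ap.add_argument("--selection", default="results/selection")
    ap.add_argument("--sets", nargs="*", default=list(DEFAULT_SETS))
    ap.add_argument("--classifiers", nargs="*", default=["lda", "svm"])
    ap.add_argument("--reps", type=int, default=10)
    ap.add_argument("--out", default="results/decode")
    args = ap.parse_args()

    design = json.loads(Path(args.design).read_text())
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    base = make_condition_table()
    fixed = {s.name: s for s in fixed_sets()}
    rows = []
    for subj, s_seed in design["subject_seeds"].items():
        rng = np.random.default_rng(s_seed)
        conds = subject_conditions(base, rng)
        cfg = SimulationConfig(seed=s_seed, n_sessions=design["n_sessions"],
                               conditions=conds)
        epochs = subject_epochs(cfg)
        for cond in sorted({str(c) for c in epochs.condition}):
            sub = epochs.where(epochs.condition.astype(str) == cond)
            for name in args.sets:
                if name == "6":
                    path = Path(args.selection) / f"subject{int(subj):02d}_{cond}.json"
                    if not path.exists():
                        continue
                    cset = rio.read_subset(path)
                else:
                    cset = fixed[name]
                for clf in args.classifiers:
                    res = cross_validate(sub, cset, classifier=clf,
                                         reps=args.reps, seed=s_seed,
                                         condition=cond)
                    bits = itr(res.mean / 100.0)
                    rows.append({"subject": int(subj), "condition": cond,
                                 "set": name, "classifier": clf,
                                 "accuracy": res.mean, "stderr": res.stderr,
                                 "itr": bits})
                    print(f"subject {subj} {cond} set{name} {clf}: "
                          f"{res.mean:5.2f} ± {res.stderr:4.2f} %  "
                          f"ITR {bits:5.2f} bits/min")

    long = pd.DataFrame(rows)
    long.to_csv(out / "decode_long.tsv", sep="\t", index=False)
    for value in ("accuracy", "itr"):
        table = long.pivot_table(index="set", columns=["classifier", "condition"],
                                 values=value)
        table.to_csv(out / f"{value}_table.tsv", sep="\t")
    print("\nmean accuracy by set and condition (LDA):")
    print(long[long.classifier == "lda"].pivot_table(
        index="set", columns="condition", values="accuracy").round(2).to_string())


if __name__ == "__main__":
    main()
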