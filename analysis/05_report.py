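"""Assemble the summary figures and a compact findings report.

Reads the tables written by stages 02-04 and produces: the ERP summary with
significance stars, accuracy/ITR violin figures for the full montage versus
the selected 6-channel set, and a plain-text recap of the headline
quantities (benchmark-vs-weakest amplitude and accuracy changes, channel
reduction).

Run last:  python analysis/05_report.py
"""

import argparse
from pathlib import Path

import pandas as pd

from rsvpweak.plots import plot_accuracy_violin


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--erp", default="results/erp")
    ap.add_argument("--decode", default="results/decode")
    ap.add_argument("--out", default="results/report")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    lines = []

    summary_path = Path(args.erp) / "p300_summary.tsv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path, sep="\t")
        lines.append("P300 by condition (mean ± SE, stars vs C1):")
        for r in summary.itertuples(index=False):
            stars = r.amplitude_stars if isinstance(r.amplitude_stars, str) else ""
            lines.append(f"  {r.condition}: {r.amplitude_mean:.2f} ± "
                         f"{r.amplitude_se:.2f} μV {stars}")
        c1 = summary[summary.condition == "C1"].iloc[0]
        c5 = summary[summary.condition == "C5"].iloc[0]
        lines.append(f"benchmark vs weakest amplitude: {c1.amplitude_mean:.2f}"
                     f" -> {c5.amplitude_mean:.2f} μV")

    decode_path = Path(args.decode) / "decode_long.tsv"
    if decode_path.exists():
        long = pd.read_csv(decode_path, sep="\t")
        long["set"] = long["set"].astype(str)
        for value in ("accuracy", "itr"):
            both = long[long.set.isin(["1", "6"])]
            if len(both):
                ax = plot_accuracy_violin(both, value=value)
                ax.figure.savefig(out / f"{value}_violin.png", dpi=150,
                                  bbox_inches="tight")
        by_set = long[long.classifier == "lda"].groupby("set").accuracy.mean()
        if {"1", "6"} <= set(by_set.index):
            lines.append(
                f"mean LDA accuracy, 62 channels vs selected 6: "
                f"{by_set.loc['1']:.2f}% vs {by_set.loc['6']:.2f}% "
                f"(90.3% channel reduction)")

    report = "\n".join(lines) if lines else "no stage outputs found"
    (out / "report.txt").write_text(report + "\n")
    print(report)


if __name__ == "__main__":
    main()
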