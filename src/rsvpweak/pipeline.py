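"""End-to-end orchestration: simulate -> preprocess -> ERP -> select -> decode.

One ``run`` simulates a cohort of subjects (independent seeds derived from
the base seed; condition means offset per subject by the between-subject
calibration spread), pushes every subject through preprocessing, ERP
statistics, floating channel selection, and cross-validated decoding, and
writes condition-by-channel-set summary tables, a selection-frequency table,
and a JSON manifest capturing the configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .channels import ChannelSubset, fixed_sets, selection_frequency, sffs_select
from .conditions import make_condition_table, subject_conditions
from .decode import CV_FOLDS, CV_REPS, ITR_COMMANDS, ITR_PERIOD_S, cross_validate, itr
from .erp import P300_WINDOW, average_erp, erp_summary_table, p300_features
from .montage import MONTAGE_62
from .preprocess import DEFAULT_BAND, DEFAULT_FACTOR, EpochSet, preprocess_recording
from .schedule import generate_schedule, schedule_to_events
from .simulate import RawRecording, SimulationConfig, simulate_session

log = logging.getLogger("rsvpweak")


@dataclass
class RunConfig:
    """Everything one reproducible run needs (see module docstring)."""

    seed: int = 0
    n_subjects: int = 3
    n_sessions: int = 10
    channels: tuple[str, ...] = MONTAGE_62
    noise_sd: float = 15.0
    pink_exponent: float = 1.0
    band: tuple[float, float] = DEFAULT_BAND
    downsample_factor: int = DEFAULT_FACTOR
    window: tuple[float, float] = P300_WINDOW
    erp_channel: str | None = None  # None -> topography peak channel
    between_subject_variability: bool = True
    select_k: int = 6
    select_per_class: int = 200
    channel_sets: tuple[str, ...] = ("1", "2", "3", "4", "5", "6")
    classifiers: tuple[str, ...] = ("lda", "svm")
    cv_reps: int = CV_REPS
    cv_folds: int = CV_FOLDS
    itr_commands: int = ITR_COMMANDS
    itr_period_s: float = ITR_PERIOD_S
    run_erp: bool = True
    run_selection: bool = True
    run_decoding: bool = True
    make_figures: bool = False
    output_dir: str = "results/run"


def subject_seed(base_seed: int, subject: int) -> int:
    """Stable per-subject seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{subject}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def subject_epochs(sim_cfg: SimulationConfig,
                   band=DEFAULT_BAND, factor: int = DEFAULT_FACTOR) -> EpochSet:
    """Simulate one subject's sessions and return preprocessed epochs.

    Sessions are simulated, filtered, segmented, and decimated one at a time
    to bound memory, then concatenated.
    """
    schedules = generate_schedule(
        sim_cfg.conditions, sim_cfg.n_sessions, seed=sim_cfg.seed,
        iti_ms=sim_cfg.iti_ms,
    )
    rng = np.random.default_rng(np.random.SeedSequence([sim_cfg.seed, 202]))
    parts = []
    for sched in schedules:
        sig = simulate_session(sim_cfg, sched, rng)
        rec = RawRecording(tuple(sim_cfg.channels), sim_cfg.sampling_rate,
                           sig, [sched])
        events = schedule_to_events([sched])
        parts.append(preprocess_recording(rec, events, band=band, factor=factor))
    first = parts[0]
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        condition=np.concatenate([p.condition for p in parts]),
        rate=first.rate,
        channels=first.channels,
    )


def erp_features_by_condition(epochs: EpochSet, channel: str,
                              window=P300_WINDOW) -> dict[str, tuple[float, float]]:
    """(amplitude, latency) of the target average per condition at one channel."""
    out = {}
    for cond in np.unique(epochs.condition.astype(str)):
        sub = epochs.where(epochs.condition.astype(str) == cond)
        wave = average_erp(sub, "target", channel)
        out[cond] = p300_features(wave, window)
    return out


def balanced_subsample(epochs: EpochSet, per_class: int, rng) -> EpochSet:
    """Seeded 1:1 subsample of targets and non-targets (for selection)."""
    t_idx = np.flatnonzero(epochs.labels)
    n_idx = np.flatnonzero(~epochs.labels)
    keep = min(per_class, len(t_idx), len(n_idx))
    sel = np.concatenate([rng.choice(t_idx, keep, replace=False),
                          rng.choice(n_idx, keep, replace=False)])
    return epochs.where(np.isin(np.arange(len(epochs.labels)), sel))


@dataclass
class RunReport:
    """All tables a run produced plus its manifest."""

    erp_table: pd.DataFrame | None
    accuracy_table: pd.DataFrame | None
    itr_table: pd.DataFrame | None
    selection_counts: dict[str, int] | None
    selected_sets: list[ChannelSubset] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(cfg: RunConfig) -> RunReport:
    """Execute the full analysis for a simulated cohort and write outputs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_conditions = make_condition_table()
    erp_rows, acc_rows, itr_rows = [], [], []
    selected: list[ChannelSubset] = []
    fixed = {s.name: s for s in fixed_sets()}

    for subj in range(1, cfg.n_subjects + 1):
        s_seed = subject_seed(cfg.seed, subj)
        rng = np.random.default_rng(s_seed)
        conds = (subject_conditions(base_conditions, rng)
                 if cfg.between_subject_variability else base_conditions)
        sim_cfg = SimulationConfig(
            seed=s_seed, n_sessions=cfg.n_sessions, conditions=conds,
            channels=cfg.channels, noise_sd=cfg.noise_sd,
            pink_exponent=cfg.pink_exponent,
        )
        epochs = subject_epochs(sim_cfg, band=cfg.band,
                                factor=cfg.downsample_factor)
        log.info("subject %d: %d epochs (%d targets)", subj,
                 len(epochs.labels), int(epochs.labels.sum()))

        channel = cfg.erp_channel or sim_cfg.peak_channel()
        if cfg.run_erp:
            for cond, (amp, lat) in erp_features_by_condition(
                    epochs, channel, cfg.window).items():
                erp_rows.append({"subject": subj, "condition": cond,
                                 "amplitude": amp, "latency": lat})

        fixed_used: dict[str, ChannelSubset] = {
            name: fixed[name] for name in cfg.channel_sets if name in fixed
        }
        set6_by_cond: dict[str, ChannelSubset] = {}
        if cfg.run_selection and "6" in cfg.channel_sets:
            for cond in sorted({str(c) for c in epochs.condition}):
                sub = epochs.where(epochs.condition.astype(str) == cond)
                small = balanced_subsample(sub, cfg.select_per_class, rng)
                chosen = sffs_select(small, k=cfg.select_k)
                selected.append(chosen)
                set6_by_cond[cond] = chosen
                log.info("subject %d %s: selected %s (score %.3g)",
                         subj, cond, chosen.channels, chosen.score)

        if cfg.run_decoding:
            for cond in sorted({str(c) for c in epochs.condition}):
                sub = epochs.where(epochs.condition.astype(str) == cond)
                sets_here = dict(fixed_used)
                if cond in set6_by_cond:
                    sets_here["6"] = set6_by_cond[cond]
                for set_name, cset in sets_here.items():
                    for clf in cfg.classifiers:
                        res = cross_validate(
                            sub, cset, classifier=clf, reps=cfg.cv_reps,
                            folds=cfg.cv_folds, seed=s_seed, condition=cond,
                        )
                        acc_rows.append({
                            "subject": subj, "condition": cond,
                            "set": set_name, "classifier": clf,
                            "accuracy": res.mean, "stderr": res.stderr,
                        })
                        itr_rows.append({
                            "subject": subj, "condition": cond,
                            "set": set_name, "classifier": clf,
                            "itr": itr(res.mean / 100.0, cfg.itr_commands,
                                       cfg.itr_period_s),
                        })

    erp_table = acc_table = itr_table = None
    counts = None
    if erp_rows:
        per_subject = pd.DataFrame(erp_rows)
        erp_table = erp_summary_table(per_subject)
        per_subject.to_csv(out / "erp_per_subject.tsv", sep="\t", index=False)
        erp_table.to_csv(out / "erp_summary.tsv", sep="\t", index=False)
    if selected:
        counts = selection_frequency(selected)
        pd.DataFrame(sorted(counts.items()), columns=["channel", "count"]).to_csv(
            out / "selection_frequency.tsv", sep="\t", index=False)
    if acc_rows:
        acc_long = pd.DataFrame(acc_rows)
        acc_long.to_csv(out / "accuracy_long.tsv", sep="\t", index=False)
        acc_table = acc_long.pivot_table(index="set", columns=["classifier", "condition"],
                                         values="accuracy")
        acc_table.to_csv(out / "accuracy_table.tsv", sep="\t")
        itr_long = pd.DataFrame(itr_rows)
        itr_long.to_csv(out / "itr_long.tsv", sep="\t", index=False)
        itr_table = itr_long.pivot_table(index="set", columns=["classifier", "condition"],
                                         values="itr")
        itr_table.to_csv(out / "itr_table.tsv", sep="\t")

    if cfg.make_figures:
        from .plots import plot_accuracy_violin, plot_selection_map

        if counts is not None:
            ax = plot_selection_map(counts)
            ax.figure.savefig(out / "selection_map.png", dpi=150,
                              bbox_inches="tight")
        if acc_rows:
            ax = plot_accuracy_violin(pd.DataFrame(acc_rows))
            ax.figure.savefig(out / "accuracy_violin.png", dpi=150,
                              bbox_inches="tight")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "subject_seeds": [subject_seed(cfg.seed, s)
                          for s in range(1, cfg.n_subjects + 1)],
        "n_selected_sets": len(selected),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunReport(erp_table=erp_table, accuracy_table=acc_table,
                     itr_table=itr_table, selection_counts=counts,
                     selected_sets=selected, manifest=manifest)


def make_fixtures(size: str = "tiny", seed: int = 0, out_dir=None):
    """Miniature simulated recordings + events for tests and demos.

    tiny: 1 session, 8 midline-ish channels; small: 2 sessions, full montage.
    Returns (recordings, events) and optionally writes the events TSV.
    """
    if size == "tiny":
        channels = ("Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz", "P3")
        n_sessions = 1
    elif size == "small":
        channels = MONTAGE_62
        n_sessions = 2
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    cfg = SimulationConfig(seed=seed, n_sessions=n_sessions, channels=channels)
    schedules = generate_schedule(cfg.conditions, n_sessions, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    recs = [RawRecording(tuple(channels), cfg.sampling_rate,
                         simulate_session(cfg, s, rng), [s])
            for s in schedules]
    events = schedule_to_events(schedules)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rio.write_events(events, out_dir / "events.tsv")
    return recs, events
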