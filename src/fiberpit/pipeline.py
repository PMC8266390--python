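"""End-to-end orchestration: simulate -> preprocess -> quantify -> score -> test.

``run_experiment`` simulates a full cohort (Pavlovian conditioning with
optional photometry, instrumental training, and the PIT test), runs
preprocessing and QC on every recording, quantifies peri-event responses,
scores the behavior, runs the group statistics, and writes tidy TSV
tables plus a JSON run manifest.  Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, events, preprocess, simulate, stats
from .config import AnalysisConfig, SimConfig
from .core import LEVER_IDS
from .io import write_event_log, write_recording, write_schedule

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, files, QC outcomes."""

    config: dict
    seed: int
    subject_files: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "subject_files": self.subject_files,
            "qc": self.qc,
            "outputs": sorted(self.outputs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _subject_rngs(seed: int, n_subjects: int, streams_per_subject: int = 16):
    """Deterministic per-subject child generators from one master seed."""
    root = np.random.SeedSequence(seed)
    return [
        [np.random.default_rng(child) for child in ss.spawn(streams_per_subject)]
        for ss in root.spawn(n_subjects)
    ]


def run_experiment(
    sim_cfg: SimConfig,
    analysis_cfg: AnalysisConfig,
    out_dir,
    seed: int | None = None,
    photometry: bool = True,
    write_raw: bool = True,
) -> RunManifest:
    """Simulate and analyze a full cohort; write tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw_dir = out / "raw"
    if write_raw:
        raw_dir.mkdir(exist_ok=True)
    seed = sim_cfg.seed if seed is None else seed

    manifest = RunManifest(
        config={**dataclasses.asdict(sim_cfg), **dataclasses.asdict(analysis_cfg)},
        seed=seed,
    )
    rngs = _subject_rngs(seed, sim_cfg.n_subjects)

    photo_rows, elev_rows, pit_rows, press_rows = [], [], [], []
    for subj in range(sim_cfg.n_subjects):
        contingency = simulate.make_contingency(subj)
        subj_id = f"s{subj:02d}"
        files = []
        streams = iter(rngs[subj])

        # --- Pavlovian conditioning ---
        for session in range(1, sim_cfg.n_conditioning_sessions + 1):
            rng = next(streams)
            schedule = simulate.generate_conditioning_session(
                sim_cfg, contingency, session, rng
            )
            log = simulate.simulate_behavior(schedule, sim_cfg, contingency, rng)
            if write_raw:
                for obj, writer, name in (
                    (schedule, write_schedule, "schedule"),
                    (log, write_event_log, "events"),
                ):
                    path = raw_dir / f"{subj_id}_cond{session}_{name}.tsv"
                    writer(obj, path)
                    files.append(str(path.relative_to(out)))

            per_trial, ratio = behavior.pavlovian_elevation(schedule, log)
            elev_rows.append(
                {"subject": subj_id, "session": session, "measure":
                 "elevation_ratio", "value": ratio}
            )

            if photometry:
                rec = simulate.simulate_photometry(schedule, log, sim_cfg, rng)
                if write_raw:
                    path = raw_dir / f"{subj_id}_cond{session}_photometry.csv"
                    write_recording(rec, path)
                    files.append(str(path.relative_to(out)))
                trace = preprocess.preprocess_recording(rec)
                report = preprocess.qc_session(
                    trace,
                    analysis_cfg.qc_min_r2,
                    analysis_cfg.qc_min_transient_rate_per_min,
                )
                manifest.qc[f"{subj_id}_cond{session}"] = {
                    "passed": report.passed,
                    "reasons": report.reasons,
                    "r_squared": round(report.r_squared, 6),
                    "transient_rate_per_min": round(
                        report.transient_rate_per_min, 6
                    ),
                }
                if not report.passed:
                    logger.warning(
                        "QC excluded %s session %d: %s",
                        subj_id, session, ",".join(report.reasons),
                    )
                    continue
                derived = events.derive_events(schedule, log)
                aligned = {
                    "cs_onset": derived.cs_onsets,
                    "retrieval": _retrievals_by_cs(schedule, derived),
                }
                for kind, times_by_cs in aligned.items():
                    tables = {}
                    for cs_id, times in times_by_cs.items():
                        tensor = events.extract_peri_event(
                            trace,
                            times,
                            analysis_cfg.window_pre_s,
                            analysis_cfg.window_post_s,
                            event_kind=kind,
                        )
                        if tensor.n_trials:
                            tables[cs_id] = events.quantify_trial(tensor)
                    if not tables:
                        continue
                    summary = events.average_trials(tables)
                    for measure, value in summary.items():
                        photo_rows.append(
                            {
                                "subject": subj_id,
                                "session": session,
                                "event_kind": kind,
                                "measure": measure,
                                "value": value,
                            }
                        )

        # --- instrumental training (final-day press rates) ---
        rng = next(streams)
        for lever in LEVER_IDS:
            log = simulate.generate_instrumental_session(
                sim_cfg, contingency, lever, sim_cfg.press_rate_base_per_min, rng
            )
            presses = log.times("lever_press", lever)
            press_rows.append(
                {
                    "subject": subj_id,
                    "lever": lever,
                    "measure": "press_rate_per_min",
                    "value": len(presses) / (log.end_s / 60.0),
                }
            )

        # --- PIT test ---
        rng = next(streams)
        pit_schedule = simulate.generate_pit_session(sim_cfg, rng)
        pit_log = simulate.simulate_behavior(pit_schedule, sim_cfg, contingency, rng)
        if write_raw:
            path = raw_dir / f"{subj_id}_pit_events.tsv"
            write_event_log(pit_log, path)
            files.append(str(path.relative_to(out)))
        result = behavior.pit_lever_scores(pit_schedule, pit_log, contingency)
        for name, score in (
            ("same_ratio", result.same_ratio),
            ("different_ratio", result.different_ratio),
            ("foodport_ratio", result.foodport_ratio),
        ):
            pit_rows.append(
                {"subject": subj_id, "measure": name, "value": score.ratio}
            )

        manifest.subject_files[subj_id] = files

    # --- group statistics ---
    stat_rows = []
    elev = pd.DataFrame(elev_rows)
    wide = elev.pivot_table(index="subject", columns="session", values="value")
    if wide.shape[1] >= 2 and not wide.isna().any().any():
        res = stats.rm_anova(wide.to_numpy())
        stat_rows.append(
            {"test": "rm_anova_elevation_across_sessions", "effect": res.effect_name,
             "statistic": res.F, "df_num": res.df_num, "df_den": res.df_den,
             "epsilon_gg": res.epsilon_gg, "p": res.p_gg}
        )
    pit = pd.DataFrame(pit_rows)
    same = pit.loc[pit["measure"] == "same_ratio", "value"].to_numpy()
    diff = pit.loc[pit["measure"] == "different_ratio", "value"].to_numpy()
    mask = ~(np.isnan(same) | np.isnan(diff))
    if mask.sum() >= 2 and np.var(same[mask] - diff[mask]) > 0:
        res_t = stats.paired_t(same[mask], diff[mask])
        stat_rows.append(
            {"test": "paired_t_same_vs_different", "effect": "lever",
             "statistic": res_t.statistic, "df_num": res_t.df, "df_den": res_t.df,
             "epsilon_gg": 1.0, "p": res_t.p}
        )

    tables = {
        "elevation_ratios.tsv": elev,
        "pit_scores.tsv": pit,
        "press_rates.tsv": pd.DataFrame(press_rows),
        "group_stats.tsv": pd.DataFrame(stat_rows),
    }
    if photo_rows:
        photo = pd.DataFrame(photo_rows)
        tables["photometry_summaries.tsv"] = photo
        if sim_cfg.n_conditioning_sessions == 8:
            tables["binned_summaries.tsv"] = _binned_table(photo, manifest)
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        manifest.outputs.append(name)
    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def _retrievals_by_cs(schedule, derived) -> dict:
    """Retrieval times grouped by the cue of the trial they occurred in."""
    by_cs: dict = {}
    for t_retr, _delivery, trial_idx in derived.reward_retrievals:
        cs = schedule.trials[trial_idx].cs_id
        by_cs.setdefault(cs, []).append(t_retr)
    return by_cs


def _binned_table(photo: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    """Two-session-bin summaries per event kind, with exclusion logging."""
    frames = []
    for kind, sub in photo.groupby("event_kind"):
        wide = sub.pivot_table(
            index=["subject", "session"], columns="measure", values="value"
        ).reset_index()
        summary = events.bin_sessions(wide)
        table = summary.table.copy()
        table.insert(1, "event_kind", kind)
        frames.append(table)
        if summary.excluded_subjects:
            manifest.qc[f"binning_excluded_{kind}"] = summary.excluded_subjects
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
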