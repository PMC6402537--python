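"""Pipeline orchestration: simulate -> analyze -> report.

Everything is driven by a YAML config; per-subject results are written as
CSV files plus a JSON summary.  Subjects are analyzed independently and
never pooled or averaged.  Every exclusion (neuron, pair, trial, session)
is surfaced through module loggers; session-level failures are isolated
and recorded, and the pipeline continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_mod
from . import session_io
from .core import PLACEBO, SessionRecord, SessionSpec
from .correlations import (
    correlation_structure,
    noise_correlations,
    sign_split_summary,
)
from .decoding import decode_epoch, percent_change_from_flanking, permutation_null
from .neuron_metrics import dose_effect_scan, metrics_table
from .preprocessing import CANONICAL_EPOCHS, extract_counts
from .selectivity import session_selectivity
from .synthetic import (
    BehaviorModel,
    DoseEffectSpec,
    SubjectConfig,
    build_schedule,
    flanking_placebo_indices,
    session_rng,
    simulate_session,
    tuned_ensemble,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    subjects: List[SubjectConfig]
    behavior: BehaviorModel
    dose_effect: DoseEffectSpec
    master_seed: int = 0
    n_neurons: int = 48
    latent_sd: float = 0.2
    selectivity_alpha: float = 0.01
    alpha: float = 0.05
    folds: int = 5
    n_perm: int = 1000
    run_permutation_null: bool = False
    fano_convention: str = "cv"
    n_trials_override: Optional[int] = None
    decode_c: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            subjects = [SubjectConfig(**s) for s in raw["subjects"]]
            behavior = BehaviorModel(**raw.get("behavior", {}))
            dose_effect = DoseEffectSpec(**raw.get("dose_effect", {}))
            analysis = raw.get("analysis", {})
            return cls(
                subjects=subjects,
                behavior=behavior,
                dose_effect=dose_effect,
                master_seed=int(raw.get("master_seed", 0)),
                n_neurons=int(raw.get("ensemble", {}).get("n_neurons", 48)),
                latent_sd=float(raw.get("ensemble", {}).get("latent_sd", 0.2)),
                selectivity_alpha=float(analysis.get("selectivity_alpha", 0.01)),
                alpha=float(analysis.get("alpha", 0.05)),
                folds=int(analysis.get("folds", 5)),
                n_perm=int(analysis.get("n_perm", 1000)),
                run_permutation_null=bool(analysis.get("run_permutation_null", False)),
                fano_convention=str(analysis.get("fano_convention", "cv")),
                n_trials_override=analysis.get("n_trials_override"),
                decode_c=float(analysis.get("decode_c", 1.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_to_dir(config: PipelineConfig, out_dir) -> List[Path]:
    """Simulate every subject's schedule and write session directories."""
    out_dir = Path(out_dir)
    written = []
    for subject in config.subjects:
        schedule = build_schedule(subject)
        ens_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, hash(subject.subject_id) % (2**31)])
        )
        ensemble = tuned_ensemble(config.n_neurons, ens_rng, latent_sd=config.latent_sd)
        for spec in schedule:
            record = simulate_session(
                spec, ensemble, config.behavior, config.dose_effect,
                seed=session_rng(config.master_seed, spec.session_index),
                n_trials=config.n_trials_override,
            )
            path = out_dir / subject.subject_id / f"session_{spec.session_index:03d}"
            session_io.write_session(record, path)
            written.append(path)
    return written


def read_subject_sessions(subject_dir) -> List[SessionRecord]:
    subject_dir = Path(subject_dir)
    paths = sorted(p for p in subject_dir.iterdir() if (p / "manifest.json").exists())
    return [session_io.read_session(p) for p in paths]


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _schedule_from_sessions(sessions: Sequence[SessionRecord]) -> List[SessionSpec]:
    return [
        SessionSpec(s.subject_id, s.session_index, s.treatment)
        for s in sorted(sessions, key=lambda s: s.session_index)
    ]


def analyze_subject(
    sessions: List[SessionRecord],
    config: PipelineConfig,
) -> Dict[str, object]:
    """All per-subject analyses; returns a dict of DataFrames/records."""
    subject_id = sessions[0].subject_id
    schedule = _schedule_from_sessions(sessions)
    flank_map = flanking_placebo_indices(schedule)
    by_index = {s.session_index: s for s in sessions}
    failures: List[dict] = []

    # --- behavior -------------------------------------------------------
    behavior_rows = []
    comparison_rows = []
    for dose, flank_idx in flank_map.items():
        dose_trials = [t for s in sessions if s.treatment == dose for t in s.trials]
        flank_trials = [t for i in flank_idx if i in by_index
                        for t in by_index[i].trials]
        if not dose_trials or not flank_trials:
            continue
        summary = behavior_mod.summarize(dose_trials)
        behavior_rows.append({"treatment": dose, "n_trials": summary.n_trials,
                              "hit_rate": summary.hit_rate, "se": summary.hit_rate_se,
                              **{f"rate[{k}]": v for k, v in summary.error_rates.items()}})
        for category, test in behavior_mod.compare_to_matched_placebo(
            dose_trials, flank_trials
        ).items():
            comparison_rows.append({
                "treatment": dose, "category": category, "chi2": test.statistic,
                "p": test.p, "p_dose": test.p_a, "p_placebo": test.p_b,
            })
    placebo_trials = [t for s in sessions if s.is_placebo for t in s.trials]
    if placebo_trials:
        summary = behavior_mod.summarize(placebo_trials)
        behavior_rows.append({"treatment": PLACEBO, "n_trials": summary.n_trials,
                              "hit_rate": summary.hit_rate, "se": summary.hit_rate_se,
                              **{f"rate[{k}]": v for k, v in summary.error_rates.items()}})

    # --- selectivity + metrics -----------------------------------------
    metric_tables: Dict[str, List[pd.DataFrame]] = {}
    tuning_by_session: Dict[int, Dict] = {}
    for s in sessions:
        try:
            tuning = session_selectivity(s, CANONICAL_EPOCHS, alpha=config.selectivity_alpha)
            tuning_by_session[s.session_index] = tuning
            table = metrics_table(s, tuning, fano_convention=config.fano_convention)
            metric_tables.setdefault(s.treatment, []).append(table)
        except Exception as exc:  # session-level isolation
            log.exception("metrics failed for session %d", s.session_index)
            failures.append({"stage": "metrics", "session": s.session_index,
                             "error": str(exc)})
    pooled_tables = {t: pd.concat(v) for t, v in metric_tables.items()}

    # --- correlations ---------------------------------------------------
    pair_frames: Dict[str, List[pd.DataFrame]] = {"all": [], "selective": []}
    for s in sessions:
        tuning = tuning_by_session.get(s.session_index)
        if tuning is None:
            continue
        for epoch_name, epoch in CANONICAL_EPOCHS.items():
            # baseline tuning is substituted by the visual (cue) epoch's
            tune_epoch = "cue" if epoch_name == "baseline" else epoch_name
            try:
                pairs = noise_correlations(
                    s, epoch, subset="all", tuning=tuning.get(tune_epoch, {})
                )
                pair_frames["all"].append(pairs)
                pair_frames["selective"].append(pairs[pairs["both_selective"]])
            except Exception as exc:
                log.exception("correlations failed for session %d", s.session_index)
                failures.append({"stage": "correlations", "session": s.session_index,
                                 "error": str(exc)})
    pairs_all = (pd.concat(pair_frames["all"], ignore_index=True)
                 if pair_frames["all"] else pd.DataFrame())
    pairs_sel = (pd.concat(pair_frames["selective"], ignore_index=True)
                 if pair_frames["selective"] else pd.DataFrame())
    corr_summaries = {}
    structures = {}
    for subset_name, frame in (("all", pairs_all), ("selective", pairs_sel)):
        if len(frame) == 0:
            continue
        for epoch_name, grp in frame.groupby("epoch"):
            corr_summaries[(subset_name, epoch_name)] = sign_split_summary(grp, schedule)
            if subset_name == "all":
                structures[epoch_name] = correlation_structure(grp)

    # --- decoding -------------------------------------------------------
    decode_rows = []
    for s in sessions:
        for epoch_name in ("cue", "attention", "saccade"):
            epoch = CANONICAL_EPOCHS[epoch_name]
            if epoch_name == "saccade":
                trials = [t for t in s.trials
                          if t.outcome == "hit" and t.saccade_time is not None]
                label_fn = lambda t: t.saccade_endpoint()  # noqa: E731
            else:
                trials = [t for t in s.trials if t.trial_type == "target"]
                label_fn = None
            try:
                cm = extract_counts(s, epoch, trials=trials, label_fn=label_fn)
                result = decode_epoch(cm.counts, cm.labels, folds=config.folds,
                                      seed=config.master_seed, c=config.decode_c)
                if config.run_permutation_null:
                    result = permutation_null(
                        cm.counts, cm.labels, n_perm=config.n_perm,
                        folds=config.folds, seed=config.master_seed,
                        c=config.decode_c, observed=result,
                    )
                decode_rows.append({
                    "session_index": s.session_index, "treatment": s.treatment,
                    "epoch": epoch_name, "accuracy": result.accuracy,
                    "n_trials": result.n_trials, "n_neurons": result.n_neurons,
                    "null_mean": result.null_mean, "p_empirical": result.p_empirical,
                })
            except Exception as exc:
                log.exception("decoding failed for session %d", s.session_index)
                failures.append({"stage": "decoding", "session": s.session_index,
                                 "error": str(exc)})
    decode_df = pd.DataFrame(decode_rows)
    decode_summary = (
        percent_change_from_flanking(decode_df, schedule)
        if len(decode_df) else {"summary": pd.DataFrame(), "anova": pd.DataFrame()}
    )

    return {
        "subject_id": subject_id,
        "behavior": pd.DataFrame(behavior_rows),
        "behavior_comparisons": pd.DataFrame(comparison_rows),
        "metric_tables": pooled_tables,
        "pairs_all": pairs_all,
        "pairs_selective": pairs_sel,
        "correlation_summaries": corr_summaries,
        "structures": structures,
        "decoding": decode_df,
        "decoding_summary": decode_summary,
        "failures": failures,
    }


def run_pipeline(config: PipelineConfig, sessions_dir, report_dir) -> Dict[str, object]:
    """Analyze every subject found under ``sessions_dir`` and write the
    report bundle; returns the in-memory results keyed by subject."""
    sessions_dir = Path(sessions_dir)
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    subject_dirs = sorted(p for p in sessions_dir.iterdir() if p.is_dir())

    per_subject = {}
    metric_tables_by_subject = {}
    for sdir in subject_dirs:
        sessions = read_subject_sessions(sdir)
        if not sessions:
            continue
        results = analyze_subject(sessions, config)
        per_subject[results["subject_id"]] = results
        metric_tables_by_subject[results["subject_id"]] = results["metric_tables"]

    # dose scan over all subjects (analyzed separately; Bonferroni m = 19 * n_subjects)
    scan = dose_effect_scan(metric_tables_by_subject, alpha=config.alpha)

    _write_report(per_subject, scan, report_dir)
    return {"subjects": per_subject, "dose_scan": scan}


def _write_report(per_subject, scan: pd.DataFrame, report_dir: Path) -> None:
    scan.to_csv(report_dir / "metric_dose_scan.csv", index=False)
    summary = {"n_metric_tests": int(len(scan)),
               "n_significant_after_bonferroni": int(scan["significant"].sum())
               if len(scan) else 0,
               "subjects": {}}
    for subject_id, res in per_subject.items():
        sdir = report_dir / subject_id
        sdir.mkdir(exist_ok=True)
        res["behavior"].to_csv(sdir / "behavior_summary.csv", index=False)
        res["behavior_comparisons"].to_csv(sdir / "behavior_comparisons.csv", index=False)
        if len(res["pairs_all"]):
            res["pairs_all"].to_csv(sdir / "pairs_all.csv", index=False)
        for (subset, epoch), df in res["correlation_summaries"].items():
            df.to_csv(sdir / f"correlation_summary_{subset}_{epoch}.csv", index=False)
        for epoch, structure in res["structures"].items():
            structure["curve"].to_csv(sdir / f"structure_curve_{epoch}.csv", index=False)
            structure["bin_tests"].to_csv(sdir / f"structure_tests_{epoch}.csv", index=False)
        res["decoding"].to_csv(sdir / "decoding_sessions.csv", index=False)
        res["decoding_summary"]["summary"].to_csv(sdir / "decoding_summary.csv", index=False)
        res["decoding_summary"]["anova"].to_csv(sdir / "decoding_anova.csv", index=False)
        for treatment, table in res["metric_tables"].items():
            safe = treatment.replace("/", "_")
            table.to_csv(sdir / f"metrics_{safe}.csv")
        summary["subjects"][subject_id] = {
            "n_sessions_failed": len(res["failures"]),
            "failures": res["failures"],
        }
    (report_dir / "summary.json").write_text(json.dumps(summary, indent=2))
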