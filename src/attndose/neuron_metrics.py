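"""The 19 single-neuron response metrics and the per-metric dose scan.

Metric groups and eligibility:

* 1-11 (visual epoch): only neurons selective in the cue epoch.
* 12-15 (attention epoch): only attention-selective neurons.
* 16-19 (saccade epoch): only saccade-selective neurons.

"Fano factor" follows the source convention — SD/mean (coefficient of
variation) across trials — with an optional switch to the conventional
variance/mean.  Ratio metrics are undefined (NaN, logged) when the
denominator falls below ``RATIO_EPSILON`` spikes/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SessionRecord, TrialRecord
from .preprocessing import aligned_sdf_matrix, count_spikes
from .selectivity import SelectivityResult
from .stats_core import one_way_anova

log = logging.getLogger(__name__)

RATIO_EPSILON = 0.1  # spikes/s
VISUAL_WINDOW = (0.0, 200.0)  # re cue onset / stimuli onset
SACCADE_WINDOW = (-50.0, 50.0)  # re saccade onset
ATTENTION_HALF_WIDTH = 200.0  # 400-ms window centered between cue off and Go

METRIC_IDS = [f"m{i:02d}" for i in range(1, 20)]
VISUAL_METRICS = METRIC_IDS[0:11]
ATTENTION_METRICS = METRIC_IDS[11:15]
SACCADE_METRICS = METRIC_IDS[15:19]


def fano(values: np.ndarray, convention: str = "cv") -> float:
    """Trial-to-trial variability: SD/mean by default, or variance/mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return np.nan
    mean = values.mean()
    if mean <= RATIO_EPSILON:
        return np.nan
    if convention == "cv":
        return float(values.std(ddof=1) / mean)
    if convention == "variance":
        return float(values.var(ddof=1) / mean)
    raise ValueError(f"unknown Fano convention {convention!r}")


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den <= RATIO_EPSILON:
        return np.nan
    return num / den


def _peak(avg: np.ndarray, offsets: np.ndarray) -> tuple:
    """(peak value, peak time) of a trial-averaged SDF; earliest tie wins."""
    i = int(np.argmax(avg))
    return float(avg[i]), float(offsets[i])


def visual_metrics(
    session: SessionRecord,
    neuron_id: str,
    trials: Sequence[TrialRecord],
    tuning: SelectivityResult,
    fano_convention: str = "cv",
) -> Dict[str, float]:
    """Metrics 1-11 from cue- and distractor-aligned responses."""
    pref, anti = tuning.preferred_quadrant, tuning.anti_preferred_quadrant
    out = {m: np.nan for m in VISUAL_METRICS}

    # (1) baseline rate over [-200, 0) ms re cue onset
    base_counts = []
    for t in trials:
        times = session.spikes.get(t.trial_index, {}).get(neuron_id, np.empty(0))
        base_counts.append(count_spikes(times, t.cue_on - 200.0, t.cue_on))
    if base_counts:
        out["m01"] = float(np.mean(base_counts)) / 0.2

    pref_trials = [t for t in trials if t.cue_quadrant == pref]
    anti_trials = [t for t in trials if t.cue_quadrant == anti]
    distr_trials = [t for t in trials if t.cue_quadrant != pref]

    if pref_trials:
        offsets, sdf = aligned_sdf_matrix(session, neuron_id, pref_trials,
                                          "cue_on", VISUAL_WINDOW)
        avg = sdf.mean(axis=0)
        peak, peak_t = _peak(avg, offsets)
        out["m02"] = peak  # peak cue-elicited response, preferred quadrant
        out["m03"] = peak_t  # its latency re cue onset
        at_peak = sdf[:, int(peak_t - offsets[0])]
        out["m04"] = fano(at_peak, fano_convention)
        out["m08"] = fano(sdf.max(axis=1), fano_convention)  # single-trial peaks

    if distr_trials:
        offsets, sdf = aligned_sdf_matrix(session, neuron_id, distr_trials,
                                          "stimuli_on", VISUAL_WINDOW)
        avg = sdf.mean(axis=0)
        out["m06"], out["m07"] = _peak(avg, offsets)  # distractor peak + latency

    out["m05"] = _ratio(out["m02"], out["m06"])  # target vs distractor in RF

    if anti_trials:
        offsets, sdf = aligned_sdf_matrix(session, neuron_id, anti_trials,
                                          "cue_on", VISUAL_WINDOW)
        avg = sdf.mean(axis=0)
        out["m10"], out["m11"] = _peak(avg, offsets)  # anti-preferred peak + latency

    out["m09"] = _ratio(out["m02"], out["m10"])  # RF modulation
    return out


def _sustained_rates(
    session: SessionRecord, neuron_id: str, trials: Sequence[TrialRecord]
) -> np.ndarray:
    """Per-trial mean rate over the 400-ms window centered between cue
    offset and the Go signal."""
    rates = []
    for t in trials:
        mid = 0.5 * (t.cue_off + t.change_time)
        times = session.spikes.get(t.trial_index, {}).get(neuron_id, np.empty(0))
        n = count_spikes(times, mid - ATTENTION_HALF_WIDTH, mid + ATTENTION_HALF_WIDTH)
        rates.append(n / (2 * ATTENTION_HALF_WIDTH / 1000.0))
    return np.asarray(rates, dtype=float)


def attention_metrics(
    session: SessionRecord,
    neuron_id: str,
    trials: Sequence[TrialRecord],
    tuning: SelectivityResult,
    fano_convention: str = "cv",
) -> Dict[str, float]:
    """Metrics 12-15 from the sustained delay-period response."""
    pref, anti = tuning.preferred_quadrant, tuning.anti_preferred_quadrant
    out = {m: np.nan for m in ATTENTION_METRICS}
    in_rf = _sustained_rates(session, neuron_id,
                             [t for t in trials if t.cue_quadrant == pref])
    out_rf = _sustained_rates(session, neuron_id,
                              [t for t in trials if t.cue_quadrant == anti])
    if in_rf.size:
        out["m12"] = float(in_rf.mean())
        out["m15"] = fano(in_rf, fano_convention)
    if out_rf.size:
        out["m13"] = float(out_rf.mean())
    out["m14"] = _ratio(out["m12"], out["m13"])
    return out


def saccade_metrics(
    session: SessionRecord,
    neuron_id: str,
    trials: Sequence[TrialRecord],
    tuning: SelectivityResult,
    fano_convention: str = "cv",
) -> Dict[str, float]:
    """Metrics 16-19 from saccade-aligned responses.

    Only trials that ended in an interpretable saccade (hits and saccades
    to the distractor) contribute; fixation breaks and no-response trials
    have no usable saccade alignment.
    """
    pref, anti = tuning.preferred_quadrant, tuning.anti_preferred_quadrant
    out = {m: np.nan for m in SACCADE_METRICS}
    sac_trials = [
        t for t in trials
        if t.saccade_time is not None and t.outcome in ("hit", "saccade_to_distractor")
    ]
    toward_pref = [t for t in sac_trials if t.saccade_endpoint() == pref]
    toward_anti = [t for t in sac_trials if t.saccade_endpoint() == anti]
    if toward_pref:
        offsets, sdf = aligned_sdf_matrix(session, neuron_id, toward_pref,
                                          "saccade_time", SACCADE_WINDOW)
        out["m16"], _ = _peak(sdf.mean(axis=0), offsets)
        out["m19"] = fano(sdf.max(axis=1), fano_convention)
    if toward_anti:
        offsets, sdf = aligned_sdf_matrix(session, neuron_id, toward_anti,
                                          "saccade_time", SACCADE_WINDOW)
        out["m17"], _ = _peak(sdf.mean(axis=0), offsets)
    out["m18"] = _ratio(out["m16"], out["m17"])
    return out


def metrics_table(
    session: SessionRecord,
    tuning: Mapping[str, Mapping[str, SelectivityResult]],
    fano_convention: str = "cv",
    trial_types: Sequence[str] = ("target",),
) -> pd.DataFrame:
    """All 19 metrics for every eligible neuron of a session.

    ``tuning`` maps epoch name ("cue", "attention", "saccade") to per-neuron
    selectivity results.  Ineligible or undefined metrics are NaN.
    Returns a DataFrame indexed by neuron_id with columns m01..m19 plus
    eligibility flags.
    """
    trials = [t for t in session.trials if t.trial_type in trial_types]
    rows = []
    for neuron_id in session.neuron_ids:
        row: Dict[str, float] = {m: np.nan for m in METRIC_IDS}
        vis = tuning.get("cue", {}).get(neuron_id)
        att = tuning.get("attention", {}).get(neuron_id)
        sac = tuning.get("saccade", {}).get(neuron_id)
        vis_ok = vis is not None and vis.selective
        att_ok = att is not None and att.selective
        sac_ok = sac is not None and sac.selective
        if vis_ok:
            row.update(visual_metrics(session, neuron_id, trials, vis, fano_convention))
        if att_ok:
            row.update(attention_metrics(session, neuron_id, trials, att, fano_convention))
        if sac_ok:
            row.update(saccade_metrics(session, neuron_id, trials, sac, fano_convention))
        row["visual_selective"] = vis_ok
        row["attention_selective"] = att_ok
        row["saccade_selective"] = sac_ok
        row["neuron_id"] = neuron_id
        rows.append(row)
    df = pd.DataFrame(rows).set_index("neuron_id")
    return df[METRIC_IDS + ["visual_selective", "attention_selective", "saccade_selective"]]


@dataclass
class DoseEffectResult:
    subject: str
    metric: str
    group_means: Dict[str, float]
    group_sems: Dict[str, float]
    f: float
    df: float
    p_uncorrected: float
    p_bonferroni: float
    significant: bool
    skipped: bool = False


def dose_effect_scan(
    tables: Mapping[str, Mapping[str, pd.DataFrame]],
    metrics: Sequence[str] = tuple(METRIC_IDS),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way dose-factor ANOVA per metric per subject, Bonferroni over all.

    ``tables[subject][treatment]`` is a metric table pooled over that
    subject's sessions at that treatment (placebo included as a level).
    Subjects are never pooled; the correction size is
    ``m = len(metrics) * len(tables)`` regardless of skipped tests.
    """
    results: List[DoseEffectResult] = []
    m = len(metrics) * len(tables)
    for subject, by_treatment in tables.items():
        for metric in metrics:
            groups, means, sems = [], {}, {}
            for treatment, table in by_treatment.items():
                values = table[metric].dropna().to_numpy()
                means[treatment] = float(values.mean()) if values.size else np.nan
                sems[treatment] = (
                    float(values.std(ddof=1) / np.sqrt(values.size))
                    if values.size > 1 else np.nan
                )
                if values.size >= 2:
                    groups.append(values)
            if len(groups) < 2:
                log.info("dose scan: %s/%s skipped (<2 usable groups)", subject, metric)
                results.append(DoseEffectResult(
                    subject, metric, means, sems, np.nan, np.nan, np.nan, np.nan,
                    significant=False, skipped=True,
                ))
                continue
            test = one_way_anova(groups)
            results.append(DoseEffectResult(
                subject, metric, means, sems, test.statistic, test.df,
                test.p, min(1.0, test.p * m),
                significant=bool(test.p < alpha / m),
            ))
    df = pd.DataFrame([
        {
            "subject": r.subject,
            "metric": r.metric,
            "F": r.f,
            "df": r.df,
            "p_uncorrected": r.p_uncorrected,
            "p_bonferroni": r.p_bonferroni,
            "significant": r.significant,
            "skipped": r.skipped,
            "n_tests_corrected": m,
            **{f"mean[{t}]": v for t, v in r.group_means.items()},
            **{f"sem[{t}]": v for t, v in r.group_sems.items()},
        }
        for r in results
    ])
    return df
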