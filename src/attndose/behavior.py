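"""Session-level behavioral summaries and dose-vs-placebo comparisons.

Hit rate treats every non-hit outcome as a miss (hits / all trials); the
per-category error rates are reported separately.  Dose pools are always
compared against the flanking placebo sessions of the same block, never
against all placebos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import ERROR_OUTCOMES, TrialRecord
from .stats_core import ProportionComparison, chi_square_proportions


@dataclass
class BehaviorSummary:
    n_trials: int
    hits: int
    fixation_breaks: int
    saccades_to_distractor: int
    no_responses: int
    hit_rate: float
    hit_rate_se: float
    error_rates: Dict[str, float]
    error_rate_ses: Dict[str, float]

    @property
    def misses(self) -> int:
        return self.n_trials - self.hits


def _proportion_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n)) if n else 0.0


def summarize(trials: Sequence[TrialRecord]) -> BehaviorSummary:
    """Outcome counts and proportions (with SE) for a pooled trial set."""
    if len(trials) == 0:
        raise ValueError("summarize requires at least one trial")
    n = len(trials)
    counts = {o: sum(1 for t in trials if t.outcome == o)
              for o in ("hit",) + ERROR_OUTCOMES}
    hit_rate = counts["hit"] / n
    error_rates = {o: counts[o] / n for o in ERROR_OUTCOMES}
    return BehaviorSummary(
        n_trials=n,
        hits=counts["hit"],
        fixation_breaks=counts["fixation_break"],
        saccades_to_distractor=counts["saccade_to_distractor"],
        no_responses=counts["no_response"],
        hit_rate=hit_rate,
        hit_rate_se=_proportion_se(hit_rate, n),
        error_rates=error_rates,
        error_rate_ses={o: _proportion_se(r, n) for o, r in error_rates.items()},
    )


def compare_to_matched_placebo(
    dose_trials: Sequence[TrialRecord],
    placebo_trials: Sequence[TrialRecord],
) -> Dict[str, ProportionComparison]:
    """Chi-square difference in proportions for the hit rate and each error
    category, dose pool vs flanking placebo pool."""
    if not dose_trials or not placebo_trials:
        raise ValueError("both pools must be non-empty")
    a, b = summarize(dose_trials), summarize(placebo_trials)
    out = {"hit": chi_square_proportions(a.hits, a.n_trials, b.hits, b.n_trials)}
    a_counts = {
        "fixation_break": a.fixation_breaks,
        "saccade_to_distractor": a.saccades_to_distractor,
        "no_response": a.no_responses,
    }
    b_counts = {
        "fixation_break": b.fixation_breaks,
        "saccade_to_distractor": b.saccades_to_distractor,
        "no_response": b.no_responses,
    }
    for cat in ERROR_OUTCOMES:
        out[cat] = chi_square_proportions(
            a_counts[cat], a.n_trials, b_counts[cat], b.n_trials
        )
    return out


def error_taxonomy(trials: Sequence[TrialRecord]) -> Dict[str, Dict[str, float]]:
    """Rates of impulsivity-type (fixation break) and distractibility-type
    (saccade to distractor) errors, as proportions of all trials."""
    n = len(trials)
    if n == 0:
        return {"impulsivity": {"rate": 0.0, "se": 0.0},
                "distractibility": {"rate": 0.0, "se": 0.0}}
    fb = sum(1 for t in trials if t.outcome == "fixation_break") / n
    sd = sum(1 for t in trials if t.outcome == "saccade_to_distractor") / n
    return {
        "impulsivity": {"rate": fb, "se": _proportion_se(fb, n)},
        "distractibility": {"rate": sd, "se": _proportion_se(sd, n)},
    }
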