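"""Per-neuron, per-epoch tuning classification.

Selectivity is a Kruskal-Wallis test of epoch firing rates across the four
cue quadrants on target-only trials, at alpha = 0.01.  The preferred
quadrant is the one with the highest mean rate (ties broken by the lowest
quadrant index, logged); the anti-preferred is the lowest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .core import QUADRANTS, SessionRecord
from .preprocessing import CountMatrix, EpochWindow, extract_counts
from .stats_core import kruskal_wallis

log = logging.getLogger(__name__)

SELECTIVITY_ALPHA = 0.01


@dataclass
class SelectivityResult:
    neuron_id: str
    epoch: str
    h: float
    p: float
    selective: bool
    preferred_quadrant: int
    anti_preferred_quadrant: int


def classify_selectivity(
    counts: CountMatrix, alpha: float = SELECTIVITY_ALPHA
) -> Dict[str, SelectivityResult]:
    """Classify every neuron in a target-trial count matrix.

    Neurons with fewer than 2 trials in any quadrant, or with a quadrant
    entirely absent, are excluded (logged) and missing from the result.
    """
    results: Dict[str, SelectivityResult] = {}
    labels = np.asarray(counts.labels)
    masks = {q: labels == q for q in QUADRANTS}
    if any(m.sum() < 2 for m in masks.values()):
        log.info(
            "classify_selectivity(%s): a quadrant has <2 trials; all neurons excluded",
            counts.epoch.name,
        )
        return results
    rate_scale = 1.0 / counts.epoch.duration_s
    for j, neuron_id in enumerate(counts.neuron_ids):
        groups = [counts.counts[masks[q], j] * rate_scale for q in QUADRANTS]
        test = kruskal_wallis(groups)
        means = np.array([g.mean() for g in groups])
        preferred = int(QUADRANTS[int(np.argmax(means))])
        anti_candidates = [q for q in QUADRANTS if q != preferred]
        anti_means = [means[q - 1] for q in anti_candidates]
        anti = int(anti_candidates[int(np.argmin(anti_means))])
        if np.sum(means == means.max()) > 1:
            log.info("neuron %s: tied preferred quadrant, lowest index kept", neuron_id)
        results[neuron_id] = SelectivityResult(
            neuron_id=neuron_id,
            epoch=counts.epoch.name,
            h=test.statistic,
            p=test.p,
            selective=bool(test.p < alpha) and not test.flagged,
            preferred_quadrant=preferred,
            anti_preferred_quadrant=anti,
        )
    return results


def session_selectivity(
    session: SessionRecord,
    epochs: Dict[str, EpochWindow],
    alpha: float = SELECTIVITY_ALPHA,
) -> Dict[str, Dict[str, SelectivityResult]]:
    """Selectivity per epoch on target-only trials.

    Returns ``{epoch_name: {neuron_id: SelectivityResult}}``.  The baseline
    epoch has no tuning of its own; analyses that need baseline tuning
    substitute the cue (visual) epoch's result.
    """
    target_trials = [t for t in session.trials if t.trial_type == "target"]
    out: Dict[str, Dict[str, SelectivityResult]] = {}
    for name, epoch in epochs.items():
        if name == "baseline":
            continue
        counts = extract_counts(session, epoch, trials=target_trials)
        out[name] = classify_selectivity(counts, alpha=alpha)
    return out
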