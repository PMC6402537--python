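"""Cross-validated linear ensemble decoding with permutation nulls.

A linear maximum-margin classifier (one-vs-rest over the four quadrants,
C = 1) is trained on spike counts standardized per fold using training
statistics only, under stratified 5-fold cross-validation.  The null
distribution retrains the decoder after permuting trial labels; the
empirical p uses the +1 correction and is therefore never exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .core import PLACEBO, SessionSpec
from .stats_core import one_way_anova
from .synthetic import flanking_placebo_indices

log = logging.getLogger(__name__)

DEFAULT_FOLDS = 5
DEFAULT_N_PERM = 1000
DEFAULT_C = 1.0


@dataclass
class DecodeResult:
    accuracy: float
    fold_accuracies: List[float]
    n_neurons: int
    n_trials: int
    null_mean: Optional[float] = None
    null_p95: Optional[float] = None
    n_permutations: int = 0
    p_empirical: Optional[float] = None


def _check_labels(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < folds:
            raise ValueError(
                f"class {cls!r} has only {n} trials; needs at least {folds}"
            )


def decode_epoch(
    counts: np.ndarray,
    labels: Sequence,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    c: float = DEFAULT_C,
) -> DecodeResult:
    """Stratified k-fold decoding accuracy of the trial labels."""
    x = np.asarray(counts, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("counts and labels must have matching trial counts")
    _check_labels(y, folds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc: List[float] = []
    for train, test in cv.split(x, y):
        clf = make_pipeline(
            StandardScaler(),
            LinearSVC(C=c, random_state=seed),
        )
        clf.fit(x[train], y[train])
        fold_acc.append(float(np.mean(clf.predict(x[test]) == y[test])))
    return DecodeResult(
        accuracy=float(np.mean(fold_acc)),
        fold_accuracies=fold_acc,
        n_neurons=x.shape[1],
        n_trials=x.shape[0],
    )


def permutation_null(
    counts: np.ndarray,
    labels: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    c: float = DEFAULT_C,
    observed: Optional[DecodeResult] = None,
) -> DecodeResult:
    """Label-permutation null distribution and empirical p for the observed
    accuracy; ``p = (1 + #{null >= observed}) / (n_perm + 1)``."""
    if n_perm < 100:
        log.warning("permutation_null: n_perm=%d is low; p resolution is coarse", n_perm)
    y = np.asarray(labels)
    if observed is None:
        observed = decode_epoch(counts, y, folds=folds, seed=seed, c=c)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(y)
        null[k] = decode_epoch(counts, perm, folds=folds, seed=seed, c=c).accuracy
    p = (1 + int(np.sum(null >= observed.accuracy))) / (n_perm + 1)
    return DecodeResult(
        accuracy=observed.accuracy,
        fold_accuracies=observed.fold_accuracies,
        n_neurons=observed.n_neurons,
        n_trials=observed.n_trials,
        null_mean=float(null.mean()),
        null_p95=float(np.percentile(null, 95)),
        n_permutations=n_perm,
        p_empirical=float(p),
    )


def percent_change_from_flanking(
    session_results: pd.DataFrame,
    schedule: Sequence[SessionSpec],
) -> Dict[str, pd.DataFrame]:
    """Dose-level decoding summaries against each block's flanking placebos.

    ``session_results`` needs columns session_index, treatment, epoch,
    accuracy.  Returns ``{"summary": per-dose percent change,
    "anova": dose-factor ANOVA per epoch (placebo included)}``.
    """
    flank_map = flanking_placebo_indices(schedule)
    rows = []
    for (epoch, treatment), grp in session_results.groupby(["epoch", "treatment"]):
        if treatment == PLACEBO:
            continue
        mean_acc = float(grp["accuracy"].mean())
        pct = np.nan
        incomplete = True
        if treatment in flank_map:
            flank = session_results[
                (session_results["epoch"] == epoch)
                & (session_results["session_index"].isin(flank_map[treatment]))
            ]
            if len(flank):
                flank_acc = float(flank["accuracy"].mean())
                if flank_acc > 0:
                    pct = 100.0 * (mean_acc - flank_acc) / flank_acc
                incomplete = False
        if incomplete:
            log.info("flanking placebo missing for dose %s, epoch %s", treatment, epoch)
        rows.append({
            "epoch": epoch,
            "dose": treatment,
            "mean_accuracy": mean_acc,
            "n_sessions": len(grp),
            "pct_change_vs_flanking": pct,
            "incomplete": incomplete,
        })
    anova_rows = []
    for epoch, grp in session_results.groupby("epoch"):
        groups = [g["accuracy"].to_numpy() for _, g in grp.groupby("treatment")
                  if len(g) >= 2]
        if len(groups) >= 2:
            t = one_way_anova(groups)
            anova_rows.append({"epoch": epoch, "F": t.statistic, "df": t.df,
                               "p": t.p, "eta_sq": t.effect_size})
    return {
        "summary": pd.DataFrame(rows),
        "anova": pd.DataFrame(anova_rows, columns=["epoch", "F", "df", "p", "eta_sq"]),
    }
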