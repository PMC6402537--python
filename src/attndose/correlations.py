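"""Pairwise noise/signal correlations and their dose-level summaries.

Noise correlations: epoch spike counts are z-scored within each cue
quadrant condition (removing condition mean and SD), pooled across
conditions, and Pearson-correlated per pair of simultaneously recorded
neurons from *different* electrodes.  Signal correlations are the Pearson
correlation of the two neurons' 4-point condition-mean tuning vectors.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import QUADRANTS, SessionRecord, SessionSpec, PLACEBO
from .preprocessing import CountMatrix, EpochWindow, extract_counts
from .selectivity import SelectivityResult
from .stats_core import one_way_anova, spearman_rho
from .synthetic import flanking_placebo_indices

log = logging.getLogger(__name__)

MIN_TRIALS_PER_CONDITION = 10

PAIR_COLUMNS = [
    "session_index", "treatment", "epoch", "neuron_i", "neuron_j",
    "electrode_i", "electrode_j", "noise_r", "signal_r", "both_selective",
]

STRUCTURE_BIN_EDGES = np.linspace(-1.0, 1.0, 11)


def _condition_zscores(counts: CountMatrix) -> tuple:
    """Z-score counts within each condition; returns (z, valid_mask).

    A neuron with zero variance in any retained condition is invalid (its
    pairs are excluded).  Conditions with too few trials are dropped.
    """
    labels = np.asarray(counts.labels)
    z = np.full(counts.counts.shape, np.nan)
    valid = np.ones(len(counts.neuron_ids), dtype=bool)
    kept_rows = np.zeros(counts.n_trials, dtype=bool)
    for q in QUADRANTS:
        mask = labels == q
        if mask.sum() < MIN_TRIALS_PER_CONDITION:
            log.info("noise correlations: condition %s dropped (%d trials)",
                     q, int(mask.sum()))
            continue
        kept_rows |= mask
        sub = counts.counts[mask].astype(float)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        zero = sd == 0
        if np.any(zero):
            valid &= ~zero
        with np.errstate(invalid="ignore", divide="ignore"):
            z[mask] = (sub - mean) / sd
    return z[kept_rows], valid


def _tuning_vectors(counts: CountMatrix) -> np.ndarray:
    """Condition-mean counts per neuron: shape (n_neurons, 4)."""
    labels = np.asarray(counts.labels)
    vecs = np.full((len(counts.neuron_ids), len(QUADRANTS)), np.nan)
    for k, q in enumerate(QUADRANTS):
        mask = labels == q
        if mask.any():
            vecs[:, k] = counts.counts[mask].mean(axis=0)
    return vecs


def noise_correlations(
    session: SessionRecord,
    epoch: EpochWindow,
    subset: str = "all",
    tuning: Optional[Mapping[str, SelectivityResult]] = None,
    trial_types: Sequence[str] = ("target",),
) -> pd.DataFrame:
    """Pair records (noise r, signal r) for one session and epoch.

    ``subset="selective"`` keeps only pairs where both neurons are selective
    per ``tuning`` (for the baseline epoch pass the visual-epoch tuning).
    Same-electrode pairs are always excluded.
    """
    if subset not in ("all", "selective"):
        raise ValueError("subset must be 'all' or 'selective'")
    if subset == "selective" and tuning is None:
        raise ValueError("subset='selective' requires tuning results")
    trials = [t for t in session.trials if t.trial_type in trial_types]
    counts = extract_counts(session, epoch, trials=trials)
    rows: List[dict] = []
    if counts.n_trials == 0:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    z, valid = _condition_zscores(counts)
    if z.shape[0] < 3:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    vecs = _tuning_vectors(counts)
    tuning_sd = np.nanstd(vecs, axis=1)
    neuron_ids = counts.neuron_ids
    emap = session.electrode_map
    for i, j in combinations(range(len(neuron_ids)), 2):
        ni, nj = neuron_ids[i], neuron_ids[j]
        if emap[ni] == emap[nj]:
            continue
        if not (valid[i] and valid[j]):
            continue
        if subset == "selective":
            ti, tj = tuning.get(ni), tuning.get(nj)
            if not (ti and tj and ti.selective and tj.selective):
                continue
        zi, zj = z[:, i], z[:, j]
        noise_r = float(np.corrcoef(zi, zj)[0, 1])
        if tuning_sd[i] > 0 and tuning_sd[j] > 0:
            signal_r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
        else:
            signal_r = np.nan  # flat tuning: excluded from structure analysis
        both_sel = bool(
            tuning is not None
            and tuning.get(ni) is not None and tuning.get(nj) is not None
            and tuning[ni].selective and tuning[nj].selective
        )
        rows.append({
            "session_index": session.session_index,
            "treatment": session.treatment,
            "epoch": epoch.name,
            "neuron_i": ni,
            "neuron_j": nj,
            "electrode_i": emap[ni],
            "electrode_j": emap[nj],
            "noise_r": noise_r,
            "signal_r": signal_r,
            "both_selective": both_sel,
        })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def signal_correlations(session: SessionRecord, epoch: EpochWindow,
                        trial_types: Sequence[str] = ("target",)) -> pd.DataFrame:
    """Per-pair tuning-vector correlations only (subset of noise_correlations)."""
    pairs = noise_correlations(session, epoch, subset="all", trial_types=trial_types)
    return pairs[["neuron_i", "neuron_j", "signal_r"]].dropna()


def sign_split_summary(
    pairs: pd.DataFrame,
    schedule: Sequence[SessionSpec],
) -> pd.DataFrame:
    """Median noise r per sign per treatment, with percent change vs the
    flanking placebo pool of each dose block.

    ``pairs`` must carry ``session_index``, ``treatment`` and ``noise_r``
    pooled over the sessions of interest (one epoch, one subset).  Pairs
    with r exactly 0 belong to neither stratum.
    """
    flank_map = flanking_placebo_indices(schedule)
    rows = []
    for treatment, grp in pairs.groupby("treatment"):
        r = grp["noise_r"].to_numpy()
        pos, neg = r[r > 0], r[r < 0]
        med_pos = float(np.median(pos)) if pos.size else np.nan
        med_neg = float(np.median(neg)) if neg.size else np.nan
        pct_pos = pct_neg = np.nan
        if treatment != PLACEBO and treatment in flank_map:
            flank = pairs[pairs["session_index"].isin(flank_map[treatment])]
            fr = flank["noise_r"].to_numpy()
            fpos, fneg = fr[fr > 0], fr[fr < 0]
            if pos.size and fpos.size and np.median(fpos) != 0:
                mp = float(np.median(fpos))
                pct_pos = 100.0 * (med_pos - mp) / abs(mp)
            if neg.size and fneg.size and np.median(fneg) != 0:
                mn = float(np.median(fneg))
                pct_neg = 100.0 * (med_neg - mn) / abs(mn)
        rows.append({
            "treatment": treatment,
            "n_pos": int(pos.size),
            "n_neg": int(neg.size),
            "median_pos": med_pos,
            "median_neg": med_neg,
            "pct_change_pos": pct_pos,
            "pct_change_neg": pct_neg,
        })
    return pd.DataFrame(rows)


def correlation_structure(pairs: pd.DataFrame) -> Dict[str, object]:
    """10-bin noise-vs-signal-correlation curve with per-bin dose ANOVA.

    Returns ``{"curve": DataFrame, "trend_rho": float, "trend_p": float,
    "bin_tests": DataFrame}``.  Bins partition [-1, 1]; the last bin is
    closed on the right.  Empty bins appear with n=0 and are excluded from
    the monotone-trend statistic.
    """
    usable = pairs.dropna(subset=["signal_r"])
    edges = STRUCTURE_BIN_EDGES
    curve_rows = []
    test_rows = []
    bin_means = []
    bin_idx = []
    for b in range(10):
        lo, hi = edges[b], edges[b + 1]
        if b == 9:
            mask = (usable["signal_r"] >= lo) & (usable["signal_r"] <= hi)
        else:
            mask = (usable["signal_r"] >= lo) & (usable["signal_r"] < hi)
        sub = usable[mask]
        n = len(sub)
        mean_r = float(sub["noise_r"].mean()) if n else np.nan
        sem_r = (float(sub["noise_r"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan)
        curve_rows.append({"bin": b, "lo": lo, "hi": hi,
                           "mean_noise_r": mean_r, "sem": sem_r, "n": n})
        if n:
            bin_means.append(mean_r)
            bin_idx.append(b)
        if "treatment" in sub.columns and sub["treatment"].nunique() >= 2:
            groups = [g["noise_r"].to_numpy() for _, g in sub.groupby("treatment")
                      if len(g) >= 2]
            if len(groups) >= 2:
                t = one_way_anova(groups)
                test_rows.append({"bin": b, "F": t.statistic, "p": t.p,
                                  "eta_sq": t.effect_size})
    trend_rho = trend_p = np.nan
    if len(bin_idx) >= 3:
        trend_rho, trend_p = spearman_rho(bin_idx, bin_means)
    return {
        "curve": pd.DataFrame(curve_rows),
        "trend_rho": trend_rho,
        "trend_p": trend_p,
        "bin_tests": pd.DataFrame(test_rows, columns=["bin", "F", "p", "eta_sq"]),
    }
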