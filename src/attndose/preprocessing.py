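"""Epoching, spike counting, spike-density functions and normalization.

All windows are half-open ``[start, end)`` on a 1-ms grid, which makes
spike-count additivity over disjoint windows exact.  The SDF kernel is a
unit-area Gaussian truncated at +/-5 sigma with zero padding outside the
trial (no edge renormalization), so the bias is confined to a 150 ms
border outside every analysis window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import SessionRecord, TrialRecord

log = logging.getLogger(__name__)

SDF_SIGMA_MS = 30.0


@dataclass(frozen=True)
class EpochWindow:
    """An analysis window relative to an alignment event."""

    name: str
    align: str  # "cue_on" | "stimuli_on" | "saccade_time"
    start_offset: float  # ms, inclusive
    end_offset: float  # ms, exclusive

    def __post_init__(self) -> None:
        if self.end_offset <= self.start_offset:
            raise ValueError("epoch end must be after start")

    @property
    def duration_s(self) -> float:
        return (self.end_offset - self.start_offset) / 1000.0

    def align_time(self, trial: TrialRecord) -> Optional[float]:
        value = getattr(trial, self.align)
        return value


CANONICAL_EPOCHS: Dict[str, EpochWindow] = {
    "baseline": EpochWindow("baseline", "cue_on", -200.0, 0.0),
    "cue": EpochWindow("cue", "cue_on", 0.0, 200.0),
    "attention": EpochWindow("attention", "cue_on", 600.0, 1000.0),
    "saccade": EpochWindow("saccade", "saccade_time", -50.0, 50.0),
}


@dataclass
class RateSeries:
    """A firing-rate time series on a uniform 1-ms grid (spikes/s)."""

    grid: np.ndarray  # ms
    rates: np.ndarray
    sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.grid.shape != self.rates.shape:
            raise ValueError("grid and rates must have the same shape")


@dataclass
class CountMatrix:
    """Spike counts (trials x neurons) for one epoch, with trial labels."""

    counts: np.ndarray  # int, n_trials x n_neurons
    trial_indices: np.ndarray
    neuron_ids: List[str]
    labels: np.ndarray  # condition label per trial (cue quadrant by default)
    epoch: EpochWindow
    dropped_trials: List[int]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------


def gaussian_kernel(sigma_ms: float = SDF_SIGMA_MS) -> np.ndarray:
    """Unit-area Gaussian sampled at 1 ms, truncated at +/-5 sigma, in 1/s."""
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    half = int(np.ceil(5 * sigma_ms))
    offsets = np.arange(-half, half + 1, dtype=float)
    return stats.norm.pdf(offsets, scale=sigma_ms) * 1000.0


def spike_density(
    times: np.ndarray, grid: np.ndarray, sigma_ms: float = SDF_SIGMA_MS
) -> RateSeries:
    """Convolve a spike train with a Gaussian kernel; result in spikes/s.

    ``grid`` is a uniform 1-ms array of sample times; spikes outside it
    still contribute through the kernel tails (zero-padded evaluation).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not np.allclose(np.diff(grid), 1.0):
        raise ValueError("grid must have a 1-ms step")
    kernel = gaussian_kernel(sigma_ms)
    half = (kernel.size - 1) // 2
    times = np.asarray(times, dtype=float)
    t0 = grid[0]
    # bin spikes on an extended grid so near-edge spikes contribute
    n_ext = grid.size + 2 * half
    idx = np.round(times - t0).astype(int) + half
    keep = (idx >= 0) & (idx < n_ext)
    binned = np.bincount(idx[keep], minlength=n_ext).astype(float)
    rates = np.convolve(binned, kernel, mode="same")[half : half + grid.size]
    return RateSeries(grid=grid, rates=rates)


def trial_average(series: Sequence[RateSeries]) -> RateSeries:
    """Pointwise mean across trials of one condition, with SEM."""
    if len(series) == 0:
        raise ValueError("trial_average requires at least one trial")
    grid = series[0].grid
    for s in series[1:]:
        if not np.array_equal(s.grid, grid):
            raise ValueError("all series must share a grid")
    stack = np.stack([s.rates for s in series])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(series)) if len(series) > 1 else None
    return RateSeries(grid=grid, rates=mean, sem=sem)


def zscore_series(series: RateSeries) -> Optional[RateSeries]:
    """Standardize a trial-averaged series to mean 0, SD 1.

    Returns ``None`` (and logs) for constant series, which must be excluded
    from population averages.
    """
    sd = float(np.std(series.rates))
    if sd == 0.0:
        log.info("zscore_series: constant series excluded")
        return None
    z = (series.rates - series.rates.mean()) / sd
    return RateSeries(grid=series.grid, rates=z)


def count_spikes(times: np.ndarray, start: float, end: float) -> int:
    """Number of spikes with start <= t < end (half-open window)."""
    times = np.asarray(times, dtype=float)
    return int(
        np.searchsorted(times, end, side="left")
        - np.searchsorted(times, start, side="left")
    )


def extract_counts(
    session: SessionRecord,
    epoch: EpochWindow,
    trials: Optional[Sequence[TrialRecord]] = None,
    label_fn=None,
) -> CountMatrix:
    """Per trial x neuron spike counts in ``epoch``.

    Trials missing the alignment event (e.g. the saccade on a no-response
    trial) are dropped and logged.  ``label_fn(trial)`` provides the
    condition label; default is the cue quadrant.
    """
    if trials is None:
        trials = session.trials
    if label_fn is None:
        label_fn = lambda t: t.cue_quadrant  # noqa: E731
    neuron_ids = session.neuron_ids
    rows: List[np.ndarray] = []
    kept: List[int] = []
    labels: List = []
    dropped: List[int] = []
    for trial in trials:
        align = epoch.align_time(trial)
        if align is None:
            dropped.append(trial.trial_index)
            continue
        start = align + epoch.start_offset
        end = align + epoch.end_offset
        by_neuron = session.spikes.get(trial.trial_index, {})
        rows.append(
            np.array(
                [count_spikes(by_neuron.get(nid, ()), start, end) for nid in neuron_ids],
                dtype=int,
            )
        )
        kept.append(trial.trial_index)
        labels.append(label_fn(trial))
    if dropped:
        log.info(
            "extract_counts(%s): dropped %d trials missing %s",
            epoch.name, len(dropped), epoch.align,
        )
    counts = np.stack(rows) if rows else np.zeros((0, len(neuron_ids)), dtype=int)
    return CountMatrix(
        counts=counts,
        trial_indices=np.asarray(kept, dtype=int),
        neuron_ids=list(neuron_ids),
        labels=np.asarray(labels),
        epoch=epoch,
        dropped_trials=dropped,
    )


def aligned_sdf_matrix(
    session: SessionRecord,
    neuron_id: str,
    trials: Sequence[TrialRecord],
    align: str,
    window: Tuple[float, float],
    sigma_ms: float = SDF_SIGMA_MS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial SDFs of one neuron aligned to an event.

    Returns ``(grid_offsets, matrix)`` where ``matrix[i]`` is trial i's SDF
    sampled at 1 ms over ``[window[0], window[1])`` relative to the event.
    Trials missing the event are skipped.
    """
    offsets = np.arange(window[0], window[1])
    rows = []
    for trial in trials:
        t0 = getattr(trial, align)
        if t0 is None:
            continue
        times = session.spikes.get(trial.trial_index, {}).get(neuron_id, np.empty(0))
        rows.append(spike_density(np.asarray(times) - t0, offsets, sigma_ms).rates)
    matrix = np.stack(rows) if rows else np.zeros((0, offsets.size))
    return offsets, matrix
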