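"""On-disk session format: a JSON manifest plus two CSV tables.

A session directory contains::

    manifest.json   subject_id, session_index, treatment, electrode_map
    trials.csv      one row per trial (event times in ms; empty = absent)
    spikes.csv      long format: trial_index, neuron_id, electrode_id, time_ms

CSV dialect: comma-separated, header row, UTF-8, '.' decimal.  A missing
saccade_time is an empty field, never 0.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .core import (
    CUE_DURATION_MS,
    DELAY_RANGE_MS,
    OUTCOMES,
    QUADRANTS,
    TRIAL_TYPES,
    SessionRecord,
    TrialRecord,
)

MANIFEST = "manifest.json"
TRIALS_CSV = "trials.csv"
SPIKES_CSV = "spikes.csv"

TRIAL_COLUMNS = [
    "trial_index", "trial_type", "cue_quadrant", "cue_on", "cue_off",
    "stimuli_on", "change_time", "saccade_time", "outcome",
]


class SessionValidationError(ValueError):
    """Raised when a record violating its invariants is written."""

    def __init__(self, violations: List[str]):
        self.violations = violations
        super().__init__("invalid session:\n" + "\n".join(f"  - {v}" for v in violations))


class SessionParseError(ValueError):
    pass


def validate_session(record: SessionRecord) -> List[str]:
    """Return a list of invariant violations (empty iff the record is valid)."""
    problems: List[str] = []
    neuron_set = set(record.electrode_map)
    trial_indices = {t.trial_index for t in record.trials}

    for t in record.trials:
        where = f"trial {t.trial_index}"
        if t.trial_type not in TRIAL_TYPES:
            problems.append(f"{where}: unknown trial_type {t.trial_type!r}")
        if t.cue_quadrant not in QUADRANTS:
            problems.append(f"{where}: cue_quadrant {t.cue_quadrant} not in 1-4")
        if t.outcome not in OUTCOMES:
            problems.append(f"{where}: unknown outcome {t.outcome!r}")
        if abs((t.cue_off - t.cue_on) - CUE_DURATION_MS) > 1e-9:
            problems.append(
                f"{where}: cue_off - cue_on = {t.cue_off - t.cue_on:g} ms, "
                f"must equal the {CUE_DURATION_MS} ms cue duration"
            )
        delay = t.change_time - t.stimuli_on
        if not (DELAY_RANGE_MS[0] <= delay <= DELAY_RANGE_MS[1]):
            problems.append(
                f"{where}: change_time - stimuli_on = {delay:g} ms outside "
                f"[{DELAY_RANGE_MS[0]}, {DELAY_RANGE_MS[1]}]"
            )
        times = [t.cue_on, t.cue_off, t.stimuli_on, t.change_time]
        if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
            problems.append(f"{where}: event times not non-decreasing")

    for trial_index, by_neuron in record.spikes.items():
        if trial_index not in trial_indices:
            problems.append(f"spikes reference unknown trial {trial_index}")
        if set(by_neuron) - neuron_set:
            extra = sorted(set(by_neuron) - neuron_set)
            problems.append(f"trial {trial_index}: unknown neurons {extra}")
        for neuron_id, times in by_neuron.items():
            arr = np.asarray(times, dtype=float)
            if arr.size and np.any(np.diff(arr) <= 0):
                problems.append(
                    f"trial {trial_index}, neuron {neuron_id}: spike times not strictly sorted"
                )
            if arr.size and arr[0] < 0:
                problems.append(
                    f"trial {trial_index}, neuron {neuron_id}: negative spike time"
                )
    return problems


def write_session(record: SessionRecord, path: Union[str, Path]) -> None:
    """Write a validated session to ``path`` (a directory, created if needed)."""
    problems = validate_session(record)
    if problems:
        raise SessionValidationError(problems)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "subject_id": record.subject_id,
        "session_index": record.session_index,
        "treatment": record.treatment,
        "electrode_map": record.electrode_map,
        "n_trials": len(record.trials),
    }
    (path / MANIFEST).write_text(json.dumps(manifest, indent=2, sort_keys=True))

    rows = [
        {
            "trial_index": t.trial_index,
            "trial_type": t.trial_type,
            "cue_quadrant": t.cue_quadrant,
            "cue_on": t.cue_on,
            "cue_off": t.cue_off,
            "stimuli_on": t.stimuli_on,
            "change_time": t.change_time,
            "saccade_time": "" if t.saccade_time is None else repr(t.saccade_time),
            "outcome": t.outcome,
        }
        for t in record.trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path / TRIALS_CSV, index=False)

    spike_rows = {"trial_index": [], "neuron_id": [], "electrode_id": [], "time_ms": []}
    for trial_index in sorted(record.spikes):
        for neuron_id in sorted(record.spikes[trial_index]):
            times = np.asarray(record.spikes[trial_index][neuron_id], dtype=float)
            spike_rows["trial_index"].extend([trial_index] * times.size)
            spike_rows["neuron_id"].extend([neuron_id] * times.size)
            spike_rows["electrode_id"].extend(
                [record.electrode_map[neuron_id]] * times.size
            )
            spike_rows["time_ms"].extend(repr(t) for t in times.tolist())
    pd.DataFrame(spike_rows).to_csv(path / SPIKES_CSV, index=False)


def sessions_equal(a: SessionRecord, b: SessionRecord) -> bool:
    """Field-wise equality, comparing spike arrays exactly."""
    if (a.subject_id, a.session_index, a.treatment, a.electrode_map) != (
        b.subject_id, b.session_index, b.treatment, b.electrode_map
    ):
        return False
    if a.trials != b.trials:
        return False
    if set(a.spikes) != set(b.spikes):
        return False
    for trial_index in a.spikes:
        if set(a.spikes[trial_index]) != set(b.spikes[trial_index]):
            return False
        for nid in a.spikes[trial_index]:
            if not np.array_equal(
                np.asarray(a.spikes[trial_index][nid], dtype=float),
                np.asarray(b.spikes[trial_index][nid], dtype=float),
            ):
                return False
    return True


def read_session(path: Union[str, Path]) -> SessionRecord:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    try:
        manifest = json.loads((path / MANIFEST).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionParseError(f"{path / MANIFEST}: {exc}") from exc

    trials_path = path / TRIALS_CSV
    try:
        trials_df = pd.read_csv(trials_path, dtype={"saccade_time": str},
                                float_precision="round_trip")
    except Exception as exc:
        raise SessionParseError(f"{trials_path}: {exc}") from exc
    missing = set(TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise SessionParseError(f"{trials_path}: missing columns {sorted(missing)}")

    trials: List[TrialRecord] = []
    for row_no, row in enumerate(trials_df.itertuples(index=False), start=2):
        try:
            sac = row.saccade_time
            sac_time = None if (sac is None or (isinstance(sac, float) and math.isnan(sac))
                                or str(sac) == "") else float(sac)
            trials.append(
                TrialRecord(
                    trial_index=int(row.trial_index),
                    trial_type=str(row.trial_type),
                    cue_quadrant=int(row.cue_quadrant),
                    cue_on=float(row.cue_on),
                    cue_off=float(row.cue_off),
                    stimuli_on=float(row.stimuli_on),
                    change_time=float(row.change_time),
                    saccade_time=sac_time,
                    outcome=str(row.outcome),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SessionParseError(f"{trials_path}: row {row_no}: {exc}") from exc

    spikes_path = path / SPIKES_CSV
    try:
        spikes_df = pd.read_csv(spikes_path, float_precision="round_trip")
    except Exception as exc:
        raise SessionParseError(f"{spikes_path}: {exc}") from exc

    electrode_map = {str(k): str(v) for k, v in manifest["electrode_map"].items()}
    spikes = {
        t.trial_index: {nid: np.empty(0) for nid in electrode_map} for t in trials
    }
    if len(spikes_df):
        for (trial_index, neuron_id), grp in spikes_df.groupby(
            ["trial_index", "neuron_id"], sort=False
        ):
            trial_index = int(trial_index)
            if trial_index not in spikes:
                raise SessionParseError(
                    f"{spikes_path}: spikes for unknown trial {trial_index}"
                )
            spikes[trial_index][str(neuron_id)] = grp["time_ms"].to_numpy(dtype=float)

    record = SessionRecord(
        subject_id=str(manifest["subject_id"]),
        session_index=int(manifest["session_index"]),
        treatment=str(manifest["treatment"]),
        trials=trials,
        spikes=spikes,
        electrode_map=electrode_map,
    )
    problems = validate_session(record)
    if problems:
        raise SessionValidationError(problems)
    return record
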