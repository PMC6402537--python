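"""Core domain records shared by every stage of the pipeline.

All event and spike times are in milliseconds from the start of the trial
recording window, which opens ``PRE_CUE_MS`` before cue onset so the
pre-cue baseline is representable with non-negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

#: recording window opens this many ms before cue onset
PRE_CUE_MS = 200
#: fixed cue presentation duration (ms)
CUE_DURATION_MS = 363
#: delay between distractor-array onset and the orientation change (ms)
DELAY_RANGE_MS = (585, 1755)
#: response window after the Go signal (ms)
RESPONSE_WINDOW_MS = 250

TRIAL_TYPES = ("target", "distractor", "target+distractor")
OUTCOMES = ("hit", "fixation_break", "saccade_to_distractor", "no_response")
ERROR_OUTCOMES = ("fixation_break", "saccade_to_distractor", "no_response")
QUADRANTS = (1, 2, 3, 4)

PLACEBO = "placebo"


def opposite_quadrant(q: int) -> int:
    """Diagonally opposite screen quadrant (1<->3, 2<->4)."""
    return ((q + 1) % 4) + 1


@dataclass
class TrialRecord:
    """One behavioral trial.

    Times are ms from recording onset; ``saccade_time`` is ``None`` on
    trials without an eye-movement response.
    """

    trial_index: int
    trial_type: str
    cue_quadrant: int
    cue_on: float
    cue_off: float
    stimuli_on: float
    change_time: float
    saccade_time: Optional[float]
    outcome: str

    def saccade_endpoint(self) -> Optional[int]:
        """Quadrant of the saccade target, if the trial ended in a saccade."""
        if self.saccade_time is None:
            return None
        if self.outcome == "saccade_to_distractor":
            return opposite_quadrant(self.cue_quadrant)
        return self.cue_quadrant


@dataclass
class SpikeTrain:
    neuron_id: str
    electrode_id: str
    times: np.ndarray  # sorted, non-negative ms offsets from recording onset

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class SessionRecord:
    """One recording session: metadata, trials and per-trial spike trains.

    ``spikes[trial_index][neuron_id]`` is a sorted array of spike times;
    the neuron set is constant across trials (given by ``electrode_map``).
    """

    subject_id: str
    session_index: int
    treatment: str  # PLACEBO or a mg/kg dose label such as "0.86"
    trials: List[TrialRecord]
    spikes: Dict[int, Dict[str, np.ndarray]]
    electrode_map: Dict[str, str]
    meta: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> List[str]:
        return sorted(self.electrode_map)

    @property
    def is_placebo(self) -> bool:
        return self.treatment == PLACEBO

    def trial_by_index(self, trial_index: int) -> TrialRecord:
        for t in self.trials:
            if t.trial_index == trial_index:
                return t
        raise KeyError(trial_index)


@dataclass(frozen=True)
class SessionSpec:
    """A slot in the dosing schedule before any data exist."""

    subject_id: str
    session_index: int
    treatment: str

    @property
    def is_placebo(self) -> bool:
        return self.treatment == PLACEBO
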