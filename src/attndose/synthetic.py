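"""Synthetic sessions: dosing schedules, behavior, and correlated spike trains.

The generator emulates the statistical structure the downstream analyses
assume: a four-location covert-attention task with three interleaved trial
types, a flanked dosing schedule, quadrant-tuned inhomogeneous-Poisson
neurons, and a rank-1 shared latent that induces pairwise spike-count
correlations.  Optional per-dose multipliers inject "drug" effects for
power and parameter-recovery testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import (
    CUE_DURATION_MS,
    DELAY_RANGE_MS,
    PLACEBO,
    PRE_CUE_MS,
    QUADRANTS,
    RESPONSE_WINDOW_MS,
    TRIAL_TYPES,
    SessionRecord,
    SessionSpec,
    TrialRecord,
)

log = logging.getLogger(__name__)

#: duration of the transient visual response to a stimulus in the RF (ms)
VISUAL_RESPONSE_MS = 50
#: earliest/latest saccade latency after the Go signal (ms)
SACCADE_LATENCY_RANGE_MS = (100, 250)

# A box response of width w smoothed by the analysis kernel (SD 30 ms) is
# attenuated by 2*Phi(w/(2*sigma)) - 1 at its center.  The generator boosts
# the transient's height by 1/c so the *smoothed* peak equals
# visual_gain * baseline at ~latency + w/2, which is what the peak-response
# metrics estimate.
_SDF_SIGMA_MS = 30.0


def _box_attenuation(width_ms: float) -> float:
    return 2.0 * float(stats.norm.cdf(width_ms / (2 * _SDF_SIGMA_MS))) - 1.0


_VISUAL_ATTENUATION = _box_attenuation(VISUAL_RESPONSE_MS)
_SACCADE_ATTENUATION = _box_attenuation(100.0)  # the +/-50 ms saccade box


def _calibrated_height(gain: float, attenuation: float = _VISUAL_ATTENUATION) -> float:
    """Multiplicative box height whose smoothed peak equals ``gain``."""
    return 1.0 + (gain - 1.0) / attenuation


# ---------------------------------------------------------------------------
# configuration records
# ---------------------------------------------------------------------------


@dataclass
class SubjectConfig:
    subject_id: str
    body_weight_kg: float
    tablet_doses_mg: Sequence[float]
    sessions_per_dose_block: int = 3
    flank_placebo_count: int = 2

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be positive")
        doses = list(self.tablet_doses_mg)
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("tablet_doses_mg must be strictly increasing")
        if self.sessions_per_dose_block < 0 or self.flank_placebo_count < 0:
            raise ValueError("session counts must be >= 0")


@dataclass
class BehaviorModel:
    """Outcome model for one subject.

    ``hit_probability`` may be a scalar or a mapping from treatment label to
    probability.  ``error_mix`` gives the conditional probabilities of
    (fixation_break, saccade_to_distractor, no_response) given an error.
    With ``policy="random_response"`` outcomes instead come from saccading
    to a uniformly random quadrant (hit iff it matches the target).
    """

    hit_probability: Union[float, Mapping[str, float]] = 0.8
    error_mix: Sequence[float] = (0.5, 0.3, 0.2)
    trials_mean: float = 817.0
    trials_sd: float = 93.0
    policy: str = "model"

    def __post_init__(self) -> None:
        mix = np.asarray(self.error_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("error_mix must be 3 non-negative probabilities summing to 1")
        for p in self._all_hit_probs():
            if not 0.0 <= p <= 1.0:
                raise ValueError("hit probabilities must lie in [0, 1]")
        if self.policy not in ("model", "random_response"):
            raise ValueError(f"unknown policy {self.policy!r}")

    def _all_hit_probs(self) -> List[float]:
        if isinstance(self.hit_probability, Mapping):
            return list(self.hit_probability.values())
        return [float(self.hit_probability)]

    def hit_prob_for(self, treatment: str) -> float:
        if isinstance(self.hit_probability, Mapping):
            try:
                return float(self.hit_probability[treatment])
            except KeyError:
                return float(self.hit_probability.get("default", 0.8))
        return float(self.hit_probability)


@dataclass
class NeuronSpec:
    neuron_id: str
    electrode_id: str
    baseline_rate: float  # spikes/s
    preferred_quadrant: Optional[int] = None
    visual_gain: float = 1.0
    attention_gain: float = 1.0
    saccade_gain: float = 1.0
    response_latency_ms: float = 50.0
    distractor_attenuation: float = 0.6  # scales the RF response to a distractor

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.preferred_quadrant is not None and self.preferred_quadrant not in QUADRANTS:
            raise ValueError("preferred_quadrant must be 1-4 or None")
        for g in (self.visual_gain, self.attention_gain, self.saccade_gain):
            if g < 0:
                raise ValueError("gains must be >= 0")


@dataclass
class EnsembleSpec:
    """Ensemble with a rank-1 shared latent plus optional per-quadrant
    latents (``quadrant_latent_scale``) that give similarly tuned neurons
    extra common noise — the source of the noise-vs-signal-correlation
    structure."""

    neurons: List[NeuronSpec]
    latent_loadings: Sequence[float] = ()
    independent_noise_scale: float = 0.0
    quadrant_latent_scale: float = 0.0

    def __post_init__(self) -> None:
        if len(self.latent_loadings) == 0:
            self.latent_loadings = [0.0] * len(self.neurons)
        loadings = np.asarray(self.latent_loadings, dtype=float)
        if loadings.shape != (len(self.neurons),):
            raise ValueError("latent_loadings must match the number of neurons")
        if not np.all(np.isfinite(loadings)):
            raise ValueError("latent_loadings must be finite")
        self.latent_loadings = loadings


@dataclass
class DoseEffectSpec:
    """Per-treatment multipliers; empty mappings mean a null (all-ones) effect."""

    attention_gain: Mapping[str, float] = field(default_factory=dict)
    latent_loadings: Mapping[str, float] = field(default_factory=dict)
    hit_probability: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.attention_gain, self.latent_loadings, self.hit_probability):
            if any(v < 0 for v in m.values()):
                raise ValueError("dose-effect multipliers must be >= 0")

    def _get(self, mapping: Mapping[str, float], treatment: str) -> float:
        return float(mapping.get(treatment, 1.0))

    def attention_mult(self, treatment: str) -> float:
        return self._get(self.attention_gain, treatment)

    def latent_mult(self, treatment: str) -> float:
        return self._get(self.latent_loadings, treatment)

    def hit_mult(self, treatment: str) -> float:
        return self._get(self.hit_probability, treatment)


NULL_DOSE_EFFECT = DoseEffectSpec()


# ---------------------------------------------------------------------------
# schedule & dosing arithmetic
# ---------------------------------------------------------------------------


def mg_per_kg(dose_mg: float, weight_kg: float) -> float:
    """Weight-based dose rate, rounded half-up to two decimals."""
    if dose_mg <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    rate = Decimal(str(dose_mg)) / Decimal(str(weight_kg))
    return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def dose_label(dose_mg: float, weight_kg: float) -> str:
    return f"{mg_per_kg(dose_mg, weight_kg):.2f}"


def build_schedule(config: SubjectConfig) -> List[SessionSpec]:
    """Ordered session plan: each dose block flanked by shared placebo blocks.

    For D dose blocks, block b and mg/kg f flanks, the sequence is
    Pb^f (D^b Pb^f)^D, i.e. consecutive blocks share their flanking placebo
    sessions; total sessions = f + D * (b + f).
    """
    treatments: List[str] = []
    doses = list(config.tablet_doses_mg)
    if doses:
        treatments.extend([PLACEBO] * config.flank_placebo_count)
        for dose in doses:
            label = dose_label(dose, config.body_weight_kg)
            treatments.extend([label] * config.sessions_per_dose_block)
            treatments.extend([PLACEBO] * config.flank_placebo_count)
    return [
        SessionSpec(subject_id=config.subject_id, session_index=i, treatment=t)
        for i, t in enumerate(treatments)
    ]


def flanking_placebo_indices(schedule: Sequence[SessionSpec]) -> Dict[str, List[int]]:
    """Map each dose label to the session indices of its flanking placebos.

    Flanks are the placebo runs immediately before and after each block of
    consecutive sessions at that dose.
    """
    out: Dict[str, List[int]] = {}
    n = len(schedule)
    i = 0
    while i < n:
        spec = schedule[i]
        if spec.is_placebo:
            i += 1
            continue
        j = i
        while j < n and schedule[j].treatment == spec.treatment:
            j += 1
        flanks = out.setdefault(spec.treatment, [])
        k = i - 1
        while k >= 0 and schedule[k].is_placebo:
            flanks.append(schedule[k].session_index)
            k -= 1
        k = j
        while k < n and schedule[k].is_placebo:
            flanks.append(schedule[k].session_index)
            k += 1
        i = j
    return {d: sorted(set(ix)) for d, ix in out.items()}


# ---------------------------------------------------------------------------
# behavior simulation
# ---------------------------------------------------------------------------


def _draw_trial_count(model: BehaviorModel, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(model.trials_mean, model.trials_sd)))
    return max(1, n)


def simulate_behavior(
    spec: SessionSpec,
    model: BehaviorModel,
    seed: Union[int, np.random.Generator],
    n_trials: Optional[int] = None,
    hit_prob_multiplier: float = 1.0,
) -> List[TrialRecord]:
    """Draw one session's worth of trials (types, quadrants, outcomes, events)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_trials is None:
        n_trials = _draw_trial_count(model, rng)
    p_hit = min(1.0, model.hit_prob_for(spec.treatment) * hit_prob_multiplier)
    mix = np.asarray(model.error_mix, dtype=float)

    trials: List[TrialRecord] = []
    for idx in range(n_trials):
        trial_type = TRIAL_TYPES[rng.integers(3)]
        quadrant = int(rng.integers(1, 5))
        cue_on = float(PRE_CUE_MS)
        cue_off = cue_on + CUE_DURATION_MS
        stimuli_on = cue_off
        delay = float(rng.integers(DELAY_RANGE_MS[0], DELAY_RANGE_MS[1] + 1))
        change_time = stimuli_on + delay

        if model.policy == "random_response":
            chosen = int(rng.integers(1, 5))
            outcome = "hit" if chosen == quadrant else "saccade_to_distractor"
        else:
            if rng.random() < p_hit:
                outcome = "hit"
            else:
                outcome = ("fixation_break", "saccade_to_distractor", "no_response")[
                    rng.choice(3, p=mix)
                ]

        saccade_time: Optional[float] = None
        lat_lo, lat_hi = SACCADE_LATENCY_RANGE_MS
        if outcome == "hit":
            # hits on pure-distractor trials are correct fixation holds
            if trial_type != "distractor" or model.policy == "random_response":
                saccade_time = change_time + float(rng.uniform(lat_lo, lat_hi))
        elif outcome == "saccade_to_distractor":
            saccade_time = change_time + float(rng.uniform(lat_lo, lat_hi))
        elif outcome == "fixation_break":
            saccade_time = float(rng.uniform(stimuli_on, change_time))

        trials.append(
            TrialRecord(
                trial_index=idx,
                trial_type=trial_type,
                cue_quadrant=quadrant,
                cue_on=cue_on,
                cue_off=cue_off,
                stimuli_on=stimuli_on,
                change_time=change_time,
                saccade_time=saccade_time,
                outcome=outcome,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------


def _rate_segments(
    neuron: NeuronSpec,
    trial: TrialRecord,
    attention_mult: float,
    trial_end: float,
) -> List[tuple]:
    """Piecewise-constant multiplicative gain profile for one trial.

    Returns (start, end, gain) segments covering [0, trial_end).
    """
    events: List[tuple] = []  # (start, end, gain factor), multiplied when overlapping
    pref = neuron.preferred_quadrant
    lat = neuron.response_latency_ms
    if pref is not None:
        if trial.cue_quadrant == pref:
            # transient response to the cue in the RF
            events.append((trial.cue_on + lat, trial.cue_on + lat + VISUAL_RESPONSE_MS,
                           _calibrated_height(neuron.visual_gain)))
            # sustained attentional modulation until the Go signal
            events.append((trial.cue_off + lat, trial.change_time,
                           neuron.attention_gain * attention_mult))
        else:
            # a distractor appears in the RF with the stimulus array
            g = 1.0 + (neuron.visual_gain - 1.0) * neuron.distractor_attenuation
            events.append((trial.stimuli_on + lat, trial.stimuli_on + lat + VISUAL_RESPONSE_MS,
                           max(0.0, _calibrated_height(g))))
        if trial.saccade_time is not None and trial.saccade_endpoint() == pref:
            events.append((trial.saccade_time - 50.0, trial.saccade_time + 50.0,
                           _calibrated_height(neuron.saccade_gain, _SACCADE_ATTENUATION)))

    cuts = {0.0, trial_end}
    for s, e, _ in events:
        cuts.add(min(max(s, 0.0), trial_end))
        cuts.add(min(max(e, 0.0), trial_end))
    edges = sorted(cuts)
    segments = []
    for s, e in zip(edges, edges[1:]):
        if e <= s:
            continue
        gain = 1.0
        mid = 0.5 * (s + e)
        for es, ee, g in events:
            if es <= mid < ee:
                gain *= g
        segments.append((s, e, gain))
    return segments


def _poisson_spikes(
    segments: List[tuple], rate_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw spike times from a piecewise-constant rate (spikes/s)."""
    times: List[np.ndarray] = []
    for s, e, gain in segments:
        rate = gain * rate_scale  # spikes/s
        if rate <= 0:
            continue
        n = rng.poisson(rate * (e - s) / 1000.0)
        if n:
            times.append(rng.uniform(s, e, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def simulate_session(
    spec: SessionSpec,
    ensemble: EnsembleSpec,
    model: BehaviorModel,
    dose_fx: DoseEffectSpec = NULL_DOSE_EFFECT,
    seed: Union[int, np.random.Generator] = 0,
    n_trials: Optional[int] = None,
) -> SessionRecord:
    """Compose behavior and spike generation into one full session.

    Each neuron's rate is its baseline times epoch-dependent gains (applied
    when the cue / attention locus / saccade endpoint falls in its preferred
    quadrant, shifted by its response latency), multiplied by a per-trial
    shared-latent factor ``max(0, 1 + loading * z + s * eps)``.  Dose-effect
    multipliers apply only on treatment sessions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_treatment = not spec.is_placebo
    att_mult = dose_fx.attention_mult(spec.treatment) if is_treatment else 1.0
    lat_mult = dose_fx.latent_mult(spec.treatment) if is_treatment else 1.0
    hit_mult = dose_fx.hit_mult(spec.treatment) if is_treatment else 1.0

    trials = simulate_behavior(spec, model, rng, n_trials=n_trials,
                               hit_prob_multiplier=hit_mult)
    loadings = np.asarray(ensemble.latent_loadings, dtype=float) * lat_mult
    s_ind = ensemble.independent_noise_scale

    spikes: Dict[int, Dict[str, np.ndarray]] = {}
    n_clipped = 0
    for trial in trials:
        trial_end = trial.change_time + RESPONSE_WINDOW_MS + 150.0
        z = rng.standard_normal()
        q_scale = ensemble.quadrant_latent_scale * lat_mult
        zq = rng.standard_normal(4) if q_scale else None
        eps = rng.standard_normal(len(ensemble.neurons)) if s_ind else None
        by_neuron: Dict[str, np.ndarray] = {}
        for i, neuron in enumerate(ensemble.neurons):
            mult = 1.0 + loadings[i] * z
            if zq is not None and neuron.preferred_quadrant is not None:
                mult += q_scale * zq[neuron.preferred_quadrant - 1]
            if eps is not None:
                mult += s_ind * eps[i]
            if mult < 0.0:
                mult = 0.0
                n_clipped += 1
            segments = _rate_segments(neuron, trial, att_mult, trial_end)
            by_neuron[neuron.neuron_id] = _poisson_spikes(
                segments, neuron.baseline_rate * mult, rng
            )
        spikes[trial.trial_index] = by_neuron
    if n_clipped:
        log.info("clipped %d negative trial rate multipliers to 0", n_clipped)

    return SessionRecord(
        subject_id=spec.subject_id,
        session_index=spec.session_index,
        treatment=spec.treatment,
        trials=trials,
        spikes=spikes,
        electrode_map={n.neuron_id: n.electrode_id for n in ensemble.neurons},
    )


def session_rng(master_seed: int, session_index: int) -> np.random.Generator:
    """Per-session substream: master seed + session index."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, session_index]))


def simulate_subject(
    config: SubjectConfig,
    ensemble: EnsembleSpec,
    model: BehaviorModel,
    dose_fx: DoseEffectSpec = NULL_DOSE_EFFECT,
    master_seed: int = 0,
    n_trials: Optional[int] = None,
) -> List[SessionRecord]:
    """Simulate every session of a subject's schedule, one substream each."""
    schedule = build_schedule(config)
    return [
        simulate_session(
            spec, ensemble, model, dose_fx,
            seed=session_rng(master_seed, spec.session_index),
            n_trials=n_trials,
        )
        for spec in schedule
    ]


# ---------------------------------------------------------------------------
# convenience ensemble builders
# ---------------------------------------------------------------------------


def tuned_ensemble(
    n_neurons: int,
    rng: np.random.Generator,
    baseline_range: tuple = (5.0, 25.0),
    visual_gain_range: tuple = (1.5, 3.0),
    attention_gain_range: tuple = (1.2, 2.0),
    saccade_gain_range: tuple = (1.2, 2.5),
    latency_range: tuple = (40.0, 120.0),
    latent_sd: float = 0.2,
    neurons_per_electrode: int = 2,
    untuned_fraction: float = 0.1,
    quadrant_latent_scale: float = 0.15,
) -> EnsembleSpec:
    """Random quadrant-tuned ensemble with signed shared-latent loadings."""
    neurons = []
    for i in range(n_neurons):
        pref: Optional[int] = int(rng.integers(1, 5))
        if rng.random() < untuned_fraction:
            pref = None
        neurons.append(
            NeuronSpec(
                neuron_id=f"n{i:03d}",
                electrode_id=f"e{i // neurons_per_electrode:03d}",
                baseline_rate=float(rng.uniform(*baseline_range)),
                preferred_quadrant=pref,
                visual_gain=float(rng.uniform(*visual_gain_range)),
                attention_gain=float(rng.uniform(*attention_gain_range)),
                saccade_gain=float(rng.uniform(*saccade_gain_range)),
                response_latency_ms=float(rng.uniform(*latency_range)),
            )
        )
    loadings = rng.normal(0.0, latent_sd, size=n_neurons)
    return EnsembleSpec(neurons=neurons, latent_loadings=loadings,
                        quadrant_latent_scale=quadrant_latent_scale)


def expected_pair_noise_r(
    mu1: float, mu2: float, loading1: float, loading2: float
) -> float:
    """Closed-form spike-count correlation for two conditionally-Poisson
    neurons sharing a standard-normal latent via multiplicative loadings
    (clipping ignored; valid for small loadings)."""
    cov = mu1 * mu2 * loading1 * loading2
    var1 = mu1 + (mu1 * loading1) ** 2
    var2 = mu2 + (mu2 * loading2) ** 2
    return cov / np.sqrt(var1 * var2)
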