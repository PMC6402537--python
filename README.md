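# attndose

Analysis pipeline for multielectrode prefrontal recordings from a
four-location covert-attention task run under a placebo-flanked oral dosing
schedule, together with a synthetic-data generator that emulates the task,
the schedule, and the statistical structure of the recordings.  Every
analysis stage is verifiable end to end on generated data: injected "drug"
effects are recovered, and null scenarios stay null.

## What it does

* **synthetic** — dosing schedules (`Pb-Pb-drug-drug-drug-Pb-Pb` blocks with
  shared flanks), weight-based mg/kg conversion, behavioral trial
  simulation (three interleaved trial types, four cue quadrants, outcome
  model with an error taxonomy), and inhomogeneous-Poisson spike trains
  with quadrant tuning, attentional modulation, saccadic responses, and a
  shared trial-wise latent that induces pairwise spike-count correlations.
  Per-dose multipliers can inject effects for power/recovery testing.
* **session_io** — a diffable on-disk session format (JSON manifest +
  trials.csv + long-format spikes.csv) with strict validation.
* **preprocessing** — half-open 1-ms epoch windows (baseline, cue,
  attention, saccade), spike counting, Gaussian-kernel spike density
  functions (SD 30 ms), trial averaging, z-scoring.
* **stats_core** — Kruskal–Wallis, one-way ANOVA with eta-squared,
  Bonferroni, 2x2 chi-square for proportions (no continuity correction),
  Pearson r.
* **selectivity** — per-neuron, per-epoch tuning classification
  (Kruskal–Wallis over quadrants at alpha = 0.01, target trials only).
* **neuron_metrics** — the 19 single-neuron response metrics (visual 1–11,
  attention 12–15, saccade 16–19; "Fano factor" = SD/mean by convention,
  switchable) and the per-metric dose-factor ANOVA scan with Bonferroni
  over metrics x subjects.
* **correlations** — noise correlations (condition-z-scored, pooled,
  same-electrode pairs excluded), signal correlations, sign-split medians
  with percent change from flanking placebos, and the 10-bin
  noise-vs-signal correlation structure with per-bin dose ANOVAs.
* **decoding** — stratified 5-fold linear SVM decoding of cue/attention/
  saccade quadrant, 1000-permutation label nulls, percent change from
  flanking placebo sessions.
* **behavior** — pooled hit rates, chi-square dose-vs-flanking-placebo
  comparisons, impulsivity/distractibility error rates.
* **pipeline / cli** — YAML-configured `simulate` → `analyze` → `report`
  orchestration; subjects are never pooled anywhere.

## CLI

```bash
attndose simulate --config scenario.yaml --out sessions/
attndose analyze  --config scenario.yaml --sessions sessions/ --out report/
attndose report   --out report/
```

A minimal scenario config:

```yaml
master_seed: 7
subjects:
  - subject_id: F
    body_weight_kg: 5.8
    tablet_doses_mg: [2.5, 5, 6.25, 7.5, 10]
    sessions_per_dose_block: 3
    flank_placebo_count: 2
behavior:
  hit_probability: 0.85
  error_mix: [0.5, 0.3, 0.2]
  trials_mean: 817
  trials_sd: 93
ensemble:
  n_neurons: 48
  latent_sd: 0.2
dose_effect: {}          # empty = null effects
analysis:
  folds: 5
  n_perm: 1000
  fano_convention: cv
```

The report bundle contains `metric_dose_scan.csv` (one row per metric per
subject, with uncorrected and Bonferroni-corrected p), per-subject
behavioral summaries and comparisons, pair-level correlation exports,
sign-split and structure-curve CSVs, per-session decoding accuracies and
their flanking-placebo summaries, plus `summary.json`.

## Session format

A session is a directory:

* `manifest.json` — `subject_id`, `session_index`, `treatment` (`placebo`
  or a mg/kg label like `0.86`), `electrode_map` (neuron id → electrode
  id), `n_trials`.
* `trials.csv` — `trial_index, trial_type, cue_quadrant, cue_on, cue_off,
  stimuli_on, change_time, saccade_time, outcome`; times in ms from the
  recording onset (200 ms before cue onset); a missing `saccade_time` is
  an empty field.
* `spikes.csv` — long format `trial_index, neuron_id, electrode_id,
  time_ms`.

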