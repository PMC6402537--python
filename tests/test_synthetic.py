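"""Generator tests: schedule arithmetic, dosing, behavior and spike oracles."""

import numpy as np
import pytest
from scipy import stats

from attndose.core import PLACEBO, SessionSpec
from attndose.preprocessing import CANONICAL_EPOCHS, extract_counts
from attndose.synthetic import (
    BehaviorModel,
    DoseEffectSpec,
    EnsembleSpec,
    NeuronSpec,
    SubjectConfig,
    build_schedule,
    expected_pair_noise_r,
    flanking_placebo_indices,
    mg_per_kg,
    simulate_behavior,
    simulate_session,
    session_rng,
)

from conftest import single_neuron_ensemble


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


class TestBuildSchedule:
    def test_five_dose_design(self):
        config = SubjectConfig("F", 5.8, [2.5, 5, 6.25, 7.5, 10])
        schedule = build_schedule(config)
        assert len(schedule) == 27
        assert sum(not s.is_placebo for s in schedule) == 15
        assert sum(s.is_placebo for s in schedule) == 12

    def test_single_block(self):
        config = SubjectConfig("X", 5.0, [5.0])
        labels = [s.treatment for s in build_schedule(config)]
        assert labels == [PLACEBO, PLACEBO, "1.00", "1.00", "1.00", PLACEBO, PLACEBO]

    def test_empty_dose_list(self):
        assert build_schedule(SubjectConfig("X", 5.0, [])) == []

    @pytest.mark.parametrize("n_doses,block,flank", [(1, 3, 2), (3, 2, 1), (5, 3, 2), (2, 1, 4)])
    def test_length_formula(self, n_doses, block, flank):
        doses = [float(i + 1) for i in range(n_doses)]
        config = SubjectConfig("X", 5.0, doses,
                               sessions_per_dose_block=block,
                               flank_placebo_count=flank)
        schedule = build_schedule(config)
        assert len(schedule) == flank + n_doses * (block + flank)

    def test_every_block_is_flanked(self):
        config = SubjectConfig("F", 5.8, [2.5, 5, 6.25, 7.5, 10])
        schedule = build_schedule(config)
        flanks = flanking_placebo_indices(schedule)
        assert len(flanks) == 5
        for dose, idx in flanks.items():
            assert len(idx) == 4  # 2 before + 2 after, shared with neighbors
            block = [s.session_index for s in schedule if s.treatment == dose]
            assert any(i < min(block) for i in idx)
            assert any(i > max(block) for i in idx)

    def test_session_indices_are_consecutive(self):
        schedule = build_schedule(SubjectConfig("F", 5.8, [2.5, 5]))
        assert [s.session_index for s in schedule] == list(range(len(schedule)))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SubjectConfig("X", -1.0, [5.0])
        with pytest.raises(ValueError):
            SubjectConfig("X", 5.0, [5.0, 5.0])


class TestMgPerKg:
    def test_printed_tables(self):
        doses = [2.5, 5, 6.25, 7.5, 10]
        assert [mg_per_kg(d, 5.8) for d in doses] == [0.43, 0.86, 1.08, 1.29, 1.72]
        assert [mg_per_kg(d, 7.5) for d in doses] == [0.33, 0.67, 0.83, 1.00, 1.33]

    def test_dose_equals_weight(self):
        for x in (0.5, 1.0, 7.3):
            assert mg_per_kg(x, x) == 1.00

    def test_half_up_rounding(self):
        assert mg_per_kg(1.25, 10.0) == 0.13  # 0.125 rounds up

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mg_per_kg(0, 5.0)
        with pytest.raises(ValueError):
            mg_per_kg(5.0, -1)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


class TestSimulateBehavior:
    def test_all_hits_when_p_is_one(self, placebo_spec):
        model = BehaviorModel(hit_probability=1.0)
        trials = simulate_behavior(placebo_spec, model, seed=0, n_trials=200)
        assert all(t.outcome == "hit" for t in trials)

    def test_hit_rate_within_binomial_se(self, placebo_spec):
        p, n = 0.8, 10_000
        model = BehaviorModel(hit_probability=p)
        trials = simulate_behavior(placebo_spec, model, seed=1, n_trials=n)
        rate = np.mean([t.outcome == "hit" for t in trials])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se

    def test_random_response_policy_is_chance(self, placebo_spec):
        model = BehaviorModel(policy="random_response")
        trials = simulate_behavior(placebo_spec, model, seed=2, n_trials=10_000)
        rate = np.mean([t.outcome == "hit" for t in trials])
        assert abs(rate - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_task_timing(self, placebo_spec):
        trials = simulate_behavior(placebo_spec, BehaviorModel(), seed=3, n_trials=500)
        for t in trials:
            assert t.cue_off - t.cue_on == 363
            assert t.stimuli_on == t.cue_off
            assert 585 <= t.change_time - t.stimuli_on <= 1755
            if t.saccade_time is not None and t.outcome != "fixation_break":
                assert 0 < t.saccade_time - t.change_time <= 250

    def test_types_and_quadrants_roughly_uniform(self, placebo_spec):
        trials = simulate_behavior(placebo_spec, BehaviorModel(), seed=4, n_trials=9000)
        type_counts = np.array([
            sum(t.trial_type == tt for t in trials)
            for tt in ("target", "distractor", "target+distractor")
        ])
        assert stats.chisquare(type_counts).pvalue > 1e-4
        quad_counts = np.array([sum(t.cue_quadrant == q for t in trials)
                                for q in (1, 2, 3, 4)])
        assert stats.chisquare(quad_counts).pvalue > 1e-4

    def test_error_mix_validation(self):
        with pytest.raises(ValueError):
            BehaviorModel(error_mix=(0.5, 0.5, 0.5))


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


class TestSimulateSession:
    def test_reproducible_under_fixed_seed(self, placebo_spec, small_ensemble):
        from attndose.session_io import sessions_equal

        a = simulate_session(placebo_spec, small_ensemble, BehaviorModel(),
                             seed=42, n_trials=50)
        b = simulate_session(placebo_spec, small_ensemble, BehaviorModel(),
                             seed=42, n_trials=50)
        assert sessions_equal(a, b)

    def test_independent_neurons_uncorrelated(self, placebo_spec):
        neurons = [
            NeuronSpec(f"n{i}", f"e{i}", baseline_rate=20.0, preferred_quadrant=None)
            for i in range(6)
        ]
        ensemble = EnsembleSpec(neurons=neurons)
        session = simulate_session(placebo_spec, ensemble, BehaviorModel(),
                                   seed=5, n_trials=1200)
        counts = extract_counts(session, CANONICAL_EPOCHS["attention"]).counts
        r = np.corrcoef(counts.T)
        off_diag = r[np.triu_indices_from(r, k=1)]
        assert abs(np.mean(off_diag)) < 0.02

    def test_latent_correlation_matches_closed_form(self, placebo_spec):
        # two neurons, equal loadings, counts over the 400-ms attention window
        lam = 0.25
        mu_rate = 30.0
        neurons = [
            NeuronSpec("a", "e0", baseline_rate=mu_rate, preferred_quadrant=None),
            NeuronSpec("b", "e1", baseline_rate=mu_rate, preferred_quadrant=None),
        ]
        ensemble = EnsembleSpec(neurons=neurons, latent_loadings=[lam, lam])
        session = simulate_session(placebo_spec, ensemble, BehaviorModel(),
                                   seed=6, n_trials=2500)
        counts = extract_counts(session, CANONICAL_EPOCHS["attention"]).counts
        observed = np.corrcoef(counts[:, 0], counts[:, 1])[0, 1]
        mu = mu_rate * 0.4  # expected count in the 400-ms window
        expected = expected_pair_noise_r(mu, mu, lam, lam)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_closed_form_against_brute_force(self, rng):
        # independent verification of the oracle itself, no spike machinery
        mu, lam = 12.0, 0.25
        z = rng.standard_normal(300_000)
        m = np.clip(1 + lam * z, 0, None)
        x = rng.poisson(mu * m)
        y = rng.poisson(mu * m)
        brute = np.corrcoef(x, y)[0, 1]
        assert expected_pair_noise_r(mu, mu, lam, lam) == pytest.approx(brute, abs=0.01)

    def test_poisson_counts_without_latent(self, placebo_spec):
        ensemble = single_neuron_ensemble(baseline=25.0)
        session = simulate_session(placebo_spec, ensemble, BehaviorModel(),
                                   seed=8, n_trials=2000)
        counts = extract_counts(session, CANONICAL_EPOCHS["baseline"]).counts[:, 0]
        fano = counts.var(ddof=1) / counts.mean()
        # variance/mean of a Poisson sample: SE ~ sqrt(2/n)
        assert abs(fano - 1.0) < 4 * np.sqrt(2 / counts.size)

    def test_null_dose_effect_distribution_invariance(self, small_ensemble):
        model = BehaviorModel()
        pb = simulate_session(SessionSpec("S", 0, "placebo"), small_ensemble,
                              model, seed=9, n_trials=600)
        drug = simulate_session(SessionSpec("S", 1, "0.86"), small_ensemble,
                                model, DoseEffectSpec(), seed=10, n_trials=600)
        counts_pb = extract_counts(pb, CANONICAL_EPOCHS["attention"]).counts
        counts_dr = extract_counts(drug, CANONICAL_EPOCHS["attention"]).counts
        ks = stats.ks_2samp(counts_pb.sum(axis=1), counts_dr.sum(axis=1))
        assert ks.pvalue > 0.001

    def test_attention_dose_multiplier_scales_delay_rate(self, placebo_spec):
        fx = DoseEffectSpec(attention_gain={"0.86": 2.0})
        ensemble = single_neuron_ensemble(baseline=20.0, attention_gain=1.5,
                                          preferred=1, latency=50.0)
        drug_spec = SessionSpec("S", 1, "0.86")
        pb = simulate_session(placebo_spec, ensemble, BehaviorModel(), fx,
                              seed=11, n_trials=1200)
        drug = simulate_session(drug_spec, ensemble, BehaviorModel(), fx,
                                seed=11, n_trials=1200)

        def attend_in_rate(session):
            trials = [t for t in session.trials if t.cue_quadrant == 1]
            cm = extract_counts(session, CANONICAL_EPOCHS["attention"], trials=trials)
            return cm.counts[:, 0].mean()

        ratio = attend_in_rate(drug) / attend_in_rate(pb)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_session_rng_substreams_differ(self):
        a = session_rng(1, 0).integers(0, 2**31, 10)
        b = session_rng(1, 1).integers(0, 2**31, 10)
        assert not np.array_equal(a, b)
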