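"""Residual t statistics and the iterative biased-symptom selection."""

import numpy as np
import pytest

from vacsmf import (
    CSMFVector,
    DataError,
    EstimatorConfig,
    SimulationDesign,
    SymptomDataset,
    predicted_symptom_prevalence,
    residual_t_statistics,
    select_biased_symptoms,
    simulate_design,
    table2_misreports,
)
from vacsmf.bias_detection import bonferroni_critical_value


def _community_with_prevalence(prev: np.ndarray, n: int = 1000) -> SymptomDataset:
    """Deterministic dataset whose column means equal ``prev`` exactly."""
    cols = [
        np.concatenate([np.ones(round(p * n)), np.zeros(n - round(p * n))])
        for p in prev
    ]
    return SymptomDataset(
        np.column_stack(cols).astype(int), [f"s{i + 1}" for i in range(len(prev))]
    )


class TestPredictedPrevalence:
    def test_point_mass_returns_cause_prevalence(self, tiny_hospital):
        csmf = CSMFVector(np.array([0.0, 1.0]), ["a", "b"])
        pred = predicted_symptom_prevalence(csmf, tiny_hospital)
        np.testing.assert_allclose(pred, [1.0, 1.0])  # cause b records are 11, 11

    def test_even_mixture_averages(self, tiny_hospital):
        csmf = CSMFVector(np.array([0.5, 0.5]), ["a", "b"])
        pred = predicted_symptom_prevalence(csmf, tiny_hospital)
        # cause a prevalences (0, 0.5); cause b (1, 1)
        np.testing.assert_allclose(pred, [0.5, 0.75])

    def test_unbiased_simulation_predictions_track_observed(self, fast_config):
        design = SimulationDesign(
            n_causes=5, n_symptoms=12, n_hospital=4000, n_community=4000,
            case_control=True, s_max=0.9,
            community_csmf=CSMFVector(
                np.array([0.4, 0.25, 0.15, 0.1, 0.1]), [f"cause_{i+1}" for i in range(5)]
            ),
        )
        study = simulate_design(design, 3)
        from vacsmf import estimate_csmf

        est = estimate_csmf(study.hospital, study.community, fast_config)
        pred = predicted_symptom_prevalence(est.point, study.hospital)
        observed = study.community.symptoms.mean(axis=0)
        assert np.abs(pred - observed).max() < 0.04


class TestResidualTStats:
    def test_hand_computation(self):
        community = _community_with_prevalence(np.array([0.6, 0.4]))
        predicted = np.array([0.5, 0.5])  # residuals (0.1, -0.1)
        ts = residual_t_statistics(community, predicted)
        assert ts.df == 1
        np.testing.assert_allclose(ts.sigma_hat, np.sqrt(0.02), atol=1e-12)
        np.testing.assert_allclose(ts.t_stats, [0.7071, -0.7071], atol=1e-4)

    def test_perfect_fit_is_degenerate(self):
        community = _community_with_prevalence(np.array([0.3, 0.7, 0.5]))
        ts = residual_t_statistics(community, np.array([0.3, 0.7, 0.5]))
        assert ts.degenerate and np.all(ts.t_stats == 0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        prev = rng.uniform(0.2, 0.8, 6)
        predicted = rng.uniform(0.2, 0.8, 6)
        community = _community_with_prevalence(prev)
        ts = residual_t_statistics(community, predicted)
        perm = rng.permutation(6)
        community_p = SymptomDataset(
            community.symptoms[:, perm], [community.symptom_names[i] for i in perm]
        )
        ts_p = residual_t_statistics(community_p, predicted[perm])
        np.testing.assert_allclose(ts_p.t_stats, ts.t_stats[perm], atol=1e-12)

    def test_needs_two_symptoms(self):
        community = _community_with_prevalence(np.array([0.5]))
        with pytest.raises(DataError):
            residual_t_statistics(community, np.array([0.5]))


class TestSelection:
    def test_bonferroni_critical_value_grows_with_tests(self):
        c1 = bonferroni_critical_value(0.05, 1, 19)
        c3 = bonferroni_critical_value(0.05, 3, 19)
        assert c3 > c1 > 1.9

    def test_removes_planted_misreported_symptoms(self):
        design = SimulationDesign(
            n_causes=10, n_symptoms=20, n_hospital=2000, n_community=2000,
            case_control=True, misreports=table2_misreports(3, 20),
        )
        study = simulate_design(design, 5)
        sel = select_biased_symptoms(
            study.hospital, study.community, alpha=0.05,
            config=EstimatorConfig(subset_size=6, n_subsets=80, seed=5),
        )
        assert set(sel.removed_names) == {"s1", "s5", "s10"}
        assert sel.stopped_reason == "no symptom exceeds the critical value"

    def test_bookkeeping_partition_and_trace(self):
        design = SimulationDesign(
            n_causes=10, n_symptoms=15, n_hospital=1200, n_community=1200,
            case_control=True, misreports=table2_misreports(3, 15),
        )
        study = simulate_design(design, 9)
        sel = select_biased_symptoms(
            study.hospital, study.community, alpha=0.05,
            config=EstimatorConfig(subset_size=6, n_subsets=60, seed=9),
        )
        assert len(sel.removed) + len(sel.final_symptom_set) == 15
        assert not set(sel.removed_names) & set(sel.final_symptom_set)
        # one CSMF estimate per iteration, including the stopping iteration
        assert len(sel.per_iteration_csmf) == len(sel.removed) + 1
        # removals recorded with exceeding t values
        for _, _, t, crit in sel.removed:
            assert abs(t) > crit

    def test_max_removals_cap_and_floor(self):
        design = SimulationDesign(
            n_causes=10, n_symptoms=12, n_hospital=800, n_community=800,
            case_control=True, misreports=table2_misreports(3, 12),
        )
        study = simulate_design(design, 1)
        sel = select_biased_symptoms(
            study.hospital, study.community, alpha=0.5,
            config=EstimatorConfig(subset_size=5, n_subsets=40, seed=1),
            max_removals=2,
        )
        assert sel.n_removed <= 2
        sel_floor = select_biased_symptoms(
            study.hospital, study.community, alpha=0.5,
            config=EstimatorConfig(subset_size=5, n_subsets=40, seed=1),
            min_symptoms=10,
        )
        assert len(sel_floor.final_symptom_set) >= 9

    def test_alpha_validation(self, bernoulli_pair):
        _, _, hospital, community = bernoulli_pair
        with pytest.raises(DataError):
            select_biased_symptoms(hospital, community, alpha=0.7)
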