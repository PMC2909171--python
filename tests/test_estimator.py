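"""Simplex-constrained LS solver, subset-averaged CSMF estimation,
stratified adjustment and individual classification."""

import numpy as np
import pytest

from vacsmf import (
    CSMFVector,
    DataError,
    EstimatorConfig,
    SymptomDataset,
    SymptomModel,
    classify_individual,
    estimate_csmf,
    profile_marginal,
    simulate_deaths,
    solve_simplex_ls,
    stratified_estimate_csmf,
)
from vacsmf.data_model import ConditionalProfileMatrix, ProfileDistribution
from vacsmf.estimator import _solve_simplex_ls_raw


def simplex_grid(j: int, step: float = 0.001) -> np.ndarray:
    """All points of the probability simplex on a regular grid (oracle)."""
    m = round(1 / step)
    if j == 2:
        a = np.arange(m + 1) / m
        return np.column_stack([a, 1 - a])
    if j == 3:
        pts = []
        for i in range(m + 1):
            k = np.arange(m - i + 1)
            pts.append(np.column_stack([np.full(k.size, i), k, m - i - k]))
        return np.vstack(pts) / m
    raise NotImplementedError


def grid_search_objective(a: np.ndarray, b: np.ndarray, step=0.001) -> float:
    """Brute-force minimum of ||b - a beta||^2 over the simplex grid."""
    g = simplex_grid(a.shape[1], step)
    r = g @ a.T - b
    return float(np.min(np.einsum("ij,ij->i", r, r)))


class TestSolveSimplexLS:
    def test_exactly_solvable_two_columns(self):
        sub = np.array([0, 1])
        m = ConditionalProfileMatrix(
            sub, np.array([[1.0, 0.0], [0, 0], [0, 0], [0, 1.0]]), ["a", "b"]
        )
        p = ProfileDistribution(sub, np.array([0.3, 0, 0, 0.7]))
        beta = solve_simplex_ls(p, m)
        np.testing.assert_allclose(beta.fractions, [0.3, 0.7], atol=1e-7)

    def test_single_cause_returns_unity(self):
        sub = np.array([0])
        m = ConditionalProfileMatrix(sub, np.array([[0.4], [0.6]]), ["only"])
        p = ProfileDistribution(sub, np.array([0.9, 0.1]))
        assert solve_simplex_ls(p, m).fractions.tolist() == [1.0]

    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(5)
        a = rng.dirichlet(np.ones(8), size=3).T  # 8 x 3 column-stochastic
        truth = np.array([0.2, 0.3, 0.5])
        beta, _ = _solve_simplex_ls_raw(a @ truth, a)
        np.testing.assert_allclose(beta, truth, atol=1e-6)
        # objective can be no worse than the brute-force grid optimum
        assert np.sum((a @ beta - a @ truth) ** 2) <= grid_search_objective(
            a, a @ truth
        ) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(DataError):
            _solve_simplex_ls_raw(np.ones(3), np.ones((4, 2)))

    def test_rank_deficient_still_feasible(self):
        a = np.column_stack([np.full(4, 0.25)] * 3)  # identical columns
        beta, _ = _solve_simplex_ls_raw(np.full(4, 0.25), a)
        assert beta.min() >= 0 and abs(beta.sum() - 1) < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = rng.integers(2, 4)
        b_bits = rng.integers(2, 5)
        a = rng.dirichlet(np.ones(2**b_bits), size=j).T
        target = rng.dirichlet(np.ones(2**b_bits))
        beta, _ = _solve_simplex_ls_raw(target, a)
        obj = np.sum((a @ beta - target) ** 2)
        oracle = grid_search_objective(a, target)
        # grid resolution: the optimum can beat the grid, never trail it by
        # more than the grid spacing allows
        assert obj <= oracle + 1e-10
        assert obj >= oracle - 2 * j * 0.001


class TestEstimateCSMF:
    def test_noiseless_back_calculation(self):
        # community profile distribution constructed analytically from the
        # hospital conditionals: the linear identity holds without error
        rng = np.random.default_rng(11)
        sub = np.arange(4)
        m = ConditionalProfileMatrix(
            sub, rng.dirichlet(np.ones(16), size=3).T, list("abc")
        )
        truth = np.array([0.5, 0.3, 0.2])
        p = ProfileDistribution(sub, m.matrix @ truth)
        est = solve_simplex_ls(p, m)
        np.testing.assert_allclose(est.fractions, truth, atol=1e-6)

    def test_self_consistency_hospital_as_community(self, bernoulli_pair, fast_config):
        _, _, hospital, _ = bernoulli_pair
        est = estimate_csmf(hospital, hospital.drop_cause_labels(), fast_config)
        empirical = np.bincount(hospital.cause_labels, minlength=5) / hospital.n
        assert np.abs(est.point.fractions - empirical).max() < 0.03

    def test_point_is_renormalized_mean_of_subsets(self, bernoulli_pair, fast_config):
        _, _, hospital, community = bernoulli_pair
        est = estimate_csmf(hospital, community, fast_config)
        mean = est.per_subset_estimates.mean(axis=0)
        np.testing.assert_allclose(est.point.fractions, mean / mean.sum(), atol=1e-9)
        assert est.point.fractions.min() >= 0
        assert abs(est.point.fractions.sum() - 1) < 1e-8

    def test_recovers_community_csmf_not_hospital(self, fast_config):
        # case-control hospital (uniform mix) must not drag the estimate away
        # from a very non-uniform community truth
        rng = np.random.default_rng(17)
        j, k = 4, 14
        model = SymptomModel(
            rng.uniform(0.05, 0.95, (j, k)),
            [f"c{i}" for i in range(j)],
            [f"s{i + 1}" for i in range(k)],
        )
        truth = CSMFVector(np.array([0.55, 0.25, 0.15, 0.05]), model.cause_names)
        hospital = simulate_deaths(model, truth, 2400, True, rng)  # uniform counts
        community = simulate_deaths(model, truth, 2400, False, rng).drop_cause_labels()
        est = estimate_csmf(hospital, community, fast_config)
        assert np.abs(est.point.fractions - truth.fractions).max() < 0.06
        # decisively closer to the community mix than to the hospital's
        assert np.abs(est.point.fractions - truth.fractions).sum() < 0.5 * np.abs(
            np.full(j, 0.25) - truth.fractions
        ).sum()

    def test_symptom_name_mismatch_raises(self, bernoulli_pair, fast_config):
        _, _, hospital, community = bernoulli_pair
        other = SymptomDataset(
            community.symptoms, [f"x{i}" for i in range(community.n_symptoms)]
        )
        with pytest.raises(DataError, match="symptom names"):
            estimate_csmf(hospital, other, fast_config)

    def test_bootstrap_standard_errors(self, bernoulli_pair):
        _, _, hospital, community = bernoulli_pair
        cfg = EstimatorConfig(subset_size=5, n_subsets=20, seed=1, bootstrap_reps=8)
        est = estimate_csmf(hospital, community, cfg)
        assert est.standard_errors.shape == (5,)
        assert (est.standard_errors >= 0).all()
        assert est.standard_errors.max() < 0.2


class TestStratifiedEstimate:
    @staticmethod
    def _two_stratum_data(rng, oversample_child=True, distinct=True):
        j, k = 3, 10
        names = [f"c{i}" for i in range(j)]
        snames = [f"s{i + 1}" for i in range(k)]
        p_adult = rng.uniform(0.1, 0.9, (j, k))
        p_child = rng.uniform(0.1, 0.9, (j, k)) if distinct else p_adult
        m_adult = SymptomModel(p_adult, names, snames)
        m_child = SymptomModel(p_child, names, snames)
        csmf = CSMFVector(np.array([0.5, 0.3, 0.2]), names)
        # community: 70% adult, 30% child
        ca = simulate_deaths(m_adult, csmf, 1400, False, rng)
        cc = simulate_deaths(m_child, csmf, 600, False, rng)
        community = SymptomDataset(
            np.vstack([ca.symptoms, cc.symptoms]), snames,
            stratum_labels=np.array(["adult"] * 1400 + ["child"] * 600),
        )
        # hospital: oversamples children (30/70 instead of 70/30)
        n_a, n_c = (600, 1400) if oversample_child else (1400, 600)
        ha = simulate_deaths(m_adult, csmf, n_a, False, rng)
        hc = simulate_deaths(m_child, csmf, n_c, False, rng)
        hospital = SymptomDataset(
            np.vstack([ha.symptoms, hc.symptoms]), snames,
            np.concatenate([ha.cause_labels, hc.cause_labels]),
            names,
            np.array(["adult"] * n_a + ["child"] * n_c),
        )
        return hospital, community, csmf

    def test_single_stratum_weight_one_matches_unstratified(
        self, bernoulli_pair, fast_config
    ):
        _, _, hospital, community = bernoulli_pair
        hospital = SymptomDataset(
            hospital.symptoms, hospital.symptom_names, hospital.cause_labels,
            hospital.cause_names, np.array(["all"] * hospital.n),
        )
        plain = estimate_csmf(hospital, community, fast_config)
        strat = stratified_estimate_csmf(hospital, community, {"all": 1.0}, fast_config)
        np.testing.assert_allclose(
            plain.point.fractions, strat.point.fractions, atol=1e-12
        )

    def test_identical_strata_models_are_invariant(self, fast_config):
        rng = np.random.default_rng(23)
        hospital, community, _ = self._two_stratum_data(rng, distinct=False)
        plain = estimate_csmf(hospital, community, fast_config)
        strat = stratified_estimate_csmf(
            hospital, community, {"adult": 0.5, "child": 0.5}, fast_config
        )
        assert np.abs(plain.point.fractions - strat.point.fractions).max() < 0.02

    def test_stratification_reduces_bias_under_oversampling(self, fast_config):
        errs_plain, errs_strat = [], []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            hospital, community, csmf = self._two_stratum_data(rng)
            plain = estimate_csmf(hospital, community, fast_config)
            strat = stratified_estimate_csmf(
                hospital, community, {"adult": 0.7, "child": 0.3}, fast_config
            )
            errs_plain.append(np.abs(plain.point.fractions - csmf.fractions).mean())
            errs_strat.append(np.abs(strat.point.fractions - csmf.fractions).mean())
        assert np.mean(errs_strat) < np.mean(errs_plain)

    def test_unknown_stratum_and_bad_weights_raise(self, fast_config):
        rng = np.random.default_rng(29)
        hospital, community, _ = self._two_stratum_data(rng)
        with pytest.raises(DataError, match="absent"):
            stratified_estimate_csmf(
                hospital, community, {"adult": 0.5, "elder": 0.5}, fast_config
            )
        with pytest.raises(DataError, match="sum"):
            stratified_estimate_csmf(
                hospital, community, {"adult": 0.5, "child": 0.4}, fast_config
            )


class TestClassifyIndividual:
    def test_hand_computable_posterior(self):
        # q1 = (0.9, 0.9), q2 = (0.1, 0.1), uniform prior, profile (1, 1):
        # posterior = (0.81, 0.01) / 0.82
        x1 = np.array([[1, 1]] * 9 + [[0, 0]])
        x2 = np.array([[0, 0]] * 9 + [[1, 1]])
        hospital = SymptomDataset(
            np.vstack([x1, x2]), ["s1", "s2"],
            np.array([0] * 10 + [1] * 10), ["a", "b"],
        )
        csmf = CSMFVector(np.array([0.5, 0.5]), ["a", "b"])
        post = classify_individual([1, 1], hospital, csmf)
        np.testing.assert_allclose(post, [0.81 / 0.82, 0.01 / 0.82], atol=1e-10)

    def test_point_mass_prior_dominates(self, tiny_hospital):
        csmf = CSMFVector(np.array([1.0, 0.0]), ["a", "b"])
        post = classify_individual([0, 1], tiny_hospital, csmf)
        np.testing.assert_allclose(post, [1.0, 0.0], atol=1e-12)

    def test_mean_posterior_on_true_cause_beats_chance(self, bernoulli_pair, fast_config):
        _, csmf, hospital, community = bernoulli_pair
        est = estimate_csmf(hospital, community, fast_config)
        rng = np.random.default_rng(31)
        idx = rng.choice(hospital.n, 60, replace=False)
        hits = [
            classify_individual(hospital.symptoms[i], hospital, est.point)[
                hospital.cause_labels[i]
            ]
            for i in idx
        ]
        assert np.mean(hits) > 1.0 / 5

    def test_profile_marginal_matches_count(self, tiny_hospital):
        assert profile_marginal([1, 1], tiny_hospital) == 0.5
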