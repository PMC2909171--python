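"""Iterative detection of symptoms that violate the hospital/community assumption.

The estimator assumes the distribution of symptom profiles given cause is the
same in the hospital and community samples.  A symptom reported with different
frequency in the two samples for the same causes of death ("misreported")
violates this and biases the CSMF estimate.  Such a symptom shows up as an
outlier when the community marginal prevalence of each symptom is compared
with its value predicted from the hospital conditionals and the estimated
CSMF:

    e_k = P(S_k) - sum_j P^h(S_k = 1 | D = j) * P_hat(D = j)

Under the assumption each residual is mean zero; the studentized residual
t_k = e_k / sigma_hat (sigma_hat the residual root-mean-square with K0 - 1
degrees of freedom) is referred to a t distribution.  The selection procedure
repeatedly removes the symptom with the largest |t_k| while it exceeds a
Bonferroni-adjusted critical value, re-estimating the CSMF without the removed
symptoms at each step, and stops when no symptom is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import CSMFVector, DataError, SymptomDataset
from .estimator import CSMFEstimate, EstimatorConfig, estimate_csmf

__all__ = [
    "SymptomTestStats",
    "BiasSelectionResult",
    "predicted_symptom_prevalence",
    "residual_t_statistics",
    "select_biased_symptoms",
]


@dataclass
class SymptomTestStats:
    """Residual t statistics for the active symptoms of one iteration."""

    active_symptoms: np.ndarray
    observed_prevalence: np.ndarray
    predicted_prevalence: np.ndarray
    residuals: np.ndarray
    sigma_hat: float
    t_stats: np.ndarray
    df: int
    degenerate: bool = False  # all residuals exactly zero

    def __post_init__(self) -> None:
        if self.df < 1:
            raise DataError("residual t statistics require at least 2 active symptoms")


@dataclass
class BiasSelectionResult:
    """Outcome of the iterative symptom-selection procedure.

    ``removed`` lists (symptom name, iteration, t statistic, critical value)
    in removal order; ``per_iteration_csmf`` holds the CSMF estimated at the
    *start* of each iteration (index 0 = all symptoms), so entry i is the
    estimate after i removals.
    """

    removed: list[tuple[str, int, float, float]]
    final_symptom_set: list[str]
    per_iteration_csmf: list[CSMFVector]
    per_iteration_stats: list[SymptomTestStats]
    alpha: float
    stopped_reason: str

    @property
    def removed_names(self) -> list[str]:
        return [name for name, *_ in self.removed]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def predicted_symptom_prevalence(
    csmf: CSMFVector,
    hospital: SymptomDataset,
    active_symptoms: Sequence[int] | None = None,
) -> np.ndarray:
    """Predicted community marginal prevalence of each active symptom.

    Mixture of the hospital per-cause symptom prevalences under the estimated
    CSMF: sum_j P^h(S_k = 1 | D = j) * csmf_j.
    """
    if hospital.cause_labels is None:
        raise DataError("predicted prevalence requires cause-labelled hospital data")
    active = (
        np.arange(hospital.n_symptoms)
        if active_symptoms is None
        else np.asarray(active_symptoms, dtype=np.int64)
    )
    j_count = len(hospital.cause_names)
    counts = np.bincount(hospital.cause_labels, minlength=j_count)
    if (counts == 0).any():
        empty = [hospital.cause_names[j] for j in np.flatnonzero(counts == 0)]
        raise DataError(f"causes with zero hospital records: {empty}")
    # per-cause symptom prevalence matrix (J, K0)
    sums = np.zeros((j_count, active.size))
    np.add.at(sums, hospital.cause_labels, hospital.symptoms[:, active].astype(float))
    q = sums / counts[:, None]
    return csmf.fractions @ q


def residual_t_statistics(
    community: SymptomDataset,
    predicted: np.ndarray,
    active_symptoms: Sequence[int] | None = None,
) -> SymptomTestStats:
    """Studentized prevalence residuals over the active symptoms."""
    active = (
        np.arange(community.n_symptoms)
        if active_symptoms is None
        else np.asarray(active_symptoms, dtype=np.int64)
    )
    k0 = active.size
    if k0 < 2:
        raise DataError("residual t statistics require at least 2 active symptoms")
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != (k0,):
        raise DataError("predicted prevalence length must match active symptoms")
    observed = community.symptoms[:, active].mean(axis=0)
    residuals = observed - predicted
    df = k0 - 1
    sigma_hat = float(np.sqrt(np.sum(residuals**2) / df))
    if sigma_hat == 0.0:
        return SymptomTestStats(
            active, observed, predicted, residuals, 0.0,
            np.zeros(k0), df, degenerate=True,
        )
    return SymptomTestStats(
        active, observed, predicted, residuals, sigma_hat, residuals / sigma_hat, df
    )


def bonferroni_critical_value(alpha: float, n_tests: int, df: int) -> float:
    """Two-sided t critical value at familywise level alpha over n_tests tests."""
    return float(stats.t.ppf(1.0 - alpha / (2.0 * n_tests), df))


def select_biased_symptoms(
    hospital: SymptomDataset,
    community: SymptomDataset,
    alpha: float = 0.05,
    config: EstimatorConfig | None = None,
    min_symptoms: int = 3,
    max_removals: int | None = None,
) -> BiasSelectionResult:
    """Iteratively remove symptoms with outlying prevalence residuals.

    Each iteration estimates the CSMF on the active symptoms, computes the
    residual t statistics, and compares the largest |t_k| with the two-sided
    t critical value at level ``alpha / m`` where m counts the symptoms
    already removed plus the one under test (sequential Bonferroni).  If it
    exceeds the critical value the symptom is removed and the procedure
    repeats; otherwise it stops.  Per-iteration CSMF estimates are recorded so
    the error-versus-removals trace can be examined when the truth is known.

    ``min_symptoms`` is a floor on the retained set (estimation degenerates
    with too few symptoms); ``max_removals`` optionally caps the number of
    removals, used when tracing deliberately past the stopping point.
    """
    if not (0.0 < alpha <= 0.5):
        raise DataError("alpha must be in (0, 0.5]")
    if hospital.n_symptoms < 3:
        raise DataError("bias detection requires at least 3 symptoms")
    config = config or EstimatorConfig()

    active = list(range(hospital.n_symptoms))
    removed: list[tuple[str, int, float, float]] = []
    per_iter_csmf: list[CSMFVector] = []
    per_iter_stats: list[SymptomTestStats] = []
    reason = ""
    iteration = 0
    while True:
        # fresh, reproducible subset-draw stream per iteration
        iter_config = EstimatorConfig(
            subset_size=config.subset_size,
            n_subsets=config.n_subsets,
            seed=np.random.SeedSequence((config.seed, iteration)).generate_state(1)[0]
            % (2**31),
            solver_tolerance=config.solver_tolerance,
            bootstrap_reps=0,
        )
        try:
            est: CSMFEstimate = estimate_csmf(
                hospital, community, iter_config, active_symptoms=active
            )
        except DataError as err:
            reason = f"estimator failure at iteration {iteration}: {err}"
            break
        per_iter_csmf.append(est.point)
        predicted = predicted_symptom_prevalence(est.point, hospital, active)
        ts = residual_t_statistics(community, predicted, active)
        per_iter_stats.append(ts)
        if ts.degenerate:
            reason = "all residuals zero"
            break
        m = len(removed) + 1
        crit = bonferroni_critical_value(alpha, m, ts.df)
        worst = int(np.argmax(np.abs(ts.t_stats)))
        t_worst = float(ts.t_stats[worst])
        if abs(t_worst) <= crit:
            reason = "no symptom exceeds the critical value"
            break
        name = hospital.symptom_names[active[worst]]
        removed.append((name, iteration, t_worst, crit))
        del active[worst]
        iteration += 1
        if len(active) < max(min_symptoms, 2):
            reason = "floor reached"
            break
        if max_removals is not None and len(removed) >= max_removals:
            reason = "max removals reached"
            break

    return BiasSelectionResult(
        removed=removed,
        final_symptom_set=[hospital.symptom_names[i] for i in active],
        per_iteration_csmf=per_iter_csmf,
        per_iteration_stats=per_iter_stats,
        alpha=alpha,
        stopped_reason=reason,
    )
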