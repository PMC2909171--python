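"""CSMF estimation by simplex-constrained least squares over random symptom subsets.

The estimator solves, for each random subset of B symptoms,

    min_beta || P(S) - P^h(S|D) beta ||^2   s.t.  beta >= 0,  sum(beta) = 1,

where P(S) is tabulated from the community sample and P^h(S|D) from the
hospital sample, and averages the per-subset solutions.  Because the linear
identity P(S) = P(S|D) P(D) holds for any subset of symptoms, averaging over
many subsets uses the full questionnaire without enumerating all 2^K profiles.

The quadratic program is solved as nonnegative least squares on an augmented
system carrying the sum-to-one constraint as a heavily weighted row; the
solution is renormalized onto the simplex.  An oracle-equivalence test against
brute-force grid search over the simplex guards this formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .data_model import (
    CSMFVector,
    ConditionalProfileMatrix,
    DataError,
    ProfileDistribution,
    SymptomDataset,
    estimate_conditional_profiles,
    tabulate_profiles,
)

__all__ = [
    "EstimatorConfig",
    "CSMFEstimate",
    "solve_simplex_ls",
    "estimate_csmf",
    "stratified_estimate_csmf",
    "classify_individual",
]

# weight on the sum-to-one row of the augmented NNLS system; large relative to
# the unit-scale profile rows so the equality constraint binds to ~1e-8
_SUM_ROW_WEIGHT = 1e4


@dataclass
class EstimatorConfig:
    """Settings for the subset-averaged estimator.

    subset_size : number of symptoms B per random draw (2^B profile cells).
    n_subsets   : number of independent subset draws averaged.
    seed        : master seed for the subset-draw stream.
    solver_tolerance : numerical tolerance used when validating solver output
        (the active-set NNLS solve itself runs to machine precision).
    bootstrap_reps   : nonparametric bootstrap replicates for standard errors
        (0 disables; resamples records of both datasets with replacement).
    """

    subset_size: int = 8
    n_subsets: int = 300
    seed: int = 0
    solver_tolerance: float = 1e-9
    bootstrap_reps: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise DataError("subset_size must be >= 1")
        if self.n_subsets < 1:
            raise DataError("n_subsets must be >= 1")
        if self.solver_tolerance < 0:
            raise DataError("solver_tolerance must be nonnegative")


@dataclass
class CSMFEstimate:
    """Point estimate with per-subset solutions and solver diagnostics."""

    point: CSMFVector
    per_subset_estimates: np.ndarray
    residual_norms: np.ndarray
    config: EstimatorConfig
    standard_errors: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def cause_names(self) -> list[str]:
        return self.point.cause_names


def solve_simplex_ls(
    p_s: ProfileDistribution,
    m: ConditionalProfileMatrix,
    tolerance: float = 1e-9,
) -> CSMFVector:
    """Solve min ||p_s - m beta||^2 over the probability simplex."""
    if p_s.subset.size != m.subset.size or (p_s.subset != m.subset).any():
        raise DataError("profile distribution and conditional matrix subsets differ")
    beta, _ = _solve_simplex_ls_raw(p_s.probabilities, m.matrix, tolerance)
    return CSMFVector(beta, list(m.cause_names))


def _solve_simplex_ls_raw(
    b: np.ndarray, a: np.ndarray, tolerance: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Simplex-constrained LS on raw arrays; returns (beta, residual norm)."""
    if a.shape[0] != b.shape[0]:
        raise DataError("dimension mismatch between profile vector and matrix")
    j = a.shape[1]
    if j == 1:
        beta = np.ones(1)
    else:
        aug = np.vstack([a, np.full((1, j), _SUM_ROW_WEIGHT)])
        rhs = np.concatenate([b, [_SUM_ROW_WEIGHT]])
        beta, _ = nnls(aug, rhs)
        total = beta.sum()
        if total <= 0:  # pragma: no cover - cannot occur with the weighted row
            beta = np.full(j, 1.0 / j)
        else:
            beta = beta / total
    resid = float(np.linalg.norm(a @ beta - b))
    return beta, resid


def _draw_subsets(
    rng: np.random.Generator, k: int, subset_size: int, n_subsets: int
) -> list[np.ndarray]:
    b = min(subset_size, k)
    if b == k:
        # only one possible subset; no need to redraw it
        return [np.arange(k, dtype=np.int64)]
    return [
        np.sort(rng.choice(k, size=b, replace=False)) for _ in range(n_subsets)
    ]


def _conditional_matrix_factory(
    hospital: SymptomDataset,
    stratum_weights: Mapping[str, float] | None,
):
    """Return a callable subset -> ConditionalProfileMatrix, optionally stratified."""
    if stratum_weights is None:
        return lambda subset: estimate_conditional_profiles(hospital, subset)

    if hospital.stratum_labels is None:
        raise DataError("stratified estimation requires stratum labels in the data")
    weights = dict(stratum_weights)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-6:
        raise DataError(f"stratum weights sum to {total}, not 1")
    present = set(np.unique(hospital.stratum_labels).tolist())
    missing = sorted(set(weights) - present)
    if missing:
        raise DataError(f"strata in weights but absent from hospital data: {missing}")
    parts = {
        a: hospital.subset_records(hospital.stratum_labels == a) for a in weights
    }

    def build(subset):
        mats = []
        for a, w in weights.items():
            mats.append(w * estimate_conditional_profiles(parts[a], subset).matrix)
        mat = np.sum(mats, axis=0)
        sub = np.sort(np.asarray(subset, dtype=np.int64))
        return ConditionalProfileMatrix(sub, mat, list(hospital.cause_names))

    return build


def _check_aligned(hospital: SymptomDataset, community: SymptomDataset) -> None:
    if hospital.cause_labels is None:
        raise DataError("hospital dataset must carry cause labels")
    if hospital.symptom_names != community.symptom_names:
        raise DataError(
            "hospital and community datasets must share symptom names and order"
        )


def _estimate_once(
    hospital: SymptomDataset,
    community: SymptomDataset,
    config: EstimatorConfig,
    rng: np.random.Generator,
    stratum_weights: Mapping[str, float] | None = None,
    active_symptoms: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One pass of subset-averaged estimation; returns (point, per-subset, residuals)."""
    active = (
        np.arange(hospital.n_symptoms, dtype=np.int64)
        if active_symptoms is None
        else np.sort(np.asarray(active_symptoms, dtype=np.int64))
    )
    build_cond = _conditional_matrix_factory(hospital, stratum_weights)
    subsets = _draw_subsets(rng, active.size, config.subset_size, config.n_subsets)
    estimates = np.empty((len(subsets), len(hospital.cause_names)))
    residuals = np.empty(len(subsets))
    for s, local in enumerate(subsets):
        subset = active[local]
        p_s = tabulate_profiles(community, subset)
        m = build_cond(subset)
        estimates[s], residuals[s] = _solve_simplex_ls_raw(
            p_s.probabilities, m.matrix, config.solver_tolerance
        )
    point = estimates.mean(axis=0)
    point = np.clip(point, 0.0, None)
    point = point / point.sum()
    return point, estimates, residuals


def estimate_csmf(
    hospital: SymptomDataset,
    community: SymptomDataset,
    config: EstimatorConfig | None = None,
    active_symptoms: Sequence[int] | None = None,
) -> CSMFEstimate:
    """Estimate the community CSMF from a cause-labelled hospital sample.

    For each of ``config.n_subsets`` seeded random subsets of
    ``config.subset_size`` symptoms: tabulate the community profile
    distribution, estimate the hospital conditional profile matrix, solve the
    simplex-constrained LS problem; the point estimate is the renormalized
    mean of the per-subset solutions.  ``active_symptoms`` restricts draws to
    a subset of the questionnaire (used by the bias-detection iteration).
    """
    config = config or EstimatorConfig()
    _check_aligned(hospital, community)
    rng = np.random.default_rng(config.seed)
    point, estimates, residuals = _estimate_once(
        hospital, community, config, rng, None, active_symptoms
    )
    se = _bootstrap_se(hospital, community, config, None, active_symptoms)
    return CSMFEstimate(
        point=CSMFVector(point, list(hospital.cause_names)),
        per_subset_estimates=estimates,
        residual_norms=residuals,
        config=config,
        standard_errors=se,
        diagnostics={"seed": config.seed, "n_subsets_used": len(estimates)},
    )


def stratified_estimate_csmf(
    hospital: SymptomDataset,
    community: SymptomDataset,
    community_stratum_dist: Mapping[str, float],
    config: EstimatorConfig | None = None,
    active_symptoms: Sequence[int] | None = None,
) -> CSMFEstimate:
    """Estimate the CSMF adjusting for a known stratum mix difference.

    The hospital conditional profile matrix is replaced, per subset draw, by
    the weighted average of per-stratum conditional matrices with weights
    equal to the community stratum distribution.  This removes bias when the
    profile-given-cause assumption holds within strata but the hospital
    over- or under-samples some strata.
    """
    config = config or EstimatorConfig()
    _check_aligned(hospital, community)
    rng = np.random.default_rng(config.seed)
    point, estimates, residuals = _estimate_once(
        hospital, community, config, rng, community_stratum_dist, active_symptoms
    )
    se = _bootstrap_se(hospital, community, config, community_stratum_dist,
                       active_symptoms)
    return CSMFEstimate(
        point=CSMFVector(point, list(hospital.cause_names)),
        per_subset_estimates=estimates,
        residual_norms=residuals,
        config=config,
        standard_errors=se,
        diagnostics={"seed": config.seed, "stratified": True},
    )


def _bootstrap_se(
    hospital: SymptomDataset,
    community: SymptomDataset,
    config: EstimatorConfig,
    stratum_weights: Mapping[str, float] | None,
    active_symptoms: Sequence[int] | None,
) -> np.ndarray | None:
    """Record-resampling bootstrap standard errors (optional plumbing).

    Uncertainty quantification here is a package convenience: both samples are
    resampled with replacement and the full subset-averaged estimate repeated.
    """
    if config.bootstrap_reps <= 0:
        return None
    rng = np.random.default_rng((config.seed, 0xB007))
    points = np.empty((config.bootstrap_reps, len(hospital.cause_names)))
    for r in range(config.bootstrap_reps):
        h = hospital.subset_records(rng.integers(0, hospital.n, hospital.n))
        c = community.subset_records(rng.integers(0, community.n, community.n))
        try:
            points[r], _, _ = _estimate_once(
                h, c, config, np.random.default_rng((config.seed, r)),
                stratum_weights, active_symptoms,
            )
        except DataError:
            # a resample can drop a rare cause entirely; redraw deterministically
            points[r] = np.nan
    return np.nanstd(points, axis=0, ddof=1)


def classify_individual(
    profile: Sequence[int],
    hospital: SymptomDataset,
    csmf: CSMFVector,
    community: SymptomDataset | None = None,
) -> np.ndarray:
    """Posterior cause probabilities for one death, by Bayes' theorem.

    The likelihood P(S = s | D = j) uses the hospital-estimated per-symptom
    prevalences q_jk under a conditional-independence assumption (needed only
    for individual classification, not for CSMF estimation); the prior is the
    estimated CSMF.  q_jk is clipped to [1/(2 n_j), 1 - 1/(2 n_j)] so an
    observed profile never receives an exactly zero likelihood.  The marginal
    P(S = s) cancels under normalization; when ``community`` is given, its
    directly tabulated value is returned alongside diagnostics via
    :func:`profile_marginal`.
    """
    if hospital.cause_labels is None:
        raise DataError("classification requires cause-labelled hospital data")
    s = np.asarray(profile, dtype=float)
    if s.shape != (hospital.n_symptoms,):
        raise DataError("profile length must equal the number of symptoms")
    j_count = len(hospital.cause_names)
    log_post = np.empty(j_count)
    for j in range(j_count):
        rows = hospital.symptoms[hospital.cause_labels == j]
        n_j = rows.shape[0]
        q = rows.mean(axis=0)
        lo = 1.0 / (2 * n_j)
        q = np.clip(q, lo, 1 - lo)
        log_post[j] = np.log(max(csmf[j], 1e-300)) + np.sum(
            s * np.log(q) + (1 - s) * np.log1p(-q)
        )
    log_post -= log_post.max()
    post = np.exp(log_post)
    return post / post.sum()


def profile_marginal(profile: Sequence[int], community: SymptomDataset) -> float:
    """Directly tabulated community probability of one full symptom profile.

    Diagnostic companion to :func:`classify_individual`: the Bayes denominator
    P(S = s) estimated without any independence assumption.
    """
    s = np.asarray(profile, dtype=np.uint8)
    return float((community.symptoms == s).all(axis=1).mean())
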