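"""Synthetic verbal-autopsy data generation for design studies.

Data are generated from a cause-conditional Bernoulli model: given cause j,
symptom k is reported with probability p_jk (its "sensitivity" for that
cause), independently across symptoms.  The generator covers the study
designs used throughout the package:

* random vs case-control hospital sampling (equal deaths per cause);
* a designated high-sensitivity symptom (100% sensitive for the first cause,
  0% for every other);
* divergent hospital and community CSMF distributions;
* community-side "misreporting": for designated symptoms the community
  cause-conditionals are shifted so the symptom's marginal prevalence moves
  by a stated number of percentage points, violating the assumption that
  profile-given-cause distributions agree across samples;
* the infeasible direct-sampling baseline estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .data_model import CSMFVector, DataError, SymptomDataset

__all__ = [
    "SymptomModel",
    "MisreportSpec",
    "SimulationDesign",
    "SimulatedStudy",
    "make_symptom_model",
    "make_bias_symptom_model",
    "simulate_deaths",
    "apply_misreporting",
    "direct_sampling_estimate",
    "simulate_design",
    "table2_misreports",
    "default_community_csmf",
]

# clip bounds for shifted cause-conditionals: every symptom stays weakly
# informative in both directions
_CLIP_LO, _CLIP_HI = 0.01, 0.99


@dataclass
class SymptomModel:
    """Cause-conditional Bernoulli symptom model: p_jk = P(S_k = 1 | D = j)."""

    sensitivities: np.ndarray  # (J, K)
    cause_names: list[str]
    symptom_names: list[str]

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        j, k = self.sensitivities.shape
        if len(self.cause_names) != j or len(self.symptom_names) != k:
            raise DataError("model name lists do not match sensitivity matrix shape")
        if (self.sensitivities < 0).any() or (self.sensitivities > 1).any():
            raise DataError("sensitivities must lie in [0, 1]")

    @property
    def n_causes(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.sensitivities.shape[1]

    def marginal_prevalence(self, csmf: CSMFVector) -> np.ndarray:
        """Marginal symptom prevalences under a given CSMF."""
        return csmf.fractions @ self.sensitivities


@dataclass
class MisreportSpec:
    """Designated misreported symptoms: (symptom index, marginal shift in pp).

    A shift of +30 means the community marginal prevalence of the symptom is
    moved 30 percentage points above its value under the unshifted model.
    """

    shifts: list[tuple[int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.shifts)

    @property
    def symptom_indices(self) -> list[int]:
        return [k for k, _ in self.shifts]


# Misreporting pattern used throughout the bias-detection designs: symptom
# numbers (1-based) and marginal shifts in percentage points.
_PATTERN_SYMPTOMS = (1, 5, 10, 11, 15, 20, 21, 25, 30, 31)
_PATTERN_SHIFTS = (30, -30, -50, 30, -30, 30, -30, -50, 30, -30)


def table2_misreports(n_biased: int, n_symptoms: int) -> MisreportSpec:
    """First ``n_biased`` columns of the standard misreporting pattern.

    The pattern designates symptoms 1, 5, 10, 11, 15, 20, 21, 25, 30, 31
    (1-based) with marginal shifts +30, -30, -50, +30, -30, +30, -30, -50,
    +30, -30 percentage points.
    """
    if n_biased > len(_PATTERN_SYMPTOMS):
        raise DataError(
            f"misreporting pattern defines at most {len(_PATTERN_SYMPTOMS)} symptoms"
        )
    spec = MisreportSpec(
        [(_PATTERN_SYMPTOMS[i] - 1, float(_PATTERN_SHIFTS[i])) for i in range(n_biased)]
    )
    over = [k + 1 for k in spec.symptom_indices if k >= n_symptoms]
    if over:
        raise DataError(
            f"misreported symptom numbers {over} exceed the questionnaire size "
            f"{n_symptoms}"
        )
    return spec


def default_community_csmf(n_causes: int) -> CSMFVector:
    """Front-loaded community CSMF vectors used in the simulation designs.

    For 10 causes this is (0.2, 0.2, 0.2, 0.1, 0.05 x 6): a few prevalent
    causes and several rarer ones.  The 5- and 15-cause vectors follow the
    same shape.
    """
    if n_causes == 10:
        fr = [0.2, 0.2, 0.2, 0.1] + [0.05] * 6
    elif n_causes == 5:
        fr = [0.4, 0.25, 0.15, 0.1, 0.1]
    elif n_causes == 15:
        fr = [0.15, 0.15, 0.1, 0.1, 0.1] + [0.04] * 10
    else:
        raise DataError(f"no default community CSMF defined for J={n_causes}")
    return CSMFVector(np.array(fr), [f"cause_{j + 1}" for j in range(n_causes)])


def _cause_names(j: int) -> list[str]:
    return [f"cause_{i + 1}" for i in range(j)]


def _symptom_names(k: int) -> list[str]:
    return [f"s{i + 1}" for i in range(k)]


def make_symptom_model(
    n_causes: int,
    n_symptoms: int,
    seed: int | np.random.Generator = 0,
    s_max: float = 0.3,
    high_sens: bool = False,
    s_min: float = 0.02,
) -> SymptomModel:
    """Random symptom model with i.i.d. Uniform(s_min, s_max) sensitivities.

    With ``high_sens`` an extra symptom is appended that is 100% sensitive for
    the first cause and never reported for any other cause.
    """
    if not (0 < s_max <= 1) or not (0 <= s_min < s_max):
        raise DataError("need 0 <= s_min < s_max <= 1")
    if high_sens and n_causes < 2:
        raise DataError("the high-sensitivity symptom needs at least 2 causes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.uniform(s_min, s_max, size=(n_causes, n_symptoms))
    names = _symptom_names(n_symptoms)
    if high_sens:
        col = np.zeros((n_causes, 1))
        col[0, 0] = 1.0
        p = np.hstack([p, col])
        names = names + ["s_highsens"]
    return SymptomModel(p, _cause_names(n_causes), names)


def make_bias_symptom_model(
    n_causes: int,
    n_symptoms: int,
    misreports: MisreportSpec,
    seed: int | np.random.Generator = 0,
    base_range: tuple[float, float] = (0.2, 0.8),
) -> SymptomModel:
    """Symptom model for misreporting designs.

    Unbiased symptoms draw sensitivities from ``base_range``.  Each symptom
    designated for a marginal shift draws from a sub-interval placed so the
    shifted marginal stays inside the admissible clip range whatever the
    draw — a large downward shift needs a prevalent symptom to shift.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = base_range
    p = rng.uniform(lo, hi, size=(n_causes, n_symptoms))
    margin = 0.05
    for k, shift in misreports.shifts:
        delta = shift / 100.0
        if delta >= 0:
            k_lo, k_hi = lo, min(hi, 1.0 - delta - margin)
        else:
            k_lo, k_hi = max(lo, -delta + margin + 0.04), min(0.9, -delta + margin + 0.44)
        if not k_lo < k_hi:
            raise DataError(f"infeasible shift {shift} pp for symptom {k + 1}")
        p[:, k] = rng.uniform(k_lo, k_hi, size=n_causes)
    return SymptomModel(p, _cause_names(n_causes), _symptom_names(n_symptoms))


def simulate_deaths(
    model: SymptomModel,
    csmf: CSMFVector,
    n: int,
    case_control: bool = False,
    seed: int | np.random.Generator = 0,
) -> SymptomDataset:
    """Draw n deaths: causes from the CSMF (or fixed case-control counts),
    then symptoms as independent Bernoulli(p_jk) given the cause."""
    if csmf.n_causes != model.n_causes:
        raise DataError("CSMF dimension does not match the symptom model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    j_count = model.n_causes
    if case_control:
        if n < j_count:
            raise DataError("case-control sampling needs at least one death per cause")
        base, extra = divmod(n, j_count)
        counts = np.full(j_count, base)
        counts[:extra] += 1  # remainder to the first causes, deterministically
        causes = np.repeat(np.arange(j_count), counts)
    else:
        causes = rng.choice(j_count, size=n, p=csmf.fractions)
    symptoms = (
        rng.random((n, model.n_symptoms)) < model.sensitivities[causes]
    ).astype(np.uint8)
    return SymptomDataset(
        symptoms, list(model.symptom_names), causes, list(model.cause_names)
    )


def _solve_common_shift(
    p_col: np.ndarray, weights: np.ndarray, target: float
) -> float:
    """Common additive shift c with weighted mean of clip(p + c) equal to target."""
    def achieved(c: float) -> float:
        return float(weights @ np.clip(p_col + c, _CLIP_LO, _CLIP_HI))

    lo_c, hi_c = -1.0, 1.0
    if not achieved(lo_c) - 1e-12 <= target <= achieved(hi_c) + 1e-12:
        raise DataError("target marginal outside attainable clip range")
    for _ in range(200):  # bisection on a monotone piecewise-linear function
        mid = 0.5 * (lo_c + hi_c)
        if achieved(mid) < target:
            lo_c = mid
        else:
            hi_c = mid
    return 0.5 * (lo_c + hi_c)


def apply_misreporting(
    model: SymptomModel,
    spec: MisreportSpec,
    community_csmf: CSMFVector,
) -> SymptomModel:
    """Community-side model with designated symptom marginals shifted.

    For each (symptom, shift) pair, every cause-conditional p_jk is moved by a
    common additive amount, chosen so the marginal prevalence under
    ``community_csmf`` changes by exactly shift/100 after clipping the
    conditionals to [0.01, 0.99].  An unattainable shift raises an error
    naming the symptom.  The achieved shifts are recorded on the returned
    model as ``achieved_shifts``.
    """
    p = model.sensitivities.copy()
    w = community_csmf.fractions
    achieved: dict[int, float] = {}
    for k, shift in spec.shifts:
        if not 0 <= k < model.n_symptoms:
            raise DataError(f"misreported symptom index {k} out of range")
        delta = shift / 100.0
        base = float(w @ p[:, k])
        target = base + delta
        try:
            c = _solve_common_shift(p[:, k], w, target)
        except DataError:
            raise DataError(
                f"marginal shift of {shift} pp unattainable for symptom "
                f"{model.symptom_names[k]!r} (baseline marginal {base:.3f})"
            ) from None
        p[:, k] = np.clip(p[:, k] + c, _CLIP_LO, _CLIP_HI)
        achieved[k] = float(w @ p[:, k]) - base
    shifted = SymptomModel(p, list(model.cause_names), list(model.symptom_names))
    shifted.achieved_shifts = achieved  # type: ignore[attr-defined]
    return shifted


def direct_sampling_estimate(
    true_csmf: CSMFVector, n: int, seed: int | np.random.Generator = 0
) -> CSMFVector:
    """The infeasible baseline: tabulate directly ascertained causes of n
    randomly sampled community deaths.  Its error is pure sampling
    variability, a lower bound for any symptom-based estimator."""
    if n < 1:
        raise DataError("direct sampling needs n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, true_csmf.fractions)
    return CSMFVector(counts / n, list(true_csmf.cause_names))


@dataclass
class SimulationDesign:
    """Full specification of one paired hospital/community simulation."""

    n_causes: int = 10
    n_symptoms: int = 20
    hospital_csmf: CSMFVector | None = None  # None = uniform
    community_csmf: CSMFVector | None = None  # None = default front-loaded vector
    n_hospital: int = 3000
    n_community: int = 3000
    case_control: bool = True
    high_sensitivity_symptom: bool = False
    misreports: MisreportSpec = field(default_factory=MisreportSpec)
    replicates: int = 1
    seed: int = 0
    s_min: float = 0.02
    s_max: float = 0.3
    bias_model_range: tuple[float, float] = (0.2, 0.8)

    def resolved_csmfs(self) -> tuple[CSMFVector, CSMFVector]:
        j = self.n_causes
        hosp = self.hospital_csmf or CSMFVector(np.full(j, 1.0 / j), _cause_names(j))
        comm = self.community_csmf or default_community_csmf(j)
        return hosp, comm


class SimulatedStudy(NamedTuple):
    """One replicate: labelled hospital data, unlabelled community data,
    the held-out community cause labels, and the generating models."""

    hospital: SymptomDataset
    community: SymptomDataset
    community_labels: np.ndarray
    true_csmf: CSMFVector
    hospital_model: SymptomModel
    community_model: SymptomModel


def simulate_design(
    design: SimulationDesign, seed: int | np.random.Generator | None = None
) -> SimulatedStudy:
    """Generate one hospital/community pair from a design.

    The community sample is drawn from the (possibly misreporting-shifted)
    model under the community CSMF; its cause labels are returned separately
    for validation scoring and stripped from the community dataset itself.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(design.seed if seed is None else seed)
    )
    hosp_csmf, comm_csmf = design.resolved_csmfs()
    if len(design.misreports):
        model = make_bias_symptom_model(
            design.n_causes, design.n_symptoms, design.misreports, rng,
            design.bias_model_range,
        )
    else:
        model = make_symptom_model(
            design.n_causes,
            design.n_symptoms - (1 if design.high_sensitivity_symptom else 0),
            rng,
            s_max=design.s_max,
            high_sens=design.high_sensitivity_symptom,
            s_min=design.s_min,
        )
    comm_model = apply_misreporting(model, design.misreports, comm_csmf)
    hospital = simulate_deaths(
        model, hosp_csmf, design.n_hospital, design.case_control, rng
    )
    community_full = simulate_deaths(
        comm_model, comm_csmf, design.n_community, False, rng
    )
    return SimulatedStudy(
        hospital=hospital,
        community=community_full.drop_cause_labels(),
        community_labels=community_full.cause_labels.copy(),
        true_csmf=comm_csmf,
        hospital_model=model,
        community_model=comm_model,
    )
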