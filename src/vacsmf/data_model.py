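"""Core containers for verbal-autopsy data and symptom-profile distributions.

A verbal-autopsy (VA) study collects dichotomous symptom indicators for each
death.  The *hospital* (training) sample additionally carries a medically
certified cause of death; the *community* (target) sample does not.  The
estimand is the cause-specific mortality fraction (CSMF) vector P(D) in the
community, linked to the data through the decomposition

    P(S) = P(S | D) P(D)

over the 2^K joint symptom profiles S.  This module holds the containers for
each factor — the dataset itself, the simplex vector P(D), the profile
distribution P(S) over a symptom subset, and the per-cause conditional
profile matrix P(S | D) — together with tabulation routines and delimited-text
I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SymptomDataset",
    "CSMFVector",
    "ProfileDistribution",
    "ConditionalProfileMatrix",
    "ValidationReport",
    "DatasetSchema",
    "load_dataset",
    "save_dataset",
    "tabulate_profiles",
    "estimate_conditional_profiles",
]

#: largest symptom subset for which the 2^B profile vector is enumerated.
MAX_SUBSET_SIZE = 20


class DataError(ValueError):
    """Raised for malformed or inconsistent verbal-autopsy inputs."""


@dataclass
class ValidationReport:
    """Outcome of dataset validation: per-record errors plus free-form warnings."""

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def to_json(self, path: str | Path) -> None:
        payload = {
            "is_valid": self.is_valid,
            "errors": [
                {"record": r, "field": f, "message": m} for r, f, m in self.errors
            ],
            "warnings": list(self.warnings),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SymptomDataset:
    """n records of K dichotomous symptom indicators, with optional labels.

    Parameters
    ----------
    symptoms:
        ``(n, K)`` array of 0/1 indicators.
    symptom_names:
        K column identifiers, in the column order of ``symptoms``.
    cause_labels:
        Length-n integer codes in ``0..J-1`` (hospital data), or ``None``
        (community data).  ``cause_names[j]`` is the label of code ``j``.
    stratum_labels:
        Optional length-n categorical labels (e.g. age group) used by the
        stratified estimator.
    """

    symptoms: np.ndarray
    symptom_names: list[str]
    cause_labels: np.ndarray | None = None
    cause_names: list[str] | None = None
    stratum_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.symptoms = np.asarray(self.symptoms)
        if self.symptoms.ndim != 2:
            raise DataError("symptom matrix must be 2-dimensional")
        n, k = self.symptoms.shape
        if n < 1 or k < 1:
            raise DataError("dataset must have at least one record and one symptom")
        if len(self.symptom_names) != k:
            raise DataError("symptom_names length does not match matrix width")
        bad = ~np.isin(self.symptoms, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-binary symptom value {self.symptoms[i, j]!r} at record {i}, "
                f"column {self.symptom_names[j]!r}"
            )
        self.symptoms = self.symptoms.astype(np.uint8)
        if self.cause_labels is not None:
            self.cause_labels = np.asarray(self.cause_labels, dtype=np.int64)
            if self.cause_labels.shape != (n,):
                raise DataError("cause_labels length does not match n")
            if self.cause_names is None:
                raise DataError("cause_labels given without cause_names")
            if self.cause_labels.min() < 0 or self.cause_labels.max() >= len(
                self.cause_names
            ):
                raise DataError("cause label code outside 0..J-1")
        if self.stratum_labels is not None:
            self.stratum_labels = np.asarray(self.stratum_labels)
            if self.stratum_labels.shape != (n,):
                raise DataError("stratum_labels length does not match n")

    @property
    def n(self) -> int:
        return self.symptoms.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.symptoms.shape[1]

    @property
    def n_causes(self) -> int | None:
        return None if self.cause_names is None else len(self.cause_names)

    def subset_records(self, mask: np.ndarray) -> "SymptomDataset":
        """Return the dataset restricted to records where ``mask`` is true."""
        return SymptomDataset(
            self.symptoms[mask],
            self.symptom_names,
            None if self.cause_labels is None else self.cause_labels[mask],
            self.cause_names,
            None if self.stratum_labels is None else self.stratum_labels[mask],
        )

    def drop_cause_labels(self) -> "SymptomDataset":
        """A community-style copy with cause information removed."""
        return SymptomDataset(
            self.symptoms, self.symptom_names, None, None, self.stratum_labels
        )


@dataclass
class CSMFVector:
    """A cause-specific mortality fraction vector: nonnegative, sums to one."""

    fractions: np.ndarray
    cause_names: list[str]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1:
            raise DataError("CSMF fractions must be a vector")
        if len(self.cause_names) != self.fractions.size:
            raise DataError("cause_names length does not match fractions")
        if (self.fractions < -1e-12).any():
            raise DataError("CSMF fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-8:
            raise DataError(f"CSMF fractions sum to {self.fractions.sum()}, not 1")
        self.fractions = np.clip(self.fractions, 0.0, None)
        self.fractions = self.fractions / self.fractions.sum()

    @property
    def n_causes(self) -> int:
        return self.fractions.size

    def __getitem__(self, j: int) -> float:
        return float(self.fractions[j])


def _profile_weights(b: int) -> np.ndarray:
    # first symptom in the subset is the most significant bit, so profiles
    # enumerate as 00..0, 00..1, ..., 11..1
    return 1 << np.arange(b - 1, -1, -1, dtype=np.int64)


def profile_index(bits: np.ndarray) -> np.ndarray:
    """Map rows of 0/1 bits to their lexicographic profile index."""
    bits = np.atleast_2d(bits)
    return bits.astype(np.int64) @ _profile_weights(bits.shape[1])


@dataclass
class ProfileDistribution:
    """Empirical distribution over the 2^B profiles of a symptom subset."""

    subset: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        b = self.subset.size
        if self.probabilities.shape != (2**b,):
            raise DataError("probability vector length must be 2^|subset|")
        if (self.probabilities < 0).any():
            raise DataError("profile probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise DataError("profile probabilities must sum to 1")

    @property
    def subset_size(self) -> int:
        return self.subset.size


@dataclass
class ConditionalProfileMatrix:
    """Per-cause profile distributions P^h(S | D): a 2^B-by-J column-stochastic matrix."""

    subset: np.ndarray
    matrix: np.ndarray
    cause_names: list[str]

    def __post_init__(self) -> None:
        self.subset = np.asarray(self.subset, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=float)
        b = self.subset.size
        if self.matrix.shape != (2**b, len(self.cause_names)):
            raise DataError("conditional profile matrix has wrong shape")
        if (self.matrix < 0).any():
            raise DataError("conditional profile probabilities must be nonnegative")
        col_sums = self.matrix.sum(axis=0)
        if np.abs(col_sums - 1.0).max() > 1e-12:
            raise DataError("each cause column must sum to 1")

    @property
    def n_causes(self) -> int:
        return len(self.cause_names)


# ---------------------------------------------------------------------------
# I/O


@dataclass
class DatasetSchema:
    """Column-role mapping for questionnaire exports.

    ``symptom_cols`` may be an explicit ordered list or ``"auto"`` (all columns
    not otherwise named).  ``missing_policy`` is ``"strict"`` (any value other
    than 0/1 is an error) or ``"zero-fill"`` (missing / don't-know coded as 0,
    counted in the validation report warnings).
    """

    cause_col: str | None = None
    id_col: str | None = None
    stratum_col: str | None = None
    symptom_cols: list[str] | str = "auto"
    missing_policy: str = "strict"
    cause_order: list[str] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "DatasetSchema":
        text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        return cls(**{k: v for k, v in cfg.items() if v is not None})


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def load_dataset(
    path: str | Path,
    role: str,
    schema: DatasetSchema | None = None,
    report: ValidationReport | None = None,
) -> SymptomDataset:
    """Read a delimited-text symptom table into a :class:`SymptomDataset`.

    ``role`` is ``"hospital"`` (cause column required) or ``"community"``
    (cause column ignored even if present in the schema's file).
    """
    if role not in ("hospital", "community"):
        raise DataError(f"role must be 'hospital' or 'community', got {role!r}")
    schema = schema or DatasetSchema()
    report = report if report is not None else ValidationReport()
    df = _read_table(path)

    reserved = {c for c in (schema.cause_col, schema.id_col, schema.stratum_col) if c}
    if schema.symptom_cols == "auto":
        symptom_cols = [c for c in df.columns if c not in reserved]
    else:
        symptom_cols = list(schema.symptom_cols)
    missing_cols = [c for c in symptom_cols if c not in df.columns]
    if missing_cols:
        raise DataError(f"symptom columns not found in file: {missing_cols}")

    raw = df[symptom_cols]
    if schema.missing_policy == "zero-fill":
        n_missing = int(raw.isna().sum().sum())
        if n_missing:
            report.warnings.append(
                f"{n_missing} missing symptom responses coded as 0 (zero-fill policy)"
            )
        raw = raw.fillna(0)
    values = raw.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        for i, j in np.argwhere(bad):
            report.errors.append(
                (int(i), symptom_cols[j], f"non-binary value {values[i, j]!r}")
            )
        raise DataError(
            f"{bad.sum()} non-binary symptom values under strict policy; "
            f"first at record {np.argwhere(bad)[0][0]}, "
            f"column {symptom_cols[np.argwhere(bad)[0][1]]!r}"
        )

    cause_labels = cause_names = None
    if role == "hospital":
        if not schema.cause_col:
            raise DataError("hospital data require schema.cause_col")
        if schema.cause_col not in df.columns:
            raise DataError(f"cause column {schema.cause_col!r} not found")
        raw_causes = df[schema.cause_col].astype(str).to_numpy()
        if schema.cause_order is not None:
            cause_names = [str(c) for c in schema.cause_order]
            unknown = set(raw_causes) - set(cause_names)
            if unknown:
                raise DataError(f"causes not in configured cause list: {sorted(unknown)}")
        else:
            cause_names = list(dict.fromkeys(raw_causes))  # first-appearance order
        code = {c: j for j, c in enumerate(cause_names)}
        cause_labels = np.array([code[c] for c in raw_causes])

    stratum = None
    if schema.stratum_col and schema.stratum_col in df.columns:
        stratum = df[schema.stratum_col].astype(str).to_numpy()

    return SymptomDataset(values, symptom_cols, cause_labels, cause_names, stratum)


def save_dataset(
    data: SymptomDataset, path: str | Path, cause_col: str = "cause",
    stratum_col: str = "stratum",
) -> None:
    """Write a dataset back to CSV/TSV (separator chosen from the extension)."""
    df = pd.DataFrame(data.symptoms, columns=data.symptom_names)
    if data.cause_labels is not None:
        df.insert(0, cause_col, [data.cause_names[j] for j in data.cause_labels])
    if data.stratum_labels is not None:
        df.insert(0, stratum_col, data.stratum_labels)
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Tabulation


def _check_subset(subset: Sequence[int], k: int) -> np.ndarray:
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise DataError("symptom subset must be nonempty")
    if subset.size > MAX_SUBSET_SIZE:
        raise DataError(
            f"subset of size {subset.size} exceeds the enumerable maximum "
            f"({MAX_SUBSET_SIZE})"
        )
    if subset.min() < 0 or subset.max() >= k:
        raise DataError("subset contains out-of-range symptom indices")
    if np.unique(subset).size != subset.size:
        raise DataError("subset contains repeated symptom indices")
    return np.sort(subset)


def tabulate_profiles(data: SymptomDataset, subset: Sequence[int]) -> ProfileDistribution:
    """Direct tabulation of P(S) over a symptom subset: profile counts / n."""
    subset = _check_subset(subset, data.n_symptoms)
    idx = profile_index(data.symptoms[:, subset])
    counts = np.bincount(idx, minlength=2 ** subset.size)
    return ProfileDistribution(subset, counts / data.n)


def estimate_conditional_profiles(
    hospital: SymptomDataset, subset: Sequence[int]
) -> ConditionalProfileMatrix:
    """Tabulate P^h(S | D): one profile distribution per hospital cause."""
    if hospital.cause_labels is None:
        raise DataError("conditional profiles require cause-labelled (hospital) data")
    subset = _check_subset(subset, hospital.n_symptoms)
    j_count = len(hospital.cause_names)
    counts = np.bincount(hospital.cause_labels, minlength=j_count)
    empty = [hospital.cause_names[j] for j in range(j_count) if counts[j] == 0]
    if empty:
        raise DataError(
            f"causes with zero hospital records cannot be estimated: {empty}"
        )
    idx = profile_index(hospital.symptoms[:, subset])
    n_profiles = 2 ** subset.size
    mat = np.zeros((n_profiles, j_count))
    # joint (profile, cause) count in one pass, then normalize columns
    flat = np.bincount(
        idx * j_count + hospital.cause_labels, minlength=n_profiles * j_count
    ).reshape(n_profiles, j_count)
    mat = flat / counts[None, :]
    return ConditionalProfileMatrix(subset, mat, list(hospital.cause_names))
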