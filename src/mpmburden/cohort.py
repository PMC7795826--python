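"""Cohort handling: reading, validating and completing peritoneal-biopsy data.

A cohort is a set of patients who each underwent complete macroscopic
cytoreductive surgery, after which up to 13 biopsies of macroscopically
healthy peritoneum were taken and examined for microscopic peritoneal
metastases (mPM).  The downstream model assumes a uniform number of
biopsies per patient, so cohorts are "completed" by padding every patient
with artificial mPM-negative biopsies up to a common total (13 in the
reference analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "RelativeHistogram",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort",
    "complete_cohort",
    "prevalence",
    "positive_count_histogram",
    "write_cohort",
    "reference_cohort",
    "MAX_BIOPSIES",
]

logger = logging.getLogger(__name__)

#: Maximum number of peritoneal biopsy sites (one per PCI region).
MAX_BIOPSIES = 13

REQUIRED_COLUMNS = ("patient_id", "n_biopsies_taken", "n_positive")
OPTIONAL_COLUMNS = ("height_cm", "weight_kg")


class CohortSchemaError(ValueError):
    """Input table does not have the expected columns."""


class CohortValidationError(ValueError):
    """A row violates a per-patient invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's biopsy tally and optional body measurements.

    ``n_positive`` counts biopsies in which mPM was found on pathology;
    it can never exceed the number of biopsies actually taken.
    """

    patient_id: str
    n_biopsies_taken: int
    n_positive: int
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_biopsies_taken <= MAX_BIOPSIES):
            raise CohortValidationError(
                f"patient {self.patient_id!r}: need "
                f"0 <= n_positive ({self.n_positive}) <= n_biopsies_taken "
                f"({self.n_biopsies_taken}) <= {MAX_BIOPSIES}"
            )
        for name in ("height_cm", "weight_kg"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: {name} must be positive, got {value}"
                )

    @property
    def has_mpm(self) -> bool:
        return self.n_positive >= 1


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of patient records.

    ``completed`` is True once every record has the same, maximal number of
    biopsies (artificial negatives added), which is what the histogram and
    inversion steps require.
    """

    records: tuple[PatientRecord, ...]
    completed: bool = False

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dup}")
        if self.completed:
            n_values = {r.n_biopsies_taken for r in self.records}
            if len(n_values) > 1:
                raise CohortValidationError(
                    f"completed cohort must have uniform biopsy count, got {sorted(n_values)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_biopsies(self) -> int:
        """Common biopsy count of a completed cohort."""
        if not self.completed or not self.records:
            raise CohortValidationError("cohort is not completed")
        return self.records[0].n_biopsies_taken

    def total_positives(self) -> int:
        return sum(r.n_positive for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "n_biopsies_taken": [r.n_biopsies_taken for r in self.records],
                "n_positive": [r.n_positive for r in self.records],
                "height_cm": [r.height_cm for r in self.records],
                "weight_kg": [r.weight_kg for r in self.records],
            }
        )


@dataclass(frozen=True)
class RelativeHistogram:
    """Relative frequencies of the per-patient positive-biopsy count.

    ``freq[x]`` is the fraction of patients with exactly ``x`` mPM-positive
    biopsies, for x on 0..n_max.  Frequencies are non-negative and sum to 1.
    """

    freq: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        if freq.ndim != 1 or freq.size < 1:
            raise ValueError("freq must be a 1-D vector")
        if np.any(freq < 0) or abs(freq.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be non-negative and sum to 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.freq.size)

    @property
    def n_max(self) -> int:
        return self.freq.size - 1

    def mean(self) -> float:
        return float(self.freq @ self.support)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.support, "relative_frequency": self.freq})


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from a CSV file.

    The file must be comma-separated with a header containing at least
    ``patient_id``, ``n_biopsies_taken`` and ``n_positive``; ``height_cm``
    and ``weight_kg`` are optional.  Extra columns are ignored with a
    warning.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    table = pd.read_csv(path)
    return cohort_from_frame(table, source=str(path))


def cohort_from_frame(table: pd.DataFrame, source: str = "<frame>") -> Cohort:
    """Validate a cohort table already in memory (same schema as :func:`read_cohort`)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"{source}: missing required column(s): {missing}")
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra column(s): %s", source, extra)
    if len(table) == 0:
        logger.info("%s: empty cohort (header only)", source)
    records = []
    for _, row in table.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                n_biopsies_taken=int(row["n_biopsies_taken"]),
                n_positive=int(row["n_positive"]),
                height_cm=_opt_float(row.get("height_cm")),
                weight_kg=_opt_float(row.get("weight_kg")),
            )
        )
    return Cohort(records=tuple(records), completed=False)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def complete_cohort(cohort: Cohort, target_n: Optional[int] = None) -> Cohort:
    """Pad every patient with artificial mPM-negative biopsies up to ``target_n``.

    Positive counts are untouched, so completion conserves the per-patient
    and cohort-total number of positive biopsies.  ``target_n`` defaults to
    the cohort maximum; the reference analysis fixes it at 13.
    """
    if target_n is None:
        target_n = max((r.n_biopsies_taken for r in cohort.records), default=MAX_BIOPSIES)
    if not (1 <= target_n <= MAX_BIOPSIES):
        raise ValueError(f"target_n must be in 1..{MAX_BIOPSIES}, got {target_n}")
    over = [r.patient_id for r in cohort.records if r.n_biopsies_taken > target_n]
    if over:
        raise CohortValidationError(
            f"patients with more than target_n={target_n} biopsies: {over}"
        )
    records = tuple(replace(r, n_biopsies_taken=target_n) for r in cohort.records)
    return Cohort(records=records, completed=True)


def prevalence(cohort: Cohort) -> float:
    """Fraction of patients with at least one mPM-positive biopsy."""
    if len(cohort) == 0:
        raise CohortValidationError("prevalence is undefined for an empty cohort")
    return sum(r.has_mpm for r in cohort.records) / len(cohort)


def positive_count_histogram(cohort: Cohort) -> RelativeHistogram:
    """Relative histogram of positive-biopsy counts over 0..n_biopsies.

    Requires a completed cohort so that every patient contributes a count
    on the same support.
    """
    if not cohort.completed:
        raise CohortValidationError(
            "histogram requires a completed cohort (uniform biopsy count); "
            "call complete_cohort first"
        )
    if len(cohort) == 0:
        raise CohortValidationError("histogram is undefined for an empty cohort")
    n = cohort.n_biopsies
    counts = np.bincount([r.n_positive for r in cohort.records], minlength=n + 1)
    return RelativeHistogram(freq=counts / len(cohort))


def reference_cohort() -> Cohort:
    """The packaged 26-patient reference cohort.

    19 patients with no mPM-positive biopsy, four with one, two with two and
    one with seven, each tabulated after completion to 13 biopsies.
    """
    with resources.files("mpmburden.data").joinpath("reference_cohort.csv").open("rb") as fh:
        table = pd.read_csv(fh)
    return cohort_from_frame(table, source="reference_cohort.csv")
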