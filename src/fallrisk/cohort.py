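"""Cohort container and CSV round-trip I/O.

A cohort is a single-visit cross-sectional table: one row per
participant, one column per registered candidate variable, a binary
``faller`` outcome (1 = fell at least once in the prior 12 months), and
optional sociodemographic columns (``sex``, ``age``, ``education``)
that are carried for the selection stage but are not key factors.

Missing cells are rejected at load rather than imputed: the percentile
anchors and model fits downstream assume complete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .registry import VariableSpec, variable_registry

__all__ = [
    "Participant",
    "Cohort",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
]

OUTCOME_COLUMN = "faller"
SOCIO_COLUMNS = ("sex", "age", "education")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema or a value invariant."""


@dataclass(frozen=True)
class Participant:
    """One participant's record in natural units."""

    id: object
    measurements: Mapping[str, float]
    faller: int
    sex: Optional[float] = None
    age: Optional[float] = None
    education: Optional[float] = None


@dataclass
class Cohort:
    """An ordered collection of participants plus the variable registry."""

    data: pd.DataFrame
    registry: tuple[VariableSpec, ...] = field(default_factory=variable_registry)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_outcome(self) -> bool:
        return OUTCOME_COLUMN in self.data.columns

    @property
    def outcome(self) -> np.ndarray:
        if not self.has_outcome:
            raise CohortValidationError("cohort carries no 'faller' outcome column")
        return self.data[OUTCOME_COLUMN].to_numpy(dtype=int)

    def values(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def participant(self, i: int) -> Participant:
        row = self.data.iloc[i]
        meas = {s.name: float(row[s.name]) for s in self.registry}
        return Participant(
            id=self.data.index[i],
            measurements=meas,
            faller=int(row[OUTCOME_COLUMN]) if self.has_outcome else -1,
            sex=float(row["sex"]) if "sex" in row.index else None,
            age=float(row["age"]) if "age" in row.index else None,
            education=float(row["education"]) if "education" in row.index else None,
        )

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        df = self.data
        for spec in self.registry:
            if spec.name not in df.columns:
                raise CohortValidationError(f"missing column {spec.name!r}")
        for col in df.columns:
            bad = df.index[df[col].isna()]
            if len(bad):
                raise CohortValidationError(
                    f"missing value in column {col!r} at row(s) {list(bad[:5])}"
                )
        for spec in self.registry:
            v = df[spec.name].to_numpy(dtype=float)
            self._check_range(spec, v, df.index)
        if self.has_outcome:
            y = df[OUTCOME_COLUMN].to_numpy(dtype=float)
            bad = df.index[~np.isin(y, (0.0, 1.0))]
            if len(bad):
                raise CohortValidationError(
                    f"'faller' must be 0 or 1; offending row(s) {list(bad[:5])}"
                )
        # TPA >= VPA is the only cross-variable activity constraint checked:
        # the instrument does not guarantee sub-domains sum to the total.
        if {"total_physical_activity", "vigorous_physical_activity"} <= set(df.columns):
            tpa = df["total_physical_activity"].to_numpy(dtype=float)
            vpa = df["vigorous_physical_activity"].to_numpy(dtype=float)
            bad = df.index[tpa < vpa - 1e-9]
            if len(bad):
                raise CohortValidationError(
                    f"total PA below vigorous PA at row(s) {list(bad[:5])}"
                )

    def _check_range(self, spec: VariableSpec, v: np.ndarray, index) -> None:
        if not np.all(np.isfinite(v)):
            bad = index[~np.isfinite(v)]
            raise CohortValidationError(
                f"non-finite value in column {spec.name!r} at row(s) {list(bad[:5])}"
            )
        if spec.lower is not None and np.any(v < spec.lower):
            bad = index[v < spec.lower]
            raise CohortValidationError(
                f"{spec.name!r} below minimum {spec.lower} at row(s) {list(bad[:5])}"
            )
        if spec.upper is not None and np.any(v > spec.upper):
            bad = index[v > spec.upper]
            raise CohortValidationError(
                f"{spec.name!r} above maximum {spec.upper} at row(s) {list(bad[:5])}"
            )
        if spec.integer and np.any(v != np.round(v)):
            bad = index[v != np.round(v)]
            raise CohortValidationError(
                f"{spec.name!r} must be integer-valued at row(s) {list(bad[:5])}"
            )


def load_cohort(path, registry: Optional[Iterable[VariableSpec]] = None) -> Cohort:
    """Load a cohort from comma-separated text.

    The file must have a header naming every registry variable plus
    ``faller``; non-numeric cells and out-of-range values are reported
    with row/column context.
    """
    registry = tuple(registry) if registry is not None else variable_registry()
    df = pd.read_csv(path, float_precision="round_trip")
    expected = [s.name for s in registry] + [OUTCOME_COLUMN]
    for col in expected:
        if col not in df.columns:
            raise CohortValidationError(f"cohort file lacks required column {col!r}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(
                f"non-numeric cell in column {col!r}: {exc}"
            ) from exc
    return Cohort(df, registry)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV (UTF-8, header row, ``faller`` column last)."""
    df = cohort.data
    cols = [c for c in df.columns if c != OUTCOME_COLUMN]
    if cohort.has_outcome:
        cols.append(OUTCOME_COLUMN)
    df[cols].to_csv(path, index=False)
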