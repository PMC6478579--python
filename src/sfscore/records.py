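"""Subject-level records and cohort containers.

A subject carries the two distal-radius microarchitecture traits measured by
HR-pQCT — cortical porosity (% of cortical volume) and trabecular volumetric
density (mg hydroxyapatite per cm³) — plus optional femoral-neck BMD T-score,
fracture status, and a cohort label identifying the role the subject plays in
the scoring pipeline (premenopausal reference, fracture derivation, or
evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

COHORT_LABELS = frozenset(
    {"premenopausal_reference", "fracture_reference", "evaluation"}
)

#: cohorts for which fracture status is mandatory
_FRACTURE_REQUIRED = frozenset({"fracture_reference", "evaluation"})


class SchemaError(ValueError):
    """A table is structurally malformed (e.g. a mandatory column is absent)."""


class ValidationError(ValueError):
    """A record violates a subject-level invariant."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's microarchitecture, BMD, age, fracture status and cohort.

    Parameters
    ----------
    subject_id:
        Opaque identifier, unique within a cohort table.
    age:
        Age in years, strictly positive.
    cortical_porosity:
        Percent of cortical volume occupied by pores, in [0, 100].
    trabecular_density:
        Volumetric trabecular mineral density, mg HA/cm³, non-negative.
    fn_bmd_tscore:
        Femoral-neck areal BMD T-score (SD units), optional.
    fracture:
        Prevalent-fracture status. Required for evaluation and
        fracture-reference cohorts, ignored for the premenopausal reference.
    cohort:
        One of ``premenopausal_reference``, ``fracture_reference``,
        ``evaluation``.
    extras:
        Pass-through columns from the source table, preserved untouched.
    """

    subject_id: str
    age: float
    cortical_porosity: float
    trabecular_density: float
    fn_bmd_tscore: Optional[float] = None
    fracture: Optional[bool] = None
    cohort: str = "evaluation"
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sid = self.subject_id
        if not sid:
            raise ValidationError("subject_id must be a non-empty string")
        if self.cohort not in COHORT_LABELS:
            raise ValidationError(
                f"subject {sid!r}: unknown cohort label {self.cohort!r}; "
                f"expected one of {sorted(COHORT_LABELS)}"
            )
        if not self.age > 0:
            raise ValidationError(f"subject {sid!r}: field 'age' must be > 0, got {self.age}")
        if not 0.0 <= self.cortical_porosity <= 100.0:
            raise ValidationError(
                f"subject {sid!r}: field 'cortical_porosity' must lie in [0, 100], "
                f"got {self.cortical_porosity}"
            )
        if not self.trabecular_density >= 0.0:
            raise ValidationError(
                f"subject {sid!r}: field 'trabecular_density' must be >= 0, "
                f"got {self.trabecular_density}"
            )
        if self.cohort in _FRACTURE_REQUIRED and self.fracture is None:
            raise ValidationError(
                f"subject {sid!r}: field 'fracture' is required for cohort {self.cohort!r}"
            )


@dataclass
class CohortTable:
    """Ordered, non-empty collection of :class:`SubjectRecord` with unique ids."""

    records: list[SubjectRecord]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"cohort table {self.label!r} is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise ValidationError(
                    f"duplicate subject_id {rec.subject_id!r} in cohort table {self.label!r}"
                )
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[SubjectRecord]:
        return iter(self.records)

    @property
    def subject_ids(self) -> list[str]:
        return [rec.subject_id for rec in self.records]

    def porosities(self) -> list[float]:
        return [rec.cortical_porosity for rec in self.records]

    def densities(self) -> list[float]:
        return [rec.trabecular_density for rec in self.records]
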