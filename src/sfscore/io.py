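"""Reading and writing subject-level cohort tables.

Canonical on-disk format is UTF-8 CSV with a header row and "." decimal
separator. Mandatory columns::

    subject_id, age, cortical_porosity_pct, trabecular_density_mghacm3,
    fn_bmd_tscore, fracture, cohort

``fn_bmd_tscore`` and ``fracture`` may be empty (missing optional values are
encoded as the empty string); ``fracture`` is 0/1. Unknown extra columns are
preserved and written back untouched. Numeric fields round-trip at full float
precision (floats are serialized with ``repr``).
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Mapping, Optional

import pandas as pd

from .records import CohortTable, SchemaError, SubjectRecord, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ScoreResult

REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "cortical_porosity_pct",
    "trabecular_density_mghacm3",
    "fn_bmd_tscore",
    "fracture",
    "cohort",
)

SCORE_COLUMNS = ("A", "B", "sfs", "quadrant")


def _parse_float(raw: str, field: str, sid: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(
            f"subject {sid!r}: field {field!r} is not numeric: {raw!r}"
        ) from exc


def _parse_optional_float(raw: str, field: str, sid: str) -> Optional[float]:
    if raw == "":
        return None
    return _parse_float(raw, field, sid)


def _parse_fracture(raw: str, sid: str) -> Optional[bool]:
    if raw == "":
        return None
    if raw in ("0", "1"):
        return raw == "1"
    raise ValidationError(
        f"subject {sid!r}: field 'fracture' must be 0, 1 or empty, got {raw!r}"
    )


def read_cohort(path: str | os.PathLike, expected_cohort: Optional[str] = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path:
        CSV file with the canonical header (see module docstring).
    expected_cohort:
        If given, every row's ``cohort`` label must equal it.

    Returns
    -------
    CohortTable with row order preserved and every record validated.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValidationError
        If any row violates a subject-level invariant, naming the subject
        and field.
    """
    # read everything as strings so empty cells stay distinguishable and
    # floats are parsed by us at full precision
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    records: list[SubjectRecord] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        sid = row_d["subject_id"]
        rec = SubjectRecord(
            subject_id=sid,
            age=_parse_float(row_d["age"], "age", sid),
            cortical_porosity=_parse_float(
                row_d["cortical_porosity_pct"], "cortical_porosity_pct", sid
            ),
            trabecular_density=_parse_float(
                row_d["trabecular_density_mghacm3"], "trabecular_density_mghacm3", sid
            ),
            fn_bmd_tscore=_parse_optional_float(row_d["fn_bmd_tscore"], "fn_bmd_tscore", sid),
            fracture=_parse_fracture(row_d["fracture"], sid),
            cohort=row_d["cohort"],
            extras={c: row_d[c] for c in extra_cols},
        )
        if expected_cohort is not None and rec.cohort != expected_cohort:
            raise ValidationError(
                f"subject {sid!r}: cohort {rec.cohort!r} does not match "
                f"expected {expected_cohort!r}"
            )
        records.append(rec)
    return CohortTable(records=records, label=str(path))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _record_row(rec: SubjectRecord) -> dict[str, str]:
    row = {
        "subject_id": rec.subject_id,
        "age": _fmt(float(rec.age)),
        "cortical_porosity_pct": _fmt(float(rec.cortical_porosity)),
        "trabecular_density_mghacm3": _fmt(float(rec.trabecular_density)),
        "fn_bmd_tscore": _fmt(None if rec.fn_bmd_tscore is None else float(rec.fn_bmd_tscore)),
        "fracture": _fmt(rec.fracture),
        "cohort": rec.cohort,
    }
    for key, val in rec.extras.items():
        row[key] = _fmt(val)
    return row


def write_cohort(cohort: CohortTable, path: str | os.PathLike) -> None:
    """Write a cohort CSV with the canonical columns (plus any extras)."""
    rows = [_record_row(rec) for rec in cohort.records]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scored_cohort(
    cohort: CohortTable,
    scores: Mapping[str, "ScoreResult"],
    path: str | os.PathLike,
) -> None:
    """Write the cohort with per-subject score columns appended.

    Output columns are the canonical input columns, any extras, then
    ``A``, ``B``, ``sfs``, ``quadrant`` in that order.

    Raises
    ------
    ValidationError
        If a subject in the cohort has no score.
    """
    rows = []
    for rec in cohort.records:
        if rec.subject_id not in scores:
            raise ValidationError(f"no score for subject {rec.subject_id!r}")
        res = scores[rec.subject_id]
        row = _record_row(rec)
        row["A"] = repr(float(res.A))
        row["B"] = repr(float(res.B))
        row["sfs"] = repr(float(res.sfs))
        row["quadrant"] = res.quadrant
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scored_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a scored cohort CSV into a typed DataFrame.

    Numeric score columns are parsed to float; ``fracture`` to nullable
    boolean. Used by the evaluation layer, which operates on columns rather
    than records.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    out = pd.DataFrame({"subject_id": df["subject_id"]})
    for src, dst in [
        ("age", "age"),
        ("cortical_porosity_pct", "cortical_porosity"),
        ("trabecular_density_mghacm3", "trabecular_density"),
    ]:
        out[dst] = df[src].astype(float)
    out["fn_bmd_tscore"] = pd.to_numeric(df["fn_bmd_tscore"].replace("", None))
    out["fracture"] = df["fracture"].map({"1": True, "0": False, "": None})
    out["cohort"] = df["cohort"]
    for col in SCORE_COLUMNS:
        if col in df.columns:
            out[col] = df[col] if col == "quadrant" else df[col].astype(float)
    return out
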