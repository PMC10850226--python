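"""Cohort table reading, validation, coding and complete-case filtering.

One row per participant: age (the exposure, kept in years so odds ratios
are per 1-year increment), sex, race, smoking status, admission NIHSS,
the binary deficit indicators feeding the frailty index, and the 90-day
modified Rankin Scale (mRS) with vital status.  Outcomes are the composite
poor outcome (mRS > 2, i.e. moderate disability or worse including death)
and 90-day mortality (mRS = 6).

Missing data are never imputed: records missing any variable required by a
given model fall out in the complete-case filter, which reports exclusion
counts per variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frailty import DeficitSchema, compute_fi, default_schema

logger = logging.getLogger(__name__)

__all__ = [
    "SEX_LEVELS",
    "RACE_LEVELS",
    "SMOKING_LEVELS",
    "COVARIATE_COLUMNS",
    "CohortValidationError",
    "CohortRecord",
    "CodedDesign",
    "read_cohort",
    "write_cohort",
    "derive_outcomes",
    "complete_case_filter",
    "encode_design",
]

# category levels; the first entry is the reference level (all-zero dummies)
SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("black", "white")
SMOKING_LEVELS = ("never", "former", "current")

#: deterministic covariate column order of the coded design
COVARIATE_COLUMNS = ("sex_male", "race_white", "nihss", "smoking_former", "smoking_current")


class CohortValidationError(ValueError):
    """A record violates a cohort invariant (range, category, consistency)."""


@dataclass
class CohortRecord:
    """One study participant.

    ``deficits`` is a float vector over the schema items (1 present,
    0 absent, NaN missing) or ``None`` when the table instead carries a
    precomputed ``frailty_index`` column.  ``mrs_90d`` is the 90-day mRS
    (0 no symptoms ... 6 death) or ``None`` when lost to follow-up.
    """

    id: str
    age_years: float | None
    sex: str | None
    race: str | None
    smoking: str | None
    nihss: float | None
    deficits: np.ndarray | None = None
    frailty_index: float | None = None
    mrs_90d: int | None = None
    died_90d: bool | None = None

    def validate(self, schema: DeficitSchema | None = None) -> None:
        rid = self.id
        if self.age_years is not None and not self.age_years > 18:
            raise CohortValidationError(
                f"record {rid}: age must be > 18 years (inclusion criterion), got {self.age_years}"
            )
        for name, value, levels in (
            ("sex", self.sex, SEX_LEVELS),
            ("race", self.race, RACE_LEVELS),
            ("smoking", self.smoking, SMOKING_LEVELS),
        ):
            if value is not None and value not in levels:
                raise CohortValidationError(
                    f"record {rid}: unknown {name} label {value!r}; expected one of {levels}"
                )
        if self.nihss is not None and not 0 <= self.nihss <= 42:
            raise CohortValidationError(
                f"record {rid}: NIHSS must lie in 0-42, got {self.nihss}"
            )
        if self.mrs_90d is not None and self.mrs_90d not in range(7):
            raise CohortValidationError(
                f"record {rid}: mrs_90d must lie in 0-6 (0 no symptoms to 6 death), got {self.mrs_90d}"
            )
        if self.mrs_90d is not None and self.died_90d is not None:
            if self.died_90d != (self.mrs_90d == 6):
                raise CohortValidationError(
                    f"record {rid}: died_90d={self.died_90d} conflicts with mrs_90d={self.mrs_90d}"
                )
        if self.frailty_index is not None and not 0 <= self.frailty_index <= 1:
            raise CohortValidationError(
                f"record {rid}: frailty index must lie in [0, 1], got {self.frailty_index}"
            )
        if schema is not None and self.deficits is not None and len(self.deficits) != schema.size:
            raise CohortValidationError(
                f"record {rid}: {len(self.deficits)} deficit values for a {schema.size}-item schema"
            )

    def fi_value(
        self, schema: DeficitSchema | None = None, min_assessed_fraction: float = 0.8
    ) -> float | None:
        """The mediator: precomputed frailty index if present, else computed
        from the deficit vector (missing when too few items were assessed)."""
        if self.frailty_index is not None:
            return self.frailty_index
        if self.deficits is None:
            return None
        fi = compute_fi(self.deficits, schema, min_assessed_fraction)
        return None if fi is None else fi.value


@dataclass
class CodedDesign:
    """Numeric design for the structural models.

    ``covariates`` has exactly the five reference-coded columns in
    :data:`COVARIATE_COLUMNS` (reference levels sex=female, race=black,
    smoking=never map to all-zero dummies; NIHSS stays continuous).
    """

    outcome: np.ndarray
    exposure: np.ndarray
    mediator: np.ndarray
    covariates: np.ndarray
    column_names: tuple[str, ...] = COVARIATE_COLUMNS
    outcome_name: str = "composite"
    ids: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.outcome.size


def _parse_cell(value, kind: str, row_id: str, column: str):
    """Parse one CSV cell; unparseable content becomes missing with a warning."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    try:
        if kind == "float":
            return float(value)
        if kind == "int":
            f = float(value)
            if f != int(f):
                raise ValueError(value)
            return int(f)
        if kind == "bool":
            s = str(value).strip().lower()
            if s in {"1", "true", "yes"}:
                return True
            if s in {"0", "false", "no"}:
                return False
            raise ValueError(value)
        return str(value).strip().lower()
    except (TypeError, ValueError):
        logger.warning(
            "row %s: could not parse %s=%r; treated as missing", row_id, column, value
        )
        return None


def read_cohort(
    path: str | Path,
    schema: DeficitSchema | None = None,
    sep: str = ",",
    validate: bool = True,
) -> list[CohortRecord]:
    """Read a cohort CSV into validated records.

    The file needs columns ``id, age_years, sex, race, smoking, nihss`` plus
    either the schema's deficit columns or a ``frailty_index`` column, and
    ``mrs_90d`` (``died_90d`` optional — it is derived from mRS = 6 when
    absent).  Unparseable cells become missing with a logged warning; rows
    are never dropped here.
    """
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path, sep=sep, dtype=object, encoding="utf-8")
    mandatory = ["id", "age_years", "sex", "race", "smoking", "nihss", "mrs_90d"]
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort file lacks mandatory columns: {missing_cols}")
    has_deficits = all(name in df.columns for name in schema.names)
    if not has_deficits and "frailty_index" not in df.columns:
        lacking = [n for n in schema.names if n not in df.columns][:5]
        raise CohortValidationError(
            "cohort file has neither a frailty_index column nor the schema's "
            f"deficit columns (first missing: {lacking})"
        )

    records = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        deficits = None
        if has_deficits:
            vals = []
            for name in schema.names:
                v = _parse_cell(row[name], "float", rid, name)
                if v is not None and v not in (0.0, 1.0):
                    raise CohortValidationError(
                        f"record {rid}: deficit {name!r} must be 0/1/missing, got {v}"
                    )
                vals.append(np.nan if v is None else v)
            deficits = np.array(vals)
        mrs = _parse_cell(row["mrs_90d"], "int", rid, "mrs_90d")
        died = (
            _parse_cell(row["died_90d"], "bool", rid, "died_90d")
            if "died_90d" in df.columns
            else None
        )
        if died is None and mrs is not None:
            died = mrs == 6
        rec = CohortRecord(
            id=rid,
            age_years=_parse_cell(row["age_years"], "float", rid, "age_years"),
            sex=_parse_cell(row["sex"], "str", rid, "sex"),
            race=_parse_cell(row["race"], "str", rid, "race"),
            smoking=_parse_cell(row["smoking"], "str", rid, "smoking"),
            nihss=_parse_cell(row["nihss"], "float", rid, "nihss"),
            deficits=deficits,
            frailty_index=(
                _parse_cell(row["frailty_index"], "float", rid, "frailty_index")
                if "frailty_index" in df.columns
                else None
            ),
            mrs_90d=mrs,
            died_90d=died,
        )
        if validate:
            rec.validate(schema if has_deficits else None)
        records.append(rec)
    return records


def write_cohort(
    records: Sequence[CohortRecord], path: str | Path, schema: DeficitSchema | None = None
) -> None:
    """Write records back to CSV (inverse of :func:`read_cohort`)."""
    schema = schema if schema is not None else default_schema()
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "age_years": r.age_years,
            "sex": r.sex,
            "race": r.race,
            "smoking": r.smoking,
            "nihss": r.nihss,
            "mrs_90d": r.mrs_90d,
            "died_90d": r.died_90d,
        }
        if r.deficits is not None:
            row.update({n: v for n, v in zip(schema.names, r.deficits)})
        if r.frailty_index is not None:
            row["frailty_index"] = r.frailty_index
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def derive_outcomes(record: CohortRecord) -> tuple[int | None, int | None]:
    """90-day outcomes: (composite mRS > 2, death mRS = 6).

    Missing mRS yields missing outcomes — never imputed.
    """
    if record.mrs_90d is None:
        death = 1 if record.died_90d else (0 if record.died_90d is not None else None)
        return None, death
    composite = int(record.mrs_90d >= 3)
    death = int(record.mrs_90d == 6 or bool(record.died_90d))
    return composite, death


_OUTCOME_VARS = {"composite", "death"}


def _is_missing(record: CohortRecord, name: str, schema, min_assessed_fraction) -> bool:
    if name in _OUTCOME_VARS:
        composite, death = derive_outcomes(record)
        return (composite if name == "composite" else death) is None
    if name in ("frailty_index", "fi"):
        return record.fi_value(schema, min_assessed_fraction) is None
    return getattr(record, name) is None


def complete_case_filter(
    records: Sequence[CohortRecord],
    required: Sequence[str],
    schema: DeficitSchema | None = None,
    min_assessed_fraction: float = 0.8,
) -> tuple[list[CohortRecord], dict[str, int]]:
    """Keep records complete on ``required``; tally exclusions.

    Each dropped record is counted under the *first* missing variable in
    ``required`` order.  Returns ``(kept, dropped_report)``.
    """
    kept, report = [], {}
    for rec in records:
        first_missing = next(
            (v for v in required if _is_missing(rec, v, schema, min_assessed_fraction)), None
        )
        if first_missing is None:
            kept.append(rec)
        else:
            report[first_missing] = report.get(first_missing, 0) + 1
            logger.info("record %s excluded: missing %s", rec.id, first_missing)
    if not kept:
        logger.warning("complete-case filter removed every record")
    return kept, report


def encode_design(
    records: Sequence[CohortRecord],
    outcome_name: str = "composite",
    schema: DeficitSchema | None = None,
    min_assessed_fraction: float = 0.8,
) -> CodedDesign:
    """Build the numeric design: 0/1 outcome, age exposure, FI mediator and
    the five-column reference-coded covariate matrix.

    Records must already be complete for all model variables (run
    :func:`complete_case_filter` first).  Constant columns are flagged in
    ``design.warnings`` for downstream collinearity handling.
    """
    if outcome_name not in _OUTCOME_VARS:
        raise ValueError(f"outcome must be one of {_OUTCOME_VARS}, got {outcome_name!r}")
    n = len(records)
    y = np.empty(n)
    age = np.empty(n)
    med = np.empty(n)
    cov = np.zeros((n, len(COVARIATE_COLUMNS)))
    ids = []
    for i, rec in enumerate(records):
        composite, death = derive_outcomes(rec)
        out = composite if outcome_name == "composite" else death
        fi = rec.fi_value(schema, min_assessed_fraction)
        if out is None or fi is None or None in (
            rec.age_years, rec.sex, rec.race, rec.smoking, rec.nihss
        ):
            raise CohortValidationError(
                f"record {rec.id}: incomplete for the {outcome_name} model; "
                "apply complete_case_filter first"
            )
        y[i] = out
        age[i] = rec.age_years
        med[i] = fi
        cov[i] = (
            1.0 if rec.sex == "male" else 0.0,
            1.0 if rec.race == "white" else 0.0,
            rec.nihss,
            1.0 if rec.smoking == "former" else 0.0,
            1.0 if rec.smoking == "current" else 0.0,
        )
        ids.append(rec.id)
    warns = tuple(
        f"covariate column {name!r} is constant"
        for j, name in enumerate(COVARIATE_COLUMNS)
        if n > 0 and np.ptp(cov[:, j]) == 0
    )
    for w in warns:
        logger.warning(w)
    return CodedDesign(
        outcome=y,
        exposure=age,
        mediator=med,
        covariates=cov,
        outcome_name=outcome_name,
        ids=tuple(ids),
        warnings=warns,
    )
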