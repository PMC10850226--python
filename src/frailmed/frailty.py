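"""Deficit-accumulation frailty index.

The frailty index (FI) summarises an individual's health state as the
fraction of assessed health deficits — diseases, disabilities, symptoms,
abnormal findings — that are present.  Each deficit scores 1 when present
and 0 when absent, and the index is the ratio of the deficit count to the
number of items actually assessed, so it always lies in [0, 1].  Someone
with 4 of 40 deficits has an FI of 0.1.  Standard construction guidelines
require at least 30 items but do not prescribe which; the packaged default
schema is a generic 31-item stand-in that users replace with their own
instrument.

The FI is used downstream strictly as a continuous mediator; no frailty
cut-points are applied anywhere in the pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MIN_SCHEMA_SIZE",
    "DeficitSchema",
    "FrailtyIndexValue",
    "FrailtyIndexTransformer",
    "validate_schema",
    "compute_fi",
    "fi_distribution",
    "default_schema",
]

#: minimum number of items a deficit-accumulation index should contain
MIN_SCHEMA_SIZE = 30


@dataclass(frozen=True)
class DeficitSchema:
    """Ordered list of binary deficit items.

    Parameters
    ----------
    items
        Sequence of ``(name, description)`` pairs; order fixes the column
        order of the deficit vector.
    """

    items: tuple[tuple[str, str], ...]

    def __init__(self, items: Iterable) -> None:
        norm = []
        for it in items:
            if isinstance(it, str):
                norm.append((it, ""))
            else:
                name, *rest = it
                norm.append((str(name), str(rest[0]) if rest else ""))
        object.__setattr__(self, "items", tuple(norm))

    @property
    def size(self) -> int:
        return len(self.items)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.items]

    @classmethod
    def from_file(cls, path: str | Path) -> "DeficitSchema":
        """Load a schema from YAML or JSON.

        Accepted layouts: a list of item names, a list of
        ``{name, description}`` mappings, or a mapping ``name -> description``.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if isinstance(data, dict) and "items" in data:
            data = data["items"]
        if isinstance(data, dict):
            return cls(list(data.items()))
        items = []
        for entry in data:
            if isinstance(entry, dict):
                items.append((entry["name"], entry.get("description", "")))
            else:
                items.append(entry)
        return cls(items)

    def to_yaml(self, path: str | Path) -> None:
        payload = {"items": [{"name": n, "description": d} for n, d in self.items]}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass(frozen=True)
class FrailtyIndexValue:
    """One individual's frailty index: ``value = n_present / n_assessed``."""

    value: float
    n_present: int
    n_assessed: int


def validate_schema(schema: DeficitSchema) -> list[str]:
    """Check a schema against construction guidelines.

    Returns a list of violation messages; an empty list means the schema is
    acceptable (>= 30 uniquely named items).
    """
    violations = []
    if schema.size < MIN_SCHEMA_SIZE:
        violations.append(
            f"schema has {schema.size} items; minimum {MIN_SCHEMA_SIZE} required"
        )
    seen: set[str] = set()
    for name in schema.names:
        if name in seen:
            violations.append(f"duplicate item name: {name!r}")
        seen.add(name)
    return violations


def _coerce_deficits(deficits: Sequence) -> np.ndarray:
    arr = np.asarray(
        [np.nan if d is None else float(d) for d in np.ravel(np.asarray(deficits, dtype=object))]
    )
    valid = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
    if not valid.all():
        bad = arr[~valid][0]
        raise ValueError(f"deficit indicators must be 0, 1 or missing; got {bad!r}")
    return arr


def compute_fi(
    deficits: Sequence,
    schema: DeficitSchema | None = None,
    min_assessed_fraction: float = 0.8,
) -> FrailtyIndexValue | None:
    """Compute the frailty index for one individual.

    Parameters
    ----------
    deficits
        Vector over the schema items: 1 present, 0 absent, NaN/None missing.
    schema
        When given, the vector length must equal ``schema.size``.
    min_assessed_fraction
        If fewer than this fraction of items were assessed the index is
        considered missing and ``None`` is returned.  The denominator counts
        only assessed items, following standard deficit-accumulation
        practice for partially assessed individuals.
    """
    arr = _coerce_deficits(deficits)
    if schema is not None and arr.size != schema.size:
        raise ValueError(
            f"deficit vector has length {arr.size}, schema has {schema.size} items"
        )
    assessed = ~np.isnan(arr)
    n_assessed = int(assessed.sum())
    if n_assessed == 0 or n_assessed < min_assessed_fraction * arr.size:
        return None
    n_present = int(np.nansum(arr))
    return FrailtyIndexValue(n_present / n_assessed, n_present, n_assessed)


class FrailtyIndexTransformer(TransformerMixin, BaseEstimator):
    """Transform a matrix of binary deficit indicators into FI values.

    Rows are individuals, columns the schema items (order must match).
    ``transform`` returns a 1-d float array; rows with too few assessed
    items come back as NaN.
    """

    def __init__(
        self,
        schema: DeficitSchema | None = None,
        min_assessed_fraction: float = 0.8,
        strict: bool = True,
    ) -> None:
        self.schema = schema
        self.min_assessed_fraction = min_assessed_fraction
        self.strict = strict

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-d deficit matrix")
        if self.schema is not None:
            if self.strict:
                problems = validate_schema(self.schema)
                if problems:
                    raise ValueError("; ".join(problems))
            if X.shape[1] != self.schema.size:
                raise ValueError(
                    f"matrix has {X.shape[1]} columns, schema {self.schema.size} items"
                )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("deficit matrix shape differs from the fitted one")
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            fi = compute_fi(row, min_assessed_fraction=self.min_assessed_fraction)
            out[i] = np.nan if fi is None else fi.value
        return out


def fi_distribution(values: Sequence[float], bins: int = 10) -> dict:
    """Summarise FI values: median, quartiles, range and histogram counts.

    Quantiles use linear interpolation between order statistics (the type-7
    convention, numpy's default).  Missing values are dropped; all-missing
    input is an error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing FI values to summarise")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    counts, edges = np.histogram(arr, bins=bins, range=(0.0, 1.0))
    return {
        "n": int(arr.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
        "quantile_convention": "linear interpolation (type 7)",
    }


_DEFAULT_ITEMS = [
    ("hypertension", "systemic arterial hypertension"),
    ("diabetes", "diabetes mellitus"),
    ("dyslipidemia", "dyslipidemia"),
    ("hypothyroidism", "hypothyroidism"),
    ("prior_mi", "previous myocardial infarction"),
    ("heart_failure", "congestive heart failure"),
    ("atrial_fibrillation", "atrial fibrillation"),
    ("kidney_failure", "chronic kidney disease"),
    ("prior_stroke", "previous ischemic stroke"),
    ("prior_tia", "previous transient ischemic attack"),
    ("peripheral_artery_disease", "peripheral arterial disease"),
    ("copd", "chronic obstructive pulmonary disease"),
    ("asthma", "asthma"),
    ("cancer", "active or treated malignancy"),
    ("liver_disease", "chronic liver disease"),
    ("depression", "depressive disorder"),
    ("cognitive_impairment", "diagnosed cognitive impairment or dementia"),
    ("anemia", "anemia"),
    ("obesity", "body-mass index >= 30"),
    ("underweight", "body-mass index < 18.5"),
    ("polypharmacy", "five or more regular medications"),
    ("hearing_impairment", "impaired hearing"),
    ("visual_impairment", "impaired vision"),
    ("mobility_aid", "uses a walking aid"),
    ("adl_dependency", "dependency in basic activities of daily living"),
    ("iadl_dependency", "dependency in instrumental activities of daily living"),
    ("baseline_mrs_ge1", "pre-event modified Rankin Scale >= 1"),
    ("baseline_mrs_ge2", "pre-event modified Rankin Scale >= 2"),
    ("recent_hospitalization", "hospital admission in the previous year"),
    ("self_rated_poor_health", "self-rated health poor or fair"),
    ("weight_loss", "unintentional weight loss"),
]


def default_schema() -> DeficitSchema:
    """Packaged 31-item generic schema (comorbidities plus baseline
    disability flags).  A runnable stand-in, not a clinical instrument:
    substitute a study-specific schema file for real analyses."""
    schema = DeficitSchema(_DEFAULT_ITEMS)
    assert not validate_schema(schema)
    return schema


def warn_if_invalid(schema: DeficitSchema) -> None:
    for msg in validate_schema(schema):
        warnings.warn(f"deficit schema: {msg}", UserWarning, stacklevel=2)
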