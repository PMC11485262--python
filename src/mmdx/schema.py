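"""Data model and I/O for multimodal cohort tables.

The framework consumes one row per subject: numeric features, categorical
features, optional precomputed image-embedding vectors, and 13 binary
diagnostic labels (three cognitive-status labels NC/MCI/DE plus ten dementia
etiologies), any of which may be missing.  Missingness is first-class:

* a missing *feature* is the sentinel :data:`MISSING` — never 0, never an
  empty string reinterpreted — so the attention mask can be derived
  unambiguously from the record;
* an unassessed *label* is :data:`UNKNOWN` (stored as −1 in the trinary
  label vector) and is excluded from the loss, not imputed.

A :class:`FeatureCatalog` (a JSON array of feature descriptors) is the
contract between data files, the embedding layer, and the masking machinery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator


class _Missing:
    """Singleton sentinel for an unobserved feature value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


#: Sentinel marking an unobserved feature value.
MISSING = _Missing()

#: Trinary label code for "this diagnosis was never assessed".
UNKNOWN: int = -1

#: The 13 diagnostic labels, in canonical order: three cognitive-status
#: labels followed by ten dementia etiologies.
LABELS: tuple[str, ...] = (
    "NC", "MCI", "DE",
    "AD", "LBD", "VD", "PRD", "FTD", "NPH", "SEF", "PSY", "TBI", "ODE",
)

#: The ten etiology labels (indices 3..12 of :data:`LABELS`).
ETIOLOGIES: tuple[str, ...] = LABELS[3:]

STRATA_COLUMNS: tuple[str, ...] = ("age_bin", "gender", "race")

Modality = Literal["numeric", "categorical", "image_embedding"]


class FeatureSpec(BaseModel):
    """Declarative description of one input feature."""

    name: str
    modality: Modality
    categories: list[str] | None = None
    embedding_width: int = 256
    group: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.modality == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise ValueError(
                    f"feature {self.name!r}: categorical features need >= 2 categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"feature {self.name!r}: duplicate category codes")
        elif self.categories:
            raise ValueError(f"feature {self.name!r}: categories only allowed for categorical")
        if self.embedding_width <= 0:
            raise ValueError(f"feature {self.name!r}: embedding_width must be positive")
        return self


class FeatureCatalog(BaseModel):
    """Ordered collection of :class:`FeatureSpec`, validated as a whole."""

    entries: list[FeatureSpec]
    allowed_groups: list[str] | None = None

    @model_validator(mode="after")
    def _check(self):
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        if self.allowed_groups is not None:
            allowed = set(self.allowed_groups)
            for e in self.entries:
                if e.group is not None and e.group not in allowed:
                    raise ValueError(
                        f"feature {e.name!r}: group {e.group!r} not in declared set {sorted(allowed)}"
                    )
        return self

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> FeatureSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def groups(self) -> set[str]:
        return {e.group for e in self.entries if e.group is not None}

    def features_in_groups(self, groups) -> list[str]:
        groups = set(groups)
        unknown = groups - self.groups
        if unknown:
            raise KeyError(f"unknown group tag(s): {sorted(unknown)}")
        return [e.name for e in self.entries if e.group in groups]

    def save(self, path: str | Path) -> None:
        payload = [e.model_dump(exclude_none=True) for e in self.entries]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class LabelSchema:
    """The fixed, ordered 13-label output space."""

    labels: tuple[str, ...] = LABELS

    def __post_init__(self):
        if len(self.labels) != 13:
            raise ValueError(f"expected 13 labels, got {len(self.labels)}")
        if len(set(self.labels)) != 13:
            raise ValueError("label names must be unique")

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class SubjectRecord:
    """Feature values (with explicit missingness) and a trinary label vector."""

    subject_id: str
    values: dict[str, object]
    labels: np.ndarray  # shape (13,), entries in {0, 1, UNKNOWN}
    strata: dict[str, object] = field(default_factory=dict)

    def observed(self, catalog: FeatureCatalog) -> list[str]:
        """Names of catalog features observed in this record, catalog order."""
        return [n for n in catalog.names if self.values.get(n, MISSING) is not MISSING]

    def n_observed(self, catalog: FeatureCatalog) -> int:
        return len(self.observed(catalog))

    def validate(self, catalog: FeatureCatalog) -> None:
        known = set(catalog.names)
        for name, value in self.values.items():
            if name not in known:
                raise ValueError(f"subject {self.subject_id}: unknown feature {name!r}")
            if value is MISSING:
                continue
            spec = catalog[name]
            if spec.modality == "numeric":
                v = float(value)  # type: ignore[arg-type]
                if not math.isfinite(v):
                    raise ValueError(f"subject {self.subject_id}: non-finite value for {name!r}")
            elif spec.modality == "categorical":
                if value not in spec.categories:  # type: ignore[operator]
                    raise ValueError(
                        f"subject {self.subject_id}: category {value!r} not in "
                        f"vocabulary of {name!r}"
                    )
            else:
                vec = np.asarray(value, dtype=float)
                if vec.shape != (spec.embedding_width,):
                    raise ValueError(
                        f"subject {self.subject_id}: embedding for {name!r} has shape "
                        f"{vec.shape}, expected ({spec.embedding_width},)"
                    )
                if not np.all(np.isfinite(vec)):
                    raise ValueError(f"subject {self.subject_id}: non-finite embedding {name!r}")
        if not any(self.values.get(n, MISSING) is not MISSING for n in catalog.names):
            raise ValueError(f"subject {self.subject_id}: no observed features")
        labels = np.asarray(self.labels)
        if labels.shape != (13,) or not np.all(np.isin(labels, (0, 1, UNKNOWN))):
            raise ValueError(f"subject {self.subject_id}: labels must be 13 entries in {{0,1,-1}}")


# --------------------------------------------------------------------------- I/O

def load_feature_catalog(path: str | Path, allowed_groups=None) -> FeatureCatalog:
    """Load and validate a JSON feature catalog (a top-level array of objects)."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("feature catalog must be a top-level JSON array")
    return FeatureCatalog(
        entries=[FeatureSpec(**obj) for obj in raw],
        allowed_groups=list(allowed_groups) if allowed_groups is not None else None,
    )


def _parse_cell(value, spec: FeatureSpec, subject_id: str, row: int):
    if value is None or value is MISSING or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    if isinstance(value, str) and value == "":
        return MISSING
    if spec.modality == "numeric":
        v = float(value)
        if not math.isfinite(v):
            raise ValueError(f"row {row} ({subject_id}): non-finite value in {spec.name!r}")
        return v
    if spec.modality == "categorical":
        code = str(value)
        if code not in spec.categories:  # type: ignore[operator]
            raise ValueError(
                f"row {row} ({subject_id}): category {code!r} not in vocabulary of {spec.name!r}"
            )
        return code
    # image_embedding: inline JSON array (CSV) or list (Parquet)
    if isinstance(value, str):
        vec = np.asarray(json.loads(value), dtype=float)
    else:
        vec = np.asarray(value, dtype=float)
    if vec.shape != (spec.embedding_width,):
        raise ValueError(
            f"row {row} ({subject_id}): embedding {spec.name!r} has length {vec.size}, "
            f"expected {spec.embedding_width}"
        )
    return vec


def _parse_label(value, label: str, row: int) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return UNKNOWN
    if isinstance(value, str):
        if value == "":
            return UNKNOWN
        value = float(value)
    iv = int(value)
    if iv != value or iv not in (0, 1):
        raise ValueError(f"row {row}: label {label!r} must be 0, 1 or empty, got {value!r}")
    return iv


def read_cohort_table(
    table_path: str | Path,
    catalog: FeatureCatalog,
    schema: LabelSchema | None = None,
) -> list[SubjectRecord]:
    """Read a cohort table (CSV or Parquet) into validated records.

    Empty cells become :data:`MISSING` for features and :data:`UNKNOWN` for
    labels.  Unknown columns and out-of-vocabulary categorical codes are
    errors, never silently coerced.
    """
    schema = schema or LabelSchema()
    path = Path(table_path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
    feature_names = set(catalog.names)
    label_names = set(schema.labels)
    allowed = feature_names | label_names | {"subject_id"} | set(STRATA_COLUMNS)
    unknown = [c for c in df.columns if c not in allowed]
    if unknown:
        raise ValueError(f"unknown column(s): {unknown}")
    if "subject_id" not in df.columns:
        raise ValueError("missing required column 'subject_id'")

    records: list[SubjectRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        sid = str(row_map["subject_id"])
        values = {}
        for spec in catalog:
            if spec.name in row_map:
                values[spec.name] = _parse_cell(row_map[spec.name], spec, sid, row_idx)
        labels = np.full(13, UNKNOWN, dtype=np.int64)
        for i, lab in enumerate(schema.labels):
            if lab in row_map:
                labels[i] = _parse_label(row_map[lab], lab, row_idx)
        strata = {}
        for col in STRATA_COLUMNS:
            if col in row_map:
                v = row_map[col]
                empty = v is None or (isinstance(v, float) and math.isnan(v)) or v == ""
                strata[col] = MISSING if empty else str(v)
        rec = SubjectRecord(subject_id=sid, values=values, labels=labels, strata=strata)
        rec.validate(catalog)
        records.append(rec)
    return records


def write_cohort_table(
    records: list[SubjectRecord],
    catalog: FeatureCatalog,
    path: str | Path,
    schema: LabelSchema | None = None,
) -> None:
    """Write records to CSV or Parquet (by suffix); inverse of :func:`read_cohort_table`."""
    schema = schema or LabelSchema()
    path = Path(path)
    rows = []
    strata_cols = [c for c in STRATA_COLUMNS if any(c in r.strata for r in records)]
    for rec in records:
        row: dict[str, object] = {"subject_id": rec.subject_id}
        for spec in catalog:
            v = rec.values.get(spec.name, MISSING)
            if v is MISSING:
                row[spec.name] = ""
            elif spec.modality == "image_embedding":
                row[spec.name] = json.dumps(np.asarray(v).tolist())
            else:
                row[spec.name] = v
        for i, lab in enumerate(schema.labels):
            row[lab] = "" if rec.labels[i] == UNKNOWN else int(rec.labels[i])
        for col in strata_cols:
            v = rec.strata.get(col, MISSING)
            row[col] = "" if v is MISSING else v
        rows.append(row)
    df = pd.DataFrame(rows)
    if path.suffix == ".parquet":
        df = df.replace({"": None})
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def write_predictions(
    records: list[SubjectRecord],
    probs: np.ndarray,
    logits: np.ndarray,
    path: str | Path,
    schema: LabelSchema | None = None,
) -> None:
    """Write per-subject probabilities and logits as CSV, columns in label order."""
    schema = schema or LabelSchema()
    probs = np.asarray(probs, dtype=float)
    logits = np.asarray(logits, dtype=float)
    if probs.shape != (len(records), 13) or logits.shape != (len(records), 13):
        raise ValueError(
            f"need one 13-vector of probs and logits per record: "
            f"{len(records)} records, probs {probs.shape}, logits {logits.shape}"
        )
    cols: dict[str, object] = {"subject_id": [r.subject_id for r in records]}
    for i, lab in enumerate(schema.labels):
        cols[f"prob_{lab}"] = probs[:, i]
    for i, lab in enumerate(schema.labels):
        cols[f"logit_{lab}"] = logits[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_predictions(path: str | Path, schema: LabelSchema | None = None):
    """Read back predictions: (subject_ids, probs [n,13], logits [n,13])."""
    schema = schema or LabelSchema()
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    probs = df[[f"prob_{lab}" for lab in schema.labels]].to_numpy(dtype=float)
    logits = df[[f"logit_{lab}" for lab in schema.labels]].to_numpy(dtype=float)
    return ids, probs, logits
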