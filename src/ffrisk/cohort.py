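"""Cohort data model and validated CSV input/output.

A cohort is a table of patients described by a fixed feature schema: binary
demographics, numeric biomarkers, and per-artery lesion fields (LAD, LCx,
RCA) that may arrive either as numbers or as free-text descriptions to be
translated downstream.  Two optional columns carry the supervision signal:
``numeric_ffr`` (fractional flow reserve in [0, 1]) and ``risk_class``
(low / high).  Records without an FFR are retained — they contribute to
imputation statistics even though they cannot be used for training.

File convention: UTF-8 CSV, one row per patient, header row with the exact
schema feature names, empty cells (or ``NA`` / ``NaN``) for missing values.
``risk_class`` is coded 0 = low risk, 1 = high risk on disk; the dangerous
class is the positive one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Feature",
    "Schema",
    "PatientRecord",
    "Cohort",
    "Violation",
    "load_schema",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
]

FeatureKind = Literal["binary", "numeric", "descriptive_lesion"]

#: canonical class labels; on disk they are coded 0 = low, 1 = high
LOW, HIGH = "low", "high"

FFR_COLUMN = "numeric_ffr"
CLASS_COLUMN = "risk_class"
ID_COLUMN = "patient_id"

_NA_TOKENS = {"", "na", "nan"}


@dataclass(frozen=True)
class Feature:
    """One schema column: name, kind and the closed valid range.

    For ``binary`` features the range is [0, 1]; for ``descriptive_lesion``
    features the range applies to the stenosis percentage after translation.
    """

    name: str
    kind: FeatureKind
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric", "descriptive_lesion"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (math.isfinite(self.min) and math.isfinite(self.max)):
            raise ValueError(f"{self.name}: range bounds must be finite")
        if self.min > self.max:
            raise ValueError(f"{self.name}: min exceeds max")
        if self.kind == "binary" and (self.min, self.max) != (0.0, 1.0):
            raise ValueError(f"{self.name}: binary features use range [0, 1]")


@dataclass(frozen=True)
class Schema:
    """An ordered set of features with unique names."""

    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def __getitem__(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def names_of_kind(self, kind: FeatureKind) -> tuple[str, ...]:
        return tuple(f.name for f in self.features if f.kind == kind)

    @property
    def lesion_names(self) -> tuple[str, ...]:
        return self.names_of_kind("descriptive_lesion")


def load_schema(path: str | Path | None = None) -> Schema:
    """Load a feature schema from YAML; with no path, the packaged default.

    The default schema mirrors the study cohort: smoker/gender flags, age,
    cardiac and metabolic biomarkers, and the three coronary lesion fields.
    """
    if path is None:
        text = (
            resources.files("ffrisk.data").joinpath("default_schema.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    feats = tuple(
        Feature(d["name"], d["kind"], float(d["min"]), float(d["max"]))
        for d in raw["features"]
    )
    return Schema(feats)


@dataclass
class PatientRecord:
    """One patient: feature values (number, raw text, or ``None`` = missing),
    plus optional FFR and risk class."""

    patient_id: str
    values: dict[str, float | str | None]
    numeric_ffr: float | None = None
    risk_class: str | None = None


@dataclass
class Cohort:
    """A schema plus an ordered patient table.

    ``data`` is a pandas DataFrame with object-dtype feature columns (cells
    hold floats, raw lesion strings, or NaN), a ``patient_id`` column, and
    the two optional label columns.
    """

    schema: Schema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in (ID_COLUMN, FFR_COLUMN, CLASS_COLUMN):
            if col not in self.data.columns:
                raise ValueError(f"cohort table lacks the {col!r} column")
        for name in self.schema.names:
            if name not in self.data.columns:
                raise ValueError(f"cohort table lacks schema feature {name!r}")
        ids = self.data[ID_COLUMN]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicated patient_id {dup!r}")

    # -- basic views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labeled_mask(self) -> np.ndarray:
        """True where a numeric FFR is present (the trainable subset)."""
        return self.data[FFR_COLUMN].notna().to_numpy()

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    def records(self) -> Iterator[PatientRecord]:
        for _, row in self.data.iterrows():
            values = {
                name: (None if _isna(row[name]) else row[name])
                for name in self.schema.names
            }
            yield PatientRecord(
                patient_id=str(row[ID_COLUMN]),
                values=values,
                numeric_ffr=None if _isna(row[FFR_COLUMN]) else float(row[FFR_COLUMN]),
                risk_class=None if _isna(row[CLASS_COLUMN]) else str(row[CLASS_COLUMN]),
            )

    def copy(self) -> "Cohort":
        return Cohort(self.schema, self.data.copy())

    @classmethod
    def from_records(cls, schema: Schema, records: Sequence[PatientRecord]) -> "Cohort":
        rows = []
        for r in records:
            unknown = set(r.values) - set(schema.names)
            if unknown:
                raise ValueError(f"record {r.patient_id}: unknown features {sorted(unknown)}")
            row: dict[str, object] = {ID_COLUMN: r.patient_id}
            for name in schema.names:
                v = r.values.get(name)
                row[name] = np.nan if v is None else v
            row[FFR_COLUMN] = np.nan if r.numeric_ffr is None else float(r.numeric_ffr)
            row[CLASS_COLUMN] = np.nan if r.risk_class is None else r.risk_class
            rows.append(row)
        columns = [ID_COLUMN, *schema.names, FFR_COLUMN, CLASS_COLUMN]
        df = pd.DataFrame(rows, columns=columns).astype(object)
        return cls(schema, df)


@dataclass(frozen=True)
class Violation:
    """One conformance problem found by :func:`validate_cohort`."""

    patient_id: str
    column: str
    message: str


def _isna(v: object) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _parse_number(text: str, *, allow_grouped_thousands: bool = False) -> float:
    """Parse a decimal with a period separator.

    Comma-grouped dialects like ``32,700.0`` are rejected unless explicitly
    allowed, so a European decimal comma cannot silently inflate a value.
    """
    t = text.strip()
    if "," in t:
        if not allow_grouped_thousands:
            raise ValueError(f"comma in numeric value {text!r}")
        t = t.replace(",", "")
    return float(t)


def read_cohort_csv(
    path: str | Path,
    schema: Schema | None = None,
    *,
    strict: bool = False,
    allow_grouped_thousands: bool = False,
) -> Cohort:
    """Read a patient cohort from CSV.

    Empty cells (and ``NA`` / ``NaN``) become missing values.  Cells of
    lesion columns that fail numeric parsing are kept verbatim as raw text
    for the downstream translator; unparseable cells elsewhere are an error.
    Unknown columns and duplicated patient ids are errors.  With
    ``strict=True`` any out-of-range value raises instead of being left to
    :func:`validate_cohort` to report.
    """
    if schema is None:
        schema = load_schema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = {ID_COLUMN, FFR_COLUMN, CLASS_COLUMN, *schema.names}
    for col in raw.columns:
        if col not in known:
            raise ValueError(f"unknown column {col!r}")
    for name in schema.names:
        if name not in raw.columns:
            raise ValueError(f"missing schema column {name!r}")

    n = len(raw)
    out: dict[str, list[object]] = {}
    if ID_COLUMN in raw.columns:
        ids = [s.strip() for s in raw[ID_COLUMN]]
    else:
        ids = [f"P{i + 1:03d}" for i in range(n)]
    out[ID_COLUMN] = ids

    for feat in schema.features:
        cells: list[object] = []
        for rid, text in zip(ids, raw[feat.name]):
            if text.strip().lower() in _NA_TOKENS:
                cells.append(np.nan)
                continue
            try:
                cells.append(
                    _parse_number(text, allow_grouped_thousands=allow_grouped_thousands)
                )
            except ValueError as err:
                if feat.kind == "descriptive_lesion":
                    cells.append(text)  # raw text, translated later
                elif "comma" in str(err):
                    raise ValueError(f"patient {rid}, {feat.name}: {err}") from None
                else:
                    raise ValueError(
                        f"patient {rid}: cannot parse {feat.name}={text!r} as a number"
                    ) from None
        out[feat.name] = cells

    ffr_cells: list[object] = []
    if FFR_COLUMN in raw.columns:
        for rid, text in zip(ids, raw[FFR_COLUMN]):
            if text.strip().lower() in _NA_TOKENS:
                ffr_cells.append(np.nan)
            else:
                v = _parse_number(text)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"patient {rid}: numeric_ffr {v} outside [0, 1]")
                ffr_cells.append(v)
    else:
        ffr_cells = [np.nan] * n
    out[FFR_COLUMN] = ffr_cells

    cls_cells: list[object] = []
    if CLASS_COLUMN in raw.columns:
        coding = {"0": LOW, "1": HIGH, "0.0": LOW, "1.0": HIGH, LOW: LOW, HIGH: HIGH}
        for rid, text in zip(ids, raw[CLASS_COLUMN]):
            t = text.strip().lower()
            if t in _NA_TOKENS:
                cls_cells.append(np.nan)
            elif t in coding:
                cls_cells.append(coding[t])
            else:
                raise ValueError(f"patient {rid}: unparseable risk_class {text!r}")
    else:
        cls_cells = [np.nan] * n
    out[CLASS_COLUMN] = cls_cells

    columns = [ID_COLUMN, *schema.names, FFR_COLUMN, CLASS_COLUMN]
    df = pd.DataFrame(out, columns=columns).astype(object)
    cohort = Cohort(schema, df)
    if strict:
        problems = validate_cohort(cohort)
        if problems:
            head = "; ".join(f"{v.patient_id}/{v.column}: {v.message}" for v in problems[:5])
            raise ValueError(f"{len(problems)} validation violations: {head}")
    return cohort


def _format_cell(v: object) -> str:
    if _isna(v):
        return ""
    if isinstance(v, str):
        return v
    return repr(float(v))  # full precision so read(write(c)) == c


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV; the inverse of :func:`read_cohort_csv`.

    Floats are written at full precision, missing values as empty cells and
    the risk class with the canonical 0 = low / 1 = high coding.
    """
    path = Path(path)
    df = cohort.data
    out = pd.DataFrame(index=df.index)
    out[ID_COLUMN] = df[ID_COLUMN]
    for name in cohort.schema.names:
        out[name] = [_format_cell(v) for v in df[name]]
    out[FFR_COLUMN] = [_format_cell(v) for v in df[FFR_COLUMN]]
    out[CLASS_COLUMN] = [
        "" if _isna(v) else ("1" if v == HIGH else "0") for v in df[CLASS_COLUMN]
    ]
    out.to_csv(path, index=False)
    return path


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Report every conformance problem; an empty list means fully conformant.

    Checks each present value against its schema range (soft bounds that
    describe the study cohort, not hard physical limits), flags unparseable
    binaries and raw text outside lesion columns, and checks FFR/risk-class
    consistency under the default labeling thresholds.
    """
    from .preprocessing import DEFAULT_THRESHOLDS, assign_risk_class

    problems: list[Violation] = []
    df = cohort.data
    for _, row in df.iterrows():
        rid = str(row[ID_COLUMN])
        for feat in cohort.schema.features:
            v = row[feat.name]
            if _isna(v):
                continue
            if isinstance(v, str):
                if feat.kind != "descriptive_lesion":
                    problems.append(
                        Violation(rid, feat.name, f"non-numeric value {v!r}")
                    )
                continue  # untranslated lesion text is not a violation
            x = float(v)
            if feat.kind == "binary" and x not in (0.0, 1.0):
                problems.append(Violation(rid, feat.name, f"binary value {x} not in {{0, 1}}"))
            elif not feat.min <= x <= feat.max:
                problems.append(
                    Violation(
                        rid,
                        feat.name,
                        f"value {x} outside [{feat.min}, {feat.max}]",
                    )
                )
        ffr, cls = row[FFR_COLUMN], row[CLASS_COLUMN]
        if not _isna(ffr) and not 0.0 <= float(ffr) <= 1.0:
            problems.append(Violation(rid, FFR_COLUMN, f"FFR {ffr} outside [0, 1]"))
        elif not _isna(ffr) and not _isna(cls):
            expected = assign_risk_class(float(ffr), DEFAULT_THRESHOLDS)
            if expected != cls:
                problems.append(
                    Violation(
                        rid,
                        CLASS_COLUMN,
                        f"class {cls!r} inconsistent with FFR {ffr} (expected {expected!r})",
                    )
                )
        if not _isna(cls) and cls not in (LOW, HIGH):
            problems.append(Violation(rid, CLASS_COLUMN, f"unknown class {cls!r}"))
    return problems
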