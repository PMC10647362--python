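"""Rule-based preprocessing of the clinical cohort.

Four concerns live here, in pipeline order:

1. **Lesion-text translation** — free-text descriptions of coronary
   narrowing are mapped to stenosis percentages by six ordered rules:
   an explicit percentage is taken verbatim (rule 1); a percentage range
   becomes the mean of its endpoints (rule 2); a "not substantial"
   narrowing becomes 10 % (rule 3); a "very minor" narrowing becomes 5 %
   (rule 4); an orderly arterial lumen becomes 0 % (rule 5); anything else
   is UNRESOLVED (rule 6) and is later replaced by the column mean of the
   translated values.
2. **Imputation** — remaining missing cells are filled with the column
   mean (numeric) or column mode (binary), computed over *all* records,
   including unlabeled ones.
3. **Risk labeling** — FFR above 0.8 is low risk; the explicit high-risk
   band (FFR < 0.74) and the clinically ambiguous border band
   [0.74, 0.8] both map to high risk, erring on the side of caution.
4. **Feature–FFR correlation** — Pearson product–moment coefficients of
   every feature against FFR on the labeled subset (point-biserial for the
   binary features, which is the same formula).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CLASS_COLUMN, FFR_COLUMN, HIGH, ID_COLUMN, LOW, Cohort, _isna

__all__ = [
    "UNRESOLVED",
    "TranslationResult",
    "ClassificationThresholds",
    "DEFAULT_THRESHOLDS",
    "Lexicon",
    "load_lexicon",
    "translate_lesion_text",
    "resolve_unresolved",
    "translate_cohort",
    "impute_missing",
    "assign_risk_class",
    "label_cohort",
    "compute_ffr_correlations",
    "preprocess",
    "design_matrix",
]


class _Unresolved:
    """Sentinel for rule-6 lesion text: recognised but not quantifiable."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNRESOLVED"


UNRESOLVED = _Unresolved()


@dataclass(frozen=True)
class TranslationResult:
    """Outcome of translating one lesion cell.

    ``value`` is a stenosis percentage in [0, 100], or ``UNRESOLVED`` iff
    ``rule_id`` is 6.  Rules 3, 4, 5 force the values 10, 5 and 0.
    """

    value: float | _Unresolved
    rule_id: int


@dataclass(frozen=True)
class ClassificationThresholds:
    """FFR cut points for risk transcription.

    ``low_risk_min``: FFR strictly above this is low risk (default 0.8).
    ``border_min``: lower edge of the ambiguous border band (default 0.74);
    the band [border_min, low_risk_min] merges into the high-risk class.
    """

    low_risk_min: float = 0.8
    border_min: float = 0.74

    def __post_init__(self) -> None:
        if not 0.0 < self.border_min < self.low_risk_min < 1.0:
            raise ValueError("need 0 < border_min < low_risk_min < 1")


DEFAULT_THRESHOLDS = ClassificationThresholds()


# --------------------------------------------------------------------------
# lesion-text translation
# --------------------------------------------------------------------------

_RANGE_RE = re.compile(
    r"(\d+(?:\.\d+)?)\s*%?\s*(?:-|–|—|\bto\b)\s*(\d+(?:\.\d+)?)\s*%"
)
_PERCENT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%")


@dataclass(frozen=True)
class Lexicon:
    """Phrase lists marking the three qualitative lesion descriptions, plus
    the templates the synthetic generator renders from.

    The study's reports were translated by hand, so any phrase list is an
    emulation of plausible clinical dialects; it is loaded from an editable
    YAML file so new dialects need no code change.
    """

    not_substantial: tuple[str, ...]
    very_minor: tuple[str, ...]
    orderly_lumen: tuple[str, ...]
    templates: dict[str, tuple[str, ...]] = field(default_factory=dict)


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    if path is None:
        text = (
            resources.files("ffrisk.data").joinpath("lesion_lexicon.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return Lexicon(
        not_substantial=tuple(raw["not_substantial"]["phrases"]),
        very_minor=tuple(raw["very_minor"]["phrases"]),
        orderly_lumen=tuple(raw["orderly_lumen"]["phrases"]),
        templates={
            "not_substantial": tuple(raw["not_substantial"]["templates"]),
            "very_minor": tuple(raw["very_minor"]["templates"]),
            "orderly_lumen": tuple(raw["orderly_lumen"]["templates"]),
            "percent": tuple(raw["percent_templates"]["templates"]),
            "range": tuple(raw["range_templates"]["templates"]),
        },
    )


_DEFAULT_LEXICON: Lexicon | None = None


def _default_lexicon() -> Lexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = load_lexicon()
    return _DEFAULT_LEXICON


def translate_lesion_text(
    text: str, lexicon: Lexicon | None = None
) -> TranslationResult | None:
    """Translate one free-text lesion description to a stenosis percentage.

    Rules are checked in order 1→6, so a cell carrying both a percentage
    and a qualitative phrase resolves by the percentage.  An empty or
    whitespace-only cell returns ``None`` — it is a *missing* value for the
    generic imputer, not an UNRESOLVED one for the rule-6 column mean.
    """
    if lexicon is None:
        lexicon = _default_lexicon()
    t = text.strip()
    if not t:
        return None
    m = _RANGE_RE.search(t)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        return TranslationResult((lo + hi) / 2.0, 2)
    m = _PERCENT_RE.search(t)
    if m:
        return TranslationResult(float(m.group(1)), 1)
    low = t.lower()
    for phrase in lexicon.not_substantial:
        if phrase in low:
            return TranslationResult(10.0, 3)
    for phrase in lexicon.very_minor:
        if phrase in low:
            return TranslationResult(5.0, 4)
    for phrase in lexicon.orderly_lumen:
        if phrase in low:
            return TranslationResult(0.0, 5)
    return TranslationResult(UNRESOLVED, 6)


def resolve_unresolved(
    column_values: Sequence[float | _Unresolved],
) -> list[float]:
    """Replace every UNRESOLVED entry by the mean of the resolved entries.

    Raises if no resolved value exists — there is then no basis for the
    mean.  Resolved values pass through untouched.
    """
    resolved = [float(v) for v in column_values if v is not UNRESOLVED]
    if not resolved and any(v is UNRESOLVED for v in column_values):
        raise ValueError("all values UNRESOLVED: no basis for the column mean")
    mean = float(np.mean(resolved)) if resolved else math.nan
    return [mean if v is UNRESOLVED else float(v) for v in column_values]


def translate_cohort(
    cohort: Cohort, lexicon: Lexicon | None = None
) -> tuple[Cohort, dict[tuple[str, str], int]]:
    """Translate all text cells of the lesion columns, then fill rule-6
    cells with their column means.

    Returns the translated cohort and a log mapping (patient_id, column)
    to the rule that fired, for audit.
    """
    out = cohort.copy()
    log: dict[tuple[str, str], int] = {}
    for col in cohort.schema.lesion_names:
        cells = list(out.data[col])
        ids = list(out.data[ID_COLUMN])
        staged: list[object] = []
        for rid, v in zip(ids, cells):
            if isinstance(v, str):
                res = translate_lesion_text(v, lexicon)
                if res is None:
                    staged.append(np.nan)
                else:
                    log[(str(rid), col)] = res.rule_id
                    staged.append(res.value)
            else:
                staged.append(v)
        basis = [x for x in staged if isinstance(x, float) and not math.isnan(x)]
        if any(x is UNRESOLVED for x in staged):
            if not basis:
                raise ValueError(f"column {col!r}: all translated values UNRESOLVED")
            mean = float(np.mean(basis))
            staged = [mean if x is UNRESOLVED else x for x in staged]
        out.data[col] = pd.Series(staged, index=out.data.index, dtype=object)
    return out, log


# --------------------------------------------------------------------------
# imputation
# --------------------------------------------------------------------------


def impute_missing(cohort: Cohort) -> Cohort:
    """Fill missing cells: column mean for numeric features, column mode for
    binary ones.

    Statistics are computed over all records — unlabeled patients still
    represent real-world feature combinations and sharpen the estimates.
    Idempotent, and originally present values are preserved bit-exactly.
    Raises if a column is entirely missing, naming the column.
    """
    out = cohort.copy()
    for feat in cohort.schema.features:
        col = out.data[feat.name]
        present = [v for v in col if not _isna(v)]
        if any(isinstance(v, str) for v in present):
            raise ValueError(
                f"column {feat.name!r} still holds raw text; translate first"
            )
        missing = [i for i, v in enumerate(col) if _isna(v)]
        if not missing:
            continue
        if not present:
            raise ValueError(f"column {feat.name!r} is entirely missing")
        if feat.kind == "binary":
            vals, counts = np.unique(np.asarray(present, dtype=float), return_counts=True)
            fill = float(vals[np.argmax(counts)])  # tie → smaller value
        else:
            fill = float(np.mean(np.asarray(present, dtype=float)))
        cells = list(col)
        for i in missing:
            cells[i] = fill
        out.data[feat.name] = pd.Series(cells, index=out.data.index, dtype=object)
    return out


# --------------------------------------------------------------------------
# FFR → risk class
# --------------------------------------------------------------------------


def assign_risk_class(
    ffr: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Transcribe an FFR value into a risk class.

    FFR strictly above ``low_risk_min`` is low risk; everything else —
    the explicit high-risk band below ``border_min`` and the closed border
    band [border_min, low_risk_min] — is high risk.  Merging the border
    into the dangerous class avoids falsely reassuring high-risk patients.
    """
    if not 0.0 <= ffr <= 1.0:
        raise ValueError(f"FFR {ffr} outside [0, 1]")
    return LOW if ffr > thresholds.low_risk_min else HIGH


def label_cohort(
    cohort: Cohort, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> Cohort:
    """Fill ``risk_class`` from ``numeric_ffr`` wherever the FFR is present."""
    out = cohort.copy()
    cls = [
        (np.nan if _isna(f) else assign_risk_class(float(f), thresholds))
        for f in out.data[FFR_COLUMN]
    ]
    out.data[CLASS_COLUMN] = pd.Series(cls, index=out.data.index, dtype=object)
    return out


# --------------------------------------------------------------------------
# feature–FFR correlation
# --------------------------------------------------------------------------


def compute_ffr_correlations(cohort: Cohort) -> dict[str, float]:
    """Pearson correlation of every feature with FFR on the labeled subset.

    Requires a fully numeric, complete cohort (translate + impute first).
    A zero-variance feature is reported as NaN — undefined, deliberately
    not 0, so downstream consumers can tell "no signal" from "no spread".
    """
    mask = cohort.labeled_mask
    if not mask.any():
        raise ValueError("no labeled records")
    sub = cohort.data.loc[mask]
    y = sub[FFR_COLUMN].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for name in cohort.schema.names:
        col = sub[name]
        if any(isinstance(v, str) or _isna(v) for v in col):
            raise ValueError(f"column {name!r} not fully numeric")
        x = col.to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            out[name] = math.nan
            continue
        xc, yc = x - x.mean(), y - y.mean()
        out[name] = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return out


# --------------------------------------------------------------------------
# full pipeline + model-input matrix
# --------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing run."""

    rule_firings: dict[tuple[str, str], int]
    n_imputed_cells: int
    n_labeled: int


def preprocess(
    cohort: Cohort,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    lexicon: Lexicon | None = None,
) -> tuple[Cohort, PreprocessReport]:
    """Run the full pipeline: translate → resolve → impute → label.

    Returns a fully numeric, complete cohort whose labeled records carry a
    risk class, plus an audit report of rule firings and imputation volume.
    """
    translated, log = translate_cohort(cohort, lexicon)
    n_missing = sum(
        sum(1 for v in translated.data[name] if _isna(v))
        for name in cohort.schema.names
    )
    imputed = impute_missing(translated)
    labeled = label_cohort(imputed, thresholds)
    report = PreprocessReport(
        rule_firings=log, n_imputed_cells=n_missing, n_labeled=labeled.n_labeled
    )
    return labeled, report


def design_matrix(
    cohort: Cohort, *, normalize_lesions: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for model input (records × schema features).

    Lesion percentages are rescaled to [0, 1] by default so the model sees
    the fractional convention; the transform is monotone, so tree-based
    learners are unaffected either way.
    """
    cols = []
    for feat in cohort.schema.features:
        col = cohort.data[feat.name]
        if any(isinstance(v, str) or _isna(v) for v in col):
            raise ValueError(f"column {feat.name!r} not fully numeric/complete")
        x = col.to_numpy(dtype=float)
        if normalize_lesions and feat.kind == "descriptive_lesion":
            x = x / 100.0
        cols.append(x)
    return np.column_stack(cols), list(cohort.schema.names)
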