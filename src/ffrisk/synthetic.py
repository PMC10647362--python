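"""Synthetic patient cohorts with the structure of the study data.

The real cohort is private, so this module generates stand-ins that
reproduce its *structure*: 276 patients of whom 181 carry an FFR label,
a roughly 123:58 low/high class imbalance, biomarker values inside the
published ranges, free-text lesion descriptions covering all six
translation rules, missing cells, and feature–FFR correlations whose signs
follow the published correlation table.  Only signs and ordering structure
are emulated — no attempt is made to match the real joint distribution.

Generation is physics-first: each patient receives a worst-lesion stenosis
whose reduced-order FFR (see :mod:`ffrisk.hemodynamics`) realises a target
FFR drawn for their risk class, so the stenosis → FFR → class chain is the
same one the classifier is asked to recover.  ``signal_strength`` scales
how informative the features are: it sets the fraction of patients whose
lesions are physically coupled to their FFR and the strength of the
class-conditional biomarker shifts.  At ``signal_strength=0`` every feature
is pure noise with respect to FFR — the null cohort for calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    CLASS_COLUMN,
    FFR_COLUMN,
    ID_COLUMN,
    Cohort,
    PatientRecord,
    Schema,
    load_schema,
)
from .hemodynamics import VesselSpec, ffr_from_vessel, stenosis_for_ffr
from .preprocessing import (
    DEFAULT_THRESHOLDS,
    Lexicon,
    _default_lexicon,
    assign_risk_class,
)

__all__ = [
    "GeneratorConfig",
    "CORRELATION_TARGETS",
    "generate_cohort",
    "render_lesion_text",
    "generate_worked_fixture",
]

#: Sign/magnitude targets for each biomarker's correlation with FFR,
#: following the published correlation table.  (That table prints "HDL"
#: twice and omits LDH; the -0.33 row is read as LDH here.)  Lesion columns
#: are absent: their association with FFR comes from the physics coupling.
CORRELATION_TARGETS: dict[str, float] = {
    "Smoker": -0.39,
    "Gender": -0.19,
    "Age": 0.21,
    "CK": -0.21,
    "CKMB": -0.07,
    "AST": -0.14,
    "LDH": -0.33,
    "Troponin": 0.25,
    "pBNP": 0.33,
    "CRP": -0.18,
    "Leukocyte": -0.23,
    "Glucose": 0.30,
    "Urea": 0.15,
    "Creatinine": 0.11,
    "Ac. uricum": 0.40,
    "Cholesterol": -0.02,
    "Trig": 0.09,
    "HDL": 0.03,
    "LDL": 0.06,
    "Atherosclerosis index": 0.16,
    "Cholesterol/HDL": 0.02,
}

# FFR sampling bands per class.  They stop short of the 0.8 decision
# boundary by more than the rounding + noise drift (< 0.005), so the
# physics-derived class always matches the intended one.
_HIGH_FFR_BAND = (0.55, 0.795)
_LOW_FFR_BAND = (0.81, 0.98)
_FFR_NOISE = 0.002

#: default vessel geometry for label generation (proximal coronary scale)
DEFAULT_VESSEL = VesselSpec(
    reference_radius=1.5e-3, stenosis_fraction=0.0, stenosis_length=0.01, flow_rate=3.0
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for cohort generation.

    Defaults mirror the study: 276 patients, 181 labeled, 58/181 high risk.
    ``missing_rate`` blanks feature cells; ``text_rate`` renders lesion
    cells as free text; ``signal_strength`` scales feature informativeness
    (0 = pure noise, >= 1 = full physics coupling); ``label_flip_rate``
    moves that fraction of labeled patients' FFR across the 0.8 boundary
    to emulate borderline label ambiguity.
    """

    n_patients: int = 276
    labeled_fraction: float = 181 / 276
    target_high_fraction: float = 58 / 181
    missing_rate: float = 0.03
    text_rate: float = 0.5
    signal_strength: float = 1.0
    label_flip_rate: float = 0.0
    seed: int = 0
    vessel: VesselSpec = DEFAULT_VESSEL

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must be in (0, 1]")
        if not 0.0 < self.target_high_fraction < 1.0:
            raise ValueError("target_high_fraction must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.text_rate <= 1.0:
            raise ValueError("text_rate must be in [0, 1]")
        if self.signal_strength < 0.0:
            raise ValueError("signal_strength must be >= 0")
        if not 0.0 <= self.label_flip_rate <= 1.0:
            raise ValueError("label_flip_rate must be in [0, 1]")


def render_lesion_text(
    percent: float,
    rule_style: int,
    rng: np.random.Generator | int,
    lexicon: Lexicon | None = None,
) -> str:
    """Render a stenosis percentage as free text firing exactly one rule.

    Style 1 embeds the percentage itself; style 2 a symmetric ±5 range
    whose endpoint mean is the percentage (requires 5 <= percent <= 95);
    styles 3/4/5 emit qualitative phrases translating to 10, 5 and 0.
    """
    if lexicon is None:
        lexicon = _default_lexicon()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    forced = {3: 10.0, 4: 5.0, 5: 0.0}
    if rule_style in forced and not math.isclose(percent, forced[rule_style]):
        raise ValueError(
            f"style {rule_style} encodes {forced[rule_style]}%, not {percent}%"
        )
    if rule_style == 1:
        tpl = lexicon.templates["percent"][rng.integers(len(lexicon.templates["percent"]))]
        return tpl.format(p=f"{percent:g}")
    if rule_style == 2:
        if not 5.0 <= percent <= 95.0:
            raise ValueError("style 2 needs 5 <= percent <= 95 for a ±5 range")
        a, b = round(percent - 5.0, 1), round(percent + 5.0, 1)
        tpl = lexicon.templates["range"][rng.integers(len(lexicon.templates["range"]))]
        return tpl.format(a=f"{a:g}", b=f"{b:g}")
    key = {3: "not_substantial", 4: "very_minor", 5: "orderly_lumen"}.get(rule_style)
    if key is None:
        raise ValueError(f"invalid rule style {rule_style}")
    tpls = lexicon.templates[key]
    return tpls[rng.integers(len(tpls))]


def _exact_class_labels(n: int, high_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_high = round(high_fraction * n)
    labels = np.array(["high"] * n_high + ["low"] * (n - n_high), dtype=object)
    rng.shuffle(labels)
    return labels


def _snap_minor(percent: float) -> float:
    """Snap small stenoses onto the qualitative grid {0, 5, 10}."""
    if percent < 12.5:
        return float(min((0.0, 5.0, 10.0), key=lambda g: abs(g - percent)))
    return round(percent, 1)


def generate_cohort(config: GeneratorConfig, schema: Schema | None = None) -> Cohort:
    """Generate one synthetic cohort; byte-identical given the same config.

    Per patient: a risk class (exact target counts within rounding), a
    class-conditional FFR, a worst-lesion stenosis realising that FFR under
    the reduced-order vessel model (for the physics-coupled fraction of
    patients), two further lesions below the worst, and biomarkers drawn
    inside the schema ranges with FFR-linked shifts whose signs follow
    ``CORRELATION_TARGETS``.  Missingness and free-text rendering are
    applied last; the unlabeled fraction has FFR and class stripped.
    """
    if schema is None:
        schema = load_schema()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_lab = round(config.labeled_fraction * n)

    labeled = np.array([True] * n_lab + [False] * (n - n_lab))
    rng.shuffle(labeled)
    # exact class counts within each labeling stratum
    classes = np.empty(n, dtype=object)
    classes[labeled] = _exact_class_labels(n_lab, config.target_high_fraction, rng)
    if n - n_lab:
        classes[~labeled] = _exact_class_labels(
            n - n_lab, config.target_high_fraction, rng
        )

    couple_frac = min(1.0, config.signal_strength)
    lesion_names = schema.lesion_names
    records: list[PatientRecord] = []
    for i in range(n):
        cls = classes[i]
        band = _HIGH_FFR_BAND if cls == "high" else _LOW_FFR_BAND
        ffr_target = rng.uniform(*band)
        coupled = rng.random() < couple_frac
        if coupled:
            sf = round(stenosis_for_ffr(ffr_target, config.vessel), 3)
            vessel = replace(config.vessel, stenosis_fraction=sf)
            ffr_val = ffr_from_vessel(vessel).exact + rng.uniform(-_FFR_NOISE, _FFR_NOISE)
        else:
            sf = round(rng.uniform(0.35, 0.72), 3)
            ffr_val = ffr_target + rng.uniform(-_FFR_NOISE, _FFR_NOISE)
        ffr_val = float(np.clip(ffr_val, 0.0, 1.0))

        if config.label_flip_rate and labeled[i] and rng.random() < config.label_flip_rate:
            # push the FFR just across the boundary: borderline label noise
            ffr_val = (
                rng.uniform(0.802, 0.83) if cls == "high" else rng.uniform(0.74, 0.798)
            )
        cls_final = assign_risk_class(ffr_val, DEFAULT_THRESHOLDS)

        # lesions: worst artery carries sf, the others something milder
        # LAD most often hosts the worst lesion, echoing its dominant
        # correlation magnitude in the study
        probs = [0.5, 0.25, 0.25] if len(lesion_names) == 3 else None
        worst = rng.choice(len(lesion_names), p=probs)
        lesions: dict[str, float] = {}
        for j, name in enumerate(lesion_names):
            if j == worst:
                lesions[name] = round(sf * 100.0, 1)
            else:
                lesions[name] = _snap_minor(rng.uniform(0.0, sf) * 100.0)

        # biomarkers: mix of noise and the FFR-linked component
        f = float(np.clip((ffr_val - 0.55) / (0.98 - 0.55), 0.0, 1.0))
        values: dict[str, float | str | None] = dict(lesions)
        for feat in schema.features:
            if feat.kind == "descriptive_lesion":
                continue
            rho = CORRELATION_TARGETS.get(feat.name, 0.0)
            w = min(0.95, config.signal_strength * abs(rho))
            d = f if rho > 0 else 1.0 - f
            if feat.kind == "binary":
                p = float(np.clip(0.5 + (w if rho > 0 else -w) * (f - 0.5), 0.02, 0.98))
                values[feat.name] = float(rng.random() < p)
            else:
                u = (1.0 - w) * rng.random() + w * d
                if feat.min > 0 and feat.max / feat.min > 20.0:
                    # heavy-ranged biomarkers (pBNP, CK, ...) are log-uniform
                    values[feat.name] = float(
                        feat.min * math.exp(u * math.log(feat.max / feat.min))
                    )
                else:
                    values[feat.name] = float(feat.min + u * (feat.max - feat.min))

        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                values=values,
                numeric_ffr=ffr_val if labeled[i] else None,
                risk_class=cls_final if labeled[i] else None,
            )
        )

    # missingness over feature cells, guarding each column's last value
    if config.missing_rate > 0:
        for name in schema.names:
            present = [i for i in range(n) if records[i].values.get(name) is not None]
            drop = [i for i in present if rng.random() < config.missing_rate]
            if len(drop) == len(present):  # keep at least one observed value
                drop = drop[1:]
            for i in drop:
                records[i].values[name] = None

    # render a fraction of the surviving lesion cells as free text
    if config.text_rate > 0:
        for rec in records:
            for name in lesion_names:
                v = rec.values.get(name)
                if v is None or rng.random() >= config.text_rate:
                    continue
                p = float(v)
                if p == 0.0:
                    style = 5
                elif p == 5.0:
                    style = 4
                elif p == 10.0:
                    style = 3
                elif p < 5.0 or p > 95.0:
                    style = 1
                else:
                    style = 1 if rng.random() < 0.5 else 2
                rec.values[name] = render_lesion_text(p, style, rng)

    return Cohort.from_records(schema, records)


def generate_worked_fixture(schema: Schema | None = None) -> Cohort:
    """A deterministic 10-record mini-cohort for hand-checked testing.

    Exercises every lesion-translation rule (records R01–R06 on the LAD
    column), one missing numeric cell (R07's glucose), one missing binary
    cell (R08's smoker flag), and FFR values straddling the 0.74 and 0.8
    thresholds.  R09 is unlabeled.  Hand-derived expectations: the LAD
    rule-6 cell resolves to the mean of the nine translated values
    (255/9); the missing glucose imputes to 49/9; the missing smoker flag
    imputes to the mode 0.
    """
    if schema is None:
        schema = load_schema()
    defaults = {
        f.name: (0.0 if f.kind == "binary" else round((f.min + f.max) / 2.0, 4))
        for f in schema.features
    }
    lad = [
        "stenosis of 70%",            # rule 1 -> 70
        "narrowing 40-50%",           # rule 2 -> 45
        "narrowing not substantial",  # rule 3 -> 10
        "very minor narrowing",       # rule 4 -> 5
        "orderly arterial lumen",     # rule 5 -> 0
        "tortuous vessel with calcifications",  # rule 6 -> column mean
        20.0, 30.0, 40.0, 35.0,
    ]
    ffrs = [0.85, 0.81, 0.80, 0.77, 0.74, 0.50, 0.90, 0.60, None, 0.95]
    glucose = [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, None, 6.0, 7.0, 6.0]
    smoker = [0.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, None, 0.0, 0.0]
    records = []
    for i in range(10):
        values: dict[str, float | str | None] = dict(defaults)
        values["LAD"] = lad[i]
        values["LCx"] = 10.0
        values["RCA"] = 5.0
        values["Glucose"] = glucose[i]
        values["Smoker"] = smoker[i]
        records.append(
            PatientRecord(
                patient_id=f"R{i + 1:02d}",
                values=values,
                numeric_ffr=ffrs[i],
                risk_class=None,
            )
        )
    return Cohort.from_records(schema, records)
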