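"""Structured vitals/labs extraction and patient feature-matrix assembly.

Vital signs and laboratory results appear in admission records as regular
``name: value unit`` lines, so simple regular expressions suffice to parse
them.  Together with the free-text feature-value pairs from the extractors,
they are assembled into a patients x features matrix with MACE labels,
median imputation plus missing-indicator columns, and a category tag per
feature (Diagnosis, Symptom, Medicine, Surgery, ECG, Personal, VitalSigns,
LabTest).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rbmlp import FeatureValuePair

log = logging.getLogger(__name__)

__all__ = [
    "VitalSpec",
    "LabSpec",
    "PanelConfig",
    "DEFAULT_PANEL",
    "StructuredPanel",
    "extract_structured",
    "MACEDefinition",
    "PatientFeatureMatrix",
    "assemble_matrix",
    "CLASS_TO_CATEGORY",
    "CATEGORIES",
]

CATEGORIES = ("Diagnosis", "Symptom", "Medicine", "Surgery", "ECG",
              "Personal", "VitalSigns", "LabTest")

#: Semantic class -> feature category used in summary bookkeeping.
CLASS_TO_CATEGORY = {
    "DG": "Diagnosis",
    "DS": "Diagnosis",
    "ST": "Symptom",
    "BP": "Symptom",
    "MD": "Medicine",
    "SG": "Surgery",
    "EC": "ECG",
    "EX": "ECG",
    "PS": "Personal",
}


@dataclass(frozen=True)
class VitalSpec:
    name: str
    pattern: str
    bounds: tuple[float, float]


@dataclass(frozen=True)
class LabSpec:
    name: str
    pattern: str
    ref_range: tuple[float, float] | None = None
    bounds: tuple[float, float] = (0.0, 1e6)


@dataclass(frozen=True)
class PanelConfig:
    vitals: tuple[VitalSpec, ...]
    labs: tuple[LabSpec, ...]


_NUM = r"(\d+(?:\.\d+)?)"

DEFAULT_PANEL = PanelConfig(
    vitals=(
        VitalSpec("BT", rf"体温[:：]?\s*{_NUM}\s*[℃°C]", (30, 45)),
        VitalSpec("pulse", rf"脉搏[:：]?\s*{_NUM}\s*次/分", (20, 250)),
        VitalSpec("BR", rf"呼吸[:：]?\s*{_NUM}\s*次/分", (4, 60)),
        VitalSpec("SBP", rf"血压[:：]?\s*{_NUM}\s*/\s*\d+(?:\.\d+)?\s*mmHg", (50, 260)),
        VitalSpec("DBP", rf"血压[:：]?\s*\d+(?:\.\d+)?\s*/\s*{_NUM}\s*mmHg", (30, 160)),
        VitalSpec("height", rf"身高[:：]?\s*{_NUM}\s*cm", (100, 220)),
        VitalSpec("weight", rf"体重[:：]?\s*{_NUM}\s*kg", (25, 250)),
        VitalSpec("age", rf"年龄[:：]?\s*{_NUM}\s*岁", (0, 119)),
    ),
    labs=(
        LabSpec("肌酐", rf"肌酐[:：]?\s*{_NUM}\s*μ?mol/L", (44, 133), (10, 2000)),
        LabSpec("血糖", rf"血糖[:：]?\s*{_NUM}\s*mmol/L", (3.9, 6.1), (0.5, 50)),
        LabSpec("甘油三酯", rf"甘油三酯[:：]?\s*{_NUM}\s*mmol/L", (0.3, 1.7), (0.05, 50)),
    ),
)


@dataclass
class StructuredPanel:
    """Parsed vitals and labs for one record; absent entries are None."""

    vitals: dict[str, float | None] = field(default_factory=dict)
    labs: list[tuple[str, float | None, bool | None]] = field(default_factory=list)

    def lab(self, name: str) -> float | None:
        for n, v, _ in self.labs:
            if n == name:
                return v
        return None


def extract_structured(record_text: str, config: PanelConfig = DEFAULT_PANEL) -> StructuredPanel:
    """Parse structured vitals/labs lines; unparseable or out-of-bounds
    entries are missing."""
    panel = StructuredPanel()
    for spec in config.vitals:
        m = re.search(spec.pattern, record_text)
        value: float | None = None
        if m:
            value = float(m.group(1))
            if not spec.bounds[0] <= value <= spec.bounds[1]:
                log.warning("vital %s=%.4g outside sanity bounds %s; treated as missing",
                            spec.name, value, spec.bounds)
                value = None
        panel.vitals[spec.name] = value
    for spec in config.labs:
        m = re.search(spec.pattern, record_text)
        value = None
        if m:
            value = float(m.group(1))
            if not spec.bounds[0] <= value <= spec.bounds[1]:
                log.warning("lab %s=%.4g outside sanity bounds; treated as missing",
                            spec.name, value)
                value = None
        flag: bool | None = None
        if value is not None and spec.ref_range is not None:
            flag = not (spec.ref_range[0] <= value <= spec.ref_range[1])
        panel.labs.append((spec.name, value, flag))
    return panel


@dataclass(frozen=True)
class MACEDefinition:
    """Composite in-hospital endpoint: which event types count as MACE."""

    events: tuple[str, ...] = ("all_cause_death", "myocardial_infarction",
                               "angina_attack", "heart_failure", "arrhythmias",
                               "re_revascularization", "transfer_to_cabg",
                               "long_length_of_stay")
    long_los_days: float = 14.0

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("at least one MACE event type must be enabled")


@dataclass
class PatientFeatureMatrix:
    """Patients x features with missingness mask, categories and MACE labels."""

    X: pd.DataFrame
    y: pd.Series
    categories: dict[str, str]
    mask: pd.DataFrame  # True where the value was observed (pre-imputation)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, columns: Sequence[str]) -> "PatientFeatureMatrix":
        cols = list(columns)
        return PatientFeatureMatrix(self.X[cols].copy(), self.y,
                                    {c: self.categories[c] for c in cols},
                                    self.mask[cols].copy())

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.X.columns:
            cat = self.categories.get(c, "Other")
            out[cat] = out.get(cat, 0) + 1
        return out

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.y)
        df.index.name = "patient_id"
        df.to_csv(path, encoding="utf-8")
        if sidecar is not None:
            obj = {"categories": self.categories,
                   "mask": {c: self.mask[c].astype(int).tolist() for c in self.mask.columns},
                   "patients": list(map(str, self.X.index))}
            Path(sidecar).write_text(json.dumps(obj, ensure_ascii=False), encoding="utf-8")


def assemble_matrix(pairs_by_patient: Mapping[str, Sequence[FeatureValuePair]],
                    panels: Mapping[str, StructuredPanel],
                    labels: Mapping[str, int],
                    three_state: bool = False,
                    drop_constant: bool = True) -> PatientFeatureMatrix:
    """Assemble the patient x feature matrix.

    Free-text pairs encode binary (affirmed=1; negated or absent=0, or -1
    for negated in ``three_state`` mode); vitals and labs are numeric with an
    abnormal flag per lab.  Missing numerics are median-imputed with a
    companion ``<col>_missing`` indicator; constant columns are dropped.
    """
    missing_pairs = sorted(set(labels) - set(pairs_by_patient))
    extra = sorted(set(pairs_by_patient) - set(labels))
    if missing_pairs or extra:
        raise ValueError(f"patient id mismatch: no extraction for {missing_pairs[:5]}, "
                         f"unlabeled {extra[:5]}")
    ids = sorted(labels)
    y = pd.Series([int(labels[i]) for i in ids], index=ids, name="label")
    if not set(y.unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    text_features: dict[str, str] = {}  # name -> class code
    for pid in ids:
        for p in pairs_by_patient[pid]:
            text_features.setdefault(p.feature, p.class_code or "ST")
    text_cols = sorted(text_features)

    data: dict[str, list[float]] = {c: [] for c in text_cols}
    for pid in ids:
        state = {p.feature: p.polarity for p in pairs_by_patient[pid]}
        for c in text_cols:
            pol = state.get(c)
            if pol == "affirmed":
                data[c].append(1.0)
            elif pol == "negated" and three_state:
                data[c].append(-1.0)
            else:
                data[c].append(0.0)
    X = pd.DataFrame(data, index=ids)
    categories = {c: CLASS_TO_CATEGORY.get(text_features[c], "Symptom") for c in text_cols}

    # numeric vitals and labs (shared column inventory across patients)
    vital_names = sorted({v for pid in ids for v in panels[pid].vitals})
    lab_names = sorted({n for pid in ids for n, _, _ in panels[pid].labs})
    for name in vital_names:
        X[name] = [panels[pid].vitals.get(name) for pid in ids]
        categories[name] = "VitalSigns"
    for name in lab_names:
        col = f"lab_{name}"
        X[col] = [panels[pid].lab(name) for pid in ids]
        categories[col] = "LabTest"
        flags = []
        for pid in ids:
            flag = next((f for n, _, f in panels[pid].labs if n == name), None)
            flags.append(np.nan if flag is None else float(flag))
        X[f"{col}_abnormal"] = flags
        categories[f"{col}_abnormal"] = "LabTest"

    X = X.astype(float)
    mask = ~X.isna()
    for c in list(X.columns):
        if mask[c].sum() == 0:
            log.warning("feature column %s is all-missing; dropped", c)
            X = X.drop(columns=[c])
            mask = mask.drop(columns=[c])
            categories.pop(c, None)
            continue
        if X[c].isna().any():
            med = float(X[c].median())
            ind = X[c].isna().astype(float)
            X[c] = X[c].fillna(med)
            X[f"{c}_missing"] = ind
            categories[f"{c}_missing"] = categories[c]
            mask[f"{c}_missing"] = True
    if drop_constant:
        for c in list(X.columns):
            if X[c].nunique() <= 1:
                log.warning("feature column %s is constant after encoding; dropped", c)
                X = X.drop(columns=[c])
                mask = mask.drop(columns=[c])
                categories.pop(c, None)
    X = X[sorted(X.columns)]
    mask = mask[X.columns]
    return PatientFeatureMatrix(X, y, categories, mask)
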