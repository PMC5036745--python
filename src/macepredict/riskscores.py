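"""Additive-point clinical risk scores (GRACE, TIMI) as table-driven engines.

The engine is table-agnostic: a score is a sum of integer points over binned
numeric variables and binary flags, loaded from a YAML point table.  Shipped
tables transcribe the GRACE in-hospital mortality model and the TIMI
UA/NSTEMI score from their original publications; the raw total serves
directly as the ranking score for ROC analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "NumericBin",
    "ScoreVariable",
    "AdditivePointModel",
    "grace_model",
    "timi_model",
    "score_to_prediction",
    "score_matrix",
]

_DATA_DIR = Path(__file__).parent / "data"

_WARNED_MISSING: set[tuple[str, str]] = set()


@dataclass(frozen=True)
class NumericBin:
    upper: float | None  # value <= upper; None = open top bin
    points: int


@dataclass(frozen=True)
class ScoreVariable:
    name: str
    kind: str  # "numeric" | "binary"
    bins: tuple[NumericBin, ...] = ()
    points: int = 0  # binary kind
    required: bool = False
    direction: str | None = None  # documented risk direction for numeric vars

    def min_points(self) -> int:
        if self.kind == "binary":
            return 0
        return min(b.points for b in self.bins)

    def assign(self, value: object) -> int:
        if self.kind == "binary":
            return self.points if bool(value) else 0
        v = float(value)  # type: ignore[arg-type]
        for b in self.bins:
            if b.upper is None or v <= b.upper:
                return b.points
        raise AssertionError("bins must end with an open top bin")


@dataclass(frozen=True)
class AdditivePointModel:
    """A named additive point model: score = sum of per-variable points."""

    name: str
    variables: tuple[ScoreVariable, ...]
    source: str = ""

    @staticmethod
    def from_yaml(path: str | Path) -> "AdditivePointModel":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        variables = []
        for v in raw["variables"]:
            kind = v["kind"]
            if kind == "numeric":
                bins = tuple(NumericBin(b["upper"], int(b["points"])) for b in v["bins"])
                if bins[-1].upper is not None:
                    raise ValueError(f"{v['name']}: last bin must be open (upper: null)")
                if any(b.points < 0 for b in bins):
                    raise ValueError(f"{v['name']}: points must be >= 0")
                variables.append(ScoreVariable(v["name"], kind, bins,
                                               required=bool(v.get("required", False)),
                                               direction=v.get("direction")))
            elif kind == "binary":
                variables.append(ScoreVariable(v["name"], kind, points=int(v["points"]),
                                               required=bool(v.get("required", False))))
            else:
                raise ValueError(f"unknown variable kind {kind!r}")
        return AdditivePointModel(raw["name"], tuple(variables), str(path))

    def min_score(self) -> int:
        return sum(v.min_points() for v in self.variables)

    def score(self, values: Mapping[str, object]) -> tuple[int, dict[str, int]]:
        """Score one patient; returns (total, per-variable breakdown).

        A missing optional variable contributes its lowest-point bin with a
        warning (risk-score tools cope poorly with missing risk factors; the
        default policy is conservative).  Missing required variables raise.
        """
        breakdown: dict[str, int] = {}
        for var in self.variables:
            value = values.get(var.name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                if var.required:
                    raise ValueError(f"{self.name}: required variable {var.name!r} missing")
                if (self.name, var.name) not in _WARNED_MISSING:
                    _WARNED_MISSING.add((self.name, var.name))
                    log.warning("%s: variable %s missing; lowest-point bin assumed "
                                "(warned once)", self.name, var.name)
                breakdown[var.name] = var.min_points()
            else:
                breakdown[var.name] = var.assign(value)
        return sum(breakdown.values()), breakdown


def grace_model() -> AdditivePointModel:
    return AdditivePointModel.from_yaml(_DATA_DIR / "grace.yaml")


def timi_model() -> AdditivePointModel:
    return AdditivePointModel.from_yaml(_DATA_DIR / "timi.yaml")


def score_to_prediction(scores: Sequence[float], labels: Sequence[int] | None = None) -> np.ndarray:
    """Raw totals used directly as the ROC ranking score."""
    arr = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    return arr


def score_matrix(model: AdditivePointModel, df: pd.DataFrame,
                 mapping: Mapping[str, Mapping[str, object]]) -> np.ndarray:
    """Score every row of a feature matrix.

    ``mapping`` maps model variable names to ``{"column": <df column>,
    "scale": <factor>}`` (or ``{"threshold": t}`` to binarize a numeric
    column as value >= t).  Unmapped variables fall to the missing-variable
    policy.
    """
    totals = np.zeros(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        values: dict[str, object] = {}
        for var, spec in mapping.items():
            col = spec["column"]  # type: ignore[index]
            if col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                continue
            v = float(v) * float(spec.get("scale", 1.0))  # type: ignore[union-attr]
            if "threshold" in spec:
                values[var] = v >= float(spec["threshold"])  # type: ignore[arg-type]
            else:
                values[var] = v
        totals[i], _ = model.score(values)
    return totals
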