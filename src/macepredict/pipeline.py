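"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: synth -> extract (rbmlp and/or crf) -> assemble -> score-baselines
-> train-eval -> report.  Every stage is seeded from one base seed and the
run writes a manifest listing inputs, seeds and SHA-256 digests of every
output, so reruns with the same config are byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .cohort import assemble_matrix
from .crf import extract_spans, train_labeler, write_conll
from .evaluation import (ClassifierSpec, CVProtocol, auc, cv_auc_summary,
                         delong_cv, run_cv)
from .rbmlp import default_rules_path, extract_record_rbmlp, load_rules, write_pairs_csv
from .riskscores import grace_model, score_matrix, timi_model
from .synth import (GRACE_SUBSET_COLUMNS, default_config, generate_cohort,
                    gold_pairs_by_patient, mini_lexicon, panels_from_cohort,
                    score_extraction, theoretical_auc, write_cohort)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "GRACE_MAPPING", "TIMI_MAPPING"]

#: Mapping of synthetic matrix columns onto GRACE inputs (creatinine is
#: generated in umol/L; the published table bins mg/dL).
GRACE_MAPPING = {
    "age": {"column": "age"},
    "heart_rate": {"column": "pulse"},
    "sbp": {"column": "SBP"},
    "creatinine": {"column": "lab_肌酐", "scale": 1 / 88.4},
}

TIMI_MAPPING = {
    "age_ge_65": {"column": "age", "threshold": 65},
    "known_cad": {"column": "冠心病"},
    "aspirin_recent": {"column": "阿司匹林"},
    "severe_angina": {"column": "心绞痛"},
}


@dataclass
class RunConfig:
    """Run configuration; stages toggle pipeline steps."""

    outdir: str = "run"
    seed: int = 0
    n: int = 500
    noise_rate: float = 0.0
    stages: tuple[str, ...] = ("synth", "extract", "assemble", "baselines",
                               "train-eval", "report")
    extractors: tuple[str, ...] = ("rbmlp",)
    models: tuple[str, ...] = ("l1lr", "nb")
    folds: int = 5
    repetitions: int = 3
    crf_train_records: int = 120

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stages", "extractors", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen = default_config(n=config.n, noise_rate=config.noise_rate)
    report: dict = {"seed": config.seed, "n": config.n}
    outputs: list[Path] = []
    cohort = None

    def stage(name: str) -> bool:
        return name in config.stages

    try:
        if stage("synth"):
            cohort = generate_cohort(gen, seed=config.seed)
            write_cohort(cohort, out / "cohort")
            outputs += sorted((out / "cohort").glob("*"))
        if cohort is None:
            raise RuntimeError("later stages require the synth stage in this run mode")

        labels = {p.patient_id: p.label for p in cohort}
        panels = panels_from_cohort(cohort)
        pairs_by_extractor: dict[str, dict] = {}
        if stage("extract"):
            if "rbmlp" in config.extractors:
                lex = mini_lexicon(gen)
                rules = load_rules(default_rules_path())
                pairs = {p.patient_id: extract_record_rbmlp(p.text, lex, rules,
                                                            record_id=p.patient_id)
                         for p in cohort}
                pairs_by_extractor["rbmlp"] = pairs
                write_pairs_csv([q for ps in pairs.values() for q in ps],
                                out / "pairs_rbmlp.csv")
                outputs.append(out / "pairs_rbmlp.csv")
                gold = [q for p in cohort for q in p.gold_pairs]
                pred = [q for ps in pairs.values() for q in ps]
                report["rbmlp_prf"] = score_extraction(pred, gold)
            if "crf" in config.extractors:
                k = min(config.crf_train_records, len(cohort))
                model = train_labeler([p.gold_bio for p in cohort[:k]])
                model.save(out / "crf_model.json")
                outputs.append(out / "crf_model.json")
                pairs = {p.patient_id: extract_spans(model.decode(p.text),
                                                     record_id=p.patient_id)
                         for p in cohort}
                pairs_by_extractor["crf"] = pairs
                write_pairs_csv([q for ps in pairs.values() for q in ps],
                                out / "pairs_crf.csv")
                outputs.append(out / "pairs_crf.csv")
                gold = [q for p in cohort for q in p.gold_pairs]
                pred = [q for ps in pairs.values() for q in ps]
                report["crf_prf"] = score_extraction(pred, gold)
        else:
            pairs_by_extractor["gold"] = gold_pairs_by_patient(cohort)

        matrices = {}
        if stage("assemble"):
            for name, pairs in pairs_by_extractor.items():
                m = assemble_matrix(pairs, panels, labels)
                m.to_csv(out / f"matrix_{name}.csv", out / f"matrix_{name}_meta.json")
                outputs += [out / f"matrix_{name}.csv", out / f"matrix_{name}_meta.json"]
                matrices[name] = m

        if stage("baselines") and matrices:
            m = next(iter(matrices.values()))
            y = m.y.values
            for model, mapping, tag in ((grace_model(), GRACE_MAPPING, "grace"),
                                        (timi_model(), TIMI_MAPPING, "timi")):
                mapping = {k: v for k, v in mapping.items()
                           if v["column"] in m.X.columns}
                scores = score_matrix(model, m.X, mapping)
                np.savetxt(out / f"{tag}_scores.csv", scores, fmt="%.1f",
                           header="score", comments="")
                outputs.append(out / f"{tag}_scores.csv")
                report[f"{tag}_auc"] = auc(scores, y)

        if stage("train-eval") and matrices:
            protocol = CVProtocol(folds=config.folds, repetitions=config.repetitions,
                                  base_seed=config.seed)
            report["theoretical_auc"] = theoretical_auc(gen, seed=config.seed, n=200_000)
            report["models"] = {}
            for name, m in matrices.items():
                y = m.y.values
                cv_scores = {}
                for kind in config.models:
                    s = run_cv(m.X, y, ClassifierSpec(kind, seed=config.seed), protocol)
                    cv_scores[kind] = s
                    summ = cv_auc_summary(s, y)
                    report["models"][f"{name}:{kind}"] = {
                        "auc_per_rep": list(summ.values),
                        "mean": summ.mean, "ci": list(summ.ci)}
                kinds = list(cv_scores)
                report.setdefault("delong_p", {})
                for i, a in enumerate(kinds):
                    for b in kinds[i + 1:]:
                        report["delong_p"][f"{name}:{a}_vs_{b}"] = delong_cv(
                            cv_scores[a], cv_scores[b], y)

        if stage("report"):
            (out / "results.json").write_text(
                json.dumps(report, ensure_ascii=False, indent=2, default=str),
                encoding="utf-8")
            outputs.append(out / "results.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return report
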