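"""Rule-based medical language processing (RBMLP) extraction.

A record is decomposed into clauses at clinical punctuation, each clause is
tokenized and annotated with semantic symbols (:mod:`macepredict.lexicon`),
and the annotated clauses are matched against a prioritized set of regular
expression rules over the symbol alphabet (e.g. ``[BodyPart]+[Symptom]``).
A clause-bounded negation detector decides whether each matched concept is
affirmed or negated.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .lexicon import AnnotatedClause, Lexicon, annotate_clause

log = logging.getLogger(__name__)

__all__ = [
    "MatchRule",
    "FeatureValuePair",
    "NegationConfig",
    "load_rules",
    "printed_rules_path",
    "default_rules_path",
    "split_clauses",
    "match_rules",
    "detect_negation",
    "extract_record_rbmlp",
    "write_pairs_csv",
    "write_pairs_jsonl",
]

#: Clause delimiters: Chinese clinical punctuation plus ASCII equivalents.
DEFAULT_DELIMITERS = "，。；：！？、,.;:!?"

_SYMBOL_RE = re.compile(r"([A-Z]{2})#(\d+)#")

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class MatchRule:
    """One extraction rule: a named regex over annotated clause text.

    ``pattern`` uses ``(?<NAME>...)`` named groups (translated to Python's
    ``(?P<NAME>...)`` at load time); ``emit`` lists the capture groups whose
    resolved surface forms are concatenated into the feature name;
    ``priority`` orders rule application (lower runs first).
    """

    name: str
    pattern: re.Pattern
    emit: tuple[str, ...]
    priority: int
    category_class: str | None = None

    @staticmethod
    def compile(name: str, pattern: str, emit: Sequence[str], priority: int,
                category_class: str | None = None) -> "MatchRule":
        # Accept the .NET-style named-group dialect and the en-dash that
        # sometimes survives typesetting inside character classes.
        src = pattern.replace("(?<", "(?P<").replace("(?P<=", "(?<=").replace("(?P<!", "(?<!")
        src = src.replace("–", "-")
        compiled = re.compile(src)
        for g in emit:
            if g not in compiled.groupindex:
                raise ValueError(f"rule {name!r}: emit group {g!r} not present in pattern")
        return MatchRule(name, compiled, tuple(emit), priority, category_class)


@dataclass(frozen=True)
class FeatureValuePair:
    """One extracted patient feature with polarity and provenance."""

    feature: str
    value: object = True
    polarity: str = "affirmed"  # or "negated"
    record_id: str = ""
    clause: str = ""
    source: str = ""  # rule name or extractor tag
    class_code: str | None = None

    def key(self) -> tuple[str, str]:
        return (self.feature, self.polarity)


@dataclass(frozen=True)
class NegationConfig:
    """Negation cues and scope exceptions.

    A concept is negated when a cue occurs in the same clause before it and
    no scope-breaking noun (e.g. 诱因 in 无明显诱因出现胸闷, where the cue
    negates the *incentive*, not the symptom) lies between cue and concept.
    """

    cues: tuple[str, ...] = ("否认", "未", "无", "不")
    exceptions: tuple[str, ...] = ("诱因",)

    def __post_init__(self) -> None:
        if not self.cues:
            raise ValueError("negation cue list must be non-empty")


def load_rules(path: str | Path) -> list[MatchRule]:
    """Load a YAML rule file: list of {name, pattern, emit, priority[, class]}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or []
    rules = [
        MatchRule.compile(r["name"], r["pattern"], r.get("emit", []), int(r["priority"]),
                          r.get("class"))
        for r in raw
    ]
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    return sorted(rules, key=lambda r: r.priority)


def printed_rules_path() -> Path:
    """The four rules printed in the source rule table, verbatim dialect."""
    return _DATA_DIR / "rules_printed.yaml"


def default_rules_path() -> Path:
    """The shipped default rule set (printed rules plus combinatorial variants)."""
    return _DATA_DIR / "rules_default.yaml"


def split_clauses(record_text: str, delimiters: str = DEFAULT_DELIMITERS) -> list[str]:
    """Split record text into clauses at punctuation; drop empties."""
    out: list[str] = []
    buf: list[str] = []
    for ch in record_text:
        if ch in delimiters or ch == "\n":
            if buf:
                out.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        out.append("".join(buf))
    return out


def detect_negation(clause: str, concept_span: tuple[int, int],
                    config: NegationConfig | None = None) -> str:
    """Clause-bounded negation: return ``"negated"`` or ``"affirmed"``.

    Negated iff some cue ends at or before the concept start and no exception
    term sits between that cue and the concept.
    """
    config = config or NegationConfig()
    start = concept_span[0]
    for cue in config.cues:
        idx = clause.find(cue)
        while idx != -1 and idx + len(cue) <= start:
            gap = clause[idx + len(cue) : start]
            if not any(exc in gap for exc in config.exceptions):
                return "negated"
            idx = clause.find(cue, idx + 1)
    return "affirmed"


def _resolve_symbols(text: str, clause: AnnotatedClause) -> tuple[str, list[int]]:
    """Concatenate original surfaces of the symbols in a captured group."""
    surfaces: list[str] = []
    indices: list[int] = []
    for m in _SYMBOL_RE.finditer(text):
        k = int(m.group(2))
        surfaces.append(clause.index_map[k].surface)
        indices.append(k)
    return "".join(surfaces), indices


def match_rules(clause: AnnotatedClause, rules: Sequence[MatchRule],
                negation: NegationConfig | None = None,
                record_id: str = "",
                consume_symbols: bool = True) -> list[FeatureValuePair]:
    """Match one annotated clause against the rule set.

    Rules are applied in priority order and each non-overlapping occurrence
    of a pattern emits one feature-value pair whose name is the concatenation
    of the resolved surfaces of the emit groups.  When ``consume_symbols`` is
    true (default), symbols claimed by an earlier match are skipped by later
    rules, so a compound rule ([BodyPart]+[Symptom]) shades the single-symbol
    rules it subsumes.
    """
    negation = negation or NegationConfig()
    pairs: list[FeatureValuePair] = []
    consumed: set[int] = set()
    for rule in rules:
        for m in rule.pattern.finditer(clause.annotated):
            _, span_indices = _resolve_symbols(m.group(0), clause)
            if consume_symbols and any(k in consumed for k in span_indices):
                continue
            surfaces: list[str] = []
            indices: list[int] = []
            skip = False
            for g in rule.emit:
                text = m.group(g)
                if text is None:
                    log.warning("rule %s: optional emit group %r unmatched; pair skipped",
                                rule.name, g)
                    skip = True
                    break
                s, idx = _resolve_symbols(text, clause)
                surfaces.append(s)
                indices.extend(idx)
            if skip or not indices:
                continue
            feature = "".join(surfaces)
            first = clause.index_map[indices[0]]
            polarity = detect_negation(clause.original, first.span, negation)
            cls = rule.category_class or clause.index_map[indices[-1]].class_code
            pairs.append(FeatureValuePair(feature, True, polarity, record_id,
                                          clause.original, rule.name, cls))
            if consume_symbols:
                consumed.update(span_indices)
    return pairs


def extract_record_rbmlp(record_text: str, lexicon: Lexicon,
                         rules: Sequence[MatchRule],
                         negation: NegationConfig | None = None,
                         record_id: str = "",
                         delimiters: str = DEFAULT_DELIMITERS) -> list[FeatureValuePair]:
    """Full RBMLP extraction for one record.

    split -> tokenize -> annotate -> match -> negate, concatenated over
    clauses; pairs deduplicated per (feature, polarity) keeping the first
    provenance.
    """
    negation = negation or NegationConfig()
    seen: set[tuple[str, str]] = set()
    out: list[FeatureValuePair] = []
    for clause_text in split_clauses(record_text, delimiters):
        ann = annotate_clause(clause_text, lexicon)
        for pair in match_rules(ann, rules, negation, record_id):
            if pair.key() not in seen:
                seen.add(pair.key())
                out.append(pair)
    return out


def write_pairs_csv(pairs: Iterable[FeatureValuePair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "feature", "value", "polarity", "rule", "clause"])
        for p in pairs:
            w.writerow([p.record_id, p.feature, p.value, p.polarity, p.source, p.clause])


def write_pairs_jsonl(pairs: Iterable[FeatureValuePair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(json.dumps({
                "record_id": p.record_id, "feature": p.feature, "value": p.value,
                "polarity": p.polarity, "rule": p.source, "clause": p.clause,
                "class": p.class_code,
            }, ensure_ascii=False) + "\n")
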