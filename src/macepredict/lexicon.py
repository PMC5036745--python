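"""Medical lexicon, reverse-directional maximum-match tokenization and
semantic-symbol annotation.

Chinese admission records narrate findings in short clauses built from a
fairly closed clinical vocabulary (body parts, symptoms, diagnoses,
medications, ...).  The extraction engine therefore segments each clause
with a dictionary-driven reverse maximum-match scan and rewrites every
matched word as a symbol ``<CODE>#<k>#`` (two-letter semantic-class code
plus an index used to retrieve the original surface form), so that the
downstream rule matcher can operate on a compact symbolic alphabet
instead of raw text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "SemanticClass",
    "ClassRegistry",
    "DEFAULT_REGISTRY",
    "Lexicon",
    "Token",
    "AnnotatedClause",
    "load_lexicon",
    "tokenize_reverse_max_match",
    "annotate",
    "annotate_clause",
    "write_annotated_jsonl",
]


@dataclass(frozen=True)
class SemanticClass:
    """A semantic class of the medical lexicon, keyed by a two-letter code."""

    code: str
    name: str

    def __post_init__(self) -> None:
        if not (len(self.code) == 2 and self.code.isascii() and self.code.isupper()):
            raise ValueError(
                f"semantic class code must be two uppercase ASCII letters, got {self.code!r}"
            )


class ClassRegistry:
    """Registry of known semantic classes.

    The full class inventory of a production lexicon is site-specific; the
    default registry ships the classes the extraction rules rely on and is
    freely extensible via :meth:`register`.
    """

    def __init__(self, classes: Iterable[SemanticClass] = ()) -> None:
        self._classes: dict[str, SemanticClass] = {}
        for c in classes:
            self.register(c)

    def register(self, cls: SemanticClass) -> None:
        if cls.code in self._classes and self._classes[cls.code].name != cls.name:
            raise ValueError(f"class code {cls.code} already registered")
        self._classes[cls.code] = cls

    def __contains__(self, code: str) -> bool:
        return code in self._classes

    def __getitem__(self, code: str) -> SemanticClass:
        return self._classes[code]

    def codes(self) -> list[str]:
        return sorted(self._classes)


DEFAULT_REGISTRY = ClassRegistry(
    [
        SemanticClass("BP", "Body part"),
        SemanticClass("ST", "Symptom"),
        SemanticClass("DS", "Description"),
        SemanticClass("DG", "Diagnosis"),
        SemanticClass("MD", "Medication"),
        SemanticClass("EX", "Examination"),
        # Placeholder classes used by the synthetic cohort and default rules;
        # additional site-specific classes can be registered at run time.
        SemanticClass("PS", "Personal history"),
        SemanticClass("SG", "Surgery"),
        SemanticClass("EC", "ECG finding"),
    ]
)


@dataclass(frozen=True)
class Lexicon:
    """Surface-form -> semantic-class-code dictionary.

    ``max_len`` is the length in code points of the longest entry and bounds
    the match window of the reverse maximum-match scan.
    """

    entries: Mapping[str, str]
    max_len: int

    @staticmethod
    def from_entries(entries: Mapping[str, str]) -> "Lexicon":
        for surface in entries:
            if not surface:
                raise ValueError("empty surface form in lexicon")
        max_len = max((len(s) for s in entries), default=0)
        return Lexicon(dict(entries), max_len)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Token:
    """One segment of a clause.

    ``class_code`` is ``None`` for characters the lexicon does not cover;
    ``span`` is a 0-based half-open code-point interval within the clause.
    """

    surface: str
    class_code: str | None
    span: tuple[int, int]


@dataclass(frozen=True)
class AnnotatedClause:
    """A clause with lexicon matches rewritten as ``CODE#k#`` symbols.

    ``index_map`` maps each symbol index ``k`` back to the matched
    :class:`Token`; indices count matched tokens from the end of the clause
    (the rightmost matched token has ``k == 1``).
    """

    original: str
    annotated: str
    index_map: Mapping[int, Token] = field(default_factory=dict)

    def restore(self) -> str:
        """Substitute every symbol by its original surface form."""
        import re

        def _sub(m: "re.Match[str]") -> str:
            return self.index_map[int(m.group(2))].surface

        return re.sub(r"([A-Z]{2})#(\d+)#", _sub, self.annotated)


def load_lexicon(path: str | Path, registry: ClassRegistry = DEFAULT_REGISTRY) -> Lexicon:
    """Load a lexicon from a UTF-8 TSV file (``surface<TAB>class_code``).

    ``#``-prefixed lines are comments.  Duplicate surfaces resolve last-wins
    with a logged warning; unknown class codes and malformed rows raise.
    """
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            surface, code = fields[0], fields[1].strip()
            if not surface:
                raise ValueError(f"{path}:{lineno}: empty surface form")
            if code not in registry:
                raise ValueError(f"{path}:{lineno}: unknown semantic class code {code!r}")
            if surface in entries:
                log.warning("duplicate lexicon surface %r at line %d; last entry wins", surface, lineno)
            entries[surface] = code
    return Lexicon.from_entries(entries)


def tokenize_reverse_max_match(clause: str, lexicon: Lexicon) -> list[Token]:
    """Segment a clause by reverse-directional maximum matching.

    Scanning from the end of the clause, the longest lexicon entry of length
    at most ``max_len`` ending at the current position is emitted as a matched
    token; when no entry matches, a single unmatched character is emitted.
    The returned tokens are in left-to-right order and tile the clause.
    """
    entries = lexicon.entries
    tokens_rev: list[Token] = []
    pos = len(clause)
    while pos > 0:
        match: Token | None = None
        for length in range(min(lexicon.max_len, pos), 0, -1):
            cand = clause[pos - length : pos]
            code = entries.get(cand)
            if code is not None:
                match = Token(cand, code, (pos - length, pos))
                break
        if match is None:
            match = Token(clause[pos - 1], None, (pos - 1, pos))
        tokens_rev.append(match)
        pos = match.span[0]
    tokens_rev.reverse()
    return tokens_rev


def annotate(tokens: Sequence[Token]) -> AnnotatedClause:
    """Rewrite matched tokens as ``CODE#k#`` symbols.

    Indices count matched tokens right-to-left (``k == 1`` is the rightmost
    matched token); unmatched characters pass through verbatim.
    """
    matched = [t for t in tokens if t.class_code is not None]
    m = len(matched)
    index_of = {id(t): m - i for i, t in enumerate(matched)}
    parts: list[str] = []
    index_map: dict[int, Token] = {}
    for t in tokens:
        if t.class_code is None:
            parts.append(t.surface)
        else:
            k = index_of[id(t)]
            parts.append(f"{t.class_code}#{k}#")
            index_map[k] = t
    original = "".join(t.surface for t in tokens)
    return AnnotatedClause(original, "".join(parts), index_map)


def annotate_clause(clause: str, lexicon: Lexicon) -> AnnotatedClause:
    """Tokenize and annotate in one step."""
    return annotate(tokenize_reverse_max_match(clause, lexicon))


def write_annotated_jsonl(clauses: Iterable[AnnotatedClause], path: str | Path) -> None:
    """Debug dump: one JSON object per annotated clause."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in clauses:
            obj = {
                "original": c.original,
                "annotated": c.annotated,
                "index_map": {
                    str(k): {"surface": t.surface, "class": t.class_code, "span": list(t.span)}
                    for k, t in c.index_map.items()
                },
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
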