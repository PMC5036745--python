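"""Character-level BIO sequence labeling with a linear-chain CRF.

The extractor labels every character of an admission record with B/I/O tags
(optionally typed by semantic class, e.g. ``B-ST``), using a fixed feature
template of character unigrams and bigrams in a +/-3 window plus binary
punctuation and negation-word indicators.  The model is a linear-chain
conditional random field fit by L2-regularized conditional likelihood
(forward-backward gradients, L-BFGS); decoding is Viterbi.  Maximal B,I+
runs are extracted as feature spans and passed through the shared
clause-bounded negation detector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .rbmlp import DEFAULT_DELIMITERS, FeatureValuePair, NegationConfig, detect_negation

log = logging.getLogger(__name__)

__all__ = [
    "BIOTaggedSequence",
    "CRFTemplate",
    "SequenceLabeler",
    "instantiate_features",
    "train_labeler",
    "decode",
    "extract_spans",
    "normalize_bio",
    "read_conll",
    "write_conll",
]

_BOS = "BOS"  # sentinel strings; never equal to a real character
_EOS = "EOS"


@dataclass(frozen=True)
class CRFTemplate:
    """Feature template: 7 unigrams, 6 bigrams, 7 punctuation flags and 7
    negation flags per position (27 features)."""

    unigram_offsets: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    bigram_offsets: tuple[int, ...] = (-3, -2, -1, 0, 1, 2)
    punct_offsets: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    neg_offsets: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    punctuation: frozenset = frozenset("，。；：！？、,.;:!?“”\"'（）()")
    negation_chars: frozenset = frozenset("未无不否")

    def __post_init__(self) -> None:
        if not self.punctuation or not self.negation_chars:
            raise ValueError("punctuation and negation-word sets must be non-empty")

    @property
    def n_features(self) -> int:
        return (len(self.unigram_offsets) + len(self.bigram_offsets)
                + len(self.punct_offsets) + len(self.neg_offsets))


DEFAULT_TEMPLATE = CRFTemplate()


@dataclass
class BIOTaggedSequence:
    """A character sequence with aligned BIO tags."""

    chars: list[str]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.tags):
            raise ValueError("chars and tags must have equal length")

    @property
    def text(self) -> str:
        return "".join(self.chars)

    @staticmethod
    def from_text(text: str, tags: Sequence[str]) -> "BIOTaggedSequence":
        return BIOTaggedSequence(list(text), list(tags))

    def validate(self) -> None:
        for i, tag in enumerate(self.tags):
            if tag == "O" or tag.startswith("B"):
                continue
            if tag.startswith("I"):
                prev = self.tags[i - 1] if i else "O"
                if prev == "O" or _tag_type(prev) != _tag_type(tag):
                    raise ValueError(f"invalid BIO transition at position {i}: {prev}->{tag}")
            else:
                raise ValueError(f"invalid tag {tag!r} at position {i}")


def _tag_type(tag: str) -> str:
    return tag.split("-", 1)[1] if "-" in tag else ""


def normalize_bio(tags: Sequence[str]) -> list[str]:
    """Promote I after O / start-of-sequence / a different span type to B."""
    out: list[str] = []
    for i, tag in enumerate(tags):
        if tag.startswith("I"):
            prev = out[i - 1] if i else "O"
            if prev == "O" or _tag_type(prev) != _tag_type(tag):
                tag = "B" + tag[1:]
        out.append(tag)
    return out


def _char_at(chars: Sequence[str], j: int) -> str:
    if j < 0:
        return _BOS
    if j >= len(chars):
        return _EOS
    return chars[j]


def instantiate_features(chars: Sequence[str], position: int,
                         template: CRFTemplate = DEFAULT_TEMPLATE) -> list[str]:
    """Emit the feature strings active at one position (27 under defaults)."""
    if not 0 <= position < len(chars):
        raise IndexError(f"position {position} out of range")
    feats: list[str] = []
    for n in template.unigram_offsets:
        feats.append(f"U{n}={_char_at(chars, position + n)}")
    for n in template.bigram_offsets:
        feats.append(f"B{n}={_char_at(chars, position + n)}/{_char_at(chars, position + n + 1)}")
    for n in template.punct_offsets:
        feats.append(f"P{n}={int(_char_at(chars, position + n) in template.punctuation)}")
    for n in template.neg_offsets:
        feats.append(f"N{n}={int(_char_at(chars, position + n) in template.negation_chars)}")
    return feats


@dataclass
class SequenceLabeler:
    """A trained linear-chain CRF over characters.

    Decoding is deterministic given fixed weights.  ``feature_index`` maps
    feature strings to rows of the emission weight matrix ``w_emit``
    (n_features x n_tags); ``w_trans`` holds tag-transition weights.
    """

    template: CRFTemplate
    tags: list[str]
    feature_index: dict[str, int]
    w_emit: np.ndarray
    w_trans: np.ndarray
    metadata: dict = field(default_factory=dict)

    def decode(self, text: str) -> BIOTaggedSequence:
        return decode(self, text)

    def save(self, path: str | Path) -> None:
        obj = {
            "tags": self.tags,
            "feature_index": self.feature_index,
            "w_emit": self.w_emit.tolist(),
            "w_trans": self.w_trans.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj, ensure_ascii=False), encoding="utf-8")

    @staticmethod
    def load(path: str | Path, template: CRFTemplate = DEFAULT_TEMPLATE) -> "SequenceLabeler":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return SequenceLabeler(template, obj["tags"], obj["feature_index"],
                               np.asarray(obj["w_emit"]), np.asarray(obj["w_trans"]),
                               obj.get("metadata", {}))


def _feature_matrix(chars: Sequence[str], template: CRFTemplate,
                    index: dict[str, int], grow: bool) -> list[list[int]]:
    """Feature ids per position; unknown features are added (training) or
    dropped (decoding)."""
    rows: list[list[int]] = []
    for i in range(len(chars)):
        ids: list[int] = []
        for f in instantiate_features(chars, i, template):
            j = index.get(f)
            if j is None:
                if not grow:
                    continue
                j = len(index)
                index[f] = j
            ids.append(j)
        rows.append(ids)
    return rows


def _emission_scores(rows: list[list[int]], w_emit: np.ndarray, n_tags: int) -> np.ndarray:
    em = np.zeros((len(rows), n_tags))
    for t, ids in enumerate(rows):
        if ids:
            em[t] = w_emit[ids].sum(axis=0)
    return em


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def train_labeler(corpus: Sequence[BIOTaggedSequence],
                  template: CRFTemplate = DEFAULT_TEMPLATE,
                  l2: float = 0.1, max_iter: int = 200,
                  seed: int = 0) -> SequenceLabeler:
    """Fit the CRF by L2-regularized conditional likelihood.

    ``l2`` is the coefficient of the (1/2)||w||^2 penalty; optimization is
    L-BFGS from a zero start, so training is deterministic for a fixed
    corpus (``seed`` is recorded in the model metadata for provenance).
    The forward-backward pass is batched over sequences (padded with a
    length mask) and active features are held in one sparse position x
    feature matrix, so training scales to corpora of full-length records.
    """
    corpus = [s for s in corpus if len(s.chars) > 0]
    if not corpus:
        raise ValueError("training corpus is empty")
    for si, seq in enumerate(corpus):
        try:
            seq.validate()
        except ValueError as e:
            raise ValueError(f"sequence {si}: {e}") from e

    tagset = sorted({t for seq in corpus for t in seq.tags} | {"O"})
    tag_index = {t: i for i, t in enumerate(tagset)}
    S = len(tagset)
    B = len(corpus)
    lengths = np.array([len(s.chars) for s in corpus])
    maxT = int(lengths.max())

    index: dict[str, int] = {}
    seq_rows = [_feature_matrix(seq.chars, template, index, grow=True) for seq in corpus]
    F = len(index)
    k = template.n_features

    from scipy import sparse

    # one sparse (B*maxT, F) indicator matrix of active features; padded
    # positions have empty rows
    rows_idx = []
    cols_idx = []
    for b, rows in enumerate(seq_rows):
        for t, ids in enumerate(rows):
            rows_idx.extend([b * maxT + t] * len(ids))
            cols_idx.extend(ids)
    M = sparse.csr_matrix(
        (np.ones(len(cols_idx)), (np.array(rows_idx), np.array(cols_idx))),
        shape=(B * maxT, F))
    Mt = M.T.tocsr()

    y_pad = np.zeros((B, maxT), dtype=np.intp)
    for b, seq in enumerate(corpus):
        y_pad[b, : lengths[b]] = [tag_index[t] for t in seq.tags]
    valid = np.arange(maxT)[None, :] < lengths[:, None]  # (B, maxT)
    batch = np.arange(B)
    # empirical counts
    emp_emit = np.zeros((B * maxT, S))
    emp_emit[np.arange(B * maxT)[valid.ravel()], y_pad[valid]] = 1.0
    emp_trans = np.zeros((S, S))
    for b in range(B):
        yb = y_pad[b, : lengths[b]]
        np.add.at(emp_trans, (yb[:-1], yb[1:]), 1.0)

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        w_emit = w[: F * S].reshape(F, S)
        w_trans = w[F * S :].reshape(S, S)
        em = (M @ w_emit).reshape(B, maxT, S)
        alpha = np.empty((maxT, B, S))
        alpha[0] = em[:, 0]
        for t in range(1, maxT):
            a = _lse(alpha[t - 1][:, :, None] + w_trans[None], axis=1) + em[:, t]
            alpha[t] = np.where(valid[:, t, None], a, alpha[t - 1])
        beta = np.zeros((maxT, B, S))
        last = lengths - 1
        for t in range(maxT - 2, -1, -1):
            bnext = em[:, t + 1] + beta[t + 1]
            bt = _lse(w_trans[None] + bnext[:, None, :], axis=2)
            beta[t] = np.where((t < last)[:, None], bt, 0.0)
        logz = _lse(alpha[last, batch], axis=1)  # (B,)
        gamma = np.exp(np.transpose(alpha + beta, (1, 0, 2)) - logz[:, None, None])
        gamma[~valid] = 0.0

        score = em[batch[:, None], np.arange(maxT)[None], y_pad][valid].sum()
        score += float((w_trans * emp_trans).sum())
        nll = float(logz.sum()) - score

        g_trans = -emp_trans.copy()
        trans_valid = valid[:, 1:]  # transition t->t+1 exists iff t+1 valid
        for t in range(maxT - 1):
            xi = np.exp(alpha[t][:, :, None] + w_trans[None]
                        + (em[:, t + 1] + beta[t + 1])[:, None, :]
                        - logz[:, None, None])
            xi[~trans_valid[:, t]] = 0.0
            g_trans += xi.sum(axis=0)
        ge = gamma.reshape(B * maxT, S) - emp_emit
        g_emit = Mt @ ge
        nll += 0.5 * l2 * float(w @ w)
        grad = np.concatenate([np.asarray(g_emit).ravel(), g_trans.ravel()]) + l2 * w
        return nll, grad

    w0 = np.zeros(F * S + S * S)
    res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxfun": 2 * max_iter})
    w = res.x
    model = SequenceLabeler(template, tagset, index,
                            w[: F * S].reshape(F, S).copy(),
                            w[F * S :].reshape(S, S).copy(),
                            {"iterations": int(res.nit), "l2": l2, "seed": seed,
                             "converged": bool(res.success), "n_sequences": len(corpus)})
    # Sanity post-condition: at least as good as always predicting the
    # majority tag on the training set.
    n_tok = sum(len(s.tags) for s in corpus)
    majority = max(sum(t == tag for s in corpus for t in s.tags) for tag in tagset) / n_tok
    correct = sum(sum(a == b for a, b in zip(model.decode(s.text).tags, s.tags))
                  for s in corpus)
    if correct / n_tok < majority:
        log.warning("trained CRF underperforms the majority-tag baseline "
                    "(%.3f < %.3f)", correct / n_tok, majority)
    return model


def decode(model: SequenceLabeler, text: str) -> BIOTaggedSequence:
    """Viterbi decoding; predicted taggings are normalized to start spans
    with B."""
    if model.w_emit.size == 0 and not model.feature_index:
        raise ValueError("model is not trained")
    chars = list(text)
    if not chars:
        return BIOTaggedSequence([], [])
    rows = _feature_matrix(chars, model.template, model.feature_index, grow=False)
    S = len(model.tags)
    em = _emission_scores(rows, model.w_emit, S)
    T = len(chars)
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.intp)
    delta[0] = em[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + model.w_trans
        back[t] = cand.argmax(axis=0)
        delta[t] = cand[back[t], np.arange(S)] + em[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(delta[-1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    tags = normalize_bio([model.tags[i] for i in path])
    return BIOTaggedSequence(chars, tags)


def extract_spans(tagged: BIOTaggedSequence,
                  negation: NegationConfig | None = None,
                  record_id: str = "",
                  delimiters: str = DEFAULT_DELIMITERS) -> list[FeatureValuePair]:
    """Turn maximal B,I+ runs into feature-value pairs with polarity.

    Negation is clause-bounded: each span is judged within the clause that
    contains its first character, via the shared negation detector.
    """
    negation = negation or NegationConfig()
    text = tagged.text
    tags = normalize_bio(tagged.tags)
    # clause id and clause-start offset per character
    clause_start = [0] * len(text)
    start = 0
    for i, ch in enumerate(text):
        if ch in delimiters or ch == "\n":
            start = i + 1
        clause_start[i] = start if not (ch in delimiters or ch == "\n") else i
    clause_end = [len(text)] * len(text)
    end = len(text)
    for i in range(len(text) - 1, -1, -1):
        if text[i] in delimiters or text[i] == "\n":
            end = i
        clause_end[i] = end

    pairs: list[FeatureValuePair] = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B"):
            j = i + 1
            while j < len(tags) and tags[j].startswith("I") and _tag_type(tags[j]) == _tag_type(tags[i]):
                j += 1
            cs, ce = clause_start[i], clause_end[i]
            clause = text[cs:ce]
            polarity = detect_negation(clause, (i - cs, min(j, ce) - cs), negation)
            cls = _tag_type(tags[i]) or "unknown"
            pairs.append(FeatureValuePair(text[i:j], True, polarity, record_id,
                                          clause, "crf", cls))
            i = j
        else:
            i += 1
    return pairs


def read_conll(path: str | Path) -> list[BIOTaggedSequence]:
    """Read a CoNLL-style two-column corpus (``char<TAB>tag``, blank-line
    separated sequences)."""
    seqs: list[BIOTaggedSequence] = []
    chars: list[str] = []
    tags: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                if chars:
                    seqs.append(BIOTaggedSequence(chars, tags))
                    chars, tags = [], []
                continue
            ch, tag = line.split("\t")
            chars.append(ch)
            tags.append(tag)
    if chars:
        seqs.append(BIOTaggedSequence(chars, tags))
    return seqs


def write_conll(seqs: Iterable[BIOTaggedSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            for ch, tag in zip(seq.chars, seq.tags):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")
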