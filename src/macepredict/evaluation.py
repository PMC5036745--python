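"""MACE prediction models and their statistical evaluation.

Four classifiers (RBF-kernel SVM, random forest with 1000 trees and
sqrt(p) features per split, naive Bayes, and L1-regularized logistic
regression) are trained under stratified 5-fold cross validation repeated
10 times.  Performance is summarized as the mean AUC over repetitions with
a t-distribution 95% confidence interval; paired ROC curves are compared
with the DeLong structural-components test; risk factors are ranked by
permutation importance (mean decrease in accuracy) for the forest and by
absolute coefficient for the lasso model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

log = logging.getLogger(__name__)

__all__ = [
    "CVProtocol",
    "ClassifierSpec",
    "AUCSummary",
    "DeLongResult",
    "MixedNB",
    "make_classifier",
    "run_cv",
    "auc",
    "summarize_auc",
    "cv_auc_summary",
    "delong_test",
    "delong_cv",
    "feature_subset_models",
    "learning_curve",
    "rank_risk_factors",
]


@dataclass(frozen=True)
class CVProtocol:
    """Stratified k-fold CV repeated several times with derived fold seeds."""

    folds: int = 5
    repetitions: int = 10
    stratified: bool = True
    base_seed: int = 0


@dataclass(frozen=True)
class ClassifierSpec:
    """Serializable description of one classifier.

    ``kind`` is one of ``svm`` (RBF kernel, C/gamma tuned by inner CV),
    ``rf`` (1000 trees, sqrt(p) features per split), ``nb`` (Gaussian on
    numeric columns, Bernoulli on binary ones), ``l1lr`` (lasso logistic
    regression, penalty tuned by inner CV).
    """

    kind: str
    seed: int = 0
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"svm", "rf", "nb", "l1lr"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class AUCSummary:
    """Per-repetition AUCs with mean and t-based 95% confidence interval."""

    values: tuple[float, ...]
    mean: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    diff: float
    variance: float
    z: float
    p_value: float


class MixedNB(BaseEstimator, ClassifierMixin):
    """Naive Bayes with Gaussian likelihoods for numeric columns and
    Bernoulli likelihoods for binary columns, combined by summing
    class-conditional log-likelihoods under one shared class prior."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.binary_cols_ = np.array([
            set(np.unique(X[:, j])) <= {0.0, 1.0} for j in range(X.shape[1])
        ])
        self.classes_ = np.unique(y)
        self.gnb_ = self.bnb_ = None
        if (~self.binary_cols_).any():
            self.gnb_ = GaussianNB().fit(X[:, ~self.binary_cols_], y)
        if self.binary_cols_.any():
            self.bnb_ = BernoulliNB().fit(X[:, self.binary_cols_], y)
        counts = np.array([(y == c).sum() for c in self.classes_], dtype=float)
        self.log_prior_ = np.log(counts / counts.sum())
        return self

    def predict_log_proba(self, X):
        X = np.asarray(X, dtype=float)
        jll = np.tile(self.log_prior_, (len(X), 1))
        if self.gnb_ is not None:
            jll += self.gnb_.predict_log_proba(X[:, ~self.binary_cols_]) - self.log_prior_
        if self.bnb_ is not None:
            jll += self.bnb_.predict_log_proba(X[:, self.binary_cols_]) - self.log_prior_
        # the per-model posteriors are already normalized; renormalize the sum
        from scipy.special import logsumexp
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X):
        return np.exp(self.predict_log_proba(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    """Instantiate the estimator for a spec (introspectable for conformance)."""
    seed = spec.seed if seed is None else seed
    params = dict(spec.params)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 1000)),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed, n_jobs=1)
    if spec.kind == "svm":
        grid = params.get("grid", {"svc__C": [1.0, 10.0], "svc__gamma": ["scale", 0.1]})
        pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        return GridSearchCV(pipe, grid, scoring="roc_auc",
                            cv=StratifiedKFold(int(params.get("inner_folds", 3)),
                                               shuffle=True, random_state=seed))
    if spec.kind == "nb":
        return MixedNB()
    if spec.kind == "l1lr":
        grid = params.get("grid", {"lr__C": [0.01, 0.1, 1.0, 10.0]})
        pipe = Pipeline([("scale", StandardScaler()),
                         ("lr", LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                                   random_state=seed, max_iter=2000))])
        return GridSearchCV(pipe, grid, scoring="roc_auc",
                            cv=StratifiedKFold(int(params.get("inner_folds", 3)),
                                               shuffle=True, random_state=seed))
    raise AssertionError(spec.kind)


def _scores(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def run_cv(X: pd.DataFrame | np.ndarray, y: Sequence[int], spec: ClassifierSpec,
           protocol: CVProtocol = CVProtocol()) -> np.ndarray:
    """Repeated stratified CV; returns out-of-fold scores, shape
    (repetitions, n_patients).  Folds differ across repetitions via seeds
    derived from the protocol base seed; a degenerate single-class training
    fold triggers a refold with a shifted seed."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=int)
    out = np.empty((protocol.repetitions, len(ya)))
    for rep in range(protocol.repetitions):
        rep_seed = (protocol.base_seed + 1000 * rep) % (2**31 - 1)
        for attempt in range(10):
            kf = StratifiedKFold(protocol.folds, shuffle=True,
                                 random_state=rep_seed + attempt)
            splits = list(kf.split(Xa, ya))
            if all(len(np.unique(ya[tr])) == 2 for tr, _ in splits):
                if attempt:
                    log.warning("refolded repetition %d (single-class fold)", rep)
                break
        else:
            raise ValueError("could not produce two-class training folds")
        for tr, te in splits:
            est = clone(make_classifier(spec, seed=rep_seed))
            est.fit(Xa[tr], ya[tr])
            out[rep, te] = _scores(est, Xa[te])
    return out


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve in the Mann-Whitney formulation, ties
    counted one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def summarize_auc(values: Sequence[float]) -> AUCSummary:
    """Mean and t-distribution 95% CI over per-repetition AUCs."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 repetitions to summarize")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(len(v)))
    half = float(stats.t.ppf(0.975, len(v) - 1)) * sem
    return AUCSummary(tuple(np.sort(v)), mean, (mean - half, mean + half))


def cv_auc_summary(scores: np.ndarray, labels: Sequence[int]) -> AUCSummary:
    """Per-repetition AUCs of run_cv output, summarized."""
    return summarize_auc([auc(rep, labels) for rep in scores])


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    return v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> DeLongResult:
    """DeLong's paired test for two correlated ROC curves on shared labels."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("score vectors and labels must have equal length")
    v10a, v01a = _structural_components(sa, y)
    v10b, v01b = _structural_components(sb, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = float((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
                + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = auc_a - auc_b
    if var <= 1e-15:
        z = 0.0
        p = 1.0 if abs(diff) <= 1e-15 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, diff, var, float(z), p)


def delong_cv(scores_a: np.ndarray, scores_b: np.ndarray,
              labels: Sequence[int]) -> float:
    """DeLong on repeated-CV output: test per repetition on the pooled
    out-of-fold scores, report the median p-value."""
    ps = [delong_test(a, b, labels).p_value for a, b in zip(scores_a, scores_b)]
    return float(np.median(ps))


def feature_subset_models(X: pd.DataFrame, y: Sequence[int],
                          subset: Sequence[str],
                          specs: Sequence[ClassifierSpec],
                          protocol: CVProtocol = CVProtocol()) -> dict[str, AUCSummary]:
    """Run the identical protocol on a restricted column set (e.g. the
    GRACE variables) to separate the value of the features from that of the
    learning algorithm."""
    cols = list(subset)
    if not cols:
        raise ValueError("feature subset must be non-empty")
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise KeyError(f"subset columns not in matrix: {missing}")
    Xs = X[cols]
    return {spec.kind: cv_auc_summary(run_cv(Xs, y, spec, protocol), y) for spec in specs}


def learning_curve(X: pd.DataFrame, y: Sequence[int], fractions: Sequence[float],
                   specs: Sequence[ClassifierSpec],
                   protocol: CVProtocol = CVProtocol(),
                   seed: int = 0) -> dict[str, dict[float, AUCSummary]]:
    """CV AUC as a function of cohort size.

    Subsamples draw the same proportion from positives and negatives
    (stratified), preserving prevalence.
    """
    y = np.asarray(y, dtype=int)
    out: dict[str, dict[float, AUCSummary]] = {s.kind: {} for s in specs}
    for i, frac in enumerate(fractions):
        if not 0 < frac <= 1:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        if frac == 1.0:
            Xs, ys = X, y
        else:
            idx = np.arange(len(y))
            sub, _ = train_test_split(idx, train_size=frac, stratify=y,
                                      random_state=(seed + i) % (2**31 - 1))
            Xs, ys = X.iloc[sub], y[sub]
        if min((ys == 1).sum(), (ys == 0).sum()) < protocol.folds:
            raise ValueError(f"fraction {frac} too small for {protocol.folds}-fold CV")
        for spec in specs:
            out[spec.kind][frac] = cv_auc_summary(run_cv(Xs, ys, spec, protocol), ys)
    return out


def rank_risk_factors(kind: str, X: pd.DataFrame, y: Sequence[int],
                      seed: int = 0, top_k: int = 20,
                      n_repeats: int = 5,
                      fitted=None) -> list[tuple[str, float]]:
    """Rank candidate risk factors.

    ``kind == "rf"``: permutation importance (mean decrease in accuracy when
    a column is shuffled, averaged over repeats) of a fitted random forest.
    ``kind == "l1lr"``: nonzero lasso coefficients ranked by magnitude with
    sign retained (positive = risk-increasing).
    """
    ya = np.asarray(y, dtype=int)
    if kind == "rf":
        est = fitted
        if est is None:
            est = make_classifier(ClassifierSpec("rf", seed=seed))
            est.fit(X.values, ya)
        imp = permutation_importance(est, X.values, ya, scoring="accuracy",
                                     n_repeats=n_repeats, random_state=seed, n_jobs=1)
        order = np.argsort(-imp.importances_mean)
        ranked = [(X.columns[j], float(imp.importances_mean[j])) for j in order]
    elif kind == "l1lr":
        est = fitted
        if est is None:
            est = make_classifier(ClassifierSpec("l1lr", seed=seed))
            est.fit(X.values, ya)
        best = est.best_estimator_ if hasattr(est, "best_estimator_") else est
        coefs = best.named_steps["lr"].coef_.ravel()
        nz = [(X.columns[j], float(coefs[j])) for j in range(len(coefs)) if coefs[j] != 0]
        ranked = sorted(nz, key=lambda t: -abs(t[1]))
    else:
        raise ValueError("ranking is defined for 'rf' and 'l1lr'")
    return ranked[:top_k]
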