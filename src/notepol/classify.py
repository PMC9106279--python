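"""Group discrimination from note text features.

Native multinomial Naive-Bayes plus a pluggable backend contract for the
other model families (SVM / random forest / neural network can be supplied
by any library implementing ``fit``/``predict_scores``). All backends share
the same stratified 75/25 split and the same metric suite: rank-based AUC,
sensitivity/specificity, Cohen's kappa, and accuracy with a Clopper-Pearson
interval and an exact one-sided binomial test against the no-information
rate.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Protocol, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "DocTermMatrix",
    "EvalReport",
    "build_dtm",
    "split",
    "NaiveBayes",
    "evaluate",
    "run_model_suite",
    "sklearn_backend",
    "write_reports_csv",
]


@dataclass(frozen=True)
class DocTermMatrix:
    X: np.ndarray  # docs x vocab nonnegative integer counts
    vocabulary: tuple
    y: np.ndarray  # 0/1 labels (1 = positive class)
    note_ids: tuple
    positive_label: str
    negative_label: str
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    seed: int | None = None


def build_dtm(tokenized_notes: Sequence, labels: Mapping, positive_label: str = "covid") -> DocTermMatrix:
    """Bag-of-content-lemma counts; ``labels`` maps note_id -> group."""
    vocab = sorted({t for tok in tokenized_notes for t in tok.flat_content()})
    index = {t: i for i, t in enumerate(vocab)}
    X = np.zeros((len(tokenized_notes), len(vocab)), dtype=np.int64)
    y = np.zeros(len(tokenized_notes), dtype=np.int64)
    ids = []
    neg_labels = sorted({g for g in labels.values() if g != positive_label})
    if len(neg_labels) != 1:
        raise ValueError(f"expected one non-positive class, got {neg_labels}")
    for d, tok in enumerate(tokenized_notes):
        ids.append(tok.note_id)
        for t in tok.flat_content():
            X[d, index[t]] += 1
        y[d] = 1 if labels[tok.note_id] == positive_label else 0
    return DocTermMatrix(X, tuple(vocab), y, tuple(ids), positive_label, neg_labels[0])


def split(dtm: DocTermMatrix, train_frac: float = 0.75, seed: int = 0) -> DocTermMatrix:
    """Stratified train/test assignment, deterministic per seed."""
    if dtm.X.shape[0] < 8:
        raise ValueError("split: need >= 8 documents")
    if not (dtm.y == 0).any() or not (dtm.y == 1).any():
        raise ValueError("split: both classes must be present")
    rng = np.random.default_rng(seed)
    # largest-remainder allocation: totals hit round(frac*N) exactly while
    # each class stays within one doc of its own proportion
    n_total = int(round(train_frac * dtm.X.shape[0]))
    targets = {c: train_frac * np.sum(dtm.y == c) for c in (0, 1)}
    counts = {c: int(np.floor(t)) for c, t in targets.items()}
    leftover = n_total - sum(counts.values())
    for c in sorted(targets, key=lambda c: targets[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1
    train, test = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.where(dtm.y == cls)[0])
        train.extend(idx[: counts[cls]])
        test.extend(idx[counts[cls] :])
    return replace(
        dtm,
        train_idx=np.sort(np.asarray(train)),
        test_idx=np.sort(np.asarray(test)),
        seed=seed,
    )


class Backend(Protocol):
    """Classifier contract: fit on counts, emit real-valued scores where
    larger means more likely positive class, plus hard labels."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Backend": ...

    def predict_scores(self, X: np.ndarray) -> tuple: ...


class NaiveBayes:
    """Multinomial Naive-Bayes with add-1 (Laplace) smoothing.

    Scores are posterior log-odds of the positive class; labels by argmax
    posterior.
    """

    def __init__(self, smoothing: float = 1.0):
        self.smoothing = smoothing
        self.log_prior_: np.ndarray | None = None
        self.log_lik_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayes":
        X = np.asarray(X)
        classes = (0, 1)
        n = X.shape[0]
        self.log_prior_ = np.array([np.log(np.sum(y == c) / n) for c in classes])
        V = X.shape[1]
        ll = np.empty((2, V))
        for c in classes:
            counts = X[y == c].sum(axis=0) + self.smoothing
            ll[c] = np.log(counts / counts.sum())
        self.log_lik_ = ll
        return self

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.log_lik_.T + self.log_prior_

    def predict_scores(self, X: np.ndarray) -> tuple:
        jll = self.joint_log_likelihood(X)
        scores = jll[:, 1] - jll[:, 0]
        labels = (scores > 0).astype(np.int64)
        return scores, labels


def sklearn_backend(kind: str, seed: int = 0):
    """Pluggable backends for the externally-implemented model families."""
    if kind == "svm":
        from sklearn.svm import SVC

        clf = SVC(kernel="linear", random_state=seed)
        score_fn = "decision_function"
    elif kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        score_fn = "predict_proba"
    elif kind == "neural_network":
        from sklearn.neural_network import MLPClassifier

        clf = MLPClassifier(hidden_layer_sizes=(32,), max_iter=500, random_state=seed)
        score_fn = "predict_proba"
    else:
        raise ValueError(f"unknown backend kind {kind!r}")

    class _Wrapper:
        def fit(self, X, y):
            clf.fit(X, y)
            return self

        def predict_scores(self, X):
            if score_fn == "decision_function":
                scores = clf.decision_function(X)
            else:
                scores = clf.predict_proba(X)[:, 1]
            return scores, clf.predict(X).astype(np.int64)

    return _Wrapper()


@dataclass(frozen=True)
class EvalReport:
    model: str
    auc: float | None
    sensitivity: float
    specificity: float
    kappa: float
    accuracy: float
    accuracy_ci95: tuple
    accuracy_p: float
    no_information_rate: float
    confusion: tuple  # ((tn, fp), (fn, tp))
    n_test: int
    flags: tuple = ()


def _rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation with mid-rank ties."""
    n1 = int(truth.sum())
    n0 = truth.size - n1
    ranks = sps.rankdata(scores)
    r1 = ranks[truth == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(scores, labels, truth, model: str = "model") -> EvalReport:
    """Full metric suite on a test set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    n = truth.size
    if n < 4:
        raise ValueError("evaluate: test size must be >= 4")
    flags = []
    if truth.min() == truth.max():
        auc = None
        flags.append("single-class truth: AUC undefined")
    else:
        auc = _rank_auc(scores, truth)

    tp = int(np.sum((labels == 1) & (truth == 1)))
    tn = int(np.sum((labels == 0) & (truth == 0)))
    fp = int(np.sum((labels == 1) & (truth == 0)))
    fn = int(np.sum((labels == 0) & (truth == 1)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / n

    p_yes = (tp + fp) / n * (tp + fn) / n
    p_no = (tn + fn) / n * (tn + fp) / n
    p_e = p_yes + p_no
    kappa = 0.0 if p_e == 1.0 else (acc - p_e) / (1.0 - p_e)

    k = tp + tn
    lo = 0.0 if k == 0 else float(sps.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(0.975, k + 1, n - k))
    nir = max(truth.mean(), 1 - truth.mean())
    acc_p = float(sps.binomtest(k, n, p=nir, alternative="greater").pvalue)

    return EvalReport(
        model=model,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        kappa=float(kappa),
        accuracy=float(acc),
        accuracy_ci95=(lo, hi),
        accuracy_p=acc_p,
        no_information_rate=float(nir),
        confusion=((tn, fp), (fn, tp)),
        n_test=n,
        flags=tuple(flags),
    )


def run_model_suite(dtm: DocTermMatrix, backends: Mapping, seed: int = 0) -> dict:
    """Fit every backend on one shared split and evaluate identically.

    A backend failure is isolated: its entry carries the error string
    instead of a report.
    """
    if dtm.train_idx is None:
        dtm = split(dtm, seed=seed)
    Xtr, ytr = dtm.X[dtm.train_idx], dtm.y[dtm.train_idx]
    Xte, yte = dtm.X[dtm.test_idx], dtm.y[dtm.test_idx]
    out = {}
    for name, backend in backends.items():
        try:
            backend.fit(Xtr, ytr)
            scores, labels = backend.predict_scores(Xte)
            out[name] = evaluate(scores, labels, yte, model=name)
        except Exception as exc:  # isolate per model
            log.exception("backend %s failed", name)
            out[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return out


def write_reports_csv(reports: Mapping, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["model", "auc", "sensitivity", "specificity", "kappa", "accuracy", "ci_low", "ci_high", "p_vs_nir"]
        )
        for name, rep in reports.items():
            if isinstance(rep, dict):
                writer.writerow([name, "ERROR", rep.get("error", ""), "", "", "", "", "", ""])
                continue
            writer.writerow(
                [
                    name,
                    "" if rep.auc is None else f"{rep.auc:.4f}",
                    f"{rep.sensitivity:.4f}",
                    f"{rep.specificity:.4f}",
                    f"{rep.kappa:.4f}",
                    f"{rep.accuracy:.4f}",
                    f"{rep.accuracy_ci95[0]:.4f}",
                    f"{rep.accuracy_ci95[1]:.4f}",
                    f"{rep.accuracy_p:.3g}",
                ]
            )
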