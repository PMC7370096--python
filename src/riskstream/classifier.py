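"""The depression language classifier.

Each training user is represented by a single document — the concatenation
of everything they wrote — vectorised to term counts, transformed to a
normalised tf-idf vector, and fed to an L1-regularised logistic regression.
The L1 penalty drives uninformative term weights exactly to zero, so the
fitted model is sparse and cheap to apply per message.  The regularisation
strength C is chosen by stratified cross-validation on the training split
(maximising mean positive-class F1, ties resolved towards stronger
regularisation) and the winner is refitted on all training data.

The fitted artifact is self-contained: vocabulary, idf weights, coefficient
vector and intercept are stored together, and prediction is computed
directly from them (``sigmoid(beta . x + beta0)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .records import Chronology, GoldenTruth
from .textrep import (
    CountVector,
    TfidfWeights,
    Vocabulary,
    build_vocabulary,
    counts_to_csr,
    fit_idf,
    tfidf_transform,
    tokenize,
    vectorize,
)

__all__ = [
    "LabeledCorpus",
    "DepressionModel",
    "build_user_documents",
    "fit_model",
    "predict_proba",
    "train_from_chronologies",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
_OPTIMIZER_TOL = 1e-6


@dataclass(frozen=True)
class LabeledCorpus:
    """One record per user: concatenated-text count vector plus binary label."""

    users: tuple[str, ...]
    counts: tuple[CountVector, ...]
    labels: np.ndarray  # 0 control, 1 depressed
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        if not (len(self.users) == len(self.counts) == len(self.labels)):
            raise ValueError("users, counts and labels must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")


@dataclass(frozen=True)
class DepressionModel:
    vocabulary: Vocabulary
    weights: TfidfWeights
    coef: np.ndarray
    intercept: float
    C: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    def top_terms(self, k: int = 10) -> list[str]:
        """Terms with the largest absolute coefficients."""
        order = np.argsort(-np.abs(self.coef), kind="stable")[:k]
        terms = self.vocabulary.terms
        return [terms[i] for i in order]

    def score_counts(self, cv: CountVector) -> float:
        """Probability of depression from an accumulated count vector."""
        x = tfidf_transform(cv, self.weights)
        return predict_proba(self, x)

    def score_text(self, text: str) -> float:
        return self.score_counts(vectorize(tokenize(text), self.vocabulary))

    # -- artifact I/O (versioned JSON; coefficients stored sparse) --

    def save(self, path: str | Path) -> None:
        nz = np.nonzero(self.coef)[0]
        artifact = {
            "format": "riskstream-model",
            "version": 1,
            "terms": self.vocabulary.terms,
            "idf": self.idf_list(),
            "coef_indices": nz.tolist(),
            "coef_values": self.coef[nz].tolist(),
            "intercept": float(self.intercept),
            "C": float(self.C),
            "metadata": dict(self.metadata),
        }
        Path(path).write_text(json.dumps(artifact), encoding="utf-8")

    def idf_list(self) -> list[float]:
        return [float(v) for v in self.weights.idf]

    @classmethod
    def load(cls, path: str | Path) -> "DepressionModel":
        artifact = json.loads(Path(path).read_text(encoding="utf-8"))
        if artifact.get("format") != "riskstream-model":
            raise ValueError(f"{path}: not a riskstream model artifact")
        terms = artifact["terms"]
        vocab = Vocabulary({t: i for i, t in enumerate(terms)})
        coef = np.zeros(len(terms))
        coef[np.asarray(artifact["coef_indices"], dtype=int)] = artifact["coef_values"]
        return cls(
            vocabulary=vocab,
            weights=TfidfWeights(np.asarray(artifact["idf"], dtype=float)),
            coef=coef,
            intercept=float(artifact["intercept"]),
            C=float(artifact["C"]),
            metadata=artifact.get("metadata", {}),
        )


def build_user_documents(
    chronologies: Sequence[Chronology],
    truth: GoldenTruth,
    vocabulary: Vocabulary | None = None,
    min_df: int = 2,
) -> LabeledCorpus:
    """Represent each user as one concatenated document of all their writings.

    If no vocabulary is supplied one is built from these documents with the
    given document-frequency floor.  Users absent from *truth* raise; users
    with zero submissions cannot occur (chronologies are non-empty by type).
    """
    token_docs = [tokenize(" ".join(c.texts())) for c in chronologies]
    if vocabulary is None:
        vocabulary = build_vocabulary(token_docs, min_df=min_df)
    users = []
    counts = []
    labels = []
    for chron, tokens in zip(chronologies, token_docs):
        if chron.user not in truth:
            raise KeyError(f"user {chron.user!r} missing from golden truth")
        users.append(chron.user)
        counts.append(vectorize(tokens, vocabulary))
        labels.append(int(truth[chron.user]))
    return LabeledCorpus(
        users=tuple(users),
        counts=tuple(counts),
        labels=np.asarray(labels, dtype=int),
        vocabulary=vocabulary,
    )


def _stack_tfidf(corpus: LabeledCorpus, weights: TfidfWeights) -> sp.csr_matrix:
    return sp.vstack(
        [tfidf_transform(cv, weights) for cv in corpus.counts], format="csr"
    )


def fit_model(
    corpus: LabeledCorpus,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 4,
    seed: int = 0,
) -> DepressionModel:
    """Cross-validate C on stratified folds, then refit on all training data.

    Deterministic given (corpus, grid, folds, seed).  Raises on a
    single-class corpus or when either class has fewer users than folds.
    """
    if len(C_grid) == 0:
        raise ValueError("C_grid must be non-empty")
    y = corpus.labels
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("corpus must contain both classes")
    if int(class_counts.min()) < folds:
        raise ValueError(
            f"need at least {folds} users per class for {folds}-fold CV, "
            f"got {dict(zip(classes.tolist(), class_counts.tolist()))}"
        )

    weights = fit_idf(list(corpus.counts))
    X = _stack_tfidf(corpus, weights)

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(splitter.split(X, y))
    best_C = None
    best_f1 = -np.inf
    cv_table = {}
    for C in C_grid:
        scores = []
        for train_idx, val_idx in split:
            clf = _make_estimator(C, seed)
            clf.fit(X[train_idx], y[train_idx])
            scores.append(f1_score(y[val_idx], clf.predict(X[val_idx]), zero_division=0))
        mean_f1 = float(np.mean(scores))
        cv_table[C] = mean_f1
        if mean_f1 > best_f1 + 1e-12:  # ties keep the earlier (smaller) C
            best_f1 = mean_f1
            best_C = C

    final = _make_estimator(best_C, seed)
    final.fit(X, y)
    return DepressionModel(
        vocabulary=corpus.vocabulary,
        weights=weights,
        coef=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        C=float(best_C),
        metadata={
            "folds": folds,
            "seed": seed,
            "C_grid": [float(c) for c in C_grid],
            "cv_mean_f1": {str(c): v for c, v in cv_table.items()},
            "selection_metric": "mean_cv_f1_positive_class",
            "n_train_users": int(len(y)),
            "n_positive": int(y.sum()),
        },
    )


def _make_estimator(C: float, seed: int) -> LogisticRegression:
    # pure L1 penalty; liblinear yields exact zeros for uninformative terms
    return LogisticRegression(
        l1_ratio=1.0,
        C=C,
        solver="liblinear",
        tol=_OPTIMIZER_TOL,
        random_state=seed,
        max_iter=1000,
    )


def predict_proba(model: DepressionModel, x: sp.spmatrix | np.ndarray) -> float:
    """``sigmoid(beta . x + beta0)`` for a single tf-idf row vector."""
    if sp.issparse(x):
        if x.shape[1] != len(model.coef):
            raise ValueError(
                f"dimension mismatch: model {len(model.coef)}, input {x.shape[1]}"
            )
        z = float(x.dot(model.coef)[0]) + model.intercept
    else:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != len(model.coef):
            raise ValueError(
                f"dimension mismatch: model {len(model.coef)}, input {x.shape[0]}"
            )
        z = float(model.coef @ x) + model.intercept
    return float(expit(z))


def train_from_chronologies(
    chronologies: Sequence[Chronology],
    truth: GoldenTruth,
    min_df: int = 2,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 4,
    seed: int = 0,
) -> DepressionModel:
    """End-to-end training convenience: documents -> vocabulary -> model."""
    corpus = build_user_documents(chronologies, truth, min_df=min_df)
    return fit_model(corpus, C_grid=C_grid, folds=folds, seed=seed)
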