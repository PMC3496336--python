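"""Precision/recall/F-measure, ROC/AUC, and document-level cross-validation.

Evaluation is mention-pair-level: a prediction is correct iff its unordered
mention pair is a gold relation.  Recall is measured against the gold
relations recoverable at the method's scope (within-sentence relations for
sentence-level methods).  Cross-validation folds split at the document
level, so sentences of one abstract never appear in both the training and
the test set.  Metrics are pooled (micro) across held-out folds; per-fold
metrics are also reported.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .corpus import AbstractDocument, within_sentence_relations

__all__ = [
    "EvalResult",
    "FoldAssignment",
    "CVReport",
    "precision_recall_f",
    "roc_auc",
    "document_kfold",
    "cross_validate",
    "gold_keys",
]

PairKey = tuple[str, frozenset]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    auc: float | None = None

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, auc: float | None = None
    ) -> "EvalResult":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(
            tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_measure=f, auc=auc
        )


@dataclass
class FoldAssignment:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_doc_ids(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)


@dataclass
class CVReport:
    pooled: EvalResult
    per_fold: list[EvalResult]
    folds: FoldAssignment
    scored: list = field(default_factory=list, repr=False)


def gold_keys(
    docs: list[AbstractDocument], scope: str = "sentence"
) -> set[PairKey]:
    """Order-insensitive keys of the gold relations recoverable at *scope*."""
    keys: set[PairKey] = set()
    for doc in docs:
        relations = (
            within_sentence_relations(doc)
            if scope == "sentence"
            else doc.relations
        )
        keys.update((doc.doc_id, r.key()) for r in relations)
    return keys


def precision_recall_f(
    predicted_keys: set[PairKey], gold: set[PairKey]
) -> EvalResult:
    """Set-intersection scoring of predicted against gold mention pairs."""
    tp = len(predicted_keys & gold)
    return EvalResult.from_counts(
        tp=tp, fp=len(predicted_keys) - tp, fn=len(gold) - tp
    )


def roc_auc(scores, labels):
    """AUC (Mann-Whitney with ties counted half) and the ROC curve points.

    Returns ``(auc, points)`` where points are (fpr, tpr) pairs at each
    distinct threshold.  Requires at least one positive and one negative.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires >=1 positive and >=1 negative label")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def document_kfold(
    corpus: list[AbstractDocument], k: int, seed: int
) -> FoldAssignment:
    """Shuffle documents with *seed* and deal them round-robin into k folds.

    Fold sizes differ by at most one; all candidate pairs of a document
    share its fold.
    """
    doc_ids = [d.doc_id for d in corpus]
    if k > len(doc_ids):
        raise ValueError(
            f"k={k} exceeds the number of documents ({len(doc_ids)})"
        )
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = random.Random(seed)
    shuffled = sorted(doc_ids)
    rng.shuffle(shuffled)
    return FoldAssignment(
        k=k,
        assignment={d: i % k for i, d in enumerate(shuffled)},
        seed=seed,
    )


def _evaluate_scored(scored, gold: set[PairKey]) -> EvalResult:
    predicted = {p.key() for p, s in scored if s > 0.0}
    result = precision_recall_f(predicted, gold)
    labels = [bool(p.label) for p, _ in scored]
    if any(labels) and not all(labels):
        result.auc = roc_auc([s for _, s in scored], labels)[0]
    return result


def _evaluate_predicted(predicted_pairs, gold: set[PairKey]) -> EvalResult:
    return precision_recall_f({p.key() for p in predicted_pairs}, gold)


def cross_validate(
    corpus: list[AbstractDocument], method, k: int = 10, seed: int = 0
) -> CVReport:
    """Document-level k-fold CV of an extraction method.

    *method* follows the extractor contract (``connextract.methods``):
    ``trainable``/``scope`` attributes, ``fit(docs)`` and
    ``predict(docs) -> [(CandidatePair, score), ...]``.  Trainable methods
    are fit on k-1 folds and score every candidate pair of the held-out
    fold; rule methods are training-free and simply predict.  Held-out
    predictions are pooled and metrics computed once on the pool.
    """
    folds = document_kfold(corpus, k, seed)
    by_id = {d.doc_id: d for d in corpus}
    scope = getattr(method, "scope", "sentence")
    gold_all = gold_keys(corpus, scope)

    pooled_scored: list = []
    per_fold: list[EvalResult] = []
    for fold in range(k):
        test_ids = set(folds.fold_doc_ids(fold))
        test_docs = [by_id[d] for d in sorted(test_ids)]
        gold_fold = gold_keys(test_docs, scope)
        if method.trainable:
            train_docs = [
                d for d in corpus if d.doc_id not in test_ids
            ]
            method.fit(train_docs)
            scored = method.predict(test_docs)
            labels = [bool(p.label) for p, _ in scored]
            if all(labels) or not any(labels):
                raise ValueError(
                    f"fold {fold} has a single class; merge folds or reseed"
                )
        else:
            scored = method.predict(test_docs)
        pooled_scored.extend(scored)
        if method.trainable:
            per_fold.append(_evaluate_scored(scored, gold_fold))
        else:
            per_fold.append(
                _evaluate_predicted([p for p, _ in scored], gold_fold)
            )

    if method.trainable:
        pooled = _evaluate_scored(pooled_scored, gold_all)
    else:
        pooled = _evaluate_predicted(
            [p for p, _ in pooled_scored], gold_all
        )
    return CVReport(
        pooled=pooled, per_fold=per_fold, folds=folds, scored=pooled_scored
    )
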