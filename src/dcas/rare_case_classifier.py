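"""Random-forest probability classifier over the TF-IDF matrix.

A 1,500-tree forest (scikit-learn) trained on the labeled narratives,
with stratified 5-fold out-of-fold probabilities for honest metric
estimation, Gini (mean decrease in node impurity) token importances, and a
strict vocabulary-signature contract at prediction time.  Class probability
is the forest's averaged tree vote for the case class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .text_prep import TokenMatrix

__all__ = ["ForestParams", "ClassifierFit", "train_cv", "predict_prob", "importance"]

POSITIVE, NEGATIVE = "DCAS", "non-DCAS"


@dataclass
class ForestParams:
    """Forest and cross-validation settings.

    Defaults follow the study design: 1,500 trees, 5 folds, sqrt(p) candidate
    features per split, no class weighting beyond the roughly 1:3 labeled
    balance produced by keyword-seeded sampling.
    """

    n_trees: int = 1500
    n_folds: int = 5
    max_features: str | int | float = "sqrt"
    min_samples_leaf: int = 1
    class_weight: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class ClassifierFit:
    """A fitted ensemble plus its cross-validation record.

    ``token_signature`` pins the training column set; prediction requires an
    identical vocabulary (order-insensitive: columns are realigned).
    ``oof_probs`` holds one out-of-fold case probability per labeled
    document, keyed like ``doc_ids``.
    """

    model: RandomForestClassifier = field(repr=False)
    token_signature: tuple[str, ...]
    doc_ids: tuple[str, ...]
    oof_probs: np.ndarray
    cv_metrics: dict[str, float]
    importances: np.ndarray = field(repr=False)
    params: ForestParams = field(default_factory=ForestParams)


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    unknown = set(arr.tolist()) - {POSITIVE, NEGATIVE}
    if unknown:
        raise ValueError(f"labels must be {POSITIVE!r}/{NEGATIVE!r}; got {unknown}")
    return (arr == POSITIVE).astype(int)


def _cv_metric_set(y: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    from .estimation_eval import ConfusionSummary, metrics

    m = metrics(ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, assumption="cv"))
    return {
        k: v
        for k, v in (
            ("sensitivity", m.sensitivity),
            ("specificity", m.specificity),
            ("precision", m.precision),
            ("npv", m.npv),
            ("f1", m.f1),
        )
        if v is not None
    }


def train_cv(
    tm: TokenMatrix,
    labels: Mapping[str, str] | Sequence[str],
    params: ForestParams | None = None,
) -> ClassifierFit:
    """Cross-validate and fit the forest on the labeled rows.

    ``tm`` holds exactly the labeled documents (rows of the corpus-wide
    TF-IDF matrix).  Every labeled document receives exactly one out-of-fold
    probability from a stratified k-fold; CV metrics are computed at
    threshold 0.5; the returned ensemble is refit on all labeled rows.
    Deterministic given ``params.seed``.
    """
    params = params or ForestParams()
    if isinstance(labels, Mapping):
        y_labels = [labels[d] for d in tm.doc_ids]
    else:
        y_labels = list(labels)
        if len(y_labels) != len(tm.doc_ids):
            raise ValueError("labels length does not match matrix rows")
    y = _as_binary(y_labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training labels contain a single class; need both")
    minority = min(n_pos, n_neg)
    if params.n_folds > minority:
        raise ValueError(
            f"n_folds={params.n_folds} exceeds the minority class size "
            f"({minority}); reduce n_folds or label more narratives"
        )

    X = tm.matrix.tocsr()

    def make_forest(seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features=params.max_features,
            min_samples_leaf=params.min_samples_leaf,
            class_weight=params.class_weight,
            random_state=seed,
            n_jobs=1,
        )

    skf = StratifiedKFold(n_splits=params.n_folds, shuffle=True, random_state=params.seed)
    oof = np.full(len(y), np.nan)
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        forest = make_forest(params.seed + 1 + k).fit(X[train_idx], y[train_idx])
        pos_col = int(np.flatnonzero(forest.classes_ == 1)[0])
        oof[test_idx] = forest.predict_proba(X[test_idx])[:, pos_col]
    assert not np.isnan(oof).any()

    final = make_forest(params.seed).fit(X, y)
    return ClassifierFit(
        model=final,
        token_signature=tuple(tm.tokens),
        doc_ids=tuple(tm.doc_ids),
        oof_probs=oof,
        cv_metrics=_cv_metric_set(y, oof),
        importances=final.feature_importances_.copy(),
        params=params,
    )


def predict_prob(fit: ClassifierFit, tm: TokenMatrix) -> dict[str, float]:
    """Per-document case probability (fraction of tree votes), id-keyed.

    The matrix must carry exactly the training vocabulary; a permuted column
    order is realigned, anything else is an error naming the offending
    tokens.
    """
    if tuple(tm.tokens) != fit.token_signature:
        missing = sorted(set(fit.token_signature) - set(tm.tokens))
        extra = sorted(set(tm.tokens) - set(fit.token_signature))
        if missing or extra:
            raise ValueError(
                "vocabulary mismatch with the fitted model; "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''}, "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        idx = {t: j for j, t in enumerate(tm.tokens)}
        order = [idx[t] for t in fit.token_signature]
        X = tm.matrix[:, order]
    else:
        X = tm.matrix
    pos_col = int(np.flatnonzero(fit.model.classes_ == 1)[0])
    probs = fit.model.predict_proba(X.tocsr())[:, pos_col]
    return dict(zip(tm.doc_ids, probs.tolist()))


def importance(fit: ClassifierFit) -> list[tuple[str, float]]:
    """Tokens ranked by mean decrease in Gini impurity (descending; ties
    broken lexicographically).  Constant columns never split and score 0."""
    pairs = list(zip(fit.token_signature, fit.importances.tolist()))
    return sorted(pairs, key=lambda p: (-p[1], p[0]))
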