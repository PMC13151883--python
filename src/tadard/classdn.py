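"""ClassDn: imbalanced-data classifiers for inheritance class.

A typical offspring exome carries one to two de novo PTVs against roughly
thirty times as many rare inherited ones, so a naive learner trained on
family data all but ignores the minority class. ClassDn therefore uses
resampling ensembles built for class imbalance:

* **RUSBoost** — AdaBoost.M1 in which each boosting round randomly
  undersamples the majority (inherited) class down to ``sampling_ratio``
  before fitting the base learner; the boosting weights are updated on
  the full training set.
* **UnderBagging** — a bag of base learners, each fitted on an
  independent balanced undersample of the majority class (all minority
  examples kept).

Both output a de novo score in [0, 1] per variant: for UnderBagging the
fraction of base learners voting de novo, for RUSBoost the
alpha-weighted vote fraction. A variant is classified likely de novo iff
its score strictly exceeds the chosen threshold; the trade-off is
summarized by sensitivity w1 = P(called de novo | de novo) and
specificity w2 = P(called inherited | inherited).
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .variant_io import (
    COVARIATES,
    InheritanceLabel,
    PredictedClass,
    VariantRecord,
)

__all__ = [
    "ClassifierModel",
    "ClassifierPerformance",
    "train",
    "score",
    "score_records",
    "classify",
    "classify_records",
    "evaluate",
    "threshold_sweep",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class ClassifierModel:
    """A fitted resampling ensemble plus its imputation state."""

    algorithm: str
    n_estimators: int
    base_learner_depth: int
    sampling_ratio: float
    seed: int
    imputation_values: dict[str, float] = field(default_factory=dict)
    estimators: list = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return bool(self.estimators)


@dataclass
class ClassifierPerformance:
    """Sensitivity/specificity of a thresholded classifier.

    ``w1`` (sensitivity) is the probability a de novo variant is called
    likely de novo; ``w2`` (specificity) the probability an inherited
    variant is called likely inherited. Either is ``nan`` when its truth
    class is empty.
    """

    threshold_c: float
    w1: float
    w2: float
    n_de_novo_eval: int
    n_inherited_eval: int


def _design_matrix(
    records: Sequence[VariantRecord], imputation: dict[str, float] | None
) -> np.ndarray:
    X = np.array(
        [[getattr(r, c) for c in COVARIATES] for r in records], dtype=float
    )
    if imputation:
        for j, c in enumerate(COVARIATES):
            col = X[:, j]
            col[np.isnan(col)] = imputation[c]
    return X


def _labels(records: Sequence[VariantRecord]) -> np.ndarray:
    y = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        if r.inheritance_label is InheritanceLabel.DE_NOVO:
            y[i] = 1
        elif r.inheritance_label is InheritanceLabel.INHERITED:
            y[i] = 0
        else:
            raise ValueError(f"variant {r.variant_id} has no training label")
    return y


def _undersample(
    minority: np.ndarray,
    majority: np.ndarray,
    ratio: float,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of all minority rows plus a majority subsample.

    ``ratio`` is minority:majority after sampling (1.0 = balanced). When
    boosting weights are supplied the majority subsample is drawn with
    probability proportional to weight, concentrating each round on the
    majority examples the ensemble currently gets wrong.
    """
    n_major = min(len(majority), max(1, int(round(len(minority) / ratio))))
    if weights is not None:
        p = weights[majority]
        p = p / p.sum()
        picked = rng.choice(majority, size=n_major, replace=False, p=p)
    else:
        picked = rng.choice(majority, size=n_major, replace=False)
    return np.concatenate([minority, picked])


def train(
    records: Sequence[VariantRecord],
    algorithm: str = "rusboost",
    n_estimators: int = 100,
    base_learner_depth: int = 3,
    sampling_ratio: float = 1.0,
    seed: int = 0,
) -> ClassifierModel:
    """Fit a ClassDn ensemble on labeled family-based variants.

    Missing covariates are imputed by training-set medians, which are
    stored on the model and re-applied at scoring time. Deterministic
    under a fixed seed.
    """
    if algorithm not in ("rusboost", "underbagging"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if not records:
        raise ValueError("training set is empty")
    y = _labels(records)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both inheritance classes")
    X_raw = _design_matrix(records, imputation=None)
    imputation = {}
    for j, c in enumerate(COVARIATES):
        col = X_raw[:, j]
        med = float(np.nanmedian(col)) if not np.all(np.isnan(col)) else 0.0
        imputation[c] = med
    model = ClassifierModel(
        algorithm=algorithm,
        n_estimators=n_estimators,
        base_learner_depth=base_learner_depth,
        sampling_ratio=sampling_ratio,
        seed=seed,
        imputation_values=imputation,
    )
    X = _design_matrix(records, imputation)
    rng = np.random.default_rng(seed)
    minority = np.flatnonzero(y == 1)
    majority = np.flatnonzero(y == 0)
    if len(minority) > len(majority):  # unusual, but keep the roles straight
        minority, majority = majority, minority

    if algorithm == "underbagging":
        for t in range(n_estimators):
            idx = _undersample(minority, majority, sampling_ratio, rng)
            tree = DecisionTreeClassifier(
                max_depth=base_learner_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            model.estimators.append(tree)
            model.alphas.append(1.0)
        return model

    # RUSBoost: AdaBoost.M1 with random undersampling before each round.
    n = len(y)
    w = np.full(n, 1.0 / n)
    eps = 1e-10
    for t in range(n_estimators):
        idx = _undersample(minority, majority, sampling_ratio, rng, weights=w)
        tree = DecisionTreeClassifier(
            max_depth=base_learner_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        sw = w[idx]
        tree.fit(X[idx], y[idx], sample_weight=sw / sw.sum())
        pred = tree.predict(X)
        miss = pred != y
        err = float(np.clip(w[miss].sum() / w.sum(), eps, 1 - eps))
        if err >= 0.5:
            # worse than chance on the weighted set: skip this round
            continue
        alpha = 0.5 * math.log((1 - err) / err)
        w = w * np.exp(alpha * np.where(miss, 1.0, -1.0))
        w = w / w.sum()
        model.estimators.append(tree)
        model.alphas.append(alpha)
    if not model.estimators:
        raise RuntimeError("boosting failed: no round beat chance")
    return model


def score(model: ClassifierModel, records: Sequence[VariantRecord]) -> np.ndarray:
    """De novo score in [0, 1] for each record (higher = more de novo-like)."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    if not records:
        return np.empty(0)
    X = _design_matrix(records, model.imputation_values)
    votes = np.zeros(len(records))
    total = float(sum(model.alphas))
    for tree, alpha in zip(model.estimators, model.alphas):
        votes += alpha * (tree.predict(X) == 1)
    return votes / total


def score_records(
    model: ClassifierModel, records: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Return copies of ``records`` with ``de_novo_score`` populated."""
    s = score(model, records)
    return [r.with_score(float(si)) for r, si in zip(records, s)]


def classify(scores: Sequence[float], threshold_c: float) -> list[PredictedClass]:
    """Threshold scores: likely de novo iff score strictly exceeds c.

    A score exactly equal to the threshold is likely inherited (a variant
    must *exceed* the threshold to be called de novo).
    """
    if not 0.0 <= threshold_c <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    return [
        PredictedClass.LIKELY_DE_NOVO if s > threshold_c
        else PredictedClass.LIKELY_INHERITED
        for s in scores
    ]


def classify_records(
    records: Sequence[VariantRecord], threshold_c: float
) -> list[VariantRecord]:
    """Attach predicted classes to scored records."""
    scores = [r.de_novo_score for r in records]
    if any(s is None for s in scores):
        missing = next(r.variant_id for r in records if r.de_novo_score is None)
        raise ValueError(f"variant {missing} has no de novo score")
    preds = classify(scores, threshold_c)
    return [r.with_score(r.de_novo_score, p) for r, p in zip(records, preds)]


def evaluate(
    predicted: Sequence[PredictedClass],
    truth: Sequence[InheritanceLabel],
    threshold_c: float = math.nan,
) -> ClassifierPerformance:
    """Tally sensitivity (w1) and specificity (w2) against known labels."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    n_dn = sum(1 for t in truth if t is InheritanceLabel.DE_NOVO)
    n_inh = sum(1 for t in truth if t is InheritanceLabel.INHERITED)
    tp = sum(
        1
        for p, t in zip(predicted, truth)
        if t is InheritanceLabel.DE_NOVO and p is PredictedClass.LIKELY_DE_NOVO
    )
    tn = sum(
        1
        for p, t in zip(predicted, truth)
        if t is InheritanceLabel.INHERITED and p is PredictedClass.LIKELY_INHERITED
    )
    w1 = tp / n_dn if n_dn else math.nan
    w2 = tn / n_inh if n_inh else math.nan
    return ClassifierPerformance(
        threshold_c=threshold_c, w1=w1, w2=w2,
        n_de_novo_eval=n_dn, n_inherited_eval=n_inh,
    )


def threshold_sweep(
    model: ClassifierModel,
    records: Sequence[VariantRecord],
    grid: Sequence[float],
) -> list[ClassifierPerformance]:
    """Evaluate (w1, w2) over a grid of thresholds on labeled records.

    With the strict-exceeds rule, w1 is nonincreasing and w2 nondecreasing
    in the threshold.
    """
    scores = score(model, records)
    truth = [r.inheritance_label for r in records]
    out = []
    for c in grid:
        perf = evaluate(classify(scores, c), truth, threshold_c=c)
        out.append(perf)
    return out


def save_model(model: ClassifierModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, fh)


def load_model(path) -> ClassifierModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return payload["model"]
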