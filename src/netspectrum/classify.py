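"""Evidence-weighted radial-kernel classification.

A support-vector machine with a radial (RBF) kernel is trained on the
network feature vectors of the positive (C1-C4) and negative (C5)
training genes. Evidence weighting enters as per-gene sample weights
drawn from a tier->weight map (default 4:3:2:1 for C1..C4 against C5
weight 1), so higher-confidence positives pull the decision boundary
harder. Decision margins are mapped to probabilities with a monotone
sigmoid (Platt) calibration; stratified k-fold cross-validation reports
the "correct rate" (accuracy at probability 0.5), and the operating
threshold is chosen on the ROC by Youden's J.

Tier assignment for new candidates uses four one-vs-negatives models
(one per positive tier, all sharing the C5 set); a candidate gets the
tier whose model gives it the largest probability, ties resolved toward
the stronger-evidence tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import POSITIVE_TIERS, PredictionRecord, TieredGeneSet
from .features import FeatureMatrix, column_order

#: Default evidence weights: probable-pathogenic genes count 4x a
#: possibly-associated gene; negatives weigh 1.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {"C1": 4.0, "C2": 3.0, "C3": 2.0, "C4": 1.0, "C5": 1.0}


@dataclass
class ClassifierModel:
    """A fitted radial-kernel model plus its training reference."""

    svc: SVC
    col_genes: list[str]
    train_genes: list[str]
    train_tiers: dict[str, str]
    class_weights: dict[str, float]
    gamma: float
    C: float
    seed: int

    def predict_proba(self, features: FeatureMatrix, genes: Sequence[str] | None = None):
        """P(associated) for the given genes (default: all rows)."""
        if features.col_genes != self.col_genes:
            raise ValueError("feature columns do not match the model's training reference")
        X = features.values if genes is None else features.rows(genes)
        return self.svc.predict_proba(X)[:, list(self.svc.classes_).index(1)]


@dataclass
class CVResult:
    k: int
    fold_assignments: dict[str, int]
    per_fold_correct_rate: list[float]
    mean_correct_rate: float
    seed: int
    #: out-of-fold P(associated) per training gene; feeds the ROC
    oof_probabilities: dict[str, float] = field(default_factory=dict)


@dataclass
class RocResult:
    points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float
    chosen_threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float


def _validate_weights(class_weights: Mapping[str, float] | None) -> dict[str, float]:
    weights = dict(DEFAULT_CLASS_WEIGHTS)
    if class_weights:
        weights.update(class_weights)
    if any(w <= 0 for w in weights.values()):
        raise ValueError("class weights must be strictly positive")
    return weights


def _training_arrays(features: FeatureMatrix, labels: TieredGeneSet, weights):
    genes = column_order(labels)  # deterministic: tier blocks, lexicographic
    missing = [g for g in genes if g not in set(features.row_genes)]
    if missing:
        raise ValueError(f"labeled genes missing from feature rows: {missing[:5]}")
    X = features.rows(genes)
    y = np.array([1 if labels[g] != "C5" else 0 for g in genes])
    w = np.array([weights[labels[g]] for g in genes], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    return genes, X, y, w


def _make_svc(n_features: int, gamma: float | None, C: float, seed: int) -> tuple[SVC, float]:
    g = 1.0 / n_features if gamma is None else float(gamma)
    svc = SVC(kernel="rbf", gamma=g, C=C, probability=True, random_state=seed)
    return svc, g


def _fit_svc(svc: SVC, X, y, sample_weight) -> SVC:
    # libsvm's built-in Platt calibration; quiet sklearn's deprecation
    # chatter about the probability flag
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, module=r"sklearn\.svm.*")
        svc.fit(X, y, sample_weight=sample_weight)
    return svc


def train(
    features: FeatureMatrix,
    labels: TieredGeneSet,
    class_weights: Mapping[str, float] | None = None,
    gamma: float | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the evidence-weighted RBF-SVM with Platt probability
    calibration. Deterministic under a fixed seed."""
    weights = _validate_weights(class_weights)
    genes, X, y, w = _training_arrays(features, labels, weights)
    svc, g = _make_svc(len(features.col_genes), gamma, C, seed)
    _fit_svc(svc, X, y, w)
    return ClassifierModel(
        svc=svc,
        col_genes=list(features.col_genes),
        train_genes=genes,
        train_tiers={g_: labels[g_] for g_ in genes},
        class_weights=weights,
        gamma=g,
        C=C,
        seed=seed,
    )


def cross_validate(
    features: FeatureMatrix,
    labels: TieredGeneSet,
    k: int = 5,
    class_weights: Mapping[str, float] | None = None,
    gamma: float | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the classifier.

    The correct rate is the fraction of held-out genes whose calibrated
    probability falls on the right side of 0.5. Fold assignment depends
    only on (seed, gene set): genes are sorted before splitting, so input
    row order is irrelevant.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    weights = _validate_weights(class_weights)
    genes, X, y, w = _training_arrays(features, labels, weights)
    order = np.argsort(genes)  # lexicographic; column_order is tier-blocked
    genes_s = [genes[i] for i in order]
    X_s, y_s, w_s = X[order], y[order], w[order]
    if min(np.bincount(y_s)) < k:
        raise ValueError(f"k={k} exceeds the size of the smaller class")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignments: dict[str, int] = {}
    per_fold: list[float] = []
    oof: dict[str, float] = {}
    for fold, (tr, te) in enumerate(skf.split(X_s, y_s)):
        svc, _ = _make_svc(len(features.col_genes), gamma, C, seed)
        _fit_svc(svc, X_s[tr], y_s[tr], w_s[tr])
        proba = svc.predict_proba(X_s[te])[:, list(svc.classes_).index(1)]
        correct = ((proba >= 0.5).astype(int) == y_s[te]).mean()
        per_fold.append(float(correct))
        for i, p in zip(te, proba):
            fold_assignments[genes_s[i]] = fold
            oof[genes_s[i]] = float(p)
    return CVResult(
        k=k,
        fold_assignments=fold_assignments,
        per_fold_correct_rate=per_fold,
        mean_correct_rate=float(np.mean(per_fold)),
        seed=seed,
        oof_probabilities=oof,
    )


def roc_and_threshold(
    probabilities: Sequence[float],
    truth_labels: Sequence[int],
    criterion: str = "youden",
) -> RocResult:
    """ROC curve, AUC, and the operating threshold.

    AUC is the probability that a random positive outscores a random
    negative (ties counted 1/2). The threshold maximizes Youden's
    J = sensitivity + specificity - 1 over the observed scores (or
    accuracy, with ``criterion="accuracy"``); among ties the lowest
    threshold wins. A score is called positive when it is >= the
    threshold.
    """
    y = np.asarray(truth_labels, dtype=int)
    s = np.asarray(probabilities, dtype=float)
    if y.shape != s.shape:
        raise ValueError("probabilities and labels differ in length")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in truth_labels")

    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    points = [
        (float(f), float(t), float(min(th, s.max())))  # clamp sklearn's +inf anchor
        for f, t, th in zip(fpr, tpr, thr)
    ]

    candidates = np.unique(s)
    calls = s[None, :] >= candidates[:, None]  # (threshold, sample)
    sens = (calls & (y == 1)).sum(axis=1) / n_pos
    spec = (~calls & (y == 0)).sum(axis=1) / n_neg
    if criterion == "youden":
        objective = sens + spec - 1.0
    elif criterion == "accuracy":
        objective = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    else:
        raise ValueError(f"unknown threshold criterion {criterion!r}")
    best = int(np.flatnonzero(objective == objective.max())[0])  # lowest threshold
    return RocResult(
        points=points,
        auc=auc,
        chosen_threshold=float(candidates[best]),
        sensitivity_at_threshold=float(sens[best]),
        specificity_at_threshold=float(spec[best]),
    )


def predict_genome(
    model: ClassifierModel, features: FeatureMatrix, threshold: float
) -> list[PredictionRecord]:
    """Score every feature row; one record per gene.

    Training genes are scored too but flagged ``in_training`` so the
    candidate list can exclude them.
    """
    proba = model.predict_proba(features)
    training = set(model.train_genes)
    records = []
    for gene, p in zip(features.row_genes, proba):
        p = float(min(max(p, 0.0), 1.0))
        records.append(
            PredictionRecord(
                gene=gene,
                probability=p,
                label="associated" if p >= threshold else "not_associated",
                in_training=gene in training,
            )
        )
    return records


def candidate_records(records: Sequence[PredictionRecord]) -> list[PredictionRecord]:
    """Associated, non-training records — the candidate list."""
    return [r for r in records if r.label == "associated" and not r.in_training]


def train_tier_models(
    features: FeatureMatrix,
    labels: TieredGeneSet,
    class_weights: Mapping[str, float] | None = None,
    gamma: float | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> dict[str, ClassifierModel]:
    """One one-vs-negatives model per positive tier with members.

    Every model shares the full C5 set; tier k's model is trained on
    tier-k genes versus all negatives and scores P(tier k) for new genes.
    """
    weights = _validate_weights(class_weights)
    negatives = sorted(labels.negatives)
    if not negatives:
        raise ValueError("no negatives in the training set")
    models: dict[str, ClassifierModel] = {}
    for tier in POSITIVE_TIERS:
        members = sorted(labels.genes_in_tier(tier))
        if not members:
            continue
        sub = TieredGeneSet({g: tier for g in members})
        for g in negatives:
            sub.add(g, "C5")
        sub_feats_rows = column_order(sub)
        # reuse the full matrix rows; columns stay the full training reference
        sub_matrix = FeatureMatrix(
            sub_feats_rows, features.col_genes, features.rows(sub_feats_rows)
        )
        models[tier] = train(
            sub_matrix, sub, class_weights=weights, gamma=gamma, C=C, seed=seed
        )
    return models


def tier_probabilities(
    models: Mapping[str, ClassifierModel], features: FeatureMatrix, genes: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Per-gene map tier -> P(tier) from the one-vs-negatives models."""
    out: dict[str, dict[str, float]] = {g: {} for g in genes}
    for tier, model in models.items():
        proba = model.predict_proba(features, genes=list(genes))
        for g, p in zip(genes, proba):
            out[g][tier] = float(p)
    return out


def assign_tiers(gene: str, per_tier_probabilities: Mapping[str, float]) -> str:
    """Argmax tier; ties resolve toward the stronger-evidence tier
    (C1 beats C2 beats C3 beats C4)."""
    missing = [t for t in POSITIVE_TIERS if t not in per_tier_probabilities]
    if missing:
        raise ValueError(f"missing tier probabilities for {gene}: {missing}")
    return max(POSITIVE_TIERS, key=lambda t: (per_tier_probabilities[t], -POSITIVE_TIERS.index(t)))
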