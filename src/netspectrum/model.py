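"""Model/Results interface to the prioritization classifier.

:class:`GenePrioritizationModel` bundles a weighted gene network with a
tiered training set (positives C1-C4, negatives C5); ``fit()`` runs
stratified cross-validation, builds the ROC from the out-of-fold
probabilities, chooses the operating threshold, trains the final
evidence-weighted RBF-SVM and returns a
:class:`GenePrioritizationResults` that can score the genome, assign
candidate tiers and print a summary table.

    >>> model = GenePrioritizationModel(network, training)
    >>> res = model.fit(cv_folds=5, seed=7)
    >>> print(res.summary())
    >>> records = res.predict()          # every network gene
    >>> candidates = res.candidates()    # associated, non-training
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import classify
from .classify import (
    DEFAULT_CLASS_WEIGHTS,
    ClassifierModel,
    CVResult,
    RocResult,
)
from .containers import (
    POSITIVE_TIERS,
    PredictionRecord,
    TieredGeneSet,
    WeightedGeneNetwork,
)
from .features import FeatureMatrix, build_feature_matrix


class GenePrioritizationModel:
    """Guilt-by-association disease-gene classifier over a weighted
    functional network.

    Parameters
    ----------
    network : WeightedGeneNetwork
        Tissue-specific functional interaction network; edge weights are
        posterior probabilities in [0, 1].
    training : TieredGeneSet
        Known disease genes in evidence tiers C1-C4 plus the C5 negative
        set. Feature vectors are each gene's edge weights to these
        training genes.
    class_weights : mapping, optional
        Evidence weight per tier (default 4:3:2:1 for C1..C4, 1 for C5).
    gamma, C : float, optional
        RBF kernel width (default 1/n_features) and SVM regularization.
    """

    def __init__(
        self,
        network: WeightedGeneNetwork,
        training: TieredGeneSet,
        class_weights: Mapping[str, float] | None = None,
        gamma: float | None = None,
        C: float = 1.0,
    ) -> None:
        if not training.positives:
            raise ValueError("training set has no positives (C1-C4)")
        if not training.negatives:
            raise ValueError("training set has no negatives (C5)")
        self.network = network
        self.training = training
        self.class_weights = dict(DEFAULT_CLASS_WEIGHTS) | dict(class_weights or {})
        self.gamma = gamma
        self.C = C

    @classmethod
    def from_files(
        cls,
        network_path,
        positives_path,
        negatives_path=None,
        **kwargs,
    ) -> "GenePrioritizationModel":
        """Build from an edge-list TSV and gene-set TSV(s).

        ``positives_path`` may already contain C5 rows; otherwise pass a
        separate ``negatives_path`` (bare gene list or tiered TSV,
        default tier C5).
        """
        from .io import read_edge_list, read_gene_set

        network = read_edge_list(network_path)
        training = read_gene_set(positives_path, default_tier="C1")
        if negatives_path is not None:
            training = training.merged_with(read_gene_set(negatives_path, default_tier="C5"))
        return cls(network, training, **kwargs)

    def training_features(self) -> FeatureMatrix:
        """Feature rows for the training genes themselves."""
        rows = sorted(self.training)
        return build_feature_matrix(rows, self.training, self.network)

    def fit(
        self,
        cv_folds: int = 5,
        threshold_criterion: str = "youden",
        seed: int = 0,
    ) -> "GenePrioritizationResults":
        """Cross-validate, pick the ROC threshold, train the final model."""
        feats = self.training_features()
        cv = classify.cross_validate(
            feats,
            self.training,
            k=cv_folds,
            class_weights=self.class_weights,
            gamma=self.gamma,
            C=self.C,
            seed=seed,
        )
        genes = sorted(cv.oof_probabilities)
        probs = [cv.oof_probabilities[g] for g in genes]
        truth = [1 if self.training[g] != "C5" else 0 for g in genes]
        roc = classify.roc_and_threshold(probs, truth, criterion=threshold_criterion)
        final = classify.train(
            feats,
            self.training,
            class_weights=self.class_weights,
            gamma=self.gamma,
            C=self.C,
            seed=seed,
        )
        return GenePrioritizationResults(model=self, classifier=final, cv=cv, roc=roc, seed=seed)


@dataclass
class GenePrioritizationResults:
    """Fitted classifier with its cross-validation and ROC diagnostics."""

    model: GenePrioritizationModel
    classifier: ClassifierModel
    cv: CVResult
    roc: RocResult
    seed: int
    _tier_models: dict[str, ClassifierModel] | None = field(default=None, repr=False)

    @property
    def threshold(self) -> float:
        return self.roc.chosen_threshold

    def genome_features(self, genes: Sequence[str] | None = None) -> FeatureMatrix:
        if genes is None:
            genes = sorted(self.model.network.nodes | set(self.model.training))
        return build_feature_matrix(list(genes), self.model.training, self.model.network)

    def predict(self, genes: Sequence[str] | None = None) -> list[PredictionRecord]:
        """Score genes (default: every network/training gene); training
        genes are flagged and excluded from :meth:`candidates`."""
        feats = self.genome_features(genes)
        return classify.predict_genome(self.classifier, feats, self.threshold)

    def candidates(self, genes: Sequence[str] | None = None) -> list[PredictionRecord]:
        return classify.candidate_records(self.predict(genes))

    def assign_tiers(self, records: Sequence[PredictionRecord]) -> list[PredictionRecord]:
        """Assign an evidence tier to each associated record via the
        one-vs-negatives tier models (tiers without training members
        contribute probability 0)."""
        if self._tier_models is None:
            self._tier_models = classify.train_tier_models(
                self.model.training_features(),
                self.model.training,
                class_weights=self.model.class_weights,
                gamma=self.model.gamma,
                C=self.model.C,
                seed=self.seed,
            )
        genes = [r.gene for r in records if r.label == "associated"]
        if not genes:
            return list(records)
        feats = self.genome_features(genes)
        per_gene = classify.tier_probabilities(self._tier_models, feats, genes)
        out: list[PredictionRecord] = []
        for rec in records:
            if rec.label != "associated":
                out.append(rec)
                continue
            probs = {t: per_gene[rec.gene].get(t, 0.0) for t in POSITIVE_TIERS}
            out.append(
                PredictionRecord(
                    gene=rec.gene,
                    probability=rec.probability,
                    label=rec.label,
                    tier=classify.assign_tiers(rec.gene, probs),
                    go_filtered=rec.go_filtered,
                    in_training=rec.in_training,
                )
            )
        return out

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.model.training
        lines = [
            "Gene prioritization results",
            "=" * 46,
            f"training genes          {len(t)} ({len(t.positives)} positive / {len(t.negatives)} negative)",
            f"feature dimension       {len(self.classifier.col_genes)}",
            f"CV folds                {self.cv.k}",
            f"CV correct rate (mean)  {self.cv.mean_correct_rate:.4f}",
            "CV correct rate (folds) "
            + ", ".join(f"{r:.3f}" for r in self.cv.per_fold_correct_rate),
            f"ROC AUC                 {self.roc.auc:.4f}",
            f"threshold               {self.roc.chosen_threshold:.4f}",
            f"sensitivity @ threshold {self.roc.sensitivity_at_threshold:.4f}",
            f"specificity @ threshold {self.roc.specificity_at_threshold:.4f}",
            f"seed                    {self.seed}",
        ]
        return "\n".join(lines)
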