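"""Classifier behaviour: separable limits, evidence weighting, CV
contracts, ROC/threshold oracle checks, genome scoring, tier assignment."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from netspectrum.classify import (
    DEFAULT_CLASS_WEIGHTS,
    assign_tiers,
    candidate_records,
    cross_validate,
    predict_genome,
    roc_and_threshold,
    tier_probabilities,
    train,
    train_tier_models,
)
from netspectrum.containers import TieredGeneSet, WeightedGeneNetwork
from netspectrum.features import FeatureMatrix, build_feature_matrix
from netspectrum.model import GenePrioritizationModel
from netspectrum.synthetic import generate_network, small_config


def _matrix(rows, values):
    return FeatureMatrix(rows, rows, sp.csr_matrix(np.asarray(values, dtype=float)))


def _separable_fixture(n_per_class=15, seed=0):
    """Positives sit near 1 on every positive column, negatives near 0."""
    rng = np.random.default_rng(seed)
    pos = [f"P{i:02d}" for i in range(n_per_class)]
    neg = [f"N{i:02d}" for i in range(n_per_class)]
    training = TieredGeneSet({g: "C1" for g in pos} | {g: "C5" for g in neg})
    rows = sorted(training, key=lambda g: (training[g], g))
    X = np.zeros((len(rows), len(rows)))
    for i, g in enumerate(rows):
        base = 0.95 if training[g] != "C5" else 0.05
        X[i] = np.clip(rng.normal(base, 0.02, len(rows)), 0, 1)
    return _matrix(rows, X), training


def auc_by_pair_concordance(scores, labels):
    """Independent oracle: concordant positive-negative pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTrain:
    def test_separable_fixture_resubstitution_perfect(self):
        fm, training = _separable_fixture()
        model = train(fm, training, seed=0)
        proba = model.predict_proba(fm)
        labels = (proba >= 0.5).astype(int)
        truth = np.array([1 if training[g] != "C5" else 0 for g in fm.row_genes])
        assert (labels == truth).all()

    def test_default_class_weights(self):
        fm, training = _separable_fixture()
        model = train(fm, training, seed=0)
        assert model.class_weights == DEFAULT_CLASS_WEIGHTS == {
            "C1": 4.0, "C2": 3.0, "C3": 2.0, "C4": 1.0, "C5": 1.0
        }

    def test_graded_weights_move_the_boundary(self):
        # a C1 gene placed inside the negative cluster is rescued when its
        # evidence weight is large, flipping at least one training label
        rng = np.random.default_rng(0)
        pos = [f"P{i:02d}" for i in range(12)]
        neg = [f"N{i:02d}" for i in range(12)]
        training = TieredGeneSet(
            {pos[0]: "C1"} | {g: "C4" for g in pos[1:]} | {g: "C5" for g in neg}
        )
        rows = sorted(training, key=lambda g: ({"C1": 0, "C4": 3, "C5": 4}[training[g]], g))
        X = np.zeros((24, 24))
        for i, g in enumerate(rows):
            base = 0.12 if g == pos[0] else (0.9 if training[g] != "C5" else 0.1)
            X[i] = np.clip(rng.normal(base, 0.03, 24), 0, 1)
        fm = _matrix(rows, X)
        flat = train(fm, training, class_weights={t: 1.0 for t in DEFAULT_CLASS_WEIGHTS}, seed=0)
        graded = train(fm, training, class_weights={"C1": 50.0}, seed=0)
        flipped = (flat.predict_proba(fm) >= 0.5) != (graded.predict_proba(fm) >= 0.5)
        assert flipped.any()

    def test_single_class_is_error(self):
        fm, _ = _separable_fixture()
        training = TieredGeneSet({g: "C1" for g in fm.row_genes})
        with pytest.raises(ValueError, match="both classes"):
            train(fm, training)

    def test_missing_row_is_error(self):
        fm, training = _separable_fixture()
        training = TieredGeneSet(dict(training) | {"GHOST": "C1"})
        with pytest.raises(ValueError, match="missing"):
            train(fm, training)


class TestCrossValidate:
    def test_separable_fixture_perfect_rate(self):
        fm, training = _separable_fixture()
        cv = cross_validate(fm, training, k=5, seed=0)
        assert cv.mean_correct_rate == 1.0
        assert len(cv.per_fold_correct_rate) == 5

    def test_default_k_is_five(self):
        fm, training = _separable_fixture()
        assert cross_validate(fm, training, seed=0).k == 5

    def test_folds_partition_training_genes(self):
        fm, training = _separable_fixture()
        cv = cross_validate(fm, training, k=5, seed=0)
        assert set(cv.fold_assignments) == set(training)
        assert sorted(set(cv.fold_assignments.values())) == [0, 1, 2, 3, 4]

    def test_fold_assignment_independent_of_row_order(self, small_fixture):
        _, net, truth = small_fixture
        training = truth.tier_of
        rows = sorted(training)
        a = cross_validate(build_feature_matrix(rows, training, net), training, seed=3)
        b = cross_validate(build_feature_matrix(rows[::-1], training, net), training, seed=3)
        assert a.fold_assignments == b.fold_assignments
        assert a.per_fold_correct_rate == b.per_fold_correct_rate

    def test_k_exceeding_class_size_is_error(self):
        fm, training = _separable_fixture(n_per_class=4)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(fm, training, k=5)

    def test_permuted_labels_give_chance_rate(self, medium_fixture):
        # permutation null: shuffling tiers among training genes kills the
        # signal, so the mean correct rate sits at chance
        _, net, truth = medium_fixture
        genes = sorted(truth.tier_of)
        tiers = [truth.tier_of[g] for g in genes]
        feats = build_feature_matrix(genes, truth.tier_of, net)
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = TieredGeneSet(dict(zip(genes, rng.permutation(tiers))))
            # columns stay the original training reference; rows are the same genes
            cv = cross_validate(feats, shuffled, k=5, seed=seed)
            rates.append(cv.mean_correct_rate)
        assert 0.45 <= np.mean(rates) <= 0.55


class TestRocAndThreshold:
    def test_four_score_worked_example(self):
        roc = roc_and_threshold([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)
        assert roc.chosen_threshold == pytest.approx(0.4)  # lowest among J ties
        assert roc.sensitivity_at_threshold == pytest.approx(1.0)
        assert roc.specificity_at_threshold == pytest.approx(0.5)

    def test_perfect_ranking(self):
        roc = roc_and_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.sensitivity_at_threshold == roc.specificity_at_threshold == 1.0

    def test_all_scores_equal_gives_half_auc(self):
        roc = roc_and_threshold([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_one_class_truth_is_error(self):
        with pytest.raises(ValueError):
            roc_and_threshold([0.2, 0.8], [1, 1])

    def test_threshold_internally_consistent(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        roc = roc_and_threshold(scores, labels)
        calls = scores >= roc.chosen_threshold
        sens = (calls & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~calls & (labels == 0)).sum() / (labels == 0).sum()
        assert sens == pytest.approx(roc.sensitivity_at_threshold)
        assert spec == pytest.approx(roc.specificity_at_threshold)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_auc_matches_pair_concordance_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        roc = roc_and_threshold(scores, labels)
        assert roc.auc == pytest.approx(auc_by_pair_concordance(scores, labels))

    def test_monotone_fpr_points(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        roc = roc_and_threshold(scores, labels)
        fprs = [p[0] for p in roc.points]
        assert fprs == sorted(fprs)


class TestPredictGenome:
    def test_training_genes_flagged_and_excluded_from_candidates(self):
        fm, training = _separable_fixture()
        model = train(fm, training, seed=0)
        records = predict_genome(model, fm, threshold=0.5)
        assert all(r.in_training for r in records)
        assert candidate_records(records) == []

    def test_zero_rows_share_one_baseline_probability(self):
        fm, training = _separable_fixture()
        model = train(fm, training, seed=0)
        zero = FeatureMatrix(["Z1", "Z2", "Z3"], fm.col_genes,
                             sp.csr_matrix((3, len(fm.col_genes))))
        probs = {r.gene: r.probability for r in predict_genome(model, zero, threshold=0.5)}
        assert len(set(probs.values())) == 1

    def test_column_mismatch_is_error(self):
        fm, training = _separable_fixture()
        model = train(fm, training, seed=0)
        wrong = FeatureMatrix(["A"], ["X", "Y"], sp.csr_matrix((1, 2)))
        with pytest.raises(ValueError, match="columns"):
            predict_genome(model, wrong, threshold=0.5)

    def test_hidden_candidates_rank_above_background(self, medium_fixture, medium_results):
        _, net, truth = medium_fixture
        records = medium_results.predict(sorted(truth.genes))
        probs = {r.gene: r.probability for r in records}
        non_module = [probs[g] for g in truth.genes
                      if g not in truth.planted_module and g not in truth.tier_of]
        cutoff = np.percentile(non_module, 90)
        hidden = [probs[g] for g in truth.hidden_candidates]
        assert np.mean([h > cutoff for h in hidden]) > 0.9


class TestAssignTiers:
    def test_strict_argmax(self):
        assert assign_tiers("G", {"C1": 0.9, "C2": 0.5, "C3": 0.2, "C4": 0.1}) == "C1"
        assert assign_tiers("G", {"C1": 0.1, "C2": 0.5, "C3": 0.9, "C4": 0.2}) == "C3"

    def test_tie_resolves_to_stronger_evidence(self):
        assert assign_tiers("G", {"C1": 0.6, "C2": 0.6, "C3": 0.1, "C4": 0.1}) == "C1"
        assert assign_tiers("G", {"C1": 0.1, "C2": 0.4, "C3": 0.4, "C4": 0.4}) == "C2"

    def test_missing_tier_is_error(self):
        with pytest.raises(ValueError, match="C4"):
            assign_tiers("G", {"C1": 0.9, "C2": 0.5, "C3": 0.2})

    def test_hidden_genes_wired_like_c1_recover_c1(self):
        # build a network whose hidden genes share the C1 clique
        rng = np.random.default_rng(5)
        net = WeightedGeneNetwork()
        tiers: dict[str, str] = {}
        names: dict[str, list[str]] = {}
        for t, n in (("C1", 8), ("C2", 8), ("C3", 8), ("C4", 8), ("C5", 32)):
            names[t] = [f"{t}G{i:02d}" for i in range(n)]
            for g in names[t]:
                tiers[g] = t
                net.add_gene(g)
        hidden = [f"H{i:02d}" for i in range(10)]
        for g in hidden:
            net.add_gene(g)

        def wire(a_list, b_list, p, beta):
            for a in a_list:
                for b in b_list:
                    if a >= b and b in a_list:
                        continue
                    if a != b and rng.random() < p:
                        net.add_edge(a, b, float(np.clip(rng.beta(*beta), 0, 1)))

        wire(names["C1"] + hidden, names["C1"] + hidden, 0.6, (5, 2))
        for t in ("C2", "C3", "C4"):
            wire(names[t], names[t], 0.6, (5, 2))
        everyone = sum(names.values(), []) + hidden
        wire(everyone, everyone, 0.02, (2, 5))

        training = TieredGeneSet(tiers)
        feats = build_feature_matrix(sorted(training), training, net)
        models = train_tier_models(feats, training, seed=0)
        hfeats = build_feature_matrix(hidden, training, net)
        probs = tier_probabilities(models, hfeats, hidden)
        assigned = [
            assign_tiers(g, {t: probs[g].get(t, 0.0) for t in ("C1", "C2", "C3", "C4")})
            for g in hidden
        ]
        assert sum(t == "C1" for t in assigned) > len(hidden) / 2


class TestEffectLadder:
    def test_cv_rate_increases_with_planted_effect(self):
        rates = []
        for kw in (
            dict(p_edge_in=0.05, w_in_params=(2, 5)),
            dict(p_edge_in=0.12, w_in_params=(3, 4)),
            dict(p_edge_in=0.3, w_in_params=(5, 2)),
        ):
            net, truth = generate_network(small_config(seed=7, **kw))
            res = GenePrioritizationModel(net, truth.tier_of).fit(cv_folds=5, seed=7)
            rates.append(res.cv.mean_correct_rate)
        assert rates[0] < rates[1] < rates[2]
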