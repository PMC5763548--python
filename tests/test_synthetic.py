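"""Planted-module generator contracts: determinism, calibration of edge
weights, annotation enrichment odds, and sequence-feature regimes."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from netspectrum.containers import TieredGeneSet
from netspectrum.seqstats import mann_whitney_test
from netspectrum.synthetic import (
    BACKGROUND_REGIME,
    MODULE_REGIME,
    SyntheticConfig,
    SyntheticTruth,
    generate_annotations,
    generate_feature_comparison,
    generate_network,
    generate_sequence_features,
    null_config,
    small_config,
)


def _manual_truth(n_genes=300, n_module=60, seed=0):
    """A truth object without paying for a network draw."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    module = sorted(rng.choice(n_genes, size=n_module, replace=False))
    tier_of = TieredGeneSet({genes[i]: "C1" for i in module[: n_module // 2]})
    return SyntheticTruth(
        genes=genes,
        planted_module={genes[i] for i in module},
        tier_of=tier_of,
        hidden_candidates={genes[i] for i in module[n_module // 2 :]},
    )


class TestNetworkGenerator:
    def test_seed_determinism(self):
        cfg = small_config(seed=7)
        net1, truth1 = generate_network(cfg)
        net2, truth2 = generate_network(cfg)
        assert net1.sorted_edges() == net2.sorted_edges()
        assert truth1.planted_module == truth2.planted_module
        assert dict(truth1.tier_of) == dict(truth2.tier_of)

    def test_truth_invariants(self, small_fixture):
        cfg, net, truth = small_fixture
        training = truth.tier_of.positives | truth.tier_of.negatives
        assert not (truth.hidden_candidates & training)
        assert truth.tier_of.positives <= truth.planted_module
        assert len(truth.tier_of.positives) == cfg.n_positives
        assert len(truth.tier_of.negatives) == cfg.n_negatives
        assert len(truth.planted_module) == cfg.module_size

    def test_module_weights_match_beta_mean(self, medium_fixture):
        cfg, net, truth = medium_fixture
        module = truth.planted_module
        weights = [w for a, b, w in net.edges() if a in module and b in module]
        assert len(weights) >= 1000
        a, b = cfg.w_in_params
        mean, var = a / (a + b), a * b / ((a + b) ** 2 * (a + b + 1))
        se = math.sqrt(var / len(weights))
        assert abs(np.mean(weights) - mean) < 3 * se

    def test_null_config_has_no_module_effect(self):
        cfg = null_config(SyntheticConfig(n_genes=400, n_positives=60, n_negatives=60, seed=3))
        net, truth = generate_network(cfg)
        inside, outside = [], []
        for a, b, w in net.edges():
            both = (a in truth.planted_module) and (b in truth.planted_module)
            (inside if both else outside).append(w)
        pooled_sd = np.std(inside + outside)
        se = pooled_sd * math.sqrt(1 / len(inside) + 1 / len(outside))
        assert abs(np.mean(inside) - np.mean(outside)) < 3 * se

    def test_sparser_module_warns(self):
        cfg = SyntheticConfig(
            n_genes=100, n_positives=10, n_negatives=10, p_edge_in=0.01, p_edge_bg=0.05, seed=0
        )
        with pytest.warns(UserWarning, match="sparser"):
            generate_network(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=10, n_positives=8, n_negatives=8)
        with pytest.raises(ValueError):
            SyntheticConfig(tier_fractions=(0.5, 0.5, 0.5, 0.5))


class TestAnnotationGenerator:
    def test_null_effect_rate_matches_baseline(self):
        truth = _manual_truth()
        cfg = SyntheticConfig(
            n_genes=300, n_positives=30, n_negatives=30,
            enrichment_effect=1.0, baseline_annotation_rate=0.05,
            n_terms=100, n_disease_terms=10, seed=5,
        )
        amap = generate_annotations(cfg, truth)
        module = truth.planted_module
        hits = sum(len(amap.genes_of(f"T{i:04d}") & module) for i in range(10))
        trials = 10 * len(module)
        rate = hits / trials
        se = math.sqrt(0.05 * 0.95 / trials)
        assert abs(rate - 0.05) < 4 * se

    def test_infinite_effect_annotates_every_module_gene(self):
        truth = _manual_truth()
        cfg = SyntheticConfig(
            n_genes=300, n_positives=30, n_negatives=30,
            enrichment_effect=float("inf"), n_terms=20, n_disease_terms=5, seed=5,
        )
        amap = generate_annotations(cfg, truth)
        for i in range(5):
            assert truth.planted_module <= amap.genes_of(f"T{i:04d}")

    def test_empirical_odds_ratio_near_configured_effect(self):
        # Monte-Carlo across seeds: pooled log-odds-ratio CI covers 5
        effect, base = 5.0, 0.05
        log_ors, weights = [], []
        for seed in range(50):
            truth = _manual_truth(n_genes=500, n_module=100, seed=seed)
            cfg = SyntheticConfig(
                n_genes=500, n_positives=50, n_negatives=50,
                enrichment_effect=effect, baseline_annotation_rate=base,
                n_terms=40, n_disease_terms=8, seed=seed,
            )
            amap = generate_annotations(cfg, truth)
            module = truth.planted_module
            rest = set(truth.genes) - module
            a = sum(len(amap.genes_of(f"T{i:04d}") & module) for i in range(8))
            b = 8 * len(module) - a
            c = sum(len(amap.genes_of(f"T{i:04d}") & rest) for i in range(8))
            d = 8 * len(rest) - c
            log_ors.append(math.log((a * d) / (b * c)))
            weights.append(1 / a + 1 / b + 1 / c + 1 / d)  # Woolf variance
        pooled = np.average(log_ors, weights=[1 / w for w in weights])
        pooled_se = math.sqrt(1 / sum(1 / w for w in weights))
        assert abs(pooled - math.log(effect)) < 1.96 * pooled_se * 1.5

    def test_determinism(self):
        truth = _manual_truth()
        cfg = SyntheticConfig(n_genes=300, n_positives=30, n_negatives=30, seed=9)
        assert generate_annotations(cfg, truth).pairs() == generate_annotations(cfg, truth).pairs()


class TestFeatureGenerator:
    def test_module_median_gene_length_calibrated(self):
        # heavy-tailed lengths make a single n=335 median noisy; average
        # the sample medians over a few seeds to test the target itself
        ad_meds, ctrl_meds = [], []
        for seed in range(5):
            table, sets = generate_feature_comparison(
                SyntheticConfig(n_genes=1400, seed=seed), n_per_set=335
            )
            ad_meds.append(table.subset(sets["ad"])["gene_length"].median())
            ctrl_meds.append(table.subset(sets["control"])["gene_length"].median())
        ad, ctrl = np.mean(ad_meds), np.mean(ctrl_meds)
        assert abs(ad - MODULE_REGIME["gene_length"]) / MODULE_REGIME["gene_length"] < 0.10
        assert abs(ctrl - BACKGROUND_REGIME["gene_length"]) / BACKGROUND_REGIME["gene_length"] < 0.10
        assert ad / ctrl > 4  # disease-like genes are several-fold longer

    def test_identity_shift_is_null(self):
        # with all shifts at 1 the module and background distributions
        # coincide; MW p should rarely be small
        n_small = 0
        for seed in range(10):
            cfg = null_config(
                SyntheticConfig(n_genes=400, n_positives=60, n_negatives=60, seed=seed)
            )
            truth = _manual_truth(n_genes=400, n_module=120, seed=seed)
            table = generate_sequence_features(cfg, truth)
            module = sorted(truth.planted_module)
            rest = sorted(set(truth.genes) - truth.planted_module)
            _, p = mann_whitney_test(
                table.subset(module)["gene_length"], table.subset(rest)["gene_length"]
            )
            n_small += p < 0.05
        assert n_small <= 3

    def test_paralog_rate_within_3_se(self):
        truth = _manual_truth(n_genes=1000, n_module=1000, seed=2)  # all module
        cfg = SyntheticConfig(n_genes=1000, n_positives=100, n_negatives=100, seed=2)
        table = generate_sequence_features(cfg, truth)
        rate = table.df["has_paralog"].mean()
        p = MODULE_REGIME["has_paralog"]
        se = math.sqrt(p * (1 - p) / 1000)
        assert abs(rate - p) < 3 * se

    def test_determinism_and_flags_binary(self):
        truth = _manual_truth()
        cfg = SyntheticConfig(n_genes=300, n_positives=30, n_negatives=30, seed=4)
        t1 = generate_sequence_features(cfg, truth)
        t2 = generate_sequence_features(cfg, truth)
        assert t1.df.equals(t2.df)
        assert set(np.unique(t1.df["has_tm_domain"])) <= {0, 1}
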