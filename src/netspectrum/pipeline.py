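"""End-to-end pipeline orchestration.

Stage order: control selection -> feature building -> train/CV -> ROC
threshold -> genome-wide prediction -> tier assignment -> functional
filter -> sequence-feature statistics, with per-stage in/out counts
logged and a JSON manifest (config echo, seed, package version, stage
counts) written alongside the TSV outputs. A rerun with the same config
and inputs reproduces every numeric output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from . import __version__, io
from .containers import PredictionRecord, TieredGeneSet, normalize_gene_id
from .controls import (
    ControlCandidateSet,
    sample_random_controls,
    select_minimal_interaction_controls,
    select_optimal_control_set,
)
from .enrich import enrich_terms, enrichment_table_rows, filter_candidates, select_top_terms
from .model import GenePrioritizationModel
from .seqstats import compare_sets, medians_table, pairwise_table
from .synthetic import SyntheticConfig, generate_annotations, generate_network, generate_sequence_features

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and knobs for one pipeline run."""

    network: str
    positives: str
    background: str
    annotations: str
    outdir: str
    exclude: Optional[str] = None
    features: Optional[str] = None
    non_mental: Optional[str] = None
    # control selection
    n_controls: Optional[int] = None  # default: match the positive count
    interaction_metric: str = "weight_sum"
    interaction_cutoff: float = 0.0
    random_draws: int = 10
    # classifier
    cv_k: int = 5
    class_weights: Optional[dict[str, float]] = None
    gamma: Optional[float] = None
    C: float = 1.0
    threshold_criterion: str = "youden"
    # functional filter
    top_k_terms: int = 10
    q_max: Optional[float] = None
    go_mode: str = "any"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("network", "positives", "background", "annotations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")
        for name in ("exclude", "features", "non_mental"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")


@dataclass
class CrossCheckReport:
    """Partition of literature query genes into training / predicted."""

    query_genes: list[str]
    in_training: list[str]
    in_predicted: list[str]

    @property
    def n_query(self) -> int:
        return len(self.query_genes)

    @property
    def n_training(self) -> int:
        return len(self.in_training)

    @property
    def n_predicted(self) -> int:
        return len(self.in_predicted)


def cross_check(
    query_genes: Iterable[str],
    training: TieredGeneSet,
    predicted: Sequence[PredictionRecord] | Iterable[str],
) -> CrossCheckReport:
    """Partition query genes: training membership first (training genes
    are excluded from candidates, so the two bins are disjoint), then
    predicted membership, else neither."""
    items = list(predicted)
    predicted_genes = {
        p.gene if isinstance(p, PredictionRecord) else normalize_gene_id(p) for p in items
    }
    query = [normalize_gene_id(g) for g in query_genes]
    training_genes = set(training)
    in_training = [g for g in query if g in training_genes]
    in_predicted = [g for g in query if g not in training_genes and g in predicted_genes]
    return CrossCheckReport(query_genes=query, in_training=in_training, in_predicted=in_predicted)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    optimal_controls: ControlCandidateSet
    results: "object"  # GenePrioritizationResults
    filtered_candidates: list[PredictionRecord] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full flow and write the output bundle to config.outdir."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    # --- inputs -------------------------------------------------------
    network = io.read_edge_list(config.network)
    positives = io.read_gene_set(config.positives, default_tier="C1")
    if positives.negatives:
        raise ValueError("positives file contains C5 rows; negatives are selected by the pipeline")
    universe = io.read_gene_list(config.background)
    excluded = io.read_gene_list(config.exclude) if config.exclude else set()
    annotations = io.read_annotations(config.annotations)
    annotations.universe.update(universe | set(positives))
    stage(
        "inputs",
        genes_in_network=network.n_nodes,
        edges=network.n_edges,
        positives=len(positives),
        universe=len(universe),
        excluded=len(excluded),
        annotation_terms=len(annotations.terms),
    )

    # --- control selection -------------------------------------------
    background = sorted(universe - set(positives) - excluded)
    n_controls = config.n_controls or len(positives)
    candidates_sets = [
        select_minimal_interaction_controls(
            background,
            positives.positives,
            network,
            n_controls,
            metric=config.interaction_metric,
            cutoff=config.interaction_cutoff,
        )
    ]
    for i in range(config.random_draws):
        candidates_sets.append(
            sample_random_controls(background, n_controls, seed=config.seed * 100003 + i, draw_index=i)
        )
    optimal = select_optimal_control_set(
        candidates_sets,
        positives,
        network,
        cv_k=config.cv_k,
        seed=config.seed,
        class_weights=config.class_weights,
        gamma=config.gamma,
        C=config.C,
    )
    controls_df = pd.DataFrame(
        [
            {
                "origin": c.origin,
                "draw_index": -1 if c.draw_index is None else c.draw_index,
                "cv_correct_rate": c.cv_correct_rate,
                "chosen": c is optimal,
            }
            for c in candidates_sets
        ]
    )
    controls_df.to_csv(outdir / "control_sets.tsv", sep="\t", index=False)
    io.write_gene_list(optimal.genes, outdir / "optimal_controls.tsv")
    stage(
        "controls",
        background=len(background),
        candidate_sets=len(candidates_sets),
        chosen_origin=optimal.origin,
        chosen_cv_correct_rate=optimal.cv_correct_rate,
    )

    # --- training / CV / ROC -----------------------------------------
    training = TieredGeneSet({g: positives[g] for g in positives})
    for g in sorted(optimal.genes):
        training.add(g, "C5")
    model = GenePrioritizationModel(
        network, training, class_weights=config.class_weights, gamma=config.gamma, C=config.C
    )
    res = model.fit(cv_folds=config.cv_k, threshold_criterion=config.threshold_criterion, seed=config.seed)
    with open(outdir / "cv_report.json", "wt", encoding="utf-8") as fh:
        json.dump(
            {
                "k": res.cv.k,
                "per_fold_correct_rate": res.cv.per_fold_correct_rate,
                "mean_correct_rate": res.cv.mean_correct_rate,
                "auc": res.roc.auc,
                "threshold": res.roc.chosen_threshold,
                "sensitivity": res.roc.sensitivity_at_threshold,
                "specificity": res.roc.specificity_at_threshold,
            },
            fh,
            indent=2,
        )
    pd.DataFrame(res.roc.points, columns=["fpr", "tpr", "threshold"]).to_csv(
        outdir / "roc.tsv", sep="\t", index=False
    )
    stage(
        "train_cv",
        training_genes=len(training),
        feature_dim=len(res.classifier.col_genes),
        mean_correct_rate=res.cv.mean_correct_rate,
        auc=res.roc.auc,
        threshold=res.roc.chosen_threshold,
    )

    # --- genome-wide prediction + tiers ------------------------------
    genome = sorted((set(universe) | network.nodes | set(training)))
    records = res.predict(genome)
    records = res.assign_tiers(records)
    candidates = [r for r in records if r.label == "associated" and not r.in_training]
    stage(
        "predict",
        genome=len(records),
        associated=sum(r.label == "associated" for r in records),
        candidates=len(candidates),
    )

    # --- functional filter -------------------------------------------
    enrichment = enrich_terms(positives.positives, annotations)
    pd.DataFrame(enrichment_table_rows(enrichment)).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False
    )
    top_terms = select_top_terms(enrichment, top_k=config.top_k_terms, q_max=config.q_max)
    filtered = filter_candidates(candidates, top_terms, annotations, mode=config.go_mode)
    kept_genes = {r.gene for r in filtered}
    for r in records:  # surface the filter outcome in the genome-wide table
        r.go_filtered = r.gene in kept_genes
    io.write_predictions(records, outdir / "predictions.tsv")
    if filtered:
        io.write_predictions(filtered, outdir / "filtered_candidates.tsv")
    stage(
        "go_filter",
        terms_tested=len(enrichment),
        top_terms=len(top_terms),
        candidates_in=len(candidates),
        candidates_out=len(filtered),
    )

    # --- sequence-feature statistics ---------------------------------
    if config.features:
        table = io.read_feature_table(config.features)
        set_map: dict[str, set[str]] = {
            "ad": set(positives) & table.genes,
            "control": set(optimal.genes) & table.genes,
            "predicted": {r.gene for r in filtered} & table.genes,
        }
        if config.non_mental:
            set_map["non_mental"] = io.read_gene_list(config.non_mental) & table.genes
        set_map = {k: v for k, v in set_map.items() if len(v) >= 2}
        if len(set_map) >= 2:
            matrices = compare_sets(table, set_map)
            medians_table(matrices).to_csv(outdir / "medians.tsv", sep="\t")
            pairwise_table(matrices).to_csv(outdir / "pairwise_p.tsv", sep="\t", index=False)
            stage("stats", sets={k: len(v) for k, v in set_map.items()}, features=len(matrices))
        else:
            stage("stats", skipped="fewer than two sets with >= 2 genes in the feature table")

    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        outdir=outdir,
        manifest=manifest,
        optimal_controls=optimal,
        results=res,
        filtered_candidates=filtered,
    )


def write_fixture_bundle(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate one synthetic bundle and write it as pipeline inputs.

    Emits network/positives/background/annotations/features TSVs plus
    the ground truth (truth.json) and a ready-to-run pipeline config
    (config.yaml). Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, truth = generate_network(config)
    annotations = generate_annotations(config, truth)
    table = generate_sequence_features(config, truth)

    paths = {name: str(outdir / f"{name}.tsv") for name in
             ("network", "positives", "background", "annotations", "features")}
    io.write_edge_list(network, paths["network"])
    pos = TieredGeneSet({g: truth.tier_of[g] for g in truth.tier_of.positives})
    io.write_gene_set(pos, paths["positives"])
    io.write_gene_list(set(truth.genes) - set(pos), paths["background"])
    io.write_annotations(annotations, paths["annotations"])
    io.write_feature_table(table, paths["features"])
    with open(outdir / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(
            {
                "planted_module": sorted(truth.planted_module),
                "hidden_candidates": sorted(truth.hidden_candidates),
                "tiers": {g: truth.tier_of[g] for g in sorted(truth.tier_of)},
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
    cfg = {
        **paths,
        "outdir": str(outdir / "out"),
        "seed": config.seed,
        "n_controls": config.n_negatives,
    }
    with open(outdir / "config.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh)
    paths["truth"] = str(outdir / "truth.json")
    paths["config"] = str(outdir / "config.yaml")
    return paths
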