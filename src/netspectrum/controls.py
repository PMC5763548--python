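"""Negative training-set (control) selection.

The negative class is drawn from the background universe (all genes
minus positives minus an exclusion list of known-disease genes). The
preferred set is the *minimal-interaction* control set — the background
genes with the least network interaction with the positives — which is
compared against random draws by cross-validated correct rate, and the
best set wins.

"Interaction" of a gene with the positive set is, by default, the sum of
its edge weights to all positives (``weight_sum``); an alternative
``edge_count`` metric counts edges above a weight cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .containers import TieredGeneSet, WeightedGeneNetwork, normalize_gene_id


@dataclass(frozen=True)
class InteractionScore:
    gene: str
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("interaction score must be >= 0")


@dataclass
class ControlCandidateSet:
    """A candidate negative set and where it came from."""

    genes: frozenset[str]
    origin: str  # "minimal_interaction" | "random_draw"
    draw_index: Optional[int] = None
    cv_correct_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.origin not in ("minimal_interaction", "random_draw"):
            raise ValueError(f"unknown origin {self.origin!r}")
        self.genes = frozenset(normalize_gene_id(g) for g in self.genes)


def interaction_score(
    gene: str,
    positives: Iterable[str],
    network: WeightedGeneNetwork,
    metric: str = "weight_sum",
    cutoff: float = 0.0,
) -> InteractionScore:
    """Interaction of one background gene with the positive set.

    ``weight_sum``: sum of edge weights to positives. ``edge_count``:
    number of positive neighbors with weight > ``cutoff``. Zero iff the
    gene has no positive neighbor (above cutoff).
    """
    gene = normalize_gene_id(gene)
    pos = {normalize_gene_id(p) for p in positives}
    if gene in pos:
        raise ValueError(f"gene {gene} is itself a positive")
    weights = network.neighbor_weights(gene)
    if metric == "weight_sum":
        score = sum(w for p, w in weights.items() if p in pos)
    elif metric == "edge_count":
        score = float(sum(1 for p, w in weights.items() if p in pos and w > cutoff))
    else:
        raise ValueError(f"unknown interaction metric {metric!r}")
    return InteractionScore(gene=gene, score=float(score))


def select_minimal_interaction_controls(
    background: Iterable[str],
    positives: Iterable[str],
    network: WeightedGeneNetwork,
    n: int,
    metric: str = "weight_sum",
    cutoff: float = 0.0,
) -> ControlCandidateSet:
    """The n background genes least interacting with the positives.

    Ties broken lexicographically by gene symbol, so the result is
    deterministic across platforms. The caller guarantees the background
    excludes positives and the exclusion list.
    """
    bg = sorted({normalize_gene_id(g) for g in background})
    if len(bg) < n:
        raise ValueError(f"background has {len(bg)} genes, need {n}")
    scored = [
        (interaction_score(g, positives, network, metric=metric, cutoff=cutoff).score, g)
        for g in bg
    ]
    scored.sort()  # (score, gene): lexicographic tie-break for free
    chosen = frozenset(g for _, g in scored[:n])
    return ControlCandidateSet(genes=chosen, origin="minimal_interaction")


def sample_random_controls(
    background: Iterable[str], n: int, seed: int, draw_index: int | None = None
) -> ControlCandidateSet:
    """Uniform draw of n background genes without replacement."""
    bg = sorted({normalize_gene_id(g) for g in background})
    if len(bg) < n:
        raise ValueError(f"background has {len(bg)} genes, need {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(bg), size=n, replace=False)
    return ControlCandidateSet(
        genes=frozenset(bg[i] for i in chosen),
        origin="random_draw",
        draw_index=draw_index,
    )


def _origin_rank(cand: ControlCandidateSet) -> tuple:
    # prefer minimal_interaction, then lower draw_index
    return (
        0 if cand.origin == "minimal_interaction" else 1,
        cand.draw_index if cand.draw_index is not None else -1,
    )


def select_optimal_control_set(
    candidates: list[ControlCandidateSet],
    positives: TieredGeneSet,
    network: WeightedGeneNetwork,
    cv_k: int = 5,
    seed: int = 0,
    class_weights: dict[str, float] | None = None,
    gamma: float | None = None,
    C: float = 1.0,
) -> ControlCandidateSet:
    """Score every candidate negative set by k-fold CV correct rate of
    the downstream classifier and return the best.

    Ties favor the minimal-interaction set, then the lower draw index.
    Each candidate's ``cv_correct_rate`` is filled in in place.
    """
    from .classify import cross_validate  # local import: avoids cycle
    from .features import build_feature_matrix

    if not candidates:
        raise ValueError("no candidate control sets")
    pos_tiers = TieredGeneSet({g: positives[g] for g in positives.positives})
    for cand in candidates:
        training = TieredGeneSet(dict(pos_tiers))
        for g in sorted(cand.genes):
            training.add(g, "C5")
        rows = sorted(training)
        feats = build_feature_matrix(rows, training, network)
        cv = cross_validate(
            feats, training, k=cv_k, class_weights=class_weights, gamma=gamma, C=C, seed=seed
        )
        cand.cv_correct_rate = cv.mean_correct_rate
    best = max(
        candidates,
        key=lambda c: (c.cv_correct_rate, [-x for x in _origin_rank(c)]),
    )
    return best
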