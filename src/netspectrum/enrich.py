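"""Functional-term over-representation and candidate filtering.

Each term with at least one annotated gene is tested with the one-sided
hypergeometric upper tail: drawing n positives from a universe of N
genes of which K carry the term, the p-value is P(X >= k) for the k
positives observed with the term. p-values are adjusted across all
tested terms with Benjamini-Hochberg. The top terms (by ascending p)
define the functional filter: a predicted candidate is kept iff it is
annotated to at least one of them (strict all-of mode available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationMap, PredictionRecord, normalize_gene_id


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # positives annotated with the term
    K: int  # universe genes annotated with the term
    n: int  # positive-set size
    N: int  # universe size
    p_value: float
    q_value: float
    rank: int


def enrich_terms(positives: Iterable[str], annotations: AnnotationMap) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of every annotated term.

    Results are ranked by ascending p (ties by term id); q-values are
    BH-adjusted over all tested terms.
    """
    pos = {normalize_gene_id(g) for g in positives}
    if not pos:
        raise ValueError("empty positive set")
    if not annotations.universe:
        raise ValueError("empty annotation universe")
    stray = pos - annotations.universe
    if stray:
        raise ValueError(f"positives outside the annotation universe: {sorted(stray)[:5]}")

    N = len(annotations.universe)
    n = len(pos)
    rows = []
    for term in sorted(annotations.terms):
        genes = annotations.genes_of(term)
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & pos)
        # P(X >= k) = survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        raise ValueError("no annotated terms to test")

    _, q_values, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    ranked = sorted(zip(rows, q_values), key=lambda rz: (rz[0][3], rz[0][0]))
    return [
        EnrichmentResult(
            term=term, k=k, K=K, n=n, N=N,
            p_value=min(p, 1.0), q_value=float(min(q, 1.0)), rank=rank,
        )
        for rank, ((term, k, K, p), q) in enumerate(ranked, start=1)
    ]


def select_top_terms(
    results: Sequence[EnrichmentResult], top_k: int = 10, q_max: float | None = None
) -> list[str]:
    """First ``top_k`` terms by ascending p (ties already broken by term
    id in the ranking), optionally also requiring q <= q_max."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ordered = sorted(results, key=lambda r: r.rank)
    if q_max is not None:
        ordered = [r for r in ordered if r.q_value <= q_max]
    return [r.term for r in ordered[:top_k]]


def filter_candidates(
    candidates: Sequence[PredictionRecord],
    top_terms: Sequence[str],
    annotations: AnnotationMap,
    mode: str = "any",
) -> list[PredictionRecord]:
    """Keep candidates annotated to the top terms; order preserved.

    ``mode="any"`` (default) keeps a candidate annotated to >= 1 top
    term; ``mode="all"`` requires annotation to every top term. Kept
    records are returned as copies with ``go_filtered`` set.
    """
    if not top_terms:
        raise ValueError("no top terms to filter on")
    if mode not in ("any", "all"):
        raise ValueError(f"unknown filter mode {mode!r}")
    wanted = set(top_terms)
    kept: list[PredictionRecord] = []
    for rec in candidates:
        terms = annotations.terms_of(rec.gene)
        hit = bool(terms & wanted) if mode == "any" else wanted <= terms
        if hit:
            kept.append(
                PredictionRecord(
                    gene=rec.gene,
                    probability=rec.probability,
                    label=rec.label,
                    tier=rec.tier,
                    go_filtered=True,
                    in_training=rec.in_training,
                )
            )
    return kept


def enrichment_table_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    """Rows for the exported enrichment TSV (term, p, q, k/K, rank)."""
    return [
        {
            "term": r.term,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "rank": r.rank,
        }
        for r in sorted(results, key=lambda r: r.rank)
    ]
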