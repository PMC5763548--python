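"""Core in-memory containers for the prioritization pipeline.

Gene identifiers are plain uppercase symbols: normalization is idempotent
and case-insensitive tokens collapse to one identifier. The weighted
network is an undirected graph whose edge weights are posterior
probabilities of functional interaction in [0, 1]; querying a pair that
was never inserted returns 0, and self-pairs are rejected (features are
gene-to-*other*-gene relations).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

TIERS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5")
POSITIVE_TIERS: tuple[str, ...] = ("C1", "C2", "C3", "C4")
NEGATIVE_TIER: str = "C5"


class FormatError(ValueError):
    """A text input violated the expected file shape."""


def normalize_gene_id(token: str) -> str:
    """Normalize a gene symbol: strip surrounding space, uppercase.

    Raises ValueError for empty tokens or tokens with internal whitespace.
    """
    if token is None:
        raise ValueError("gene identifier is None")
    symbol = str(token).strip().upper()
    if not symbol:
        raise ValueError("empty gene identifier")
    if any(ch.isspace() for ch in symbol):
        raise ValueError(f"gene identifier contains whitespace: {token!r}")
    return symbol


class WeightedGeneNetwork:
    """Symmetric weighted gene-gene interaction network.

    Thin wrapper over :class:`networkx.Graph` enforcing the pipeline's
    contracts: weights in [0, 1], no self-pairs, absent pair => weight 0,
    duplicate insertions resolved by keeping the maximum weight.
    """

    def __init__(self) -> None:
        self._graph = nx.Graph()

    # -- construction -------------------------------------------------

    def add_gene(self, gene: str) -> str:
        gene = normalize_gene_id(gene)
        self._graph.add_node(gene)
        return gene

    def add_edge(self, a: str, b: str, weight: float) -> None:
        """Insert an undirected edge; repeated pairs keep the max weight."""
        a = normalize_gene_id(a)
        b = normalize_gene_id(b)
        if a == b:
            raise ValueError(f"self-pair not allowed: {a}")
        weight = float(weight)
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"weight outside [0, 1]: {weight}")
        if self._graph.has_edge(a, b):
            weight = max(weight, self._graph[a][b]["weight"])
        self._graph.add_edge(a, b, weight=weight)

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_id(gene) in self._graph

    def weight(self, a: str, b: str) -> float:
        """Edge weight between two genes; 0.0 when the pair is absent."""
        a = normalize_gene_id(a)
        b = normalize_gene_id(b)
        if self._graph.has_edge(a, b):
            return float(self._graph[a][b]["weight"])
        return 0.0

    def neighbor_weights(self, gene: str) -> dict[str, float]:
        """Map neighbor -> edge weight; empty for unknown/isolated genes."""
        gene = normalize_gene_id(gene)
        if gene not in self._graph:
            return {}
        return {n: float(d["weight"]) for n, d in self._graph[gene].items()}

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate edges as (a, b, weight) with a < b lexicographically."""
        for a, b, d in self._graph.edges(data=True):
            lo, hi = sorted((a, b))
            yield lo, hi, float(d["weight"])

    def sorted_edges(self) -> list[tuple[str, str, float]]:
        return sorted(self.edges())


class TieredGeneSet(Mapping):
    """Gene -> evidence tier map over C1..C5.

    Tiers C1-C4 are graded positive-evidence classes (probable pathogenic
    down to possibly associated); C5 is the negative / non-associated
    class. Each gene carries exactly one tier, so positives and negatives
    are disjoint by construction.
    """

    def __init__(self, members: Mapping[str, str] | Iterable[tuple[str, str]] = ()) -> None:
        self._members: dict[str, str] = {}
        items = members.items() if isinstance(members, Mapping) else members
        for gene, tier in items:
            self.add(gene, tier)

    def add(self, gene: str, tier: str) -> None:
        gene = normalize_gene_id(gene)
        tier = str(tier).strip().upper()
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r} for gene {gene} (expected one of {TIERS})")
        existing = self._members.get(gene)
        if existing is not None and existing != tier:
            raise ValueError(f"conflicting tier for gene {gene}: {existing} vs {tier}")
        self._members[gene] = tier

    def __getitem__(self, gene: str) -> str:
        return self._members[normalize_gene_id(gene)]

    def __iter__(self) -> Iterator[str]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    @property
    def positives(self) -> set[str]:
        return {g for g, t in self._members.items() if t in POSITIVE_TIERS}

    @property
    def negatives(self) -> set[str]:
        return {g for g, t in self._members.items() if t == NEGATIVE_TIER}

    def genes_in_tier(self, tier: str) -> set[str]:
        return {g for g, t in self._members.items() if t == tier}

    def merged_with(self, other: "TieredGeneSet") -> "TieredGeneSet":
        out = TieredGeneSet(self._members)
        for gene, tier in other.items():
            out.add(gene, tier)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        counts = {t: len(self.genes_in_tier(t)) for t in TIERS if self.genes_in_tier(t)}
        return f"TieredGeneSet({counts})"


class AnnotationMap:
    """Gene <-> functional-term annotation, kept as exact inverse maps.

    Terms are flat labels (no ontology DAG); the universe is the set of
    genes the map knows about, used as the enrichment background.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = (), universe: Iterable[str] = ()) -> None:
        self.gene_to_terms: dict[str, set[str]] = {}
        self.term_to_genes: dict[str, set[str]] = {}
        self.universe: set[str] = {normalize_gene_id(g) for g in universe}
        for gene, term in pairs:
            self.add(gene, term)

    def add(self, gene: str, term: str) -> None:
        gene = normalize_gene_id(gene)
        term = str(term).strip()
        if not term:
            raise ValueError("empty term identifier")
        self.gene_to_terms.setdefault(gene, set()).add(term)
        self.term_to_genes.setdefault(term, set()).add(gene)
        self.universe.add(gene)

    def terms_of(self, gene: str) -> set[str]:
        return set(self.gene_to_terms.get(normalize_gene_id(gene), set()))

    def genes_of(self, term: str) -> set[str]:
        return set(self.term_to_genes.get(term, set()))

    @property
    def terms(self) -> set[str]:
        return set(self.term_to_genes)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((g, t) for g, ts in self.gene_to_terms.items() for t in ts)

    def check_inverse(self) -> bool:
        """True iff gene_to_terms and term_to_genes are exact inverses."""
        forward = {(g, t) for g, ts in self.gene_to_terms.items() for t in ts}
        backward = {(g, t) for t, gs in self.term_to_genes.items() for g in gs}
        return forward == backward and set(self.gene_to_terms) <= self.universe


#: Continuous per-gene sequence features (tested with Mann-Whitney).
CONTINUOUS_FEATURES: tuple[str, ...] = (
    "gene_length",
    "protein_length",
    "cds_length",
    "utr3_length",
    "utr5_length",
    "transcript_count",
    "exon_count",
    "gc_content",
)

#: Binary domain/paralogy flags (tested with chi-squared on 2x2 tables).
FLAG_FEATURES: tuple[str, ...] = ("has_tm_domain", "has_signal_domain", "has_paralog")

FEATURE_COLUMNS: tuple[str, ...] = CONTINUOUS_FEATURES + FLAG_FEATURES


class SequenceFeatureTable:
    """Per-gene table of sequence/structure features.

    Columns: gene length, protein length, CDS length, 3'/5' UTR length
    (bp), transcript and exon counts, GC content (percent), plus binary
    flags for transmembrane domain, signal domain and paralogy.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        df = df.copy()
        df.index = [normalize_gene_id(g) for g in df.index]
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genes in feature table: {dups[:5]}")
        lengths = list(CONTINUOUS_FEATURES[:-1])  # all but gc_content
        if (df[lengths] < 0).any().any():
            raise ValueError("negative length/count in feature table")
        if ((df["gc_content"] < 0) | (df["gc_content"] > 100)).any():
            raise ValueError("gc_content outside [0, 100]")
        for flag in FLAG_FEATURES:
            values = set(pd.unique(df[flag]))
            if not values <= {0, 1, True, False}:
                raise ValueError(f"non-binary values in flag column {flag}")
            df[flag] = df[flag].astype(int)
        self.df = df[list(FEATURE_COLUMNS)]

    @property
    def genes(self) -> set[str]:
        return set(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_id(gene) in self.df.index

    def subset(self, genes: Iterable[str]) -> pd.DataFrame:
        wanted = [normalize_gene_id(g) for g in genes]
        missing = [g for g in wanted if g not in self.df.index]
        if missing:
            raise KeyError(f"genes missing from feature table: {missing[:5]}")
        return self.df.loc[wanted]


@dataclass
class PredictionRecord:
    """One genome-wide prediction: probability of disease association.

    ``label`` is "associated" iff probability >= the chosen ROC
    threshold; ``tier`` is assigned only to associated genes;
    ``go_filtered`` marks candidates that survived the functional-term
    filter. ``in_training`` flags training genes, which are scored but
    excluded from the candidate list.
    """

    gene: str
    probability: float
    label: str
    tier: str | None = None
    go_filtered: bool = False
    in_training: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.gene = normalize_gene_id(self.gene)
        self.probability = float(self.probability)
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability outside [0, 1]: {self.probability}")
        if self.label not in ("associated", "not_associated"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.tier is not None and self.tier not in POSITIVE_TIERS:
            raise ValueError(f"tier must be one of {POSITIVE_TIERS} or None")
        if self.tier is not None and self.label != "associated":
            raise ValueError("tier present on a non-associated record")
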