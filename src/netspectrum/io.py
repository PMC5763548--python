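"""Readers and writers for the pipeline's text formats.

All formats are plain TSV (CSV accepted where noted): 3-column edge
lists, 1/2-column gene sets, 2-column or GAF 2.x annotations, per-gene
feature tables, and 5-column prediction tables. ``#`` comment lines are
skipped in edge lists and gene sets; ``!`` comment lines in GAF.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .containers import (
    FEATURE_COLUMNS,
    AnnotationMap,
    FormatError,
    PredictionRecord,
    SequenceFeatureTable,
    TieredGeneSet,
    WeightedGeneNetwork,
    normalize_gene_id,
)

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}


def _rows(path: str | Path, delimiter: str, comment: str = "#"):
    """Yield (line_number, fields) for non-empty, non-comment lines."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line.split(delimiter)


def read_edge_list(path: str | Path, dialect: str = "tsv") -> WeightedGeneNetwork:
    """Read a 3-column (geneA, geneB, weight) edge list.

    Duplicate pairs keep the maximum weight; self-pairs are dropped and
    counted in a log message. Weights outside [0, 1] or malformed rows
    raise :class:`FormatError` naming the offending line.
    """
    if dialect not in _DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}")
    net = WeightedGeneNetwork()
    n_self = 0
    for lineno, fields in _rows(path, _DELIMS[dialect]):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        try:
            a = normalize_gene_id(fields[0])
            b = normalize_gene_id(fields[1])
            w = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if not 0.0 <= w <= 1.0:
            raise FormatError(f"{path}:{lineno}: weight {w} outside [0, 1]")
        if a == b:
            n_self += 1
            continue
        net.add_edge(a, b, w)
    if n_self:
        logger.info("read_edge_list(%s): dropped %d self-pair row(s)", path, n_self)
    return net


def write_edge_list(net: WeightedGeneNetwork, path: str | Path, dialect: str = "tsv") -> None:
    delim = _DELIMS[dialect]
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b, w in net.sorted_edges():
            fh.write(f"{a}{delim}{b}{delim}{w:.6g}\n")


def read_gene_set(path: str | Path, default_tier: str | None = None) -> TieredGeneSet:
    """Read a (gene, tier) TSV, or a bare gene list with ``default_tier``.

    Duplicate genes with conflicting tiers and unknown tier tokens are
    errors; duplicate consistent rows collapse.
    """
    out = TieredGeneSet()
    for lineno, fields in _rows(path, "\t"):
        try:
            if len(fields) >= 2 and fields[1].strip():
                out.add(fields[0], fields[1])
            elif default_tier is not None:
                out.add(fields[0], default_tier)
            else:
                raise ValueError("row has no tier and no default_tier was given")
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_set(genes: TieredGeneSet, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(genes):
            fh.write(f"{gene}\t{genes[gene]}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a 1-column gene list (e.g. an exclusion list) into a set."""
    out: set[str] = set()
    for lineno, fields in _rows(path, "\t"):
        try:
            out.add(normalize_gene_id(fields[0]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted({normalize_gene_id(g) for g in genes}):
            fh.write(gene + "\n")


def read_annotations(path: str | Path, format: str = "two_column_tsv") -> AnnotationMap:
    """Read gene->term annotations from 2-column TSV or GAF 2.x.

    GAF uses column 2 (symbol) and column 5 (term id); ``!`` header and
    comment lines are skipped. Duplicate (gene, term) pairs deduplicate.
    An empty file (or header-only GAF) is an error.
    """
    amap = AnnotationMap()
    if format == "two_column_tsv":
        for lineno, fields in _rows(path, "\t"):
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                amap.add(fields[0], fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    elif format == "gaf":
        for lineno, fields in _rows(path, "\t", comment="!"):
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: GAF row has {len(fields)} columns, need >= 5")
            try:
                amap.add(fields[1], fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not amap.gene_to_terms:
        raise FormatError(f"{path}: no annotation rows found")
    return amap


def write_annotations(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene, term in amap.pairs():
            fh.write(f"{gene}\t{term}\n")


def read_feature_table(path: str | Path) -> SequenceFeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SequenceFeatureTable(df)


def write_feature_table(table: SequenceFeatureTable, path: str | Path) -> None:
    out = table.df.sort_index()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


_PRED_HEADER = ["gene", "probability", "label", "tier", "go_filtered"]


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write prediction records as 5-column TSV, descending probability.

    Probabilities are printed at 6 decimals; a read-back reproduces the
    records bit-exactly at that precision.
    """
    if not records:
        raise ValueError("no prediction records to write")
    ordered = sorted(records, key=lambda r: (-r.probability, r.gene))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_PRED_HEADER) + "\n")
        for r in ordered:
            fh.write(
                f"{r.gene}\t{r.probability:.6f}\t{r.label}\t"
                f"{r.tier or '-'}\t{int(r.go_filtered)}\n"
            )


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PRED_HEADER:
            raise FormatError(f"{path}: unexpected header {header}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                records.append(
                    PredictionRecord(
                        gene=fields[0],
                        probability=float(fields[1]),
                        label=fields[2],
                        tier=None if fields[3] == "-" else fields[3],
                        go_filtered=bool(int(fields[4])),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records
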