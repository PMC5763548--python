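"""Network feature space for the classifier.

Each gene's feature vector is its row of edge weights against the
training genes — one column per training gene (positives in tier order
C1..C4, then negatives), entries in [0, 1], missing edge = 0. With 335
positives and 335 negatives this is the 670-dimensional guilt-by-
association representation.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import TIERS, TieredGeneSet, WeightedGeneNetwork, normalize_gene_id

_TIER_RANK = {t: i for i, t in enumerate(TIERS)}


def column_order(training: TieredGeneSet) -> list[str]:
    """Deterministic column order: C1..C4 blocks then C5, lexicographic
    within each block. Independent of the input map's iteration order."""
    if len(training) == 0:
        raise ValueError("empty training set")
    return sorted(training, key=lambda g: (_TIER_RANK[training[g]], g))


class FeatureMatrix:
    """Genes x training-genes matrix of network edge weights.

    Stored sparse (CSR); ``value`` and ``row`` answer point/row queries,
    ``to_frame`` materializes a dense DataFrame for inspection.
    """

    def __init__(self, row_genes: Sequence[str], col_genes: Sequence[str], values: sp.spmatrix):
        self.row_genes = list(row_genes)
        self.col_genes = list(col_genes)
        self.values = sp.csr_matrix(values, dtype=np.float64)
        if self.values.shape != (len(self.row_genes), len(self.col_genes)):
            raise ValueError("matrix shape does not match gene lists")
        self._row_index = {g: i for i, g in enumerate(self.row_genes)}
        self._col_index = {g: i for i, g in enumerate(self.col_genes)}
        if len(self._row_index) != len(self.row_genes):
            raise ValueError("duplicate row genes")
        if len(self._col_index) != len(self.col_genes):
            raise ValueError("duplicate column genes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def value(self, gene: str, training_gene: str) -> float:
        i = self._row_index[normalize_gene_id(gene)]
        j = self._col_index[normalize_gene_id(training_gene)]
        return float(self.values[i, j])

    def row(self, gene: str) -> np.ndarray:
        i = self._row_index[normalize_gene_id(gene)]
        return self.values[i].toarray().ravel()

    def rows(self, genes: Sequence[str]) -> sp.csr_matrix:
        idx = [self._row_index[normalize_gene_id(g)] for g in genes]
        return self.values[idx]

    def row_sums(self) -> dict[str, float]:
        sums = np.asarray(self.values.sum(axis=1)).ravel()
        return dict(zip(self.row_genes, sums))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.row_genes, columns=self.col_genes
        )

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.6g")


def build_feature_matrix(
    genes: Sequence[str],
    training: TieredGeneSet,
    network: WeightedGeneNetwork,
    standardize: bool = False,
) -> FeatureMatrix:
    """Assemble the guilt-by-association feature matrix.

    One row per requested gene (in the given order), one column per
    training gene (:func:`column_order`). A gene absent from the network
    gets an all-zero row; a training gene's own column is 0 on its own
    row because the network holds no self-pairs.

    ``standardize`` optionally z-scores columns (off by default — the
    weights are already posterior probabilities on a common [0, 1]
    scale).
    """
    genes = [normalize_gene_id(g) for g in genes]
    if not genes:
        raise ValueError("empty gene list")
    cols = column_order(training)
    col_index = {g: j for j, g in enumerate(cols)}

    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for g in genes:
        for neighbor, w in sorted(network.neighbor_weights(g).items()):
            j = col_index.get(neighbor)
            if j is not None and w != 0.0:
                indices.append(j)
                data.append(w)
        indptr.append(len(indices))
    values = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(len(genes), len(cols)),
    )
    values.sort_indices()
    if standardize:
        dense = values.toarray()
        mu = dense.mean(axis=0)
        sd = dense.std(axis=0)
        sd[sd == 0] = 1.0
        values = sp.csr_matrix((dense - mu) / sd)
    return FeatureMatrix(genes, cols, values)
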