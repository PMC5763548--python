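"""Sequence-feature assessment battery.

Pairwise comparisons of per-gene sequence features across labelled gene
sets: continuous features (lengths, counts, GC) with the two-sided
Mann-Whitney U test, binary flags (transmembrane/signal domain,
paralogy) with the Pearson chi-squared test on the 2x2 membership-by-
flag table. Formatted reports floor displayed p-values at 2.2e-16, the
conventional double-precision floor; raw values are kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CONTINUOUS_FEATURES,
    FLAG_FEATURES,
    SequenceFeatureTable,
    normalize_gene_id,
)

P_DISPLAY_FLOOR = 2.2e-16


def mann_whitney_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Exact p by enumeration when n_a + n_b <= 16 and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared_test(
    counts: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table (1 df), no continuity
    correction by default. All marginals must be positive."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {table.shape}")
    if (table < 0).any():
        raise ValueError("negative cell count")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(min(p, 1.0))


@dataclass
class ComparisonMatrix:
    """All pairwise tests of one feature across the labelled sets."""

    feature: str
    sets: list[str]
    p_values: pd.DataFrame  # symmetric, NaN diagonal
    test_used: str  # "mann_whitney" | "chi_squared"
    medians_or_rates: dict[str, float]

    def p(self, set_a: str, set_b: str) -> float:
        if set_a == set_b:
            raise ValueError("no self-comparison on the diagonal")
        return float(self.p_values.loc[set_a, set_b])


def compare_sets(
    features: SequenceFeatureTable,
    set_map: Mapping[str, Iterable[str]],
    feature_list: Sequence[str] | None = None,
) -> list[ComparisonMatrix]:
    """One :class:`ComparisonMatrix` per feature.

    Continuous features report per-set medians and Mann-Whitney p's;
    flags report per-set rates and chi-squared p's. Every listed gene
    must be present in the feature table (error names the gene).
    """
    labels = list(set_map)
    sets = {}
    for label in labels:
        genes = [normalize_gene_id(g) for g in set_map[label]]
        for g in genes:
            if g not in features:
                raise KeyError(f"gene {g} (set {label!r}) missing from the feature table")
        sets[label] = features.subset(genes)

    wanted = list(feature_list) if feature_list else list(CONTINUOUS_FEATURES + FLAG_FEATURES)
    out: list[ComparisonMatrix] = []
    for feat in wanted:
        is_flag = feat in FLAG_FEATURES
        pmat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
        summary: dict[str, float] = {}
        for label in labels:
            col = sets[label][feat]
            summary[label] = float(col.mean()) if is_flag else float(col.median())
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                if is_flag:
                    xa, xb = sets[la][feat], sets[lb][feat]
                    table = [
                        [int(xa.sum()), int(len(xa) - xa.sum())],
                        [int(xb.sum()), int(len(xb) - xb.sum())],
                    ]
                    _, p = chi_squared_test(table)
                else:
                    _, p = mann_whitney_test(sets[la][feat], sets[lb][feat])
                pmat.loc[la, lb] = pmat.loc[lb, la] = p
        out.append(
            ComparisonMatrix(
                feature=feat,
                sets=labels,
                p_values=pmat,
                test_used="chi_squared" if is_flag else "mann_whitney",
                medians_or_rates=summary,
            )
        )
    return out


def ordering_check(
    p_matrix: ComparisonMatrix,
    groups: tuple[tuple[str, str], tuple[str, str], tuple[str, str]],
) -> bool:
    """Check the expected p-value ordering across three designated pairs.

    ``groups`` = (group1, group2, group3) as (set_a, set_b) pairs —
    conventionally group 1 = disease vs other-disease comparison set,
    group 2 = disease vs predicted, group 3 = disease vs control. True
    iff p(group3) < p(group1) < p(group2): the predicted set resembles
    the disease set most, the control set least.
    """
    for pair in groups:
        for label in pair:
            if label not in p_matrix.sets:
                raise ValueError(f"set {label!r} not in the comparison matrix")
    p1 = p_matrix.p(*groups[0])
    p2 = p_matrix.p(*groups[1])
    p3 = p_matrix.p(*groups[2])
    return p3 < p1 < p2


def format_p(p: float) -> str:
    """Displayed p-value with the conventional 2.2e-16 floor."""
    if p < P_DISPLAY_FLOOR:
        return "< 2.2E-16"
    return f"{p:.4g}"


def medians_table(matrices: Sequence[ComparisonMatrix]) -> pd.DataFrame:
    """Per-set median (continuous) or rate (flags) per feature."""
    rows = {m.feature: m.medians_or_rates for m in matrices}
    return pd.DataFrame(rows).T


def pairwise_table(matrices: Sequence[ComparisonMatrix]) -> pd.DataFrame:
    """Long-format table of all pairwise p-values, with display strings."""
    rows = []
    for m in matrices:
        for i, la in enumerate(m.sets):
            for lb in m.sets[i + 1 :]:
                p = m.p(la, lb)
                rows.append(
                    {
                        "feature": m.feature,
                        "set_a": la,
                        "set_b": lb,
                        "test": m.test_used,
                        "p_value": p,
                        "p_display": format_p(p),
                    }
                )
    return pd.DataFrame(rows)


def density_table(
    features: SequenceFeatureTable,
    set_map: Mapping[str, Iterable[str]],
    feature: str,
    n_points: int = 128,
) -> pd.DataFrame:
    """Descriptive per-set kernel-density summary of one continuous
    feature on a log10 grid (distribution-plot analogue)."""
    if feature not in CONTINUOUS_FEATURES:
        raise ValueError(f"density summaries are for continuous features, not {feature!r}")
    frames = []
    for label, genes in set_map.items():
        values = np.log10(features.subset(list(genes))[feature].astype(float) + 1.0)
        grid = np.linspace(values.min(), values.max(), n_points)
        kde = stats.gaussian_kde(values)
        frames.append(
            pd.DataFrame({"set": label, "log10_value": grid, "density": kde(grid)})
        )
    return pd.concat(frames, ignore_index=True)
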