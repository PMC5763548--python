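"""Small bundled example datasets.

``LITERATURE_REPORTS`` is a curated example of a literature cross-check:
genes reported as Alzheimer's-associated in post-2014 publications,
grouped by article. ``EXAMPLE_TRAINED`` / ``EXAMPLE_PREDICTED`` are the
companion membership lists saying which of those genes sat in an
example training set and which in an example predicted candidate list;
they are a synthetic stand-in staged from the per-article report (not a
re-derived gene catalogue) and exist to exercise and demonstrate
:func:`netspectrum.pipeline.cross_check`.
"""

from __future__ import annotations

#: (article label, genes reported AD-associated in that article)
LITERATURE_REPORTS: list[tuple[str, list[str]]] = [
    ("Chen et al.", ["DYSF", "PAXIP1"]),
    ("Xiao et al.", ["CD2AP", "SORL1", "FERMT2", "PVRL2", "TOMM40"]),
    ("Gao et al.", ["DAB1"]),
    ("Malishkavich et al.", ["ADNP"]),
    ("Lee et al.", ["ANXA1", "CDC25C"]),
    ("Zheng et al.", ["APC2"]),
    ("Lin et al.", ["APOA1", "APOC3", "APOA4"]),
    ("Marchesi et al.", ["NLRP3", "APP", "TREX1", "NOTCH3", "COL4A1"]),
]

#: Example training-list members among the reported genes.
EXAMPLE_TRAINED: frozenset[str] = frozenset(
    {"SORL1", "FERMT2", "TOMM40", "APOA1", "APOA4", "APP"}
)

#: Example predicted-candidate members among the reported genes.
EXAMPLE_PREDICTED: frozenset[str] = frozenset(
    {"PAXIP1", "PVRL2", "DAB1", "ADNP", "ANXA1", "CDC25C", "APC2", "APOC3", "NLRP3", "COL4A1"}
)


def literature_query_genes() -> list[str]:
    """All genes in the literature report, in report order, deduplicated."""
    seen: list[str] = []
    for _, genes in LITERATURE_REPORTS:
        for g in genes:
            if g not in seen:
                seen.append(g)
    return seen
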