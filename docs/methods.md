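# Methods

This note documents the models and procedures implemented in
`netspectrum`, the defaults and why they were chosen, what the synthetic
benchmarks do and do not emulate, and the numerical conventions.

## The prioritization model

The core assumption is guilt by association on a tissue-specific
functional network: genes belonging to a disease module interact more —
and more strongly — with known disease genes than background genes do.
Edge weights are posterior probabilities of functional interaction in
`[0, 1]`; an absent pair is weight 0, self-pairs are excluded, and the
network is undirected (duplicate insertions keep the maximum weight, a
conservative rule against row duplication in concatenated downloads).

A gene's feature vector is its row of edge weights against the training
genes (positives in tier order C1..C4, then C5 negatives, lexicographic
within blocks — a fixed, platform-independent column order). No feature
scaling is applied by default: the weights already share the `[0, 1]`
posterior scale, and the radial kernel is applied to them directly. A
`standardize` flag exists for experimentation.

### Negative-set selection

"Interaction with the positive set" is operationalized as the sum of a
gene's edge weights to all positives (`weight_sum`). An alternative —
the count of positive neighbors above a weight cutoff (`edge_count`) —
is exposed as a config option, since either reading is defensible; the
weight-sum default uses the full information in the posteriors. The
minimal-interaction set is the `n` background genes with the smallest
score, ties broken lexicographically for determinism. Candidate negative
sets (the minimal-interaction set plus any number of uniform random
draws; the pipeline default is 10 draws, configurable upward — each
draw multiplies the cross-validation cost) are scored by mean k-fold CV
correct rate of the downstream classifier, and the argmax wins, ties
favoring the minimal-interaction origin and then the lower draw index.

### Classifier

A support-vector machine with radial (RBF) kernel, `gamma` defaulting to
`1/n_features` and `C = 1`; no hyperparameter search is in scope.
Evidence grading enters as per-sample weights from the tier→weight map,
default `C1:4, C2:3, C3:2, C4:1, C5:1`. Grading by sample weight (rather
than a two-class `class_weight`) lets each positive tier pull the
boundary in proportion to its evidence while the problem remains binary.
Decision margins are mapped to probabilities with the standard monotone
sigmoid (Platt) calibration, which tier assignment and thresholding
require.

Cross-validation is stratified k-fold, default **k = 5**. (Different
parts of the original study design describe both 5-fold and 10-fold
splitting; `k` is a parameter and 5 is the documented default.) Genes
are sorted before splitting, so fold assignment is a function of
`(seed, gene set)` only, not of input row order. "Correct rate" is the
fraction of held-out genes on the right side of probability 0.5.

The ROC is built from the out-of-fold probabilities; AUC is the
probability a random positive outscores a random negative with ties
counted ½. The operating threshold maximizes Youden's J over the
observed scores (lowest threshold among ties; an `accuracy` criterion is
available), and a gene is called associated when its probability is ≥
the threshold. Training genes are scored but flagged and excluded from
candidate lists.

Tier assignment uses four one-vs-negatives binary models sharing the C5
set — the most direct reading of "compare the probability of each group
and choose the largest"; a single multiclass model would have been the
alternative. Ties resolve toward the stronger-evidence tier. Tiers
without training members contribute probability 0.

### Functional filter

Term over-representation in the positives is the one-sided
hypergeometric upper tail `P(X ≥ k)` for each annotated term, with
Benjamini–Hochberg adjustment across all tested terms. The universe is
the full gene set known to the annotation map (the pipeline extends it
with the background universe, so unannotated genes count in `N`).
Annotations are flat labels: no ontology-DAG propagation. The filter
keeps candidates annotated to ≥ 1 of the top 10 terms by ascending p
(ties by term id); a strict all-of mode exists. Both the any-of reading
and the flat-term treatment are deliberate simplifications documented
here rather than options hidden in defaults.

### Sequence-feature assessment

Continuous features use the two-sided Mann-Whitney U test — exact by
enumeration when `n_a + n_b ≤ 16` with no ties, otherwise the
tie-corrected normal approximation with continuity correction. Binary
flags use the Pearson chi-squared test on the 2×2 membership-by-flag
table, 1 df, no Yates correction by default (flag available). Two-sided
tests throughout. Formatted reports floor displayed p-values at
`2.2e-16` (the conventional double-precision floor); raw values are kept
internally. The distribution summaries (kernel densities on a log10
grid) are descriptive output only, not tested numerics.

The ordering check formalizes the expectation that, for a feature like
gene length, the positives differ from the controls most, from an
unrelated-disease comparison set moderately, and from their own
predicted candidates least: `p(vs control) < p(vs other-disease) <
p(vs predicted)`.

## Synthetic benchmarks

The generators produce the structure the method assumes, not a faithful
interactome:

* **Network.** A planted partition: pairs with both endpoints inside the
  planted module (positives + hidden candidates) appear with probability
  `p_edge_in` and Beta(`w_in_params`) weights; all other pairs use
  `p_edge_bg` and Beta(`w_bg_params`). Beta weights because the real
  edge weights are bounded posteriors. Defaults: `p_edge_in = 0.3` with
  Beta(5, 2) against `p_edge_bg = 0.02` with Beta(2, 5) — a strong,
  clearly learnable effect; the null configuration flattens everything.
  Hidden candidates (default half the positive count) are wired like
  positives but excluded from training, giving recovery and
  tier-assignment tests a ground truth the real analysis cannot have.
  Negatives (C5) are drawn uniformly from outside the module; positives
  are split over C1..C4 by `tier_fractions` (default 0.1/0.2/0.3/0.4 —
  few probable-pathogenic genes, many possibly-associated ones).
* **Annotations.** Flat terms; a designated subset ("disease terms",
  default 20 of 200) annotates module genes at odds
  `enrichment_effect × baseline odds` (defaults 5 × odds(0.05)); all
  other gene-term pairs at baseline. No DAG, no term-size distribution.
* **Sequence features.** Per-regime log-normal draws whose medians are
  calibrated to published disease-vs-control gene-set values (module vs
  background: gene length 43,474.5 vs 8,906 bp; 3'UTR 309 vs 103; 5'UTR
  345 vs 134; transcripts 8 vs 3; exons 10 vs 5; flag rates TM
  31.31 % vs 23.18 %, signal 33.43 % vs 14.09 %, paralog 81.79 % vs
  45.97 %). Log-normal spread (`sigma = 1.0` for gene length) gives the
  heavy right tail such length distributions show; counts are rounded
  with floor 1. Protein length, CDS length and GC content have no
  published calibration target here; they get plausible genome-wide
  defaults (GC has no module shift). The four-set comparison fixture
  draws the "predicted" set from the module regime itself and the
  "non-mental-health" comparison set from the module regime attenuated
  by 0.75 on continuous medians — disease-like but measurably different —
  which is what produces the expected p-value ordering.

Everything is deterministic per seed: each generator draws from an
independent stream keyed `(seed, stream-id)`.

**What passing the synthetic tests shows:** the pipeline recovers a
planted module when one exists at the configured effect size, stays at
chance when none exists, and every statistical primitive matches an
independent oracle. **What it does not show:** performance on a real
interactome, whose degree distribution, weight distribution, modularity
and annotation structure the generators do not attempt to mimic, nor
anything about the quality of a real curated positive set.

## Problem sizes

The bundled benchmark scales are a 200-gene "small" fixture (module 40 =
30 positives + 10 hidden, 30 negatives) and a 2,000-gene "medium"
fixture (module 150 = 100 positives + 50 hidden, 100 negatives); the
acceptance script and test suite run at these scales, with 20 replicates
for the null calibration and ordering Monte-Carlos. The generator's
nominal defaults are genome scale (22,646 genes, 335 + 335 training)
and are exercised for the feature-dimension contract with a sparse
800-gene variant carrying the full 670-gene training design.

## Numerical conventions and edge cases

* Duplicate edge rows keep the maximum weight; self-pairs are dropped
  with a logged count.
* Gene identifiers are uppercase symbols; no alias resolution. Symbol
  collision across sources is the caller's problem by design.
* A gene absent from the network gets an all-zero feature row and the
  model's isolated-gene baseline probability, identical for all such
  genes.
* `P(X ≥ 0) = 1` (unannotated terms never reach significance); BH q is
  clipped to 1 and is monotone along ascending p.
* Threshold ties resolve to the lower threshold; tier-probability ties
  to the stronger-evidence tier; ranking ties to lexicographic ids —
  every tie-break is deterministic and platform-independent.
* The 100-random-draw control comparison of the original design is
  supported but defaults to 10 draws in the pipeline, since each draw
  costs one full cross-validation.

## Known limitations

* The minimal-interaction criterion and the evidence-weight magnitudes
  are design choices where the original description is silent; both are
  configurable, and conclusions that depend on them should be checked
  across settings.
* Platt calibration on small training sets (tier models with few
  members) yields coarse probabilities; tier assignments for tiers with
  < ~5 training genes are indicative only.
* The functional filter treats annotations as flat and complete;
  missing annotations silently drop candidates.
* Synthetic realism stops at the planted-module contract (see above).
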