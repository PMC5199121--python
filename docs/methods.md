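# Methods

This note documents the models and numerical choices behind
`phosphatlas`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Preprocessing

Raw input is a long table of log2 phosphopeptide fold changes (study,
condition, replicate, replicate kind, site, modification key, ratio).
`run_preprocess` applies a fixed step order; every filter is idempotent
and the per-step record counts are reported:

1. **Peptide merging.** Peptides carrying the same modification set (same
   `mod_key`) in the same condition/replicate are one measurement of the
   same biology; their ratios are averaged.
2. **Replicate handling.** Technical replicates of a condition are
   averaged per peptide. Biological replicates are *not* averaged: when a
   condition carries ≥ 2 biological replicate indices, each becomes its
   own condition column `"<condition>.rep<k>"`. Nested designs (technical
   measurements inside biological replicates) are encoded by repeating
   rows within a biological replicate index; peptide merging collapses
   them first, so the split still yields one column per biological
   replicate.
3. **Monophospho filter.** Only peptides with exactly one phosphosite
   give unambiguous site-level quantification; multi-site modification
   keys are dropped.
4. **Multi-study filter.** Sites reported by fewer than `min_studies`
   (default 2) distinct studies are removed — single-study sites are
   enriched in identification artifacts, and requiring independent
   replication trades coverage for reliability. The filter acts on
   *sites*, not peptides.
5. **Quantile normalization.** Condition columns are forced to a common
   distribution. Because columns have different numbers of observed
   values, the reference is the mean of the per-column empirical quantile
   functions evaluated on a common probability grid (linear
   interpolation, grid length = largest column count). Each column's
   values are replaced by the reference quantiles at their ranks; tied
   values receive the average of their targets; missing cells stay
   missing. For complete equal-length columns this reduces exactly to the
   classic sorted-row-means construction.
6. **Condition coverage.** Conditions with fewer than `min_quant`
   quantifications are dropped. The package default is 1,000, appropriate
   for compendium-scale inputs (tens of thousands of sites); the packaged
   synthetic fixture uses 100, the same ~2.5% of its 4,000-site universe.
   The count is taken after merging and the monophospho filter, matching
   the step order above.

Missing values are encoded as absent rows / empty matrix cells, never as
sentinel numbers.

## Weighted KSEA

The enrichment score walks the condition's sites in descending fold-change
order (ties broken by site identifier for determinism) and accumulates
`+|v|/Σ_hits|v|` at substrate sites, `−|v|/Σ_miss|v|` elsewhere. Both
sides normalize to 1, so the path ends at 0, stays within [−1, 1], is
antisymmetric under negation of the data, and is invariant to positive
rescaling. ES is the path value of maximum absolute deviation. A
`classic_misses` flag switches the decrements to GSEA-style uniform
`1/(N − N_hits)` steps for comparison; the default keeps both sides
fold-change-proportional.

**Null and p-value.** Each permutation draws a uniformly random substrate
set of the same size from the same vector, keeping the value distribution
fixed. The p-value is two-sided on |ES| with an add-one correction,
`p = (1 + #{|ES_null| ≥ |ES|})/(n_perm + 1)`, so `p ∈ [1/(n_perm+1), 1]`
and the signed activity `±(−log10 p)` is capped at `log10(n_perm + 1)`
(3.0 at the default 1,000 permutations). The direction is assigned
separately from the p-value, as the sign of the mean fold change over
quantified substrates; a two-sided p keeps the significance direction-free.
If that mean is exactly zero the activity is 0 and the result flagged.

Degenerate inputs raise a distinct not-computable signal rather than
returning p = 1: no quantified substrate, every site a substrate, or all
substrate values exactly zero.

**Implementation.** The null is evaluated without materializing full
running-sum paths: path extremes can only occur at a hit or immediately
before one, so each permutation's ES is computed from its (sorted) hit
positions alone; this is exact and is property-tested against the naive
walk. Pseudo-substrate sets are drawn as *site subsets* and mapped to rank
positions afterwards, which makes the null samples for a vector and its
negation coincide exactly under matched seeds (the negation-symmetry
guarantee). Small-instance exact p-values come from exhaustive enumeration
of all C(N, n_hits) placements and serve as the oracle for the Monte-Carlo
machinery.

**Reproducibility.** Every (kinase, condition) cell uses its own RNG
stream derived from a master seed via CRC32 of the labels, so the activity
matrix does not depend on iteration order or parallel scheduling.

## Atlas operations

`build_activity_matrix` computes one KSEA test per cell with at least
`min_hits` (default 5) quantified substrates; sparser cells stay missing.
Regulation calls use `|activity| > 1.75` (strict inequality). The
expected-regulation benchmark scores positives by direction-matched
activity and draws each of `n_random` negative sets as random
(kinase, condition) cells from the same kinases and conditions, with
directions resampled from the expected set so that both classes are scored
identically; AUC is the Mann–Whitney rank statistic with average ties.
Regulatory-site validation correlates activity profiles with the
quantification profiles of annotated regulatory sites over ≥ 10 shared
conditions, restricted to kinases whose profile is regulated somewhere
(|activity| > 1 in at least one condition).

## Fingerprints

Kinases inferred in ≥ 75% of conditions enter the fingerprint analysis;
near-duplicate conditions (Pearson r > 0.99 over ≥ 20 shared kinases —
thresholds exposed as configuration since "extreme redundancy" has no
canonical value) collapse to their best-covered representative. Remaining
missing cells are imputed by regularized iterative PCA: column-mean
initialization, then alternating rank-`ncp` SVD reconstruction — singular
values shrunk by the residual variance of the discarded components — and
refill of the missing cells until the imputed values stabilize. Observed
cells are never altered; `choose_ncp` selects the rank by cross-validated
masking error. PCA itself is SVD on centered, unscaled data (scaling off
so strongly-swinging kinases carry their real weight). Component counts
are reported under two criteria: broken stick (component k of p is
significant while its variance share exceeds `b_k = (1/p) Σ_{i=k..p} 1/i`,
counted as the leading run) and Kaiser–Guttman (eigenvalue strictly above
the mean); the broken stick is the stringent criterion and never exceeds
the Kaiser count on low-rank-plus-noise data.

Condition networks use Spearman correlation over ≥ 10 shared kinases with
Benjamini–Hochberg control across all pairs. Logic relations between
kinase pairs binarize regulation at 1.75 and test the 2×2 co-occurrence
table with Fisher's exact test (BH across pairs): significant positive
association is **AND** when co-regulated activities agree in sign and
**OR** when they oppose; significant mutual exclusivity (odds ratio < 1)
is **NOT**. Generalist scores count regulated conditions per kinase.
The kinase–kinase network has an edge A→B when B's protein hosts a
substrate site of A (self-loops removed); betweenness is Brandes'
unnormalized shortest-path count, exact against brute-force enumeration.

## Effectors

Complex regulation per condition compares |fold changes| of the sites on a
complex's subunits against all quantified sites (two-sided two-sample KS;
the complex's own sites stay in the background under the literal "against
all sites" reading — a complement-background flag exists). The score is
−log10 p signed by the complex sites' mean fold change and requires ≥ 3
quantified sites. Kinase–complex association is the Pearson correlation of
these scores with the kinase's activity profile over ≥ 10 shared
conditions, BH-corrected over all pairs; when validating, the kinase's own
training substrates are first removed from the complex score (only
complexes actually hosting such sites are recomputed) so known edges
cannot validate themselves. The PPV/FDR curve walks the q-value threshold
and compares the precision of the predictions against the prevalence
baseline of a random predictor.

Motif scoring builds a position frequency matrix from known-substrate
flanks (window ±7, pseudocount 0.05/20 per cell, padding characters
excluded with renormalization; a position observed only as padding falls
back to uniform). Two scores are min–max normalized to [0, 1] so fixed
thresholds are meaningful: the log-weight sum `Σ ln f(i, b_i)` and the
MATCH-style matrix similarity score `Σ I(i)·f(i, b_i)` with information
vector `I(i) = Σ_b f(i,b) ln(20 f(i,b))` — the alphabet constant is 20
for amino acids (the original formulation is for 4-letter DNA). The
central phosphoacceptor is excluded from both scores since it is fixed by
construction; a uniform (zero-information) matrix scores 0 by convention.
Substrate shortlisting is a conjunction of optional filters: positive
co-regulation with p < 0.01, normalized log-weights > 0.8, MSS > 0.6,
inhibition response below a cutoff, and an in-vitro evidence flag.

## Synthetic compendium

The generator draws a ground truth and emits the long record table the
preprocessing expects. Defaults are the packaged fixture: 40 kinases ×
60 conditions × 4,000 sites on 800 proteins in 6 studies, 20 substrates
per kinase (80% revealed as "known", the rest held out), activity SD 2.0
vs noise SD 1.0.

* **Activities** are sparse: each kinase is regulated in a condition with
  probability 0.15 (specialists) or 0.5 (the 20% designated generalists),
  with magnitudes drawn from N(0, σ_a); every condition is guaranteed at
  least one regulated kinase.
* **Fold-change propagation** is linear-additive in log2 space with unit
  substrate weights — the simplest model consistent with the assumption
  that substrate fold changes track kinase activity. A configurable
  fraction of substrate weights can be flipped to −1 to stress-test the
  inference with inhibitory phosphosites (off by default), and a
  heavy-tailed (t, 3 df) noise switch stresses the rank-based steps.
* **Complexes** are disjoint groups of 4–8 non-kinase proteins; half are
  coupled to a kinase and shift all their sites by 0.8 × activity
  whenever that kinase is regulated. Each coupled complex contributes one
  site to its kinase's substrate set so that substrate-based validation
  of couplings has signal.
* **Detection.** Studies observe sites as Bernoulli draws from
  site-specific propensities with two classes: curated sites (kinase
  substrates and complex subunits, the well-studied corner of any real
  compendium) draw from Beta(5, 2), background sites from Beta(0.35, 3).
  The background class is tuned so that ~52% of observed background sites
  are single-study, mirroring the sparsity of real multi-study
  compendia; it cannot hold over all sites at this scale because the
  fixture's substrate fraction is necessarily much higher than a real
  compendium's (otherwise no kinase would reach the 5-substrate minimum).
* **Replicates and decoys.** 20% of conditions carry two technical
  replicates (jitter SD 0.1); multiphosphorylated decoy peptides are
  injected at 5% of records to exercise the monophospho filter;
  biological replicates are off by default but supported.
* **Flanks.** Each kinase has a true PWM: uniform except 4 informative
  off-center positions where a preferred residue has probability 0.7.
  Substrate flanks are sampled from the owning kinase's PWM, background
  flanks uniformly.

What the generator does **not** emulate: mass-spectrometry intensity and
missingness-by-abundance models, PTM cross-talk, protein-abundance
confounding of phosphorylation changes, correlated noise between
conditions of a study, and realistic kinase-substrate network topology.
Passing recovery tests therefore demonstrate the statistical machinery is
correct and well calibrated under the stated generative model — not that
the pipeline is robust to every artifact of real compendia.

## Problem sizes and determinism

The packaged fixture (4,000 sites) builds in a few seconds and the whole
test suite, including end-to-end pipeline runs and the 10⁵-permutation
oracle comparisons, completes in about a minute; these sizes were chosen
to keep ground-truth recovery statistically stable (2,400 activity cells,
~550 observed background sites for the sparsity statistic) while staying
desk-scale. All randomness flows from explicit seeds: the generator and
the activity matrix derive per-purpose child streams from a master seed,
so outputs are byte-identical across runs and independent of evaluation
order.
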