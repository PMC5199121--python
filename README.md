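# phosphatlas

Kinase-regulation atlases from phosphoproteome compendia.

Shotgun phosphoproteomics quantifies thousands of phosphopeptides per
perturbation, but any individual phosphosite is observed stochastically —
across a multi-study compendium, half the sites may appear in a single
study only. `phosphatlas` sidesteps the site-coverage problem by inferring
the regulation of **kinases**: a kinase's activity change in a condition is
read out from the collective behaviour of its known substrate sites within
the ranked list of all quantified fold changes. The package implements the
full analysis stack around this idea, for computational biologists who
work with compendia of log2 phosphopeptide fold changes:

* **Preprocessing** — peptide merging, replicate handling, monophospho and
  multi-study filters, quantile normalization, condition-coverage filter.
* **Weighted KSEA** (kinase set enrichment analysis) — a weighted
  Kolmogorov–Smirnov-like statistic with a permutation null.
* **Atlas construction and validation** — kinase × condition activity
  matrices, expected-regulation benchmarks, regulatory-site concordance.
* **Condition fingerprinting** — iterative-PCA imputation, PCA with
  broken-stick / Kaiser–Guttman component significance, condition
  similarity networks, kinase logic relations, generalist/specialist
  scoring and signaling-network betweenness.
* **Effector discovery** — complex phospho-regulation scoring (two-sample
  KS against the condition background), kinase–complex co-regulation with
  PPV/FDR evaluation, and PWM + MATCH-style motif scoring combined with
  site co-regulation to nominate new substrates.
* **Synthetic compendia** — a generator with known ground truth (sparse
  kinase regulation, substrate-mediated fold-change propagation,
  complex-coordinated shifts, motif-bearing flanks, multi-study
  detection sparsity) so every stage is testable without external data.

## The statistic

For a condition with quantified sites ranked by their log2 fold change
`v_1 ≥ v_2 ≥ … ≥ v_N` and a kinase with substrate set *S*, a running sum is
walked down the ranking:

    step(i) =  +|v_i| / Σ_{j∈S} |v_j|      if site i ∈ S
               −|v_i| / Σ_{j∉S} |v_j|      otherwise

Increments and decrements are proportional to the observed fold change and
normalized within hits and misses, so the path starts and ends at 0 and
stays in [−1, 1]. The enrichment score ES is the maximum deviation from
zero (either sign). Significance is empirical: the null redraws |S| random
pseudo-substrates from the same vector (values fixed) `n_perm` times, and

    p = (1 + #{ |ES_null| ≥ |ES| }) / (n_perm + 1)
    activity = sign( mean_{j∈S} v_j ) × (−log10 p)

A kinase whose substrates are predominantly up-regulated is called
activated (positive activity); |activity| is capped at log10(n_perm + 1).

## Worked example

```python
import numpy as np
from scipy import stats
from phosphatlas import synthetic, preprocess, atlas

# a synthetic compendium with known ground truth:
# 40 kinases x 60 conditions x 4,000 sites in 6 studies
truth, compendium, flanks = synthetic.default_fixture(seed=7)

matrix, report = preprocess.run_preprocess(compendium, min_quant=100)
# 110073 records -> 2017 sites x 60 conditions

result = atlas.build_activity_matrix(
    matrix, truth.revealed_sets, min_hits=5, n_perm=1000, seed=7
)
acts = result.activities
# activity matrix: 40 kinases x 60 conditions, 2400 cells

rhos = [stats.spearmanr(acts[c].dropna(),
                        truth.activity.loc[acts[c].dropna().index, c])[0]
        for c in acts.columns]
print(np.median(rhos))                    # 0.637
print(atlas.call_regulated(acts, 1.75).sum().sum())   # 320 regulated calls
```

The preprocessing collapses 110,073 raw records (including technical
replicates and multiphosphorylated decoy peptides) to a normalized matrix
of 2,017 multi-study sites. KSEA then fills all 2,400 (kinase, condition)
cells with ≥ 5 quantified substrates; the inferred activities rank
kinases within a condition in good agreement with the simulated truth
(median Spearman ρ = 0.637), and 320 cells exceed the |activity| > 1.75
regulation threshold.

The same pipeline is available from the shell:

```
phosphatlas simulate  --seed 7 --out fixture/
phosphatlas normalize --in fixture/compendium.tsv --out matrix.tsv --min-quant 100
phosphatlas ksea      --matrix matrix.tsv --sets fixture/kinase_sets.gmt \
                      --out activities.tsv --nperm 1000 --seed 7
phosphatlas fingerprint --activities activities.tsv --out pca/ --network network.tsv
phosphatlas coregulate  --matrix matrix.tsv --activities activities.tsv \
                        --complexes fixture/complexes.tsv --sets fixture/kinase_sets.gmt \
                        --out assoc.tsv
phosphatlas predict-substrates --kinase P0001 --flanks fixture/flanks.tsv \
                        --activities activities.tsv --matrix matrix.tsv \
                        --sets fixture/kinase_sets.gmt --out predictions.tsv
```

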