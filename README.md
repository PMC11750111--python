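# phosflow

Time-course TMT (phospho)proteomics analysis for separating
pheromone-induced signaling from nitrogen-starvation signaling in fission
yeast mating experiments.

## The problem

When *S. pombe* cells mate they are, by necessity, also starving: sexual
differentiation is triggered by nitrogen removal. A time course of a mating
mixture therefore confounds two signals — the massive starvation response
and the comparatively subtle pheromone-driven program. The experimental
design pairs every mating time point with a starvation-only control
(partners plated separately and mixed only at collection), quantified by
10-plex TMT over 5 time points × 2 conditions × 3 biological replicates
(a 4-replicate single-condition variant covers the cell–cell fusion
course). `phosflow` implements the statistical pipeline that isolates the
mating-specific phosphorylation changes from such data, and a synthetic
data generator with planted ground truth so every stage is testable without
any download.

## The model

For each phosphosite (or protein) the log2 reporter ratios are
median-centered per replicate, filtered to at most one missing biological
replicate, and collapsed to unique quantification vectors. A group-means
linear model (one coefficient per condition × time cell) is fit per feature,
and residual variances are shrunk by empirical Bayes toward a common prior,

    s̃²ᵢ = (d₀·s₀² + dᵢ·s²ᵢ) / (d₀ + dᵢ),

with (d₀, s₀²) estimated by moment-matching of log s² against a scaled F
distribution. Significance of a site over the time course is a joint
moderated F across the stepwise difference-of-differences contrasts

    Diff_45−0 = (Mating.45min − Mating.0min) − (Ctrl.45min − Ctrl.0min), …

which cancel any change occurring with the same slope in the
starvation-only control, with Benjamini–Hochberg control of the FDR across
sites and post-hoc re-expansion of redundant sites. Downstream stages test
whether each significant site merely tracks its parent protein's abundance
(a layer × time interaction regression on per-replicate log2 fold changes),
compute kinase-substrate enrichment by Fisher's exact test over
monophosphorylated sites, and summarize ±5-residue sequence windows as
position frequency matrices. The per-feature model is numerically
equivalent to limma's `lmFit`/`eBayes`/moderated-F route (verified against
Bioconductor limma in the test suite) and re-implemented here in Python.

## Worked example

```python
from phosflow import mating_config, simulate_experiment, run_pipeline

cfg = mating_config(n_sites=2000, seed=7)        # 2 cond x 5 times x 3 reps
proteome, phospho, truth = simulate_experiment(cfg)
results, summary = run_pipeline(phospho, preset="mating")
```

`summary` for this seed prints:

```
n_input 2100, n_after_missing_filter 2068, n_representatives 1971,
n_duplicates 97, d0 99.1, s02 0.0615,
n_significant_collapsed {starvation: 481, mating: 253},
n_significant_expanded  {starvation: 507, mating: 267},
class_counts {ns: 1387, starvation_only: 414,
              mating_specific: 174, both_different: 93}
```

Reading: of 2,100 simulated sites, 2,068 survive the missing-value filter
(≤10 of 30 values missing), 97 redundant duplicates are set aside during
testing and re-added afterwards (253 → 267 significant), and the 267 sites
that change specifically during mating split into 174 that only move in the
mating condition and 93 that also move under starvation but differently.
Per-site output includes the contrast estimates, moderated F, raw and
adjusted p, class label and monotone cluster:

```
            Diff_45-0  F_mating  adj_p_mating           class   cluster
P00122_S23  -0.355116  0.511475      0.954859              ns      <NA>
P00325_S14  -1.046057  4.486435      0.018016  both_different  decrease
```

The same stages are available from the shell:

```sh
phosflow simulate --preset mating --seed 7 --out sim/
phosflow diff sim/phospho.tsv --preset mating --out diff/   # site_stats.tsv + summary.json
phosflow covary --phospho sim/phospho.tsv --protein sim/proteome.tsv \
    --sites sig_sites.tsv --significant-proteins sig_proteins.tsv \
    --correct-against control --out cov/
phosflow screenstats --individual 10 --pairs 5 --zygotes 0
```

(`sig_sites.tsv` / `sig_proteins.tsv` are one-column `feature_id` lists,
e.g. the significant rows of each layer's `site_stats.tsv`.)

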