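# Methods

This note documents the statistical model, the synthetic data generator,
the numerical choices, and the known limitations of `phosflow`.

## Design and data model

One experiment is a wide table of log2 TMT reporter ratios, features ×
samples, with an explicit missing mask. A sample is identified by
(condition, time in minutes, biological replicate); the canonical column
name is `<condition>_<time>min_R<replicate>`. The mating design has
2 conditions (starvation control, mating) × 5 time points at 45-min spacing
× 3 replicates (30 channels, one 10-plex run per replicate); the fusion
design has 1 condition × 5 time points at 11-min spacing × 4 replicates.
Phosphosite rows carry protein, residue (S/T/Y), 1-based position,
multiplicity (number of phosphates on the quantified peptide) and an
11-residue sequence window centered on the phosphoresidue, padded at
termini with `_`.

## Normalization and filtering

**Median centering.** For every feature and every replicate, the median of
that replicate's non-missing values across all time points — both
conditions pooled — is subtracted. This removes per-replicate batch
offsets exactly (the per-feature per-replicate median is zero afterwards,
an idempotent operation) and leaves all within-replicate contrasts
unchanged. Medians over even counts use the midpoint convention; medians
are computed over non-missing values only.

**Missing-value filter.** Features are kept when at most `max_missing`
values are absent; the presets are 10 of 30 (mating) and 5 of 15 (fusion),
i.e. exactly one whole biological replicate. The generator includes a
whole-replicate dropout mechanism because this boundary is where the filter
bites.

**Redundancy.** Sites quantified from the same multiply-phosphorylatable
peptide produce bit-identical rows. Duplicate detection is exact equality
on values *and* missing patterns (not tolerance-based): duplicates arise
from identical source measurements, so exactness is correct and
deterministic. One representative per group — the lexicographically
smallest feature id, an arbitrary but stable choice — is retained for
testing, and every group member receives the representative's statistics
afterwards. This keeps the multiple-testing correction unbiased.

## The moderated model

Per feature, a group-means model (one coefficient per condition × time
cell) is fit by least squares on the available samples; residual
df = n_obs − n_cells_observed. No replicate term is included: replicate
offsets are removed by the centering step, and a per-feature replicate
coefficient would be collinear with it.

Residual variances are pooled by empirical Bayes under the hierarchical
model s² ~ s₀²·F(d, d₀): with z = log s², E[z] and Var[z] have closed forms
in digamma/trigamma functions, inverted by moment matching (Newton
iteration for the trigamma inverse). No variance trend and no
robustification are used. d₀ may be estimated infinite (all shrunken
variances equal s₀²); features with zero residual df take the prior
variance and contribute d₀ degrees of freedom only. The implementation
agrees with Bioconductor limma (`lmFit`/`contrasts.fit`/`eBayes`) to
10⁻¹³ in the moderated F on complete data, and to printed precision in
(d₀, s₀²); this equivalence is enforced by a test.

**Contrasts.** Stepwise consecutive differences within the control
condition measure the starvation program; differences-of-differences
(mating step minus matched control step) cancel everything shared with
starvation and isolate pheromone-specific dynamics; the fusion course uses
plain stepwise differences. Every contrast vector sums to zero over cells.

**Decision rule.** One adjusted p per site: a joint moderated
F = b'C⁻¹b / (k·s̃²) over the k contrasts of a set, where C is built from
the contrast matrix and the feature's per-cell replicate counts, so the
correlation between consecutive differences is accounted for; p comes from
F(k, d₀+d). A feature missing an entire design cell is excluded only from
the contrasts touching that cell (k is reduced), not globally.
Benjamini–Hochberg step-up adjustment is applied across features, with
missing p-values excluded from the number of tests.

**Classification.** Sites significant on the corrected contrasts
(BH ≤ 0.05) are `mating_specific` unless also significant on the control
contrasts (`both_different`); the remainder are `starvation_only` or `ns`.
The fusion preset uses BH ≤ 0.001 — four replicates afford the stricter
threshold. Significant sites are grouped into monotone clusters by the
replicate-averaged (corrected) profile: sign of the net change for k = 2;
for k = 3, a net increase reaching half its total by the second time point
is `early_increase`, otherwise `late_increase`. An exactly zero net change
(measure zero in practice) goes to the increasing cluster and is logged.

**A calibration caveat.** Median centering consumes error degrees of
freedom that the model does not account for (the subtracted median is
estimated from the same data), which makes the moderated F slightly
anticonservative: on all-null simulations the KS distance of p-values from
uniform is ≈ 0.03 after centering versus ≈ 0.01 without. This is a property
of the normalize-then-fit procedure itself, reproduced identically by
limma on the same centered input. Calibration tests therefore run the
statistic on un-centered null data; with planted effects the empirical FDR
of the full pipeline stays well below nominal + 0.02 in our checks.

## Covariation with protein abundance

For each significant site with quantified protein, per-replicate log2 fold
changes against that replicate's t = 0 sample are pooled (no mixed
effects — a plain multiple regression) into

    Δ = b₀ + b₁·layer + b₂·time + b₃·layer×time,

and the two-sided t-test p of the interaction b₃ (the slope difference,
log2/min) is BH-adjusted over the tested sites. Adjusted p ≤ α ⇒ the site
changes `independent`ly of its protein; > α ⇒ `covarying`; a protein
without significant change ⇒ `independent_no_protein_change` with no test;
no protein data ⇒ untestable. For the mating analysis the Δ series are
starvation-corrected (mating Δ minus matched control Δ) before testing;
the starvation analysis restricts both layers to the control samples. The
reported "% independent" counts `independent_no_protein_change` as
independent over all sites with any protein information; the
tested-sites-only variant is also emitted.

A power limitation worth knowing: the linear interaction test cannot
distinguish an uncoupled site/protein pair whose profiles happen to move in
the same direction with similar net slope — at effects of 4× the noise SD
such pairs give |t| < 1. Overall classification accuracy on planted truth
(≈ 0.91 in our simulations) is carried by pairs with opposite or clearly
different dynamics and by the deterministic no-protein-change rule.

## Enrichment, motifs, screen metrics

Kinase-substrate enrichment is a two-sided Fisher exact test (one-sided by
flag) on hit × substrate 2×2 tables; the background universe is all
monophosphorylated sites quantified after filtering, and fold enrichment is
the ratio of substrate proportions among hits versus background. Motif
matrices tabulate per-position residue probabilities over 11-residue
windows; "proline-directed" means P at +1, and terminal padding characters
are excluded from each position's denominator. The microscopy metrics are
mating efficiency 100·2(pairs+zygotes)/(individuals+2(pairs+zygotes)),
fusion efficiency 100·fused/(unfused+fused) — the denominator counts all
mating-engaged pairs; the literal unfused-only variant is available by
flag — and the zygote fraction 100·2·zygotes/(individuals+2(pairs+zygotes)).

## The synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

- **Effect classes** (null / starvation_only / mating_specific /
  both_different), defaults 0.70/0.15/0.10/0.05 of sites; proteins get
  their own classes, defaults 0.68/0.30/0.01/0.01 — most proteome change
  under starvation, very little mating-specific, mirroring the relative
  magnitudes seen in such experiments.
- **Profiles** are monotone and switch-like: flat, then a full-amplitude
  transition across one uniformly chosen inter-sample interval
  (`profile_shape="ramp"` gives onset-to-end ramps instead). Planted net
  changes have fixed magnitude `effect_size_sd` (default 1.0 log2 units,
  4× the default noise SD of 0.25) with random sign; `both_different`
  sites superpose an independent second transition on the mating condition.
- **Nuisance structure**: per-replicate batch offsets (SD 0.30 log2),
  MCAR missingness (5%), whole-replicate dropout (2% of features — the
  filter's boundary case), duplicated redundancy groups (5% of sites,
  bit-identical rows), coupled sites (5%) that are pure trackers of a
  changing protein's profile, planted kinase-substrate sets (odds
  multiplier 6 among mating-specific monophosphorylated sites), and
  sequence windows from smoothed yeast-like background frequencies with an
  optional planted motif residue.
- One global seed drives hierarchical `SeedSequence` sub-streams so
  profiles, noise, missingness, redundancy, kinase sets and windows are
  independently reproducible.

What it does **not** emulate: peptide/spectral structure (no reporter-ion
interference, no co-isolation), intensity-dependent missingness (MCAR
only), per-feature variance heterogeneity (noise is homoscedastic, which
makes the empirical-Bayes prior df estimate large), and correlated sites
within a protein beyond explicit coupling. Passing recovery tests
therefore show the pipeline's statistics behave as designed under the
assumed noise model, not that they are robust to every artifact of real
TMT data.

### Recovery at the design's power limit

At the study conditions (10,000 sites, 3 replicates, effects 4× noise),
recall of planted mating-specific sites is ≈ 0.85–0.88, not higher: a
noncentrality analysis of the corrected-contrast F shows uniform-onset
monotone effects yield noncentrality 19.2 (boundary-interval transitions)
to 28.8 (interior), i.e. per-site power ≈ 0.84–0.94 at the BH-adaptive
threshold — the average cannot reach 0.95+ without concentrating
transitions in interior intervals or raising the effect size. The
empirical FDR of the same runs is ≈ 0.03–0.05. Problem sizes in the test
suite (800–10,000 sites) were chosen so the full suite runs in about a
minute.

## Interfaces

The library is the primary interface; a thin `phosflow` command-line tool
(simulate / normalize / filter / diff / covary / enrich / motif /
screenstats) wraps it for shell use. Tables are wide TSV (UTF-8, `NA` for
missing); the supplementary-workbook dialect reads per-replicate columns by
header pattern and ignores the average columns; substrate sets are
two-column TSV; position frequency matrices are written as 11 × alphabet
TSV. Logo rendering is intentionally out of scope — the frequency matrix
is the analysis result; drawing it is presentation.
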