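# Methods

This note records the statistical models behind `ovage`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Design and expression scale

The target design is two inbred strains (labelled `Ral_321`, `Ral_237`)
× two age groups (`young`, `old`) with 3–4 biological replicates per
strain×age cell; replicate counts may differ between strains (the default
is 4 for `Ral_321`, 3 for `Ral_237`). All expression work is done in RPKM
(reads per kilobase of transcript per million mapped reads), with the
per-million denominator taken over **all** features in the matrix,
including TE families and mitochondrial transcripts.

Age contrasts are summarised per strain as

    log2( (mean_old RPKM + c) / (mean_young RPKM + c) ),   c = 0.5,

with replicates averaged on the RPKM scale before forming the ratio —
per-replicate ratios are not well defined when replicate counts are
unbalanced (4 vs 3). The pseudocount `c` keeps the ratio finite at zero
expression and is configurable; `c = 0` is rejected whenever a zero mean
is present. Ratios within 1e-9 of zero are labelled `flat` (an exact-tie
guard; with continuous RPKM values ties essentially only arise from
all-zero features).

An offset-free linear fold (mean_old/mean_young, NaN when the young mean
is zero) is reported alongside the pseudocounted fold because published
fold-change tables are conventionally offset-free; the TE family table
presents folds as magnitudes ≥ 1 with a separate direction column.

## Differential expression

Counts for feature *i* in sample *j* are modelled as negative binomial
with Var = μ + αμ² and

    log μ_ij = log s_j + β0 + β_strain + β_age (+ β_strain:age),

where `s_j` are median-of-ratios size factors computed over features with
all-positive counts (geometric mean normalised to 1). The age effect
"controlling for strain" is the Wald test on β_age in the reduced
(no-interaction) model; the strain-by-age effect is the Wald test on the
interaction coefficient in the full model. Per-strain age effects are
read off the full model (β_age and β_age + β_int). p-values use the
normal reference for the Wald z; multiple testing is Benjamini–Hochberg
with NAs (non-converged fits) passed through and excluded from the test
count. Features with zero counts in every sample are dropped.

Dispersion α_i is estimated by method of moments on size-factor
normalised counts — the replicate variance pooled within strain×age cells,
α̂ = (pooled var − mean)/mean² — then pulled toward a parametric trend
α(μ) = a₀ + a₁/μ (least squares on features with mean > 1, coefficients
clamped at 0) by a weighted midpoint, weight 0.5 on the trend by default,
with a floor of 1e-8. Degenerate features (constant counts) sit at the
floor. This is a deliberately transparent pipeline: no empirical-Bayes
shrinkage priors, no outlier replacement, and no attempt to reproduce any
specific tool's internals. Tests verify the choices by calibration: the
null false-discovery fraction at FDR 0.05 stays below 0.07, injected
1.0-log₂ effects are recovered with |bias| < 0.1 at 4 replicates, and in
the α → 0 limit the Wald statistic matches a Poisson GLM.

Wald rather than likelihood-ratio testing keeps a single fit per model
and exposes interpretable standard errors; with 14 samples and 3–4
parameters the two are close except for very low counts, where both are
approximate anyway.

## Expression-matched permutation test

The focal-set statistic is the per-strain mean over set members of the
log₂ age ratio (a linear-scale variant is available; the log scale
symmetrises up- and down-shifts). Each focal gene is matched to the
`k_up + k_down` genes nearest in **overall mean expression** — mean RPKM
over all samples, both strains and both ages pooled, so the age contrast
itself never informs the null — excluding focal-set members; ranking ties
break by feature id for determinism. At rank extremes the deficit on one
side is filled from the other, so every focal gene always has exactly
`k_up + k_down` matches (defaults 10 + 10). Null sets draw one match per
focal gene independently and with replacement across replicates; within a
replicate a gene may serve several focal genes (a no-reuse mode exists but
changes the null only marginally at genome scale and is not the default).

Two exceedance rules are implemented:

- `combine="mean"` (default): a null replicate counts when its
  cross-strain average set mean ≥ the observed cross-strain average. The
  permutation p of this scalar statistic is uniform under the null, which
  the test suite checks by simulation (KS over 200 null datasets).
- `combine="all_strains"`: the replicate must reach the observed mean in
  every strain simultaneously. This joint quadrant probability is the
  stricter reading of "greater in both strains", and it is the right
  summary when concordance across genetic backgrounds is itself the
  claim; but it is **not** a calibrated p-value — for two strains with
  independent noise it is distributed like the product of two uniforms
  (P(p ≤ 0.05) ≈ 0.2 under the null). The pipeline therefore reports it
  alongside the calibrated p rather than in its place.

p-values use the add-one estimator (s+1)/(n+1), which can never be zero
and is a valid p-value for any n_perm; the raw proportion s/n is reported
too. The default n_perm is 10,000 and a seed is mandatory.

## Positional enrichment

Heterochromatin domains arrive as BED intervals (0-based half-open;
GFF3 input is converted from 1-based inclusive on read). A gene is
heterochromatic when its gene body overlaps any domain by at least 1 bp;
an optional promoter window extends genes upstream (strand-aware) but the
gene-body rule is the default. The DE × compartment 2×2 table is tested
with the Yates-corrected chi-squared,

    χ² = Σ max(|O − E| − 0.5, 0)² / E,  df = 1,

the correction truncated at zero so perfectly proportional tables give
χ² = 0. Tables with an empty margin (e.g. no significant genes) are
constructed but the test is refused. The dot-chromosome analysis is the
same machinery with flags = (chromosome == dot label).

One published heterochromatin table prints a χ² (4.494) that cannot be
derived from its own printed counts, which yield χ² = 3.879 and the
two-tailed p = 0.0489 printed beside it; the p-value is treated as the
authoritative number and the statistic as a transcription error.

The global-derepression check is a Welch (unequal-variance) two-sample
t-test on log₂ age ratios, heterochromatic vs other genes, per strain —
Welch because the two groups differ greatly in size and have no reason to
share a variance.

## TE-family statistics

TE expression is quantified per family from a family-level count matrix;
deriving such a matrix from reads (mapping against a repeat-masked genome
plus consensus library) is upstream of this package. The global
derepression test is a paired t across families within a strain, young vs
old, on log₂(mean RPKM + 0.5) — the log stabilises the heavy-tailed
family expression distribution (a linear-scale mode exists). An all-ties
input returns (t = 0, p = 1) by convention. Family-level DE delegates to
the gene machinery verbatim — a test asserts the p-values are identical to
a direct run on the relabelled matrix — and the cross-strain correlation
of family age ratios reuses the genic Pearson code.

## Stage verification

Samples are correlated (Pearson, on log₂(RPKM + 0.5)) against reference
expression profiles of a marker-gene panel across late oogenic stages
(9–10a, 10b, 12, 14). The assigned stage is the argmax correlation, ties
break by column order with a warning, and assignments with max |r| < 0.3
are flagged low-confidence.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
sequence content. Counts are NB draws with

    μ_ij = L_j · p_i · 2^(strain_offset_i·[j in strain 2] + age_effect_i[strain_j]·[j old]),

where library sizes L_j are log-normal (default mean 15 million reads,
CV 0.2 — free parameters; the source design reports no depths), relative
abundances p_i combine a log-normal expression level (log₂ mean 2, sd 2)
with a log-normal gene length (median ≈ 1.6 kb, floor 0.2 kb), and a
single genome-wide dispersion α = 0.05 — a typical bulk-RNA-seq value for
inbred-line biological replicates — applies to every feature (per-feature
dispersion variation is not simulated; the DE stage estimates dispersion
from the data regardless). Per-gene strain offsets (sd 0.25 log₂) create
baseline strain differences.

Default annotation marginals follow the published totals: 14,289 genic
features of which 1,695 overlap emitted heterochromatin blocks (one
pericentric block per arm, ~12% of its length, plus eight dispersed
intercalary blocks of 150–400 kb) and 84 sit on the dot chromosome;
15 mitochondrial transcripts live on a separate contig, and 125 TE
families (real family names for the first forty) are quantified as
consensus-length features. Default injected effects define the study
conditions: the 31-gene piRNA set +0.4 log₂ in both strains; the
mitochondrial set −0.6/−0.3 (stronger in `Ral_321`); a 40-gene
electron-transport-chain set −0.3 in both; the 49-gene eggshell panel
−0.8/−0.25 (strongly strain-asymmetric). Genes in no set have age effect
exactly 0, and `null_gene_sets()` zeroes every set effect for
calibration studies. Stage profiles make the stage-14 column the true
expression of the eggshell panel (plus small noise) and the earlier
stages permuted decoys.

What this does **not** emulate — and therefore what passing tests cannot
show about real data: per-gene effect-size heterogeneity within sets
(every member gets the identical shift, so set tests are better powered
here than on real data), correlated expression between genes, batch
structure beyond library-size variation, length biases, multi-mapping
ambiguity between TE copies, and any sequence-level artefact. Calibration
conclusions (null uniformity, FDR control, unbiased effect recovery)
transfer; absolute power numbers do not.

One consequence of RPKM worth noting: because the per-million denominator
is shared, strongly down-shifted sets (eggshell, mitochondria) push the
apparent expression of everything else up slightly in old samples. This
composition effect is a property of the unit, present in any
RPKM-based analysis; the calibration suite therefore uses fully-null
configurations where it vanishes.

## Problem sizes and runtimes

The test suite runs the permutation-calibration study on 200 null
datasets of 2,000 genes at n_perm = 2,000, the DE calibration on 2,000
genes at 4 replicates per cell, and the enumeration cross-check on every
instance up to 4 focal genes × 3 matches against n_perm = 10,000; the
acceptance script's pipeline run uses the full 14,289-gene marginals with
n_perm = 10,000. These sizes were chosen so each study completes in
seconds to a couple of minutes on a single core while leaving Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- The Wald normal reference is approximate at very low counts; features
  failing to converge are reported as NA rather than rescued.
- The dispersion trend is a two-parameter least-squares fit, not a robust
  regression; extreme outlier features can tilt it (the midpoint
  shrinkage bounds the damage).
- The permutation null conditions on the realised match table; genes
  whose expression rank sits at the extremes borrow matches from one
  side, slightly narrowing their null variance.
- `verify_stage` assumes stage profiles on the same log scale as the
  sample vector; no cross-platform normalisation is attempted.
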