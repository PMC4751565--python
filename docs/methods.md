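# Methods

This note records the statistical model behind `altqtl`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Two-stage analysis

The pipeline is a classical two-stage ("stage-wise") analysis. Stage 1
fits each experiment's design model and reduces the data to genotype means
(BLUEs); stage 2 maps QTL on those means. The stages are deliberately
decoupled: the scan never sees plot-level data, only the line × trait BLUE
table and, optionally, per-trait error floors σ²_e/r that quantify how
much of the line-mean variance is stage-1 noise.

### Hydroponics

Per plant, control and Al root growth rates over five days are
crgr = fl_c − il_c and Alrgr = fl_Al − il_Al; the tolerance index is
RNRG = 100·Alrgr/crgr. Plants with crgr ≤ 0 carry no usable signal and are
excluded (counted in the log). Plant values are averaged within each
(line, block) cell and the cell mean is log₁₀-transformed; cell means at
or below a floor of 1 percent are clamped to the floor first, since a
non-positive ratio has no logarithm and 1% is below any biologically
meaningful tolerance level. Order of operations (average, then transform)
matches the design model, which acts on block-level responses; the
alternative (transform per plant) differs only when plant-level outliers
are present and can be obtained by transforming upstream.

The cell means follow the randomised-complete-block model
`response = block + genotype + error` (block fixed). With genotype random
(REML via statsmodels MixedLM) the components give line-mean heritability
h² = σ²_g/(σ²_g + σ²_e/r), r = 2 blocks; with genotype fixed, sum-coded
block effects make the genotype coefficients the BLUEs.

### Field trials

Each environment (control vs. high Al saturation) is an incomplete block
design: 3 replicates × 10 incomplete blocks × 10 plots, with every RIL
once per replicate plus the A parent once and the tolerant B parent nine
times (the repeated check sharpens the block-variance estimate). The
model is `yield = replicate + block(replicate) + genotype + error` with
replicate fixed and block random. The two environments are fitted
separately because Al stress changes every variance component; the
cross-environment genotypic correlation is reported descriptively from
the two BLUE vectors with an explicit attenuation caveat (it is biased
toward zero by roughly √(h²₁h²₂)) — only the per-environment BLUEs feed
stage 2, so a joint bivariate REML fit would buy nothing downstream.
Variance estimates on the boundary (σ̂² = 0) are accepted and logged, not
treated as errors.

## Genome scan

### Genotype scores

Genotypes are coded 0 (A parent) / 1 (B parent), so an estimated QTL
effect is the full difference between homozygote classes. Map distances
use the Haldane function with the Haldane–Waddington selfed-RIL expansion

    r(d) = (1 − e^(−2d/100))/2,   R = 2r/(1+2r),

monotone with limit 1/2. At any grid position the QTL regressor is
x = P(B | nearest informative flanking markers), computed from the
two-state chain with transition probability R between loci; one missing
side conditions on the informative side alone, a fully missing chromosome
gives x = 0.5. A full-chromosome HMM was considered and rejected: F7:8
RILs are near-fully informative, so nearest-flank conditioning is
standard interval-mapping practice and keeps the scan linear-algebraic.
Residual heterozygosity is ignored (heterozygous calls become missing,
with a logged count). The scan grid contains every marker position plus
fill-in points so gaps never exceed the step (default 2 cM).

### The multi-trait Wald test

At each position the three traits are modelled jointly with an
unstructured residual covariance Σ. With one observation per line per
trait, the polygenic background and the stage-1 error are jointly
unidentifiable, so Σ absorbs both; the optional error floors separate
them again only where it matters (%GV denominators). Because every trait
shares the same regressors, per-trait least squares is fully efficient;
Σ̂ is the residual cross-product matrix on n − p degrees of freedom, and

    W = α̂ᵀ (Σ̂ · (XᵀX)⁻¹_xx)⁻¹ α̂ .

W is exactly Hotelling's T², so tail probabilities use the exact
transform W·(ν−k+1)/(νk) ~ F(k, ν−k+1) by default (`pvalue_method="f"`).
The asymptotic χ²(k) reference is available but is anticonservative by
roughly 3× in the far tail at n = 90, which a 200 000-draw calibration
check of the implementation confirms the F transform does not share. For
a single trait the statistic and p-value coincide with the squared t of
ordinary regression, which the tests assert to 1e-8 against a closed-form
oracle.

### Threshold, protocol, %GV

The genome-wide threshold follows the effective-number-of-tests idea:
per chromosome, eigenvalues λ of the marker correlation matrix contribute
f(λ) = 1{λ≥1} + (λ−⌊λ⌋); M_eff is the sum over chromosomes and the
comparisonwise cutoff is 1 − (1−α)^(1/M_eff). M_eff uses markers, not
grid points — interpolated positions carry no independent information.
Eigenvalues are rounded to 8 decimals before the floor, otherwise
duplicated markers yield λ = 2 − 1e-15 and f ≈ 2 instead of 1.

The mapping protocol: SIM scan → candidate peaks (per-chromosome local
maxima above threshold, accepted greedily by significance subject to a
30 cM separation, ties broken toward the lower cM) → CIM rounds with the
candidates as cofactors, excluding any cofactor within a 30 cM window of
the tested position on the same chromosome, iterated until the candidate
set stabilises (max 5 rounds, then a warning) → backward elimination of
the joint model at the comparisonwise cutoff → joint-model effects, SEs
and per-trait high-value parent. Scan step (2 cM), separation and window
(30 cM) and the round cap follow common CIM practice and are exposed as
estimator parameters. Positions whose score is collinear with the active
cofactors (multiple correlation > 0.999) are skipped with a log entry.

%GV for QTL q and trait t is 100·(V_base,t − V_+q,t)/G_base,t, where V is
the residual (polygenic + error) variance, G_base = V_base − floor is the
base genetic variance, and the per-trait "Total" adds all retained QTL
jointly. Negative drops are floored at 0 and the ratio capped at 100.

## The synthetic-data generator

The generator emulates the full study design: 90 RILs, 344 markers on 10
chromosomes (evenly spaced, deterministic; the two QTL positions 184.2 cM
on chromosome 3 and 214.0 cM on chromosome 9 are snapped onto markers so
the scan grid can hit them exactly), RIL genotypes as two-state chains
with the same R(d) the scan assumes, and three trait means
(1.50 log₁₀ %, 3.35 and 2.35 t ha⁻¹).

Trait calibration is solved, not guessed. With 0/1 coding a QTL of effect
β contributes β²/4 to the line variance. The default effects
(0.71, 0.19, 0.61) at the chromosome-3 locus and (0.34, −0.66, −0.36) at
chromosome 9 (B-allele signs) together with target genetic-variance
shares of roughly (50%, 3.5%, 38%) and (11%, 44%, 13%) pin down the
polygenic variances: 0.097, 0.140, 0.121 — satisfyingly, the implied
total genetic variance is larger under control than Al, the direction
field stress is expected to take. Polygenic correlations default to
(0.1, 0.3, 0.5) for (RNRG·control, RNRG·Al, control·Al): yield under the
two regimes shares most background, tolerance shares more with yield
under Al than without. Error variances (hydro σ²_e = 0.056 on the log
scale; field plot σ²_e = 0.20/0.22, block σ²_b = 0.05) put line-mean
heritabilities near 0.90/0.80/0.77 — inside the 0.7–0.9 band such trials
report, highest for the controlled hydroponic assay.

The hybrid split-plot trial (2 females × 4 males, Al on whole plots, four
per treatment) is calibrated on its printed summary: marginal means 3.46
and 3.96 t ha⁻¹ for the females, 4.18 and 3.24 for the environments, i.e.
0.5 t ha⁻¹ per tolerance allele under the dosage coding H1=0,
H2/3/5/7=1, H4/6/8=2, additive by default with an optional dominance
deviation. Error variances are back-solved from the two LSDs: an LSD of
0.45 in the subplot stratum (df 42, 32 plots per mean) gives
MS_sub ≈ 0.796, an LSD of 0.90 in the whole-plot stratum (df 6) gives
MS_wp ≈ 2.165 and hence σ²_wp ≈ 0.171.

One global seed fans out to per-component child seeds (SeedSequence spawn
keys), so identical seeds give byte-identical files and any stage can be
regenerated in isolation.

What the generator does **not** emulate: segregation distortion, residual
heterozygosity, genotyping error, spatial field trend, QTL×environment
interaction beyond the environment-as-trait device, and epistasis.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to these real-data
features.

## Problem sizes used in the checks

The replicated operating-characteristic studies use 200 replicates of the
full 90 × 344 × 3 configuration for type-I error and for two-QTL
recovery, 40 replicate hybrid trials for the split-plot calibration
averages, and smaller replicate counts (6–60) for variance-component and
covariance recovery checks, chosen so Monte-Carlo standard errors are a
few times smaller than the tolerances being asserted.

## Known limitations

- **Genome-wide error control is approximate.** The per-test p-values are
  exact (verified by simulation), but the eigenvalue-based M_eff (~150
  for the default map, equal to its map-implied population value, so this
  is not estimation noise) undercounts the equivalent number of
  independent tests (~260) for a dense RIL map. The realised genome-wide
  rate under the null is about 0.07–0.10 instead of 0.05. This is a
  documented property of this family of corrections; a permutation
  threshold would fix it but is deliberately out of scope because the
  protocol being implemented uses the eigenvalue correction.
- Reported QTL positions and effects at data-selected peaks carry mild
  winner's-curse inflation for small effects; the recovery study bounds
  it within Monte-Carlo error for the default configuration.
- The between-environment genotypic correlation is the attenuated BLUE
  correlation, not a joint-REML estimate.
- Stage-2 standard errors ignore stage-1 uncertainty beyond the error
  floors; with h² ≥ 0.7 this is second-order.
- The split-plot ANOVA requires an exactly balanced layout and refuses
  unbalanced data rather than approximating.
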