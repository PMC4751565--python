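# altqtl

Multi-trait mixed-model QTL mapping for aluminium-tolerance trials in a
biparental sorghum RIL population — from raw plot- and plant-level
measurements to a final QTL model with allele-substitution effects and the
percentage of genetic variance each locus explains.

Aluminium toxicity on acidic soils inhibits root growth and depresses grain
yield. The classic experimental design for dissecting tolerance combines a
hydroponic root-growth assay (fast, controlled Al³⁺ dose) with paired field
trials on limed (control) and high-Al-saturation soil. `altqtl` implements
the complete two-stage statistical path for such studies and is aimed at
quantitative geneticists and breeders who want a scriptable, testable
re-implementation of the protocol rather than a black-box package.

## What it computes

**Stage 1 — phenotypes.** Relative net root growth per plant,

    RNRG = 100 · (fl_Al − il_Al) / (fl_c − il_c),

averaged per (line, block) and log₁₀-transformed, is analysed under the
randomised-complete-block model `response = block + genotype + error`.
Field yield uses, per environment, the incomplete-block mixed model
`response = replicate + block(replicate) + genotype + error` with block
random. With genotype random, REML components give the line-mean
heritability h² = σ²_g / (σ²_g + σ²_e/r); with genotype fixed the fit
yields genotype BLUEs for stage 2.

**Stage 2 — the multi-trait genome scan.** The three line-mean responses
(RNRG, yield control, yield Al) are analysed jointly on a cM grid:

    y_t = μ_t + Σ_c γ_ct·x_c + α_t·x + ε_t ,   ε ~ N(0, Σ) unstructured,

where x is the conditional P(B-parent genotype) at the tested position
(two-state chain on the Haldane selfed-RIL recombination fraction
R = 2r/(1+2r)), x_c are cofactor scores, and α_t are trait-specific
allele-substitution effects (B-class minus A-class). Presence of a QTL is
tested by the multi-trait Wald statistic W = α̂ᵀV̂(α̂)⁻¹α̂ (df = number of
traits; exact Hotelling T²→F tail by default). The genome-wide threshold
converts α = 0.05 into a comparisonwise cutoff via the effective number of
tests M_eff (eigenvalue decomposition of per-chromosome marker correlation
matrices). The protocol is simple interval mapping → composite interval
mapping with the candidate peaks as cofactors (iterated) → backward
elimination → joint effects, SEs, high-value parent, and %GV from the drop
in polygenic variance when each QTL enters the base model.

**Hybrid trial.** The 2 female × 4 male factorial of isogenic hybrids is
analysed as a split-plot ANOVA (Al treatment on whole plots, hybrids on
subplots, correct error strata and LSDs), plus an allele-dosage covariate
model that tests additivity of the tolerance locus.

**Synthetic data.** `altqtl.simulate` generates every input the pipeline
consumes — map (344 markers, 10 chromosomes), 90 RIL genotypes, trait
values with two pleiotropic QTL and a correlated polygenic background,
plot-level field/hydroponic/hybrid records — deterministically from one
seed, so the whole pipeline is testable end to end.

## Worked example

```
altqtl simulate --seed 1 --out sim
altqtl stage1 --hydro sim/hydroponics.csv --field sim/field.csv --out stage1
altqtl scan --traits stage1/traits.csv --map sim/map.csv \
            --geno sim/genotypes.csv --varcomp stage1/varcomp.csv --out scan
altqtl hybrid-anova --plots sim/hybrids.csv --out hyb
```

prints (abridged):

```
RNRG_log10: h2 = 0.882
Gy_control: h2 = 0.799
Gy_Al: h2 = 0.681
M_eff = 148.0, -log10(p) threshold = 3.46; 3 QTL retained
  q3@184.2 RNRG_log10: effect +0.617 (SE 0.082), high-value SC283
  q3@184.2 Gy_Al:      effect +0.566 (SE 0.092), high-value SC283
  q9@214   RNRG_log10: effect +0.372 (SE 0.081), high-value SC283
  q9@214   Gy_control: effect -0.667 (SE 0.099), high-value BR007
```

Reading this: stage-1 heritabilities sit in the 0.7–0.9 range typical of
well-replicated trials. The scan retains the two simulated pleiotropic QTL
at their true positions — chromosome 3 at 184.2 cM (tolerant-parent SC283
allele raises both root growth under Al and grain yield on toxic soil) and
chromosome 9 at 214.0 cM (SC283 allele raises RNRG while the BR007 allele
raises yield) — plus, at this seed, one extra peak just above the
genome-wide 5% threshold, the expected cost of scanning at α = 0.05.
Effects are full homozygote-class differences in trait units
(log₁₀ percent for RNRG, ton ha⁻¹ for yield). `scan/percent_gv.csv` holds
the per-QTL and joint %GV table, `scan/scan_profile.csv` the plottable
−log₁₀(p) profile with its threshold. The library API mirrors the CLI:
`MultiTraitQTLScan(...).fit(genotypes, traits, genetic_map=...)` exposes
`scan_`, `threshold_`, `qtl_` and `percent_gv_`, and composes with
scikit-learn's `get_params`/`set_params`.

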