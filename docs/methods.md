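# Methods

## Setting and assumptions

The package estimates the causal effect θ of an exposure (birth weight, in
SD units after rank-based inverse-normal transformation) on binary
psychiatric outcomes (log-odds or comparable scale) from two independent
GWAS summary-statistics tables. Each instrument must satisfy the core MR
assumptions: association with the exposure (relevance), no association with
confounders (independence), and no path to the outcome other than through
the exposure (exclusion restriction). The estimators additionally assume
linearity and, method by method: IVW assumes no (or balanced) pleiotropy;
MR-Egger replaces exclusion restriction with InSIDE (pleiotropic effects
independent of instrument strength); the weighted median assumes >50% valid
weight; the weighted mode assumes the largest cluster of ratio estimates is
valid.

## Instrument selection

Instruments are exposure SNPs with p < 5×10⁻⁸ (genome-wide significance),
a fetal-effect flag (consumed as an input column — the trio-based
fetal/maternal decomposition is upstream of this package), and at least one
trophoblast-specific gene within 150 kb. Gene proximity uses edge distance:
0 inside the gene body, else distance to the nearest gene boundary (this is
what makes distance-0 entries in the packaged table meaningful); "within
150 kb" and "the 300 kb window centered on the SNP" are treated as the same
criterion with strict inequality at the boundary.

Cell-type specificity of a gene, from a genes × cell-types mean-expression
matrix, uses a fivefold rule with a minimum expression of 1 (both
configurable), in three positive tiers, most stringent first:
`cell_specific` (one cell ≥ 5× every other cell), `group_specific` (a group
of 2–4 cells, scanned as expression-descending prefixes, each ≥ threshold
and jointly ≥ 5× every cell outside the group), and `cell_enhanced` (one
cell ≥ 5× the mean of the others). The group-size cap of 4 is a package
choice; the categories mirror the common cell-enrichment tooling, which
does not publish an exact group definition. Enrichment of specific genes in
a query set uses the exact hypergeometric upper tail, with
Benjamini–Hochberg adjustment across the cell types tested (the adjustment
procedure is a package choice; only "adjusted P" is conventional).

An alternative selection replaces the specificity condition with membership
of a nearby gene in a user-supplied gene list (e.g. a Gene Ontology term for
embryonic placenta development); that route requires significance and
proximity only, not the fetal flag.

Chromatin annotation takes BED-convention intervals (0-based, half-open)
with a state label; states beginning with TssA/TssFlnk/Tx/Enh count as
active by default.

## Instrument strength

Per SNP, R² = 2β²·MAF(1−MAF) — symmetric in MAF vs 1−MAF, so the
effect-allele frequency can be used directly — and F = R²(N−2)/(1−R²).
For an instrument set, the overall F is (R²/k)(N−k−1)/(1−R²) with R² the
sum of per-SNP values and k the set size; the mean F is the arithmetic mean
of per-SNP F values. F ≫ 10 indicates negligible weak-instrument bias.

Two caveats about the packaged instrument table. First, its EAF column is a
European reference-panel frequency, while the R² column was evidently
computed from the source study's own (unprinted) frequencies: recomputing
2β²·EAF(1−EAF) from the printed columns reproduces the printed R² within
printed rounding for only 7 of 18 rows (for the rarest variant the
discrepancy is large). Strength summaries computed from the packaged table
therefore use the packaged R²/F columns, not recomputed ones. Second, the
published overall F for the 14-instrument depression set (78.21) is not
reproducible from the packaged per-SNP values under either overall-F
convention (the computation gives ≈78.8); the 15-instrument (81.78) and
ADHD (84.18) overall values do reproduce. The depression overall F is
accordingly not asserted anywhere.

## Harmonization, proxies and clumping

Outcome records are aligned to the exposure's effect allele: matching
alleles are kept; swapped order negates the outcome effect and complements
its frequency; a match after strand complementation (A↔T, C↔G) is accepted
and re-checked for order. Palindromic SNPs (A/T, C/G) carry no strand
information: they are dropped when min(EAF, 1−EAF) > 0.4 on *either* side
(the cut side is not conventionally fixed; both is the conservative
choice), and otherwise oriented by frequency concordance — if the two
studies' effect-allele frequencies sit on opposite sides of 0.5 after
nominal alignment, the outcome effect is negated. Palindromic SNPs at or
below the 0.4 cut are aligned rather than dropped, matching common
harmonization defaults. Multi-character (indel) alleles are never treated
as palindromic.

Instruments missing from an outcome GWAS may be replaced by the candidate
with maximal LD r² strictly above 0.8 within ±150 kb; ties break by smaller
outcome p, then lexical id. Proxy orientation uses the LD table's phase
column when present, else frequency concordance. LD comes from a local
long-format table; missing pairs are treated as r² = 0 with a logged
warning (local tables are sparse by construction).

Clumping is greedy by exposure significance: SNPs sorted by ascending p
(ties by id) are accepted iff r² ≤ 0.001 with every already-accepted SNP.
It is window-free because the analysis operates on ≤18 instruments under a
global rule; on small panels the greedy result equals exhaustive search
over all admissible subsets (tested). Clumping is deterministic and
invariant to input row order.

## Estimators: conventions and numerical choices

- **IVW** weights are 1/σ²_Γ (second-order weights are not used). The
  random-effects form is multiplicative overdispersion with the scale
  floored at 1, so the fixed-effect result is recovered under homogeneity.
  The floor makes the test slightly conservative under the null
  (at k = 14 the exact level of the nominal 5% test is ≈ 0.040 by
  numerical integration); the fixed-effect variant is exactly calibrated,
  and the calibration test in the suite checks precisely that, plus the
  conservatism direction for the random-effects variant. p-values are
  normal; confidence intervals are Wald-type θ̂ ± 1.96·SE everywhere.
- **Wald-ratio SE** uses the first-order delta method, ignoring σ_γ;
  with F ≳ 50 the second-order correction is < 2% and is omitted.
- **MR-Egger** orients instruments to γ̂ ≥ 0 before the regression (the
  intercept is not identified under arbitrary allele orientation); the fit
  is weighted least squares (statsmodels WLS), SEs carry the same
  multiplicative floor as IVW, and p-values use t(k−2), the convention of
  the reference implementations. Q′ ≤ Q always holds because the
  free-intercept model nests the IVW regression under identical weights.
- **Weighted median**: ratios are ordered with weights wⱼ = (γ̂ⱼ/σ_Γⱼ)²
  (the inverse ratio variance under the delta method); the standardized
  cumulative weight sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw is interpolated linearly at
  0.5. The SE is a parametric bootstrap (both effect vectors resampled at
  their SEs, weights held fixed, SD of re-estimates), with an explicit
  seed.
- **Weighted mode**: base bandwidth h₀ = 0.9·min(sd, IQR/1.349)·k^(−1/5)
  on the ratios, scaled by φ (default 1; the analysis also reports φ = 2
  and 2.5, where clusters merge and the mode migrates toward the weighted
  mean). The density argmax is found on a 2048-point grid with bounded
  local refinement between the bracketing grid cells; this equals a
  brute-force fine-grid scan to grid tolerance (tested). Degenerate inputs
  (zero spread) fall back to the exact weighted mode with a warning.
- **MR-PRESSO**: observed statistic RSS = Σⱼ wⱼ(Γ̂ⱼ − θ̂₍₋ⱼ₎γ̂ⱼ)² with
  leave-one-out IVW point estimates; the null resamples
  Γ*ⱼ ~ N(θ̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ) and recomputes the statistic (leave-one-out
  estimates recomputed per replicate, vectorized). Global p is the fraction
  of resampled RSS ≥ observed; per-SNP p-values use the (count+1)/(n+1)
  estimator on each SNP's own resampled residual distribution, Bonferroni
  corrected over k, flagged below 0.05 by default. The distortion test is
  not implemented (only global/outlier results are consumed downstream).
- **Sample overlap**: expected relative bias of IVW toward the confounded
  association is approximated first-order as ρ/F̄ for overlap fraction ρ;
  < 1% is labelled negligible. The cited method's exact constant is not
  published as a formula; this is the standard first-order bound.
- **Reverse MR** selects genome-wide-significant disorder SNPs, clumps
  them, harmonizes against the exposure table and applies IVW (Wald ratio
  at exactly one instrument; a `not_testable` result at zero).
- **Bonferroni** is strict: p < α/m.

The model surface (`MRModel`/`MRResults`) wraps these functions
statsmodels-style; estimates, heterogeneity and the Egger intercept travel
with the results object and `summary()` prints them.

## Pipeline

`run_forward` harmonizes each outcome (with proxy substitution and
clumping), fits the random-effects IVW, applies Bonferroni across outcomes,
and runs the sensitivity battery (leave-one-out, Egger, PRESSO, weighted
median, weighted mode at φ ∈ {1, 2, 2.5}, overlap bias) for significant
outcomes — or everywhere with `force_sensitivity`. Every instrument dropped
between stages appears exactly once in the attrition log with a reason.
The pipeline is a pure function of (inputs, thresholds, seed); reruns are
byte-identical. For forest-plot scaling, the effective sample size of a
case-control GWAS is 4/(1/cases + 1/controls), the standard convention
(the source figures do not define theirs).

## Synthetic-data generator

The generator emulates the two-sample summary regime directly at the
summary level: true γⱼ scaled so per-SNP R² falls in 1×10⁻⁴–4×10⁻⁴ (the
range of the packaged instrument table), EAF ~ U(0.05, 0.5), SEs
1/√(2p(1−p)n), estimation noise Gaussian, sample overlap as a correlation
ρ between the exposure- and outcome-side errors (individual-level
genotypes are never simulated). Pleiotropy models: none, balanced
(zero-mean), directional (nonzero mean, planted relative to the
exposure-increasing allele — allele orientation is arbitrary, so a mean
pleiotropic effect is only well defined, and Egger-detectable, on that
oriented scale), and a single outlier of given magnitude in units of that
SNP's outcome SE. Allele bookkeeping hazards (palindromic variants,
swapped allele order, strand-complemented records) are planted in the
outcome table at configurable rates, and the ground truth of everything
planted is always emitted; tests never re-infer it.

Defaults encode the study conditions: k = 14 instruments, exposure
N = 423,683, and outcome sample size 100,000 — chosen so the default
scenario's IVW precision matches the precision of the depression analysis
(SE ≈ 0.06, CI half-width ≈ 0.12). Scenarios for high-power checks (e.g.
the eight-outcome flagging test) pass a larger outcome N explicitly.
`scenario_from_packaged_profile` clones the packaged table's per-SNP effects, SEs and
frequencies for a given outcome's surviving instrument set.

What the generator does *not* emulate: LD between instruments beyond a
block-constant r² table, winner's curse in instrument discovery, case-
control ascertainment and liability-scale effects, population
stratification, and real minor-allele-frequency spectra. Passing tests
therefore demonstrate correctness and calibration of the estimators under
their stated assumptions, not robustness to those real-data features.

## Simulation study sizes

The calibration and recovery studies use 2000 replicates (type-I error,
compared to the exact binomial 99% interval around 0.05), 500 replicates
(parameter recovery within 3 Monte-Carlo SEs; at this size the
weak-instrument attenuation of IVW, ≈ θ/(1+1/F̄) with F̄ ≈ 79, is inside
the Monte-Carlo band) and 200 replicates (MR-PRESSO detection/null rates
against a 90% bar, with 1000 resamples per replicate). These sizes keep the
Monte-Carlo error well below the assertion margins while the whole suite
runs in well under a minute.

## Known limitations

- The trio-based decomposition of fetal vs maternal effects is consumed as
  a boolean column, never re-derived.
- LD must be supplied locally; there is no genotype-panel computation and
  no remote service access.
- The Egger intercept test has low power at k ≈ 14 and the weighted mode is
  bandwidth-sensitive by design; both are reported with their tuning
  parameters rather than "fixed".
- Proxy orientation without a phase column falls back to frequency
  concordance, which is uninformative near EAF 0.5.
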