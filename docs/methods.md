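# Methods

## Model and assumptions

The package implements two-sample Mendelian randomization: genetic
variants serve as instrumental variables for an exposure, and causal
effects are estimated from per-SNP association summaries of two
non-overlapping GWAS. Validity rests on the three instrumental-variable
assumptions — relevance (the SNP is associated with the exposure),
independence (no confounder of SNP and outcome), and exclusion (the SNP
affects the outcome only through the exposure). The estimators differ in
how much exclusion-restriction violation (horizontal pleiotropy) they
tolerate; IVW is the headline estimator, the other four are robustness
companions, and the screening cascade demands qualitative agreement among
all five.

Mediation uses the product-of-coefficients decomposition on the log-odds
scale: with β₁ the exposure→mediator effect, β₂ the mediator→outcome
effect, and θ the total exposure→outcome effect, the mediated effect is
ME = β₁β₂, the direct effect θ − ME, and the mediated proportion
MP = 100·ME/θ. All three legs are separate MR analyses on non-overlapping
samples, so the Sobel standard error √(β₁²σ₂² + β₂²σ₁²) and the
first-order ratio SE for MP carry no covariance terms. MP is reported
signed, exactly as ME/θ: when mediated and total effects oppose, MP is
negative, and no clamping or absolute value is applied. MP is a ratio of
estimates, so with weak total effects it can fall outside [0, 100].

### Two-step instrument separation

The mediator→outcome leg excludes any SNP that is also an instrument of
the exposure (at the same selection threshold). SNPs acting on the
mediator *through* the exposure carry the exposure's direct path in their
outcome effect — their Wald ratio estimates θ/β₁, not β₂ — so leaving
them in biases the second step toward the total effect. Exclusion by
exposure-instrument membership removes exactly these, at a negligible
false-exclusion rate for genuinely mediator-specific SNPs.

## Instrument pipeline

1. **Selection**: exposure p ≤ 5×10⁻⁵, boundary inclusive.
2. **Clumping**: greedy, candidates visited by ascending p (ties broken
   lexicographically by snp_id so results are order-invariant); each
   retained SNP removes not-yet-visited SNPs on the same chromosome
   within a 10,000-kb window with r² ≥ 0.01 against it. SNPs absent from
   the LD matrix are retained with a `no_ld_info` audit flag and a
   warning — dropping them silently would bias toward sparse LD tables.
3. **Harmonization**: join on snp_id; when the outcome reports the same
   allele pair with roles swapped, the outcome beta's sign is flipped.
   Palindromic SNPs (A/T, C/G) are excluded unconditionally — no
   frequency-based rescue — because strand cannot be resolved from
   alleles alone. Allele pairs that match neither directly nor swapped
   (including strand-complement representations, whose resolution would
   need a reference panel) are dropped with a count. Optional proxy
   substitution (r² ≥ 0.8, inclusive) translates the proxy's alleles to
   the target's through an explicit correspondence; a direct match always
   beats a proxy.
4. **Strength filter**: per-SNP F = (β_X/σ_X)², the squared marginal Wald
   z — the summary-data surrogate needing neither sample size nor allele
   frequency; retention is strict, F > 10.

## Estimators: numerical choices

- **IVW**: weighted least squares through the origin, weights 1/σ_Y².
  Default variant is multiplicative random effects — SE inflated by
  max(1, √(Q/(J−1))), floored at the fixed-effects SE — the de facto
  default in modern two-sample MR. At J = 1 the fixed-effects form
  reduces exactly to the Wald ratio. Normal p-values.
- **MR-Egger**: rows oriented so every β_X ≥ 0, then WLS with intercept.
  SEs use the unfloored residual variance Q′/(J−2) exactly as a weighted
  `lm` would: flooring the variance at 1 would make the intercept test
  conservative (~2% size instead of 5%), destroying its calibration.
  Inference via t with J−2 df.
- **Weighted median**: weights 1/σ_ratio² normalized; estimate by linear
  interpolation of the sorted ratios at cumulative midpoint mass 0.5.
- **Modes**: normal-kernel density of ratios, bandwidth
  φ·0.9·min(sd, MAD/0.6745)·J^(−1/5) (φ = 1 by default), evaluated on a
  512-point grid spanning the ratio range ± 3 bandwidths; estimate is the
  grid argmax. Degenerate inputs (all ratios equal) return that value
  directly.
- **Bootstrap SEs** (median and modes): parametric — β_X and β_Y
  resampled from normal distributions centered at the observed values
  with their reported SEs — 1000 replicates by default, seeded through
  the run configuration so reruns are byte-identical.

Cochran's Q is the weighted residual sum of squares around the IVW fit
(df J−1) or the Egger fit (Q′, df J−2), chi-square under homogeneity.
The Egger intercept test flags pleiotropy at p < 0.05. Leave-one-out
entries are computed by literally re-running IVW on each J−1 subset, so
they are bitwise-identical to independent calls.

## Screening cascade

Gates in order, each at α = 0.05: IVW significance; direction consistency
(all five estimates share a sign — equivalently all odds ratios on one
side of 1); Egger-intercept p > α; heterogeneity p > α under both the IVW
and Egger Q. Survivors are classified risk (all OR > 1) or protective
(all OR < 1). The significance gate uses the nominal IVW p by default
with the BH-FDR-adjusted p recorded in the same row (`screen_on: fdr`
switches the gate); both conventions appear in practice and the output
keeps the choice auditable. Reverse-direction MR (outcome as exposure) is
recorded as pass / fail / untestable and is descriptive, not a gate. A
mediation pair is flagged *meaningful* when both path estimates are
nominally significant — a named, swappable predicate.

## Synthetic-data generator

The generator emulates the three-trait summary-statistics setting
directly — no individual-level genotypes — so the analytic standard error
is itself checkable:

- J index SNPs act on the exposure with effects γ_j; j_med further SNPs
  act directly on the mediator (without them the mediator would have no
  valid instruments of its own, every M-associated SNP being downstream
  of X). All three tables share one snp_id universe.
- Per-SNP sampling noise is N(0, se²) with se = 1/√(2n·maf(1−maf)), the
  standardized-trait GWAS formula; maf ~ Uniform(0.05, 0.45) by default.
- γ_j ~ N(0, 0.05²), magnitude-floored at √f_target·se with
  f_target = (z_{2.5×10⁻⁵} + z_{0.95})² ≈ 33 — the instrument screen's
  own F threshold plus 95% one-sided discovery power — so index SNPs are
  genuine, discoverable instruments rather than boundary-straddlers
  (instruments selected on noise at the threshold would otherwise
  attenuate every downstream estimate through winner's curse).
- Defaults: θ_direct = 0.08, b1 = 0.3, b2 = 0.4 (θ_total = 0.2, true
  MP = 60%), n = 50,000 per GWAS, J = j_med = 100 — a regime comparable
  to well-powered molecular-trait GWAS.
- Pleiotropy: per-SNP direct outcome effects α_j — none, balanced
  N(0, sd²), or directional N(mean, sd²) — defined relative to the
  exposure-increasing allele (sign tied to γ_j), the orientation in which
  the Egger intercept estimates the average; a separate setting injects
  pleiotropy toward the mediator.
- LD blocks append satellite SNPs whose true effects attenuate by
  r = √r², the expectation of an LD-tagged marginal effect, with the
  block r² written to the LD matrix.
- The binary outcome reuses the same noise model on the log-odds scale at
  the nominal n; this is an approximation (a logistic GWAS's effective
  sample size depends on case fraction), documented rather than modeled.

What the generator does **not** emulate: realistic genome-wide LD,
population stratification, sample overlap, allele-frequency differences
between cohorts, and case-control ascertainment. Passing recovery tests
therefore demonstrates correctness of the estimators and pipeline logic
under the stated sampling model, not robustness to those real-data
complications.

## Calibration experiments

`medimr.calibration` packages two Monte-Carlo studies (also run by
`scripts/acceptance.py` and the test suite):

- **Null calibration** (1000 reps, J = 20, n = 20,000): Egger-intercept
  rejection rate at α = 0.05 and mean Cochran's Q. The default experiment
  is the global null — no pleiotropy *and* no causal effect — which
  isolates the intercept test's size (measured ≈ 0.05; mean Q ≈ df). The
  J designed instruments are harmonized directly without the p-screen,
  which would only shrink the degrees of freedom through selection noise.
  With a causal effect present (θ = 0.2) the same experiment measures
  ≈ 0.066: exposure-measurement noise dilutes the Egger slope and leaks
  into the intercept, the known weak-instrument (NOME-violation) behavior
  of Egger regression — reproducible by passing a custom truth.
- **Recovery study** (500 reps at the default truth): mean IVW total
  effect (≈ 0.196, the residual 2% being regression dilution from noise
  in β_X), empirical 95% CI coverage (≈ 95%), and mean estimated MP
  (≈ 59%).

Replication counts (1000 / 500) keep each study around half a minute on
one CPU while holding Monte-Carlo error well inside the assertion bands.

## Known limitations

- No Steiger filtering, MR-PRESSO, multivariable or network mediation —
  deliberately outside scope.
- LD is consumed, never computed: clumping and proxies require
  precomputed r² tables.
- The per-SNP F statistic is the squared Wald z; the 2·maf(1−maf)·R²
  form is not implemented.
- Mediation SEs ignore the sampling correlation that would arise from
  overlapping GWAS samples.
- MP's ratio SE is first-order and degrades when the total effect is
  weak relative to its SE.
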