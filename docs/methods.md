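# Methods

## The analysis problem

`mrmed` implements summary-data two-sample Mendelian randomization (MR) with
a two-step mediation extension. The scientific setting it targets is a
screen of the form *exposure phenotypes → metabolite mediators → a rare
binary disease outcome*: for each SNP *j* the exposure GWAS supplies an
association estimate γ̂ⱼ with standard error σₓⱼ, the outcome GWAS supplies
Γ̂ⱼ with σ_yⱼ, and under the instrumental-variable assumptions (relevance,
independence from confounders, no pathway to the outcome other than the
exposure) the per-SNP Wald ratio Γ̂ⱼ/γ̂ⱼ estimates the causal effect θ of the
exposure on the outcome, on the log-odds scale when the outcome is binary.

## Instrument selection and harmonization

Selection follows the conventional recipe, with defaults
`p_threshold = 1e-5`, `clump_r2 = 0.001`, `clump_kb = 10_000`,
`f_min = 10`, `drop_palindromes = True`:

1. intersect exposure and outcome tables on SNP id;
2. drop palindromic (A/T, C/G) SNPs outright — their strand is ambiguous
   and we deliberately do not attempt frequency-based rescue, so EAF may be
   missing throughout;
3. align outcome alleles to the exposure's effect allele: swapped alleles
   flip the outcome beta, strand-complement alleles are complemented first;
   anything else is dropped as incompatible;
4. keep exposure-significant SNPs (p ≤ 1e-5) with single-SNP
   F = (β̂/σ̂)² ≥ 10. The squared z-score is the standard single-SNP
   approximation to the first-stage F and is numerically indistinguishable
   from the R²-based formula at GWAS sample sizes;
5. greedy LD clumping: repeatedly take the lowest-p unclaimed SNP, discard
   unclaimed SNPs on the same chromosome within `clump_kb` kb with
   r² ≥ `clump_r2`; p-value ties break lexicographically by SNP id so the
   result is deterministic. Summary files carry no LD, so the pairwise LD
   table is an explicit input (the simulator emits one; real use would
   export one from a reference panel). A pair absent from the table is
   treated as r² = 0.

Every exclusion is logged with its stage and reason; no SNP is silently
dropped. Proxy-instrument lookup is intentionally out of scope: an
instrument missing from the outcome is dropped with a recorded reason.

## Estimators

All multi-SNP estimators use first-order ("NOME") weights
wⱼ = γ̂ⱼ²/σ_yⱼ², i.e. exposure-side uncertainty is ignored, which is
adequate for instruments passing the F ≥ 10 filter.

- **IVW**: β̂ = Σwⱼβⱼ/Σwⱼ over Wald ratios βⱼ, fixed-effect SE
  (Σwⱼ)^(-1/2). When Cochran's Q exceeds its df the SE is inflated by
  √(Q/df) (multiplicative random effects); the estimate records which rule
  fired. P-values are two-sided normal.
- **MR-Egger**: each SNP is oriented to γ̂ⱼ ≥ 0, then Γ̂ is regressed on γ̂
  with an intercept, weights 1/σ_yⱼ². The intercept estimates average
  directional pleiotropy per instrument; coefficient SEs are scaled by
  max(1, √(Q_egger/(n−2))) and p-values use t(n−2).
- **Weighted median**: the ratio at cumulative normalized weight 0.5 with
  linear interpolation between bracketing order statistics; consistent when
  valid instruments carry ≥ 50% of total weight. SE by seeded parametric
  bootstrap (default 1,000 resamples of both betas from their sampling
  distributions).
- **Mode estimators**: argmax of a normal-kernel density of the ratios on a
  512-point grid spanning the data ± 3 bandwidths; bandwidth is
  `bandwidth_factor` (default 1) × 0.9·min(sd, 1.4826·MAD)·n^(−1/5). When
  the MAD is degenerate (half the ratios tied) the sd alone sets the scale;
  identical ratios return that value. The weighted variant weights each
  kernel by wⱼ. SE by seeded parametric bootstrap.
- **Wald ratio** for a single instrument, with the first-order SE
  |σ_y/γ̂|; the pipeline emits it automatically when only one instrument
  survives (IVW with one SNP reduces to it algebraically).

Diagnostics: Cochran's Q with χ²(n−1) p-value; the Egger intercept test;
leave-one-out IVW (computed in closed form from the weight sums, flagging
drops whose estimate leaves the full-set 95% CI); and the Steiger
directionality test. For Steiger, per-SNP variance explained is recovered
from the z-statistic as r² = z²/(z² + n − 2) and summed over instruments
per trait; orientation is supported when instruments explain more variance
in the exposure, and the p-value is a Fisher-z comparison of the two
multiple correlations treating the two (non-overlapping) GWAS as
independent samples. Binary traits enter with their effective sample size
4/(1/n_cases + 1/n_controls). The z-based r² is this implementation's
choice; published pipelines do not agree on a single formula.

Every estimate carries or = exp(β), with 95% bounds exp(β ± 1.959964·σ);
these identities are enforced in the constructor, so a result table can
never print an OR inconsistent with its Beta.

## Mediation

The two-step decomposition fits three univariable MR legs with independent
instrument selection — exposure→outcome (total effect β_EO),
exposure→mediator (β_EM), mediator→outcome (β_MO) — and combines them as

    indirect = β_EM · β_MO
    direct   = β_EO − indirect
    proportion mediated = indirect / β_EO

exactly. The indirect-effect SE is the first-order delta method
√(β_EM²σ_MO² + β_MO²σ_EM²) (a seeded Monte-Carlo resampling alternative is
provided as a cross-check; the two agree within 10% at moderate noise).
The proportion CI propagates indirect_se/|β_EO|, a first-order
approximation that ignores total-effect uncertainty — adequate when the
total effect is precisely estimated, anticonservative otherwise.

β_MO comes from univariable MR, not from multivariable MR adjusted for the
exposure. This mirrors the screening design the package reproduces and is
a known limitation: SNPs that reach the mediator's significance threshold
*through* the exposure are pleiotropic instruments on the mediator→outcome
leg (their ratio estimates θ_total/θ_EM, not θ_MO). Each leg therefore
defaults to IVW with an automatic fallback to the weighted median when the
Egger intercept test signals pleiotropy (p < 0.05) — codifying the
screening rule of switching pleiotropic pairs to the weighted median. In
simulation this fallback reliably absorbs the leaked instruments (see
`tests/test_mediation.py`).

## The synthetic-data generator

Simulation is at the summary level: individual genotypes are never drawn.
The structural model is

    γⱼ  → exposure → (θ_EM) → mediator → (θ_MO) → outcome
                 ↘ (θ_direct = θ_total − θ_EM·θ_MO) ↗
    δₖ  → mediator (mediator-specific instruments)
    αⱼ  → outcome (horizontal pleiotropy on a configurable fraction)

Published betas are truth plus N(0, se²) noise with
se = 1/√(2·n·maf(1−maf)); case-control traits use the effective sample
size. MAFs are uniform on `maf_range` (default 0.05–0.5). LD is
block-diagonal: blocks of `ld_block_size` SNPs share a common noise factor
giving pairwise correlation r² = `within_block_r2`, and non-lead SNPs carry
marginal effects attenuated by r, so clumping to one SNP per block leaves
consistent Wald ratios. A fraction `prop_palindromic` (default 0.1,
roughly the share of A/T+C/G pairs left on genotyping arrays after QC)
receives palindromic alleles.

Pleiotropy: `balanced` draws αⱼ ~ N(0, sd²); `directional` draws
N(mean, sd²) *relative to the exposure-increasing allele* (sign-aligned
with γⱼ) — without that convention a symmetric γ distribution would make
E[Σγα] = 0 and "directional" pleiotropy would not bias IVW at all. The
`inside_violation` flag adds |γⱼ| to αⱼ to correlate instrument strength
with pleiotropy for Egger stress tests. Pleiotropy acts on the outcome
path only; the exposure→mediator path stays clean so the mediation truth
remains interpretable with one mechanism under test.

Mediator-specific instruments (δₖ) are not optional decoration: without
variants acting on the mediator other than through the exposure, the
mediator→outcome leg is unidentifiable by MR. They emulate the real design
in which the metabolite GWAS supplies its own, largely distinct,
instruments.

Defaults are the motivating study's cohort scales — exposure GWAS
n = 3,757, mediator GWAS n = 8,299, outcome 224 cases / 314,193 controls —
with 500 + 500 SNPs, instrument effect sd 0.15 (giving mostly strong
instruments at these sample sizes), and true effects θ_total = 0.24,
θ_EM = 0.1, θ_MO = 0.6, i.e. a true proportion mediated of 0.25. θ_EM is
deliberately small so that exposure-driven SNPs rarely reach the
mediator's instrument threshold, matching the separation of instrument
sets seen in practice. Everything is reproducible bit-for-bit from
`seed`.

What the generator does **not** emulate: realistic human LD maps, allele
frequency spectra, ancestry structure, sample overlap between GWAS,
winner's-curse-inducing discovery/replication designs, or non-collapsible
odds-ratio effects (binary-outcome betas are generated directly on the
log-odds scale). Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to everything real
summary data can contain.

## Validation harness choices

Problem sizes in the test-suite and acceptance-script harnesses were
chosen so that each check measures the estimator rather than the noise
floor of a particular cohort:

- Calibration and bias harnesses use a 10⁶-person exposure GWAS ("strong
  instruments"): at the motivating 3,757-person scale, instruments sit
  near the significance threshold and selection itself attenuates
  estimates (visible in the study-scale acceptance output, where IVW
  recovers ~0.22 of a true 0.24), which would confound a test of
  estimator bias.
- The weighted-median robustness check uses a well-powered outcome so
  valid ratios are tight and the 40% invalid weight is cleanly separated;
  the median's residual bias under one-sided contamination is intrinsic
  (it scales with the local ratio-noise quantile), so the check asserts
  the truth lies within the estimator's Monte-Carlo dispersion while IVW's
  does not, plus a direct bias contrast.
- Mediation recovery uses a 2,000-case synthetic outcome: with 224 cases
  the per-replicate proportion estimate is so noisy that 200 replicates
  measure the case count, not the decomposition.
- Replicate counts: 1,000 for type-I error and Q calibration, 200 for
  bias/recovery, matching ~1–2 minutes per harness on one core.

## Numerical and degenerate-input behaviour

- Seeds are explicit everywhere randomness exists (bootstraps, simulation,
  screen ordering); there is no hidden global RNG state.
- `ivw` requires ≥ 2 instruments, Egger/median/mode/leave-one-out ≥ 3;
  below that the operations raise `InsufficientInstrumentsError` rather
  than degrade.
- Constant exposure betas make the Egger design singular; `egger` raises a
  clear `ValueError` and the bundled sensitivity report records NaNs for
  the intercept test.
- Q is clipped at 0 in the closed-form leave-one-out to guard float
  cancellation; simulated p-values are clipped into (0, 1] so validation
  never rejects a generated row.
- Tables are written with six-decimal formatting for ordinary magnitudes
  and six significant digits in scientific notation for extreme ones, so
  write→read round-trips preserve values to printed precision.

## Known limitations

- No multivariable MR, MR-PRESSO, proxy-SNP lookup, or reference-panel LD
  management; the LD table is the caller's responsibility for real data.
- The proportion-mediated CI ignores total-effect uncertainty.
- The screen's headline significance is the raw α = 0.05 rule; BH
  q-values are reported alongside so a corrected analysis is one filter
  away.
- Steiger's p-value treats the two GWAS as independent samples; for
  overlapping cohorts it is anticonservative.
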