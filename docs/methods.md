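# Methods

## Scope and data model

`mrmediation` operates entirely on GWAS summary statistics: one row per
variant with effect/other allele, effect-allele frequency (EAF), beta, SE,
p-value and sample sizes. Binary traits carry case/control counts and
log-odds betas. Two input dialects are supported (generic TSV and the
FinnGen release layout with ALT as effect allele), both optionally gzipped.
Rows violating basic invariants (SE ≤ 0, p outside (0, 1], identical
alleles, EAF outside [0, 1]) are dropped and counted in a load report;
duplicate rsids keep the smallest-p record — a deterministic policy
matching common practice. Positions are 1-based; alleles are uppercased;
no liftover or genotype-level parsing is attempted.

## Instruments and harmonization

Instruments are variants with exposure p below a threshold (default
1e-5, the conventional relaxed threshold for molecular exposures where
genome-wide significant instruments are scarce). Clumping is greedy in
p-ascending order (ties broken by rsid for determinism): a variant is
removed when a retained variant on the same chromosome lies within the
window (default 10,000 kb) and the pair's r² from an LD provider reaches
the threshold (default 0.001). Without an LD provider the window alone
decides — appropriate for the package's synthetic data, where instruments
are generated mutually independent and widely spaced.

Harmonization aligns outcome to exposure effect alleles: identical alleles
(directly or after strand complement) are kept; swapped alleles flip the
outcome beta and mirror its frequency; palindromic variants (A/T, C/G)
whose EAF on either side falls inside (0.40, 0.60) — or is missing — are
dropped as strand-ambiguous, and outside that window the orientation with
concordant minor alleles is chosen. The window is configurable; the
default is deliberately conservative. Harmonization is idempotent and
invariant to allele-representation changes of either input (property- and
acceptance-tested).

Per-instrument strength is reported as `F_j = (β̂_Xj/se_Xj)²` with its
mean; under the generator below the mean F has the closed form
`1 + n·h²/m`, which the tests verify.

## Estimators

All five estimators consume the per-SNP Wald ratios `β̂_Dj/β̂_Xj` with
first-order delta SEs `se_Dj/|β̂_Xj|` (zero exposure effects are excluded
with a warning).

* **IVW** — inverse-variance weighted mean, equivalent to weighted
  regression through the origin with weights `se_Dj⁻²`. Default model is
  multiplicative random effects: the fixed-effect SE is inflated by
  `max(1, √(Q/(n−1)))`, never deflated; fixed effects by flag. This is the
  common default in two-sample MR tooling; under homogeneity it makes the
  test mildly conservative (observed type-I ≈ 0.04 at nominal 0.05), which
  the calibration tests accept within the binomial band.
* **MR-Egger** — weighted regression with intercept, rows orientated so
  all exposure betas are non-negative (the intercept is
  orientation-dependent; this is the conventional choice). The intercept,
  its SE and p are the directional-pleiotropy diagnostic. The residual
  variance scale is clamped at ≥ 1 (multiplicative random effects).
* **Weighted median** — ratios ordered, the estimate interpolated where
  cumulative normalized inverse-variance weight crosses 0.5; consistent
  when ≥ 50% of weight comes from valid instruments.
* **Simple/weighted mode** — argmax of a normal-kernel density over the
  ratios on a fixed 512-point grid spanning the ratio range padded by
  three bandwidths; bandwidth is `φ` (default 1.0) times a modified
  Silverman rule `0.9·min(sd, 1.4826·MAD)·n^(−1/5)`, falling back to
  whichever dispersion measure is positive (MAD degenerates to zero when a
  majority of ratios coincide). The first grid maximum wins, making the
  argmax deterministic.

Median and mode SEs use a parametric bootstrap: each ratio is resampled
from `Normal(ratio_j, se_j)` (default 1,000 draws) with a fixed, logged
seed; instruments are sorted by rsid before resampling so bootstrap SEs
are invariant to input permutation. P-values use the standard normal
throughout, matching the asymptotic theory. Cochran's Q (about the
fixed-effect IVW estimate) quantifies heterogeneity with a chi-square
upper-tail p.

ORs are reported as `exp(β)` with bounds `exp(β ∓ 1.96·se)`; the identity
`√(ci_low·ci_high) = OR` is asserted as an invariant and exploited by the
acceptance checks that reconstruct (β, se) from printed CIs.

## Sensitivity analyses and screening

**Leave-one-out** refits IVW with each instrument removed. An instrument
is flagged influential when its removal changes the sign of the estimate
or moves it outside the full fit's 95% CI — a reproducible
operationalization of "substantial influence", which forest plots usually
leave informal.

**Reverse MR** swaps roles: instruments are selected from the disease
GWAS and the disease→trait IVW p is computed. A trait passes the filter
when its reverse p exceeds 0.05. When the disease GWAS yields no usable
instruments the result is reported as *untestable* — a distinct outcome,
not an error — and the screening layer excludes such traits rather than
passing them (conservative).

**Direction consistency** requires all five estimators to agree on the
strict sign of the effect (zero counts as inconsistent).

The **screen** runs forward IVW over every exposure at raw p < 0.01,
applies the reverse filter to forward hits, then screens mediators at raw
p < 0.05 on the mediator→outcome leg plus an exposure→mediator IVW
p < 0.05 with direction consistency. Thresholds are strict inequalities.
No multiple-testing correction is applied by default — this mirrors the
raw-p screening design the package emulates and inflates family-wise
error over thousands of exposures; an optional Benjamini–Hochberg flag is
provided. Every input trait appears in the audit output exactly once
(passed, failed or untestable).

**Mediation** combines the three univariable IVW legs (instruments
re-selected per exposure role) into the product-of-coefficients
decomposition. The mediator→outcome leg is *not* adjusted for the
exposure (no multivariable MR); in a two-sample setting this is unbiased
only when the mediator's instruments are independent of the exposure —
the synthetic generator enforces this, and real analyses should check it.
No CI is propagated onto the mediated proportion: ratio CIs are unstable
when the total effect is small, so the proportion is reported as a bare
percentage. The first-order delta SE omits the `se₁²se₂²` term
(available by flag); under a complete null that first-order interval is
strongly conservative, so CI coverage is tested in the powered non-null
regime where the approximation holds.

## Synthetic-data generator

The generator emulates the three layers of a protein → immune phenotype →
rare-endpoint design: a well-powered standardized quantitative exposure
GWAS (default n = 35,559), a small quantitative mediator GWAS
(n = 3,757) and a binary outcome GWAS with extreme imbalance (126 cases /
412,055 controls). All continuous traits are standardized to unit
variance (the variance scale of real protein/phenotype GWAS varies and is
rarely reported; standardization makes effects comparable and the math
auditable).

Three disjoint, mutually independent SNP blocks (no LD), MAFs uniform on
(0.05, 0.5), non-palindromic alleles:

* `m_snps` exposure SNPs whose standardized effects are rescaled to
  explain exactly `h2_x` of the exposure (default 0.1 over 50 SNPs);
* `m_snps_mediator` mediator-specific SNPs explaining `h2_m` (default 0.2
  over 20 SNPs — immune phenotypes carry large-effect cis loci, and
  without mediator-specific instruments the mediator→outcome leg would be
  confounded by the direct path);
* `m_snps_outcome` outcome-specific SNPs (log-odds effects of total
  squared scale `outcome_snp_var`), which give reverse MR its
  instruments and are causally null for every exposure.

Causal structure: M = θ_xm·X + own genetics + noise; D is Bernoulli with
log-odds θ_xd·X + θ_md·M plus optional per-SNP horizontal pleiotropy on
the exposure block (balanced: zero-mean normal; directional: shifted
mean, defined in the exposure-increasing allele orientation — the
convention under which the Egger intercept estimates the mean direct
effect). Under the rare-disease approximation the marginal per-SNP
log-odds are linear in the per-allele effects, so summary statistics are
drawn directly from the asymptotic sampling distributions,
`β̂ ~ N(β_true, se²)` with `se = 1/√(2nf(1−f))` for standardized
continuous traits and `se = 1/√(2f(1−f)·n_cases·n_controls/n)` for the
binary trait. An individual-level oracle regenerates the same quantities
from binomial genotypes, linear traits and a logistic outcome with actual
per-SNP regressions; the tests require agreement within Monte Carlo
error (with a small explicit allowance for logistic non-collapsibility at
non-rare prevalence).

What the generator does **not** emulate: realistic LD (a block-correlated
duplicate mode exercises clumping without a reference panel), population
stratification, winner's curse, sample overlap, or non-normal effect-size
distributions. Passing tests therefore demonstrate correctness of the
estimators and pipeline logic under idealized sampling, not robustness to
those real-data pathologies.

## Test regimes and problem sizes

The paper-anchored default outcome (126 cases) has essentially no power;
it is the default because it is the condition the package emulates, and
calibration (type-I error, p-value uniformity) is tested under it.
Recovery and screening properties are tested in the package's *powered
regime* (`well_powered_config`): 1,000 cases / 100,000 controls,
θ_xm = 0.4, θ_md = 0.5, θ_xd = 0.8 (true mediated proportion 20%),
20 outcome-specific SNPs. Replicate counts are 150–1,000 per property and
the screening registry uses 50 null exposures + 20 null mediators + one
true path — sizes chosen so the full suite runs in a few minutes on one
CPU while keeping Monte Carlo error well below the tested tolerances.
The Egger intercept-recovery check uses strong instruments
(`h2_x = 0.2` over 30 SNPs) so that weak-instrument regression dilution —
a known finite-sample Egger bias, visible as a few percent at mean
F ≈ 70 — does not confound the pleiotropy diagnostic being tested.

## Numerical choices and degenerate inputs

* Ties in p during selection/clumping break by rsid; all pipelines are
  deterministic given the analysis seed.
* IVW accepts a single instrument (collapsing to its Wald ratio); Egger,
  median and modes require ≥ 3; heterogeneity and leave-one-out require
  ≥ 2. Violations raise typed errors naming the minimum.
* Instruments with β̂_X = 0 are excluded from ratio-based estimators with
  a warning, not a fatal error.
* A zero total effect leaves the mediated proportion undefined (`None`)
  rather than infinite.
* P-values are clipped away from exact 0 at the smallest positive float.

## Known limitations

* Univariable α₂ (no multivariable MR) — see above; mediator instrument
  independence is assumed, not verified, on real data.
* No Steiger filtering; instruments are selected on the exposure only.
* No proxy-SNP lookup, reference-panel LD, or multi-allelic handling
  beyond rejection; real-data clumping needs an external LD provider.
* The screen's raw-p thresholds replicate a published design and are
  anti-conservative over thousands of exposures; use the FDR flag for
  error-rate-controlled screening.
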