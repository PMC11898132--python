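# Methods

## Model

`parityrrm` fits a univariate threshold animal model for litter size in
which the genetic and permanent-environment (PE) effects of each ewe are
random regressions on parity. Parity t ∈ {1..6} (records beyond the sixth
lambing are collapsed into t = 6) is standardized to x = −1 + 2(t−1)/5 and
expanded in normalized Legendre polynomials φ_k(x) = √((2k+1)/2) P_k(x),
the covariance-function convention of animal breeding: with this scaling
the coefficient covariances G (genetic) and P (permanent environment) are
directly comparable across orders, and the per-parity variance is the
quadratic form φ(t)ᵀ M φ(t).

The liability of one lambing record is

y = year + month + φ(t)ᵀβ + φ(t)ᵀα + φ(t)ᵀμ + e,

with α ~ N(0, A ⊗ G) over all pedigree animals, μ ~ N(0, I ⊗ P) over
recorded ewes, and e independent with a class-specific variance
(prolific classes {1}, {2–4}, {5,6}; conventional {1}, {2,6}, {3–5}).
The observed category is determined by fixed thresholds: with three
categories (prolific line: 1, 2, >2 lambs) the liability intervals are
(−∞,0), (0,1), (1,∞); with two (conventional line: 1, >1) they are
(−∞,0), (0,∞). The repeatability model is the degenerate configuration
with a single raw intercept covariate (the constant 1, not φ₀) per random
effect and one residual class; it forces parity-constant h² and unit
genetic correlations, which the test suite verifies draw by draw.

## Pedigree algebra

The pedigree reader topologically sorts its input (ties broken by file
order), auto-adds undefined parents as founders, and rejects duplicated
animals and ancestry cycles. Inbreeding uses the Meuwissen–Luo recursion
on the rows of the Cholesky factor of A; A⁻¹ is assembled sparsely with
Henderson's rules including inbreeding (Mendelian-sampling variance
dᵢ = 0.5 − 0.25(F_s + F_d), with the usual unknown-parent adjustments).
A flag allows ignoring inbreeding in A⁻¹; the exact form is the default.
Unknown parents ("0" or empty) are unrelated founders; genetic groups are
out of scope. Complete and equivalent generations are reported per animal.

## Identification

A threshold model fixes neither location nor scale of the liability by
itself, and the design keeps every year level plus a fixed-regression
intercept, so the following anchors are imposed:

* τ₁ = 0 always; with three categories τ₂ = 1 as well.
* Three categories: all residual-class variances are free — the fixed
  threshold gap identifies the liability scale of every class (each class
  contains middle-category records whose liabilities live in the unit
  window).
* Two categories: **all residual-class variances are fixed at 1.** With
  binary data a free class variance has no likelihood information: the
  truncated-normal residual sum of squares of a class scales with the
  class's current variance, so a "free" variance performs a pure
  multiplicative random walk. Long diagnostic chains showed exactly this
  (a class variance drifting from 1 to >250 with no stabilization).
  Heterogeneous residual classes are therefore meaningful only for the
  3-category line; the binary model is reported with σ²_e ≡ 1.
* The month reference level (September) is dropped from X; all year
  levels are kept. The remaining level/intercept confounding is handled
  by the priors below; all derived ratios (h², c², r_g, r_p) are
  invariant to it.

## Priors

Default (`prior="weak"`): inverse-Wishart(df = dim + 2, scale = 0.1·I)
on G and P; scaled inverse-χ²(df = 4, scale = 1) on free residual
variances; independent N(0, 5²) on every fixed effect and fixed-regression
coefficient. `prior="flat"` removes all of these (improper flat priors
throughout). The proper default exists for a concrete reason beyond small
data: an order-2 per-ewe trajectory can reproduce almost any pattern of
up to six binary outcomes (at most two sign changes), so binary data are
quasi-completely separated and the flat-prior posterior drifts along a
scale ray (fixed effects toward −∞ while G, P inflate without bound —
observed directly in diagnostic chains). A weakly-informative prior on
the location block bounds that ray; 5 liability SDs is far beyond any
plausible year or month contrast, so the prior is immaterial where the
data identify the effect.

## Gibbs sampler

One sweep updates, in order: liabilities (truncated normal via inverse
CDF — never rejection, so extreme tails cannot hang the chain; the normal
quantile uses Wichura's AS241, accurate to ~1e-15), year and month levels
(single site; levels of one factor are conditionally independent and
drawn in one pass), fixed-regression coefficients (single site), genetic
coefficients (blocked 3×3 per animal against A⁻¹ ⊗ G⁻¹), PE coefficients
(blocked per ewe), then G and P (inverse-Wishart via Bartlett
decomposition) and free residual variances (scaled inverse-χ²). The
numerical kernels are numba-compiled; all random variates are drawn from
a single numpy Generator in the driver and passed into the kernels, which
makes chains bit-reproducible for a seed and allows exact
checkpoint/resume (verified by a test that an interrupted-and-resumed
chain equals an uninterrupted one).

Default chain settings mirror a production run: 500 000 iterations,
100 000 burn-in, thinning 100 (4 000 retained draws). Tests and the
acceptance study use 20 000 iterations (burn-in 5 000, thin 10), which
the recovery study below shows is adequate at its data size. Non-PD
inverse-Wishart draws are resampled with a warning; a numerical failure
mid-chain checkpoints and aborts with the iteration index.

Retained per draw: G, P, residual variances, deviance (ordinal-probit
likelihood), and optionally the full location vectors. The deviance
series supports DIC and a plug-in AIC analogue (deviance at the posterior
mean plus twice the parameter count); order comparison reports both with
DIC primary, since an exact AIC is undefined for this Bayesian fit.

## Derived parameters and summaries

Every derived quantity — σ²_a(t), σ²_p(t), h²(t), c²(t), r_g, r_p — is
computed per retained draw and then summarized; plug-in evaluation at
posterior means is never used. Phenotypic covariance across parities
includes genetic plus PE terms only (residuals are independent across
parities and enter the diagonal). Summaries are the posterior mean, the
shortest-interval 95% HPD (ties broken by the lowest left endpoint; ≥20
draws required), P(value > 0.10), the lower credible limit as the 5%
type-7 quantile, and an autocorrelation-based effective sample size
(arviz). Report tables round to 2 decimals; machine outputs keep full
precision.

## Synthetic-data generator

The generator emulates a closed nucleus flock: discrete generations,
seven ram families with one sire and a replacement each, dams rotated one
family forward before mating (a paired test confirms rotation lowers mean
inbreeding versus a no-rotation control). Breeding values follow the
pedigree exactly (founders MVN(0,G); offspring mid-parent plus Mendelian
sampling shrunk by parental inbreeding; a replicate test checks the
A ⊗ G covariance structure). Records arise by sequential parity
retention (survival-style dropout reproducing declining counts at later
parities), with lambing years tied to birth cohorts, months drawn
50/30/20 for Sep/Oct/Nov, and categories cut from the simulated
liability; litter size is decoded as the minimal count of the category.
A truth table stores every additive term of every liability so the drawn
residual is recoverable bitwise.

Two ready scenarios mirror the study flocks' shapes: `prolific`
(3 categories, ~990 ewes, ~2750 records over ~29 lambing years, mean 2.8
lambings/ewe) and `conventional` (2 categories, ~860 ewes, ~2560 records
over ~21 years, mean 3.0). Generating parameters: the prolific truth uses
liability variances of the magnitude reported for 3-category litter-size
analyses (σ²_a(t) ≈ 0.1–0.4, σ²_p(t) ≈ 0.1–0.4, residuals ≈ 0.77).
For the binary line the generating values are deliberately moderate
(σ²_a(t) ≈ 0.2–0.5, σ²_p(t) ≈ 0.3–0.6, residuals 1, h²(t) ≈ 0.10–0.25,
latent intraclass correlation ≈ 0.4): litter-size heritability is low in
sheep, and published binary-line posteriors are heavily right-skewed
(lower 95% credible limits near 0.01–0.09), so their posterior means are
poor central values to generate from — at intraclass correlations above
~0.7 with 7% multiple births the generating truth is not recoverable at
any realistic flock size. The generator caps lambings at parity 6 rather
than emitting >6 records for collapsing (the reader still collapses such
records in real files).

What passing tests do and do not show: the generator produces data from
exactly the fitted model (probit link, multivariate-normal coefficients,
known class structure), so recovery results validate the implementation,
not the model's adequacy for real flocks — real litter-size data bring
non-normal liabilities, selection, and parity mis-recording the generator
does not emulate.

## Validation studies

* **Parameter recovery** (`validation.h2_recovery_study`): 20 replicate
  conventional-like flocks of ~400 ewes (~1 200 records), each refit with
  20 000 iterations; 95% HPDs for h²(t) cover the generating truth in
  ~85% of replicate × parity cells (nominal 95%, threshold 70%; the
  deficit reflects the short chains and small flocks), and every
  posterior-mean genetic-correlation matrix is exactly symmetric with a
  unit diagonal. The study size was chosen to keep a full run within a
  few CPU-minutes.
* **Structural collapse** (`validation.repeatability_collapse_check`):
  the repeatability configuration yields h² spreads across parities and
  |r_g − 1| at machine precision (both zero to 1e-12).
* **Ratio identities**: every published per-parity row of variance
  components for both lines reproduces its printed h² and c² through the
  variance-ratio definitions at the printed precision (13 of 14 rows
  round exactly at 2 dp; the prolific repeatability row carries visible
  input rounding — its components yield 0.147/0.105 against printed
  0.14/0.10 — and is checked to one printed unit).

## Numerical choices and limitations

Liability initial values sit at category midpoints (±0.7 outside extreme
thresholds); coefficients start at zero and covariances at 0.2·I.
Near-singular inverse-Wishart scales receive a 1e-12 relative jitter.
Truncation intervals with negligible mass pin the draw to the nearest
bound instead of failing. Ties in topological sorting and year-level
ordering are deterministic, so all outputs are reproducible byte-for-byte
from a seed.

Known limitations: single-chain inference (no multi-chain Gelman–Rubin
diagnostics); no genetic groups, genomic relationships or multi-line
joint models; DIC/AIC-analogue comparisons inherit the usual caveats of
deviance-based criteria in latent-variable models; and binary-line
variance components mix slowly at small flock sizes — HPDs there are
honest but wide.
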