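# Methods

This note documents the statistical models behind `isoniche`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Data model and gating

A record is one individual: species, stranding year, bulk δ¹³C, δ¹⁵N, C:N
mass ratio, optional paired lipid-extracted δ¹³C, optional sex and total
body length.  Records are validated on ingestion (C:N > 0, δ¹³C in
(−60, 0)‰, δ¹⁵N in (−10, 30)‰); rows failing validation are dropped with
row-numbered diagnostics rather than aborting a read.

Two filters shape the analysis set:

* **Maternal independence** (opt-in): animals below a species-specific
  total-length threshold are excluded, and animals with no length are
  excluded unless the species is configured exempt.  The shipped
  thresholds are placeholders — users must supply published
  weaning/independence lengths for real data.
* **Sample-size gate** (`analysis_gate_n`, default 10): species below the
  gate appear in descriptive summaries only.  Comparative statistics
  (tests, bootstrapped metrics, ellipses, overlaps) are restricted to
  gated species *within the same habitat group*, since cross-habitat
  comparisons confound habitat baseline differences with diet.

Summaries report the sample SD (denominator n−1); with n = 1 the SD is
undefined and omitted, never reported as 0.

## Corrections

Both corrections act on δ¹³C only; δ¹⁵N is never altered (lipid extraction
perturbs nitrogen isotopes, so bulk δ¹⁵N is the right value to carry).
Order is fixed: lipid normalisation first, then Suess standardisation —
both are additive shifts so the order does not change the result, but the
fixed order keeps intermediate values interpretable (lipid-free bulk at
the sampling year).

**Lipid normalisation.**  The model is the offset regression
Δδ¹³C = δ¹³C_LE − δ¹³C_bulk = β₀ + β₁·C:N (Post-style normalisation),
fitted by ordinary least squares on paired bulk/lipid-extracted samples,
bootstrapped (default 10,000 replicates, resampling pairs with
replacement) and averaged across replicates.  Replicates whose resample
has zero C:N variance are redrawn, not dropped, so the replicate count is
exact.  The correction is applied only to samples with C:N strictly above
the threshold (default 3.5); equality passes through unchanged, matching
the convention that 3.5 is the lipid-poor boundary.  The offset form was
chosen over regressing δ¹³C_LE on δ¹³C_bulk because the correction must
gate on C:N, and the offset is the quantity that varies with lipid
content.

The *pipeline* fits the calibration on pairs with C:N above the threshold.
Rationale: the model is only ever evaluated there, and lipid-poor pairs
carry no lipid signal (their offset is ≈ 0 by construction), so including
them biases a single linear fit when the true effect is hinge-shaped.
`fit_lipid_correction` itself fits whatever pairs it receives, so users
can calibrate on the full span if their data warrant it.

**Suess correction.**  δ¹³C is shifted by rate × (reference_year − year)
with rate −0.022‰ yr⁻¹ and reference year 2021.  The sign convention:
an older sample is shifted *down*, standardising it to the more
¹³C-depleted modern baseline.  The correction is linear in the year gap,
so correcting year→mid→reference equals correcting year→reference.

## Randomisation test

Two-sided test on the absolute difference of means.  Monte-Carlo mode
reallocates the pooled values into groups of the original sizes (10,000
permutations by default) and reports the add-one p-value
p = (1 + #exceedances)/(1 + N), which cannot be exactly zero — at 10,000
permutations the difference from the plain proportion is ≤ 10⁻⁴, and it
avoids anti-conservative zero p-values.  Ties with the observed statistic
count as exceedances (with a 10⁻¹² tolerance against float noise).
Exhaustive mode enumerates all C(n_a+n_b, n_a) allocations (capped at
10⁶) and reports the exact proportion.  δ¹³C and δ¹⁵N are tested
separately per species pair with no multiplicity adjustment, matching the
convention of classifying pairs by which isotope(s) differ.

## Layman metrics and bootstrap comparison

The six metrics (δ¹³C range, δ¹⁵N range, hull total area TA, mean
centroid distance CD, mean and SD of nearest-neighbour distances) are
computed exactly; hulls and polygon areas come from shapely.  Degenerate
sets are defined rather than rejected: TA = 0 for collinear or < 3
distinct points, SDNND uses the sample SD (n−1) consistent with the
summaries.

Because TA and the ranges grow with n, species are compared after
bootstrapping each to the smallest gated n within the habitat group
(overridable), 10,000 with-replacement draws by default.  Draws are
paired by index across species, each species using an independent
substream — pairing is a convention (the draws are independent, so any
pairing gives the same expectation) that makes results reproducible and
variance behaviour explicit.  Exceedance probabilities use strict
inequality; ties count for neither side, so P(A>B) + P(B>A) ≤ 100% with
the shortfall equal to the tie probability.  Ties are not a corner case:
bootstrap draws from small discrete point sets tie with noticeable
frequency (several percent for ranges), which is why the "≈ 50% under
identical data" intuition holds only after splitting the tie mass.

## Standard ellipses

SEA = π√det(Σ̂) with the sample covariance (n−1); this is the area of the
Mahalanobis r = 1 ellipse, which for a bivariate normal contains
1 − e^(−1/2) ≈ 39.35% of the mass — the level conventionally described
as "the 40% ellipse".  All default geometry uses r = 1; an exact-40%
option (r² = −2 ln 0.6) and arbitrary containment levels
(r² = −2 ln(1−c), the χ²₂ quantile) are available.  SEA_C multiplies by
(n−1)/(n−2), removing the leading small-sample bias of the determinant.
Printed-table reproduction uses decimal arithmetic with round-half-away-
from-zero, since binary rounding of exact .5 decimals differs.

**Bayesian SEA_B.**  Under the noninformative prior
p(μ, Σ) ∝ |Σ|^−(d+1)/2, the marginal covariance posterior is
Inverse-Wishart(ν = n−1, S) with S the centred scatter matrix.  This is
sampled exactly with scipy (default 1000 draws), giving the same target
as an MCMC sampler in the vague-prior limit without convergence
diagnostics.  Each draw's area is π√det(Σ); central 50/75/95% credible
intervals are nested by construction.  Requires n ≥ 4.

**Overlap.**  Ellipse boundaries are traced through the Cholesky factor
as 1024-vertex polygons (relative area error ~10⁻⁵ vs the analytic
π r² √det Σ) and intersected with shapely's convex clipping; the overlap
is reported as a proportion of each species' own ellipse area, hence an
asymmetric matrix.  The Bayesian mode intersects per paired posterior
draw (256 vertices for speed) and reports per-draw medians; ellipse
centres stay at the sample means, so centre uncertainty is deliberately
not propagated into overlap — the posterior object carries covariance
draws only.  A maximum-likelihood mode (single fitted ellipse per
species) is also provided, since a "proportion of Bayesian area" point
estimate is not uniquely defined.

## Synthetic generator

Each species is a bivariate-normal cloud (means, SDs, correlation ρ;
ρ defaults to 0 because published tables give only marginal SDs, and is
configurable for ellipse-orientation tests).  The generator draws *true*
values — lipid-free, referenced to 2021 — then reverses the measurement
process: C:N from a lognormal (default μ = ln 3.9, σ = 0.18) clipped to
the calibration span [3.0, 8.6]; bulk δ¹³C depressed by
slope·max(0, C:N − 3.5) with slope 0.99‰ per C:N unit (the aquatic-tissue
normalisation slope of the Post lineage); Suess drift reversed for a
stranding year drawn uniformly in 2010–2021.  A configurable fraction of
samples (default 0.45, matching the proportion of paired samples typical
of such calibrations) carries the paired lipid-extracted value.  Species
substreams are keyed by a stable hash of the species name, so community
output is independent of config order.  A `saturating` lipid-effect mode
breaks the linear-model assumption on purpose for robustness checks.

The shipped `nz_odontocetes` scenario encodes a 21-species New Zealand
odontocete community (published means ± 1 SD and n per species; the two
single-specimen species get a nominal 0.5‰ SD, which affects nothing
downstream because they never pass the gate).

What the generator does *not* emulate: stranding-event clustering (mass
strandings make individuals non-independent), spatial/temporal baseline
gradients beyond the linear Suess term, within-individual tissue
heterogeneity, and measurement error on δ¹⁵N.  Passing tests therefore
validate the estimators under the model's own assumptions, not the
field-data deviations from them.

## Reproducibility and numerics

All randomness flows from one master seed through named substreams keyed
by (stage, species, …) via SHA-256, so adding a species or reordering
configs never perturbs another species' draws, and every emitted seed is
below 2³¹.  The pipeline manifest records the seed, every parameter and
per-stage record counts; a rerun from the manifest is byte-identical.

Problem sizes used by the validation suite (chosen to make Monte-Carlo
error a small fraction of each tolerance): 10,000 permutations × 1,000
replicates for test calibration, 100,000 points for containment checks,
10⁵-point hit-or-miss oracles for hull areas, 1000 posterior draws at
n = 200 for Bayesian recovery.

## Known limitations

* Two isotopes only; the ellipse machinery is explicitly bivariate.
* The lipid model is linear in C:N; strongly nonlinear lipid effects need
  the calibration restricted to the relevant C:N range (or a different
  model).
* Overlap ignores centre uncertainty in Bayesian mode (above).
* The randomisation test compares means only; it will not detect pure
  variance differences (the ellipse comparison does).
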