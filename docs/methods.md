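# Methods

This note documents the models, conventions and numerical choices behind
`dcenirs`, in the order data flows through the pipeline.

## Measurement model

A pulsed NIR laser illuminates a joint (or cuvette) in transmission; a
time-correlated single-photon-counting detector on the far side accumulates a
distribution of times of flight (DTOF) — a histogram of photon arrival times.
The measured DTOF is the tissue's temporal point spread function (TPSF)
convolved with the instrument response function (IRF).  Because convolution
adds mean times, the difference of count-weighted mean arrival times is an
instrument-free property of the tissue, and the mean optical pathlength is

    p = (c / n) (<t>_DTOF − <t>_IRF),        c = 29.9792458 cm/ns,

with tissue refractive index n = 1.4 by default.  Intensity is the total
photon count of a frame; the modified Beer–Lambert law converts intensity
changes relative to a pre-contrast baseline into absorption changes,

    Δμ_a(t) = ln(I_0 / I(t)) / p.

We adopt the baseline-over-measurement log ratio so that rising absorption is
positive; the alternative printed order merely flips the sign and would make
tracer concentrations negative.  p is computed once from the mean DTOF of the
baseline window (default: all frames in the first 10 s, before injection);
dynamic pathlength changes during a bolus are a ≲0.5% effect and propagate to
only ≈1% of blood flow (see the sensitivity analysis below).  A per-frame
pathlength diagnostic (`pathlength_per_frame`) is available.  Zero-count
frames (lost probe contact) are masked and bridged by linear interpolation of
intensity, with a warning.

Tissue indocyanine green (ICG) concentration follows from the decadic
extinction coefficient of plasma-bound ICG at 805 nm:

    Q(t) = Δμ_a(t) / (ln 10 · ε_ICG),        ε_ICG = 0.186 µM⁻¹cm⁻¹ default.

Dimensional analysis forces the division; the value of ε_ICG is a
configurable constant recorded in every output (published tables vary by a
few percent depending on plasma binding).  Ink phantoms use the analogous
relation Δμ_a,expected = ln10 · (0.885 ε_e,ink) · Δc, where 0.885 converts a
decadic transmission-measured extinction into the absorption coefficient of
India ink.  The two relations are mutually inverse conventions, and the
absorption↔concentration round trip is an exact identity (tested to 1e-12).

## Blood-flow deconvolution

The indicator-dilution model links the arterial input Ca(t) (dye densitometer)
and the tissue curve Q(t):

    Q(t) = (Ca ⊛ h)(t),     h(t) = f · R(t),

with R the impulse residue function (R(0)=1, non-increasing) and f the blood
flow per unit tissue volume in s⁻¹.  Flow in conventional units is
BF = 6000 f / ρ (mL/min/100 g), with tissue density ρ = 1.05 g/mL by default
(the density convention is exposed as configuration; arterial curves supplied
in mg/L are converted to µM via the ICG molar mass 774.96 g/mol).

Discretized on the arterial grid, the convolution is a lower-triangular
Toeplitz system solved for h by nonnegative least squares with two penalties:

* a Tikhonov identity term, weight λ chosen by generalized cross-validation
  on a 33-point logarithmic grid spanning [1e-8, 1] × σ_max(A);
* a first-difference roughness term with fixed weight 1e-2 · σ_max(A).

The roughness term exists because nonnegative deconvolution of data that
deviate smoothly from the convolution model produces alternating-spike
("picket fence") solutions whose maximum — the flow read-out — can double.
The penalty suppresses those solutions at the cost of a ≈ +0.3% bias on
noise-free data, well inside the 1% recovery budget.  BF is read from max(h)
rather than h(0), which tolerates small arterial-to-tissue delays; a delay
can additionally be scanned on a bounded grid (0–5 s) when the two
instruments are not synchronized.  An optional monotone-after-peak projection
(pool-adjacent-violators style) is available.  Every estimate records the
regularization used and the RMS refolding residual, and refolding the
estimate through Ca reproduces Q within that residual by construction.

Repeat measurements are aggregated by the study's rule: two repeats per
ankle-day → their mean; one → that value; none → the cell is absent.  No
imputation across sides or days.

## Synthetic data

The generator produces every input with known ground truth; all randomness
flows from a single seed.

**Optics.** The TPSF is the extrapolated-boundary image-source (dipole
series) solution for time-resolved total transmittance through a slab, with
the internal-reflection parameter from the Groenhuis polynomial.  Defaults
emulate transmission across a rat ankle: μ_a = 0.15 cm⁻¹, μ_s′ = 10 cm⁻¹,
thickness 1 cm, n = 1.4, 1024 bins of 10 ps; the phantom scene uses
μ_a = 0.025 cm⁻¹ (water-dominated), μ_s′ = 8 cm⁻¹ (0.8% Intralipid).
Frames are independent Poisson draws around the IRF-convolved TPSF at a
configurable expected count per frame (default 1e6, a realistic TCSPC load
for 0.3-s frames).

**Absorption dialect.** By default dynamic absorption attenuates frame
intensities through the baseline effective pathlength,
I_k = I_0 exp(−p_b Δμ_a,k) — the exact adjoint of the analysis, so noise-free
generate→process round trips are identities and recovery tests isolate the
estimator rather than the model mismatch.  The physically exact alternative
(`absorption_mode="timedomain"`) reweights the TPSF by exp(−v Δμ_a t); under
it a static baseline pathlength linearizes a curved relation and recovered
absorption changes fall 3–7% short over 0.005–0.040 cm⁻¹ — the same
sublinearity a real system shows as a phantom regression slope a few percent
below one.  Tests cover both modes; the default keeps the forward model
unbiased by construction.

**Bolus kinetics.** The arterial curve is a peak-normalized gamma variate
(injection at 10 s, peak 5 µM, shape α=3, scale β=1.5 s) plus a delayed,
scaled, broadened copy as recirculation (fraction 0.15, delay 12 s).  The
tissue curve is the discrete forward convolution with f·R using a
plateau-then-exponential residue (plateau 3 s — a minimum vascular transit
time — washout τ = 15 s).  At the baseline-like flow of 15 mL/min/100 g this
puts tissue concentrations ~70× below arterial, inside the order-of-magnitude
ratio observed in vivo, and peak tissue Δμ_a ≈ 0.03 cm⁻¹, inside the working
range.  The protocol default is 400 frames over 120 s with a 10-s baseline.

**Phantom titration.** 0.02-mL increments of an ink stock into 3.5 mL of
scattering solution, cumulative concentration accounting for dilution,
10 steps × 100 frames plus an ink-free baseline set.  With equal increments
the dilution arithmetic fixes the last/first expected-Δμ_a ratio at 9.51, so
a single series cannot hit 0.005 and 0.040 cm⁻¹ exactly at both ends; the
default stock is calibrated so step 1 is exactly 0.005 cm⁻¹ and step 10
reaches 0.0476 cm⁻¹, covering the full working range.

**Longitudinal study.** 12 animals — 4 controls in one cohort, 8 experimental
in 4 cohorts of 2 — measured on both ankles, twice per ankle, on three
baseline days (B1, B2, B3 = induction day) and every 5 days to day 40.
BF = 10 (baseline) + a day profile common to all animals + a disease profile
for experimental animals scaled by a cohort-level severity multiplier
(N(1, 0.6), truncated at 0) + cohort and animal random intercepts (SD 2 and
1) + heart-rate coupling (0.014 mL/min/100 g per bpm around 350 ± 25 bpm)
+ measurement noise (SD 2.5).  Deterministic per-cohort day profiles can be
planted on top (`cohort_day_profiles`) — the handle used by
clustering-recovery experiments, and a closer analogue of real cohort
heterogeneity, which shows up as differently timed disease trajectories
rather than level shifts.  An ankle-day loses exactly one of its two repeats
with probability 0.1 (both are never lost — matching the observed failure
mode, where one injection or probe contact fails).  Experimental cohorts
reach a humane endpoint with a per-day geometric hazard of 0.15 starting on
day 16 (shared within cohort up to a 1-day jitter), so days through 15 are
always complete and roughly half the cohorts drop out before day 20.
Controls never drop out.  First-symptom days are cohort-centred
(N(12, 2.2) days) with ≤1 day spread within a cohort.

What the generator does **not** emulate: real joint anatomy and its change
with disease (the slab is homogeneous), dye pharmacokinetics beyond
first-pass + recirculation, drift or afterpulsing in the detector, and any
treatment-phase response structure.  Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated model, not
performance on real tissue.

## Statistics

**Mixed three-way ANOVA.** Time (6 levels after restriction to complete
timepoints) and side (2) are within-subject factors; group (control vs
experimental) is between.  The analysis set is restricted to days on which
every animal has data, which avoids survivorship bias after humane-endpoint
dropout.  Each within-subject stratum is isolated by orthonormal Helmert
contrasts of subject cell means; within every stratum, group structure is
tested by Type III (unweighted-means) sums of squares via explicit
least-squares model comparisons, and partial η² = SS_effect / (SS_effect +
SS_error-of-stratum).  With 4+8 subjects, 6 times and 2 sides this yields the
reference df structure — (1,10) for between effects and (5,50) for
time-stratum effects.  The implementation agrees with R `aov` exactly on
balanced designs, with `statsmodels` Type III on the unbalanced time
contrasts, and with `pingouin.mixed_anova` for the group and interaction
terms; on balanced designs the full SS decomposition is additive to 1e-10.
With unequal group sizes the unweighted within-effect mains are not additive
with their stratum totals (standard for Type III).  Zero-variance inputs
yield zero SS and NaN F ratios (with SS floored at the numerical round-off
scale of the data).

**Sphericity.** Mauchly's W from the pooled within-group covariance of the
contrast scores (df = N − g), with Box's chi-square approximation including
the standard second-order term.  Two-level effects are trivially spherical
(p = 1).  No sphericity correction is applied to the reported F (uncorrected
df are reported after a non-significant Mauchly test; Greenhouse–Geisser
adjustment is out of scope).

**Tukey HSD.** All 15 pairwise time comparisons use the time-stratum error
mean square, n = N·D observations per time mean, and studentized-range
quantiles (scipy).  Time means pool both sides, the declared convention since
side carries no effect in the reference design.

**Heart-rate confound.** For complete animal-days (all four raw repeats), the
Pearson correlation between the four raw BF and HR values; coefficients are
averaged over all animal-days, skipping degenerate ones.  Four-point
correlations are individually noisy; only the average is interpreted.

**Clustering.** Experimental animals' side-averaged BF values from B1 through
day 15 form the feature matrix.  Ward linkage on (squared) Euclidean
distances; k chosen by the elbow — the maximum second difference of
within-cluster SS over k, with a distance-to-chord tie-break and k = 1 for
degenerate (zero-spread) data; confirmatory k-means (10 restarts) at the
chosen k; stability checked by rerunning the full analysis on three row
shuffles.  A caution that the elbow definition implies: clusters that differ
only by a scalar intercept elbow at k = 2 regardless of their number, because
the first merge dominates the curvature of the WSS curve; distinct
multivariate trajectories (the planted flare profiles) are required for a
four-cluster elbow.

**Power.** Post-hoc power and a-priori sample size for the within-between
interaction use the noncentral F distribution with f² = η_p²/(1−η_p²),
df1 = (g−1)(m−1)ε, df2 = (N−g)(m−1)ε.  Two noncentrality conventions are
implemented and always reported together, because G*Power-style calculators
differ in whether the effect size is taken on the total-variance metric
(λ = f²·N·m/(1+(m−1)ρ)·ε, assumed repeated-measures correlation ρ = 0.5 by
default) or as already error-scaled in the SPSS sense (λ = f²·N·ε).  The two
differ by roughly the factor m/(1+(m−1)ρ), which is why published power
numbers are irreproducible when the option set is unstated: at
η_p² = 0.151, N = 12, g = 2, m = 6 the conventions give 0.242 and 0.152
respectively, and no single λ ∝ N convention can simultaneously yield a
post-hoc power of 0.21 at N = 12 and a required N of 74 at power 0.8 (the
two published numbers imply λ/N ≈ 0.26 and ≈ 0.176).  The a-priori search
returns the smallest integer N per convention and verifies minimality.
Analytic tails are cross-checked against Patnaik's approximation (±0.02) and
Monte-Carlo simulation (±0.01).

## Problem sizes and tolerances

Defaults used by the test suite and the acceptance script: 400-frame stacks
of 1024 bins at 1e6 counts/frame; 100-seed Monte-Carlo per flow level for
recovery statistics; 1000 simulated null studies for error-rate calibration;
10 seeds for the pathlength-sensitivity summary.  Noise-free recovery is
asserted at 1% (estimator bias budget), noisy median error at 5%, the
type-I band at [0.03, 0.07] (±3 binomial SE around 0.05), and exact identities
at 1e-12.  GCV's λ grid floor (1e-8 σ_max) keeps the noise-free solution
effectively unregularized; the λ selection is recomputed per call, so the
estimator is scale-equivariant up to grid resolution.

## Known limitations

* The MBLL-consistent forward default means forward-model bias (the 0.96-type
  slope) is only exercised through the explicit time-domain mode.
* The ANOVA assumes one value per animal×day×side after aggregation; fully
  missing cells are rejected rather than handled by mixed-effects estimation.
* Power conventions cover the within-between interaction only.
* The deconvolution assumes a stationary residue function over the 120-s
  acquisition and a delay-free (or grid-fitted) alignment between the two
  instruments.
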