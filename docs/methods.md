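# Methods

## Chamber flux estimation

A closed chamber accumulates soil-emitted N₂O linearly as long as the
headspace stays far from equilibrium; over a 15-minute closure with a
~0.3 m headspace this is an excellent approximation, so the flux model
is a straight line through the four bag concentrations.  The fitted
slope (ppb h⁻¹) converts to an areal mass flux with the ideal-gas molar
density p/(R·T) at the site pressure and ambient air temperature:

    F = b · 10⁻⁹ · p/(R·T) · M · h

with M = 28 g N mol⁻¹ (both N atoms of N₂O, matching the N₂O-N unit)
and h the headspace height.  R = 8.314 J mol⁻¹ K⁻¹.  Pressure is a
site constant (default 96 600 Pa, appropriate for ~440 m a.s.l.) rather
than per-closure barometry; temperature enters per closure.

A fit with R² < `r2_min` (default 0.7) is flagged rejected but kept in
the flux table.  When all four concentrations are identical R² is
undefined; the estimate is recorded as a rejected zero flux — it is a
genuine observation of no accumulation, just one the gate cannot vouch
for — rather than raised as an error.

Weekly means average accepted fluxes per ISO week, chamber means first.
The reported SE is `sqrt(var(chamber means)/n_chambers + mean(se_i²))`:
the among-chamber sampling variance of the mean plus the average
regression variance.  This is one defensible reading of "combines
regression error and among-chamber variation"; with one chamber it
degrades gracefully to the regression SE alone.

Cumulative emission integrates the weekly series as a step function
over each reported week, bridges gaps by linear interpolation between
the flanking weekly values, holds the nearest value at the period
edges, and converts µg m⁻² → kg ha⁻¹ (×10⁻⁵).  The step+linear rule is
a deliberate choice — no integration rule is canonical for gappy weekly
series — and is what the brute-force quadrature oracle in the tests
integrates.

## Keeling-plot source signatures

Conservative mixing of ambient air (concentration C_a, composition δ_a)
with soil-derived N₂O (δ_s) makes δ exactly linear in 1/C, with
intercept δ_s.  The fit is ordinary least squares in (1/C, δ);
errors-in-variables alternatives (Deming, geometric mean) would matter
if concentration noise were comparable to the δ noise in leverage
terms, which it is not at CRDS precision, and OLS keeps the estimator
analysable.

Quality control evaluates the fitted line at the ambient concentration
and compares with the reference ambient composition: |dev| ≤ 4 ‰ → Q1,
(4, 6] → Q2, (6, 8] → Q3, > 8 ‰ → rejected.  The reference ambient δ
set is configuration (bulk 6.7 ‰, SP 18.7 ‰, δ¹⁸O 44.6 ‰ — tropospheric
literature values, not site measurements).  Duplicate-analyzer
intercepts are averaged per channel *before* SP and bulk are derived,
so the definitional identities SP = α − β and bulk = (α + β)/2 hold
exactly on the stored record.  A signature is emitted only when the
closure's flux is ≥ 75 µg N₂O-N m⁻² h⁻¹ *and* its regression passed
the R² gate *and* both ¹⁵N Keeling fits have R² ≥ 0.7; a failed δ¹⁸O
channel nulls that field without rejecting the record, since δ¹⁸O is
carried for context and is the channel most often lost to calibration
filtering in practice.

A caution the test suite quantifies: the Keeling intercept is an
extrapolation from x̄ = mean(1/C) to 0, and its standard error is
σ_δ·sqrt(1/n + x̄²/Sxx).  At ambient 330 ppb, a 0.3 m chamber and a
flux of ~100 µg N₂O-N m⁻² h⁻¹, the headspace only reaches ~400 ppb, the
leverage factor is ≈ 9, and a 0.3 ‰ per-bag δ repeatability becomes a
~2.7 ‰ intercept uncertainty.  Since OLS with noise confined to δ is
the minimum-variance unbiased estimator, this is a physical limit of
the sampling geometry, not an implementation property; per-signature
precision improves only with larger ΔC (higher flux, longer closures,
smaller headspace).  This is why the flux threshold doubles as a
precision gate.

## Source partitioning

The observed signature is modelled as a two-endmember mixture altered
by closed-system Rayleigh reduction of the residual N₂O pool:

    δ_emit = δ_prod + ε_red · ln(1 − r),  ε_red < 0
    SP_prod = f_den · SP_den + (1 − f_den) · SP_nit     (bulk likewise)

Per Monte-Carlo draw the sampler takes endmembers uniform in their
boxes (SP: −5…+5 ‰ denitrification group, +33…+38 ‰ nitrification;
bulk boxes are wide literature-style intervals and deliberately weakly
informative), r uniform in [0, r_max), and the observation perturbed by
its measurement sd (default 0.5 ‰ per axis).  The draw's f_den solves
the SP equation; a Gaussian likelihood (sd 2 ‰) on the bulk residual
weights the draw.  The mean clips per-draw fractions to [0, 1]; the
2.5/97.5 weighted percentiles are reported unclipped, so an interval
bound above 1 or below 0 is visible evidence that the observation sits
outside the endmember boxes (or that reduction is underestimated)
rather than being silently truncated.  Fractions sum to 1 by
construction.  The published Monte-Carlo mass-balance tool this
emulates does not document its internal sampler; this generic
importance sampler reproduces its observable behaviour (unconstrained
CIs, reduction correction) with every prior exposed in configuration.

Perturbing the observation inside the sampler is what gives the 95 %
interval frequentist meaning against observation noise: with point
endmembers the interval then covers the true fraction at close to the
nominal rate (measured ≈ 0.93–0.95 over 200 synthetic signatures).

Net reduction isotope effects default to ε_SP = −5 ‰, ε_bulk = −7 ‰,
ε_¹⁸O = −15 ‰ — literature-typical magnitudes, configurable, since no
single canonical value exists.  Ignoring reduction when it occurred
biases the apparent nitrification share upward (SP enrichment mimics
nitrification admixture); the acceptance study measures this direction
explicitly.

## Soil water

WFPS = 100·VWC/(1 − BD/PD), with BD = 1.39 g cm⁻³ (site topsoil) and
PD = 2.65 g cm⁻³ (mineral-soil convention).  Values above 100 % are
retained and flagged, not clipped: a supersaturated reading is
diagnostic of sensor or BD mismatch.  Daily means of the 15-minute
record are gap-filled by direct substitution of neighbor-plot daily
means (no bias adjustment — the neighbor is 50 m away on the same
soil), flagged by source.  Obs-vs-sim r² is the squared Pearson
correlation of paired daily values; threshold day counts use inclusive
comparisons (≥ field capacity 78.87 % WFPS, ≤ wilting point 39.33 %),
making the counts invariant under any common monotone rescaling of
series and thresholds.

## Model evaluation

Model runs are consumed as daily delimited tables (total N₂O and its
nitrification/denitrification split, N₂, simulated WFPS; g N ha⁻¹ d⁻¹)
— native model output dialects vary by build and are out of scope.
Cumulative simulated N₂O is interpolated to the observation dates and
scored by RMSE; pathway shares are cumulative fractions.  The Welch
two-sample t-test (Welch–Satterthwaite df) compares monthly samples of
daily weather variables between years; two degenerate zero-variance
samples with equal means report t = 0, p = 1.

## Synthetic generator

The generator emulates the campaign the pipeline assumes: linear
headspace accumulation from a true flux (inverted through the same
ideal-gas conversion, so generator and estimator are exact inverses at
zero noise), exact conservative δ mixing against a configurable
ambient, a pathway mix with optional Rayleigh reduction behind each
source signature, 15-minute VWC series with prescribed field-capacity
and wilting-point exceedance days, seasonal-sinusoid weather with
Bernoulli-gamma precipitation, and pulse-shaped pathway-split daily
emission series.  Noise is independent Gaussian per concentration and
per δ channel — the simplest model consistent with CRDS repeatability
and sufficient for calibration studies.  Deliberately not emulated:
diurnal flux-temperature coupling, instrument drift and spectral
interference, bag-fill duration (15 s fills are treated as
instantaneous), spatial heterogeneity among chambers, and any
mechanistic soil process.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated error
model, not robustness to structural errors a field dataset could
contain.

Generator defaults are the study conditions: flux scale 103 µg N₂O-N
m⁻² h⁻¹ (a realistic high-emission weekly mean), noise 1 ppb / 0.3 ‰,
ambient 330 ppb, chamber height 0.3 m and pressure 96 600 Pa (neither
printed in the source campaign's description; chosen as a typical
automatic-chamber geometry and the barometric pressure of the site
altitude), 85/15 denitrification/nitrification split.

## Problem sizes and numerical choices

Calibration studies use 1000 closures (flux), 500 replicates (Keeling),
and 200 signatures × 2000 draws (partition) — sizes at which Monte-Carlo
error is well below the tolerances being checked while the whole suite
runs in seconds.  Partition percentiles are weighted quantiles by
inversion of the weighted empirical CDF.  Degenerate inputs have
defined behaviour throughout: flat concentrations → rejected zero flux;
insufficient Keeling spread → error; identical endmember SP ranges →
unidentifiable error; constant WFPS series → r² reported missing with a
warning.  All randomness flows from explicit seeds; reruns of the
pipeline with the same seed produce byte-identical output bundles
(fixed float formatting, LF line endings, no wall-clock content).

## Known limitations

Two-endmember SP partitioning cannot separate fungal denitrification
(high SP) from nitrification, nor bacterial from nitrifier
denitrification — the pathway groups are the finest resolution the
fingerprint supports.  Reduction extent and nitrification share are
partially confounded on the SP axis; only the prior on r and the bulk
channel constrain them apart.  The weekly SE formula and the cumulative
integration rule are documented choices among defensible alternatives.
The quality-class ambient reference is configuration, so class
assignments are only as good as the supplied ambient composition.
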