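# n2osource

Pipeline for attributing soil N₂O emissions to their microbial source
pathways from automatic-chamber measurements: areal flux estimation,
Keeling-plot isotopic source signatures, Monte-Carlo
nitrification-vs-denitrification partitioning, soil-water (WFPS)
diagnostics, and evaluation statistics for biogeochemical-model
parameterizations.  Written for biogeochemists processing chamber +
CRDS isotopologue campaigns and for modellers who want observational
constraints on pathway-resolved N₂O.

## What it computes

**Flux.** Each 15-min chamber closure yields four sequential gas-bag
samples (default fill times 3.50, 7.25, 11.50, 14.25 min).  OLS of the
N₂O mole fraction against time gives a slope converted by the ideal-gas
law,

```
F = b · 10⁻⁹ · p/(R·T) · M · h        [µg N₂O-N m⁻² h⁻¹]
```

with slope *b* (ppb h⁻¹), chamber height *h* (m) and M = 28 g N per mol
N₂O.  Fits with R² < 0.7 are rejected; weekly treatment means carry an
SE combining regression error and among-chamber variation.

**Source signature.** The headspace is a two-endmember mixture of
ambient air and soil-emitted N₂O, so δ¹⁵Nᵅ, δ¹⁵Nᵝ and δ¹⁸O regressed
against 1/[N₂O] extrapolate to the microbial source at 1/C → 0 (Keeling
plot).  Quality classes compare the regression's prediction at ambient
concentration with the known ambient composition (Q1 ≤ 4 ‰, Q2 ≤ 6 ‰,
Q3 ≤ 8 ‰, rejected beyond); duplicate-analyzer intercepts are averaged,
and signatures require flux ≥ 75 µg N₂O-N m⁻² h⁻¹ to guard against
false positives.  Site preference SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ and
δ¹⁵N_bulk = (δ¹⁵Nᵅ + δ¹⁵Nᵝ)/2 are derived from the averaged intercepts.

**Partition.** SP fingerprints the pathway: ≈ −5…+5 ‰ for the bacterial
+ nitrifier denitrification group, ≈ +33…+38 ‰ for nitrification.
Partial reduction of N₂O to N₂ enriches the residual pool
(δ_emit = δ_prod + ε·ln(1−r), ε < 0), so a Monte-Carlo sampler draws
endmembers from their literature boxes, a uniform reduction extent, and
the observation's measurement error, inverts the Rayleigh shift, solves
the SP mixing equation for f_den, and weights draws by a Gaussian
likelihood on the bulk channel.  Reported: mean fractions and 95 %
percentile intervals (left unclipped as a box-tension diagnostic).

**Soil water & evaluation.** WFPS = 100·VWC/(1 − BD/PD) converts sensor
volumetric water content to percent of pore space (defaults BD 1.39,
PD 2.65 g cm⁻³); daily means are gap-filled from a neighbor plot, and
obs-vs-sim diagnostics count days at/above field capacity (78.87 %) and
at/below wilting point (39.33 %).  Model parameter sets are scored by
RMSE = √(Σ(Sᵢ−Oᵢ)²/n) against the observed cumulative flux, with
pathway shares and cumulative N₂; monthly weather differences use the
Welch two-sample t-test.

Because no public field dataset accompanies this problem, the package
ships a first-class synthetic generator (`n2osource.synthetic`) that
emulates all four inputs from known ground truth, making every
estimator testable as the inverse of a generator.

## Worked example

```python
from n2osource import (TrueScenario, generate_closure, compute_flux,
                       PipelineConfig, finalize_signature, monte_carlo_partition)
from n2osource.config import EndmemberBox, ReductionModel

sc = TrueScenario(flux_true=103.0, source_d15a=-9.0, source_d15b=-11.0,
                  noise_conc=0.0, noise_delta=0.0)
ev = generate_closure(sc)
flux = compute_flux(ev)
print(f"flux {flux.flux:.1f} ug N2O-N m-2 h-1, R2 {flux.r2:.3f}")
sig = finalize_signature(ev, flux, PipelineConfig())
print(f"SP {sig.d15_sp:.2f} permil, bulk {sig.d15_bulk:.2f} permil, {sig.quality}")
res = monte_carlo_partition(
    sig,
    (EndmemberBox("bD+nD", (-5, 5), (-45, 5)),
     EndmemberBox("Ni", (33, 38), (-60, -10))),
    ReductionModel(r_max=0.0), n_draws=20000, seed=1)
print(f"f_den {res.f_den_mean:.2f}  95% CI "
      f"[{res.ci95_den[0]:.2f}, {res.ci95_den[1]:.2f}]")
```

prints

```
flux 103.0 ug N2O-N m-2 h-1, R2 1.000
SP 2.00 permil, bulk -10.00 permil, Q1
f_den 0.93  95% CI [0.82, 1.09]
```

— the noiseless closure returns the true flux exactly, the Keeling
intercepts recover the source δ, and a signature with SP 2 ‰ sits deep
in the denitrification-group box, so ~93 % of the emission is
attributed to denitrification (the interval's upper bound exceeding 1
reflects endmember-box width, not probability mass above 1 in the
clipped mean).

## Analysis scripts

`analysis/01_generate_inputs.py` … `06_model_evaluation.py` run the full
chain on a synthetic season (three chambers, two fertilization pulses,
an April–June sensor outage, three model parameter sets) and write
their tables under `results/`.  Each script prints what it found;
`python analysis/01_generate_inputs.py --seed 7` then the rest in order.

## Command line

`n2osource synth|flux|keeling|partition|soilwater|evaluate|run` wrap the
same library functions for file-based use; see `n2osource --help`.

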