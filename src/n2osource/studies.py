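"""Self-calibration studies: generator–estimator recovery experiments.

Each study pairs the synthetic generator with one estimator and measures
how well known ground truth is recovered under realistic noise — the
package's substitute for validation against field data that are not
publicly deposited.  All studies are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import EndmemberBox, PipelineConfig, ReductionModel
from .fluxes import compute_flux
from .keeling import SourceSignature, fit_keeling, signatures_from_events
from .partition import monte_carlo_partition
from .synthetic import (PathwayMixSpec, TrueScenario, generate_campaign,
                        generate_closure, mix_and_reduce)


def flux_calibration_study(n: int = 1000, flux_true: float = 103.0,
                           noise_conc: float = 1.0, seed: int = 0) -> dict:
    """Bias and SE calibration of the flux estimator over noisy closures.

    Returns relative bias of the mean recovered flux, the empirical sd
    of the estimates, and the mean reported regression SE.
    """
    master = np.random.default_rng(seed)
    template = TrueScenario(flux_true=flux_true, noise_conc=noise_conc,
                            noise_delta=0.0)
    ests, ses = [], []
    for _ in range(n):
        ev = generate_closure(template, rng=np.random.default_rng(
            int(master.integers(2**31))))
        est = compute_flux(ev)
        ests.append(est.flux)
        ses.append(est.se_flux)
    ests = np.asarray(ests)
    return dict(n=n, flux_true=flux_true,
                mean_flux=float(ests.mean()),
                rel_bias=float((ests.mean() - flux_true) / flux_true),
                empirical_sd=float(ests.std()),
                mean_reported_se=float(np.mean(ses)))


def keeling_recovery_study(n: int = 500, flux_true: float = 103.0,
                           noise_delta: float = 0.3, channel: str = "d15a",
                           source_delta: float = 0.0, seed: int = 0) -> dict:
    """Keeling intercept recovery rate under δ measurement noise.

    Reports the fraction of replicates whose intercept lands within
    ±1 ‰ of the true source δ, the empirical intercept sd, and the
    analytic OLS prediction σ·sqrt(1/n + x̄²/Sxx) for the generated
    concentration geometry.
    """
    master = np.random.default_rng(seed)
    template = TrueScenario(flux_true=flux_true, noise_conc=0.0,
                            noise_delta=noise_delta,
                            source_d15a=source_delta,
                            source_d15b=source_delta,
                            source_d18o=source_delta)
    intercepts = []
    x = None
    for _ in range(n):
        ev = generate_closure(template, rng=np.random.default_rng(
            int(master.integers(2**31))))
        intercepts.append(fit_keeling(ev, channel).intercept)
        if x is None:
            x = 1.0 / np.array([b.conc_n2o for b in ev.bags])
    errs = np.asarray(intercepts) - source_delta
    sxx = float(np.sum((x - x.mean()) ** 2))
    analytic_sd = noise_delta * float(np.sqrt(1 / len(x) + x.mean() ** 2 / sxx))
    return dict(n=n, flux_true=flux_true, noise_delta=noise_delta,
                frac_within_1_permil=float(np.mean(np.abs(errs) < 1.0)),
                empirical_sd=float(errs.std()),
                analytic_sd=analytic_sd)


POINT_DEN = EndmemberBox("bD+nD", sp_range=(0.0, 0.0), bulk_range=(-20.0, -20.0))
POINT_NIT = EndmemberBox("Ni", sp_range=(35.0, 35.0), bulk_range=(-35.0, -35.0))


def partition_recovery_study(n_signatures: int = 200, f_den_true: float = 0.85,
                             noise: float = 0.5, reduction_r: float = 0.0,
                             correct_reduction: bool = True,
                             n_draws: int = 2000, seed: int = 0) -> dict:
    """Recovery of a known pathway split by the Monte-Carlo partition.

    Signatures are drawn from point endmembers with Gaussian observation
    noise on SP and bulk; when the generator applies partial reduction
    (``reduction_r`` > 0) the partition can either correct for it with a
    uniform prior spanning the true extent or ignore it
    (``correct_reduction=False``), exposing the nitrification-vs-reduction
    ambiguity: ignoring reduction pushes fractions toward nitrification.
    """
    mix = PathwayMixSpec(
        f_den=f_den_true,
        endmember_sp_den=POINT_DEN.sp_range[0],
        endmember_sp_nit=POINT_NIT.sp_range[0],
        endmember_bulk_den=POINT_DEN.bulk_range[0],
        endmember_bulk_nit=POINT_NIT.bulk_range[0],
        reduction_r=reduction_r)
    sp_true, bulk_true = mix_and_reduce(mix)
    r_max = min(2.0 * reduction_r, 0.95) if (correct_reduction and
                                             reduction_r > 0) else 0.0
    red = ReductionModel(r_max=r_max)
    rng = np.random.default_rng(seed)
    f_means, covered = [], 0
    for i in range(n_signatures):
        sp_obs = sp_true + rng.normal(0.0, noise)
        bulk_obs = bulk_true + rng.normal(0.0, noise)
        sig = SourceSignature(chamber_id="CH1", timestamp=None,
                              d15a_src=bulk_obs + sp_obs / 2,
                              d15b_src=bulk_obs - sp_obs / 2,
                              d18o_src=None, quality="Q1")
        res = monte_carlo_partition(sig, (POINT_DEN, POINT_NIT), red,
                                    n_draws=n_draws,
                                    seed=int(rng.integers(2**31)),
                                    obs_sd_sp=noise, obs_sd_bulk=noise)
        f_means.append(res.f_den_mean)
        if res.ci95_den[0] <= f_den_true <= res.ci95_den[1]:
            covered += 1
    f_means = np.asarray(f_means)
    return dict(n=n_signatures, f_den_true=f_den_true,
                reduction_r=reduction_r, corrected=correct_reduction,
                mean_f_den=float(f_means.mean()),
                mean_f_nit=float(1.0 - f_means.mean()),
                mae=float(np.abs(f_means - f_den_true).mean()),
                ci95_coverage=covered / n_signatures)


def gate_bookkeeping_study(config: PipelineConfig | None = None,
                           n_above: int = 5, n_below: int = 3,
                           n_poor_fit: int = 2, seed: int = 0) -> dict:
    """Exact accounting of the flux-threshold and R² gates.

    Builds a noiseless campaign with ``n_above`` closures clearly above
    the 75 µg m⁻² h⁻¹ threshold, ``n_below`` clearly below, and
    ``n_poor_fit`` whose concentration sequences scatter too much for
    the R² gate, then counts accepted signatures.
    """
    from datetime import datetime, timedelta

    from .fluxes import BagSample, ClosureEvent

    if config is None:
        config = PipelineConfig()
    template = TrueScenario(noise_conc=0.0, noise_delta=0.0)
    fluxes = [2.0 * config.flux_min] * n_above + [config.flux_min / 3.0] * n_below
    events = generate_campaign(n_above + n_below, fluxes, PathwayMixSpec(),
                               template=template, seed=seed)
    t0 = events[-1].timestamp
    rng = np.random.default_rng(seed + 1)
    for k in range(n_poor_fit):
        # large but non-monotone accumulation: magnitude passes, R² fails
        concs = 380.0 + rng.permutation([0.0, 60.0, 10.0, 80.0])
        bags = [BagSample(t_fill=t, conc_n2o=c, d15a=5.0 + 0.01 * c,
                          d15b=-5.0, d18o=30.0)
                for t, c in zip((3.5, 7.25, 11.5, 14.25), concs)]
        events.append(ClosureEvent("CHX", "NPK",
                                   t0 + timedelta(hours=4 * (k + 1)), bags,
                                   template.air_temp, template.pressure,
                                   template.chamber_height))
    accepted, rejected = signatures_from_events(events, config)
    return dict(n_events=len(events), n_accepted=len(accepted),
                n_rejected=len(rejected), expected_accepted=n_above)
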