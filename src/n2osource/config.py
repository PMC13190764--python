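"""Pipeline configuration: physical constants, gates, priors.

All thresholds that gate data acceptance (flux threshold, regression R²,
Keeling quality classes) and all physical constants (chamber geometry,
site pressure, bulk/particle density, field-capacity and wilting-point
WFPS) live here so that every stage of the pipeline reads the same values.

Ambient isotopic composition of tropospheric N₂O and the bulk-δ¹⁵N
endmember boxes are literature-style defaults, not site measurements;
they are meant to be overridden from a config file for real campaigns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Grams of N per mole of N₂O (two N atoms at 14 g mol⁻¹); the basis of
#: the µg N₂O-N flux unit.
M_N2O_N = 28.0


@dataclass(frozen=True)
class EndmemberBox:
    """Rectangular prior for one N₂O production pathway in (SP, bulk) space.

    ``sp_range`` carries the site-preference fingerprint that separates
    pathways; ``bulk_range`` is broad and overlapping by nature.
    """

    pathway: str
    sp_range: tuple[float, float]
    bulk_range: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.sp_range, self.bulk_range):
            if lo > hi:
                raise ValueError(f"range lower bound {lo} exceeds upper {hi}")


@dataclass(frozen=True)
class ReductionModel:
    """Net isotope effects of N₂O reduction to N₂ and the prior on its extent.

    ``eps_sp`` and ``eps_bulk`` are the net (closed-system Rayleigh)
    enrichment factors in per mil; both negative, so the residual emitted
    pool is enriched as reduction proceeds.  ``r_max`` bounds the uniform
    prior on the reduced fraction r ∈ [0, r_max).
    """

    eps_sp: float = -5.0
    eps_bulk: float = -7.0
    eps_d18o: float = -15.0
    r_max: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_sp >= 0 or self.eps_bulk >= 0:
            raise ValueError("reduction isotope effects must be negative")
        if not 0.0 <= self.r_max < 1.0:
            raise ValueError("r_max must lie in [0, 1)")


# Site-preference boxes quoted for the pathway groups: the combined
# bacterial-denitrification + nitrifier-denitrification group sits near 0 ‰,
# nitrification near +33…+38 ‰.  Bulk ranges are wide literature-style
# intervals (soil-emitted N₂O is strongly depleted in 15N) — NOT site values.
DEFAULT_DEN_BOX = EndmemberBox("bD+nD", sp_range=(-5.0, 5.0), bulk_range=(-45.0, 5.0))
DEFAULT_NIT_BOX = EndmemberBox("Ni", sp_range=(33.0, 38.0), bulk_range=(-60.0, -10.0))


@dataclass
class PipelineConfig:
    """Every tunable the pipeline reads, with field-campaign defaults."""

    # chamber geometry & site meteorology
    chamber_height: float = 0.3          # m
    pressure: float = 96600.0            # Pa (≈443 m a.s.l.)

    # acceptance gates
    r2_min: float = 0.7                  # flux and Keeling regression gate
    flux_min: float = 75.0               # µg N2O-N m-2 h-1
    quality_thresholds: tuple[float, float, float] = (4.0, 6.0, 8.0)  # ‰, Q1/Q2/Q3

    # ambient (tropospheric background) reference — literature-style values
    ambient_conc: float = 330.0          # ppb
    ambient_d15_bulk: float = 6.7        # ‰
    ambient_sp: float = 18.7             # ‰
    ambient_d18o: float = 44.6           # ‰

    # source-partition priors
    den_box: EndmemberBox = field(default_factory=lambda: DEFAULT_DEN_BOX)
    nit_box: EndmemberBox = field(default_factory=lambda: DEFAULT_NIT_BOX)
    reduction: ReductionModel = field(default_factory=ReductionModel)
    likelihood_sd_bulk: float = 2.0      # ‰, Gaussian likelihood on bulk residual
    obs_sd_sp: float = 0.5               # ‰, measurement sd of the SP intercept
    obs_sd_bulk: float = 0.5             # ‰, measurement sd of the bulk intercept
    n_draws: int = 10000

    # soil water
    fc_wfps: float = 78.87               # % WFPS at field capacity
    wp_wfps: float = 39.33               # % WFPS at wilting point
    bulk_density: float = 1.39           # g cm-3
    particle_density: float = 2.65       # g cm-3

    seed: int = 0

    @property
    def ambient_d15a(self) -> float:
        return self.ambient_d15_bulk + self.ambient_sp / 2.0

    @property
    def ambient_d15b(self) -> float:
        return self.ambient_d15_bulk - self.ambient_sp / 2.0

    def __post_init__(self) -> None:
        q1, q2, q3 = self.quality_thresholds
        if not q1 < q2 < q3:
            raise ValueError("quality thresholds must be strictly ordered")
        for name in ("chamber_height", "pressure", "ambient_conc",
                     "bulk_density", "particle_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bulk_density >= self.particle_density:
            raise ValueError("bulk density must be below particle density")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["den_box"]["sp_range"] = list(d["den_box"]["sp_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("den_box", "nit_box"):
            if key in d and isinstance(d[key], dict):
                b = d[key]
                d[key] = EndmemberBox(b["pathway"], tuple(b["sp_range"]),
                                      tuple(b["bulk_range"]))
        if "reduction" in d and isinstance(d["reduction"], dict):
            d["reduction"] = ReductionModel(**d["reduction"])
        if "quality_thresholds" in d:
            d["quality_thresholds"] = tuple(d["quality_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
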