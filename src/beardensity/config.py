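"""Configuration for the synthetic study system.

`SimConfig` describes the landscape and sampling design; `TrueParams`
holds the generating parameters of the bear population and the
detection process. Together with a seed they fully determine every
simulated dataset.

Defaults emulate the southwestern Alberta study system: a ~3,600 km^2
landscape split 52/34/14% between private, Crown, and protected land,
rub-object and fence-line detectors surveyed over seven systematic
21-day occasions, plus one pooled opportunistic occasion gridded at
7 x 7 km.
"""
from __future__ import annotations

from dataclasses import dataclass, field


def _default_covariates() -> dict:
    # Synthetic stand-ins for the gridded habitat covariates used by the
    # density and selection models. Kinds:
    #   smooth        - seeded harmonic field rescaled to [low, high]
    #   patch         - one disc of 1s covering `fraction` of the extent
    #   tenure_levels - piecewise constant by tenure block
    #   lndist        - ln(distance + 0.1 km) to seeded linear features
    return {
        "ndvi": {"kind": "smooth", "low": 0.0, "high": 1.0},
        "canopy": {"kind": "smooth", "low": 0.0, "high": 100.0},
        "burn": {"kind": "patch", "fraction": 0.05},
        "harvest": {
            "kind": "tenure_levels",
            "levels": {"private": 2.0, "crown": 1.0, "protected": 0.0},
        },
        "water": {"kind": "lndist", "n_lines": 2},
        "tertiary_rd": {"kind": "lndist", "n_lines": 3},
        "rddens": {"kind": "smooth", "low": 0.0, "high": 1.5},
    }


@dataclass
class SimConfig:
    """Landscape and sampling design of the synthetic study.

    extent : (width, height) of the rectangular landscape, km.
    cell_spacing : landscape grid spacing, km.
    tenure_proportions : fractions of area for (private, crown, protected);
        must sum to 1. Defaults mirror the study area's 52/34/14 split.
    covariates : per-covariate generator specs, see `_default_covariates`.
    n_rub, n_fence : numbers of rub-object and fence-line detectors.
    opp_cell_size : edge (km) of the opportunistic sampling grid cells.
    n_occasions : total occasions; the last one is the pooled
        opportunistic occasion, the others are systematic surveys.
    seed : master seed; all downstream randomness derives from it.
    """

    extent: tuple = (60.0, 60.0)
    cell_spacing: float = 2.0
    tenure_proportions: tuple = (0.52, 0.34, 0.14)
    covariates: dict = field(default_factory=_default_covariates)
    n_rub: int = 120
    n_fence: int = 30
    opp_cell_size: float = 7.0
    n_occasions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ValueError("extent dimensions must be positive")
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be positive")
        if abs(sum(self.tenure_proportions) - 1.0) > 1e-9:
            raise ValueError("tenure proportions must sum to 1")
        if len(self.tenure_proportions) != 3:
            raise ValueError("three tenure proportions required")
        if min(self.n_rub, self.n_fence, self.n_occasions) < 0:
            raise ValueError("counts must be non-negative")
        if self.opp_cell_size <= 0:
            raise ValueError("opp_cell_size must be positive")


@dataclass
class TrueParams:
    """Generating parameters for one sex cohort.

    Density is log-linear over landscape covariates:
    ln D(x) = density_intercept + sum(density_beta) with D in bears/km^2.
    Keys of `density_beta` are either plain covariate names (linear
    terms) or ``"tenure:<level>"`` indicators.

    Detection follows the hazard half-normal model. `lambda0` is the
    baseline cumulative detection hazard for a naive animal at a rub
    object on occasion T=0; `sigma` the baseline spatial scale (km).
    Multiplicative (log-scale) effects: trap type, trap-specific
    behavioral response (bk, switched on after an individual's first
    detection at a site), linear time trend T (0-based occasion index),
    and grizzly bear presence GB.
    """

    density_intercept: float = -2.8  # ln(bears/km^2); ~61 bears/1,000 km^2
    density_beta: dict = field(
        default_factory=lambda: {"tenure:private": -0.45, "tenure:crown": -0.9}
    )
    lambda0: float = 0.03
    beta_traptype: dict = field(
        default_factory=lambda: {"fence": -0.7, "opp": 0.1}
    )
    beta_bk: float = 1.7
    beta_T: float = 0.0
    beta_GB: float = 0.0
    sigma: float = 3.0
    sigma_beta_traptype: dict = field(
        default_factory=lambda: {"fence": 0.0, "opp": 0.5}
    )
    sigma_beta_T: float = 0.0
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lambda0 <= 0:
            raise ValueError("baseline lambda0 must be positive")
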