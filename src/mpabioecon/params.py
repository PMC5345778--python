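"""Parameter blocks for the cod fishery–MPA simulator.

Defaults reproduce the published Atlantic cod (*Gadus morhua*)
parameterization for eastern Canada: von Bertalanffy growth, a logistic
maturity ogive with 50% maturity at 4 y, fecundity of 0.5 million eggs per kg
of female, Beta-distributed larval mortality, truncated-normal adult natural
mortality, e-folding dispersal kernels (156 km larval / 272 km adult), an
FMSY-based quota rule with a 10 kt moratorium trigger, and a mixed-fleet
profitability ratio of 1.6.

Each block is a plain dataclass so configurations serialize cleanly and the
sensitivity driver can perturb single fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any


@dataclass
class LifeHistoryParams:
    """Growth, maturation and reproduction parameters.

    ``age_mat_steepness`` defaults to ln(99)/2 so that the logistic ogive puts
    1% maturity at age 2 and 99% at age 6, matching the midpoint-at-4
    description ("begin maturing at 2 y, 50% at 4 y, all mature at 6 y").
    """

    k_mean: float = 0.13              # VB growth coefficient, 1/yr
    L_inf: float = 120.0              # asymptotic length, cm
    t0: float = 0.0                   # VB age at zero length, yr
    lw_a: float = 0.0085              # length-weight coefficient, g cm^-b
    lw_b: float = 3.0                 # length-weight exponent
    age_mat_mid: float = 4.0          # age at 50% maturity, yr
    age_mat_steepness: float = math.log(99.0) / 2.0  # 1/yr
    fecundity: float = 5.0e5          # eggs per kg of female
    female_fraction: float = 0.5
    min_age_migration: int = 6        # yr, shared with DispersalParams
    initial_abun: float = 2.5e8       # fish at initialization
    max_age: int = 25                 # oldest tracked cohort, yr


@dataclass
class MortalityParams:
    """Non-fishing mortality: larval, adult, and density-dependent recruitment.

    Larval mortality ~ Beta(1000, 1.2) per cell-year (mean 99.88%, 1st–99th
    percentile range ~98.98–99.99%). Adult mortality ~ Normal(0.5938, 0.0517)
    clipped to [0, 1]. ``bh_slope`` is the Beverton–Holt low-density
    settler-to-recruit survival; see docs/methods.md for its calibration.
    """

    larval_alpha: float = 1000.0
    larval_beta: float = 1.2
    adult_mu: float = 0.5938
    adult_sd: float = 0.0517
    bh_slope: float = 0.03            # settler->recruit survival at low density
    K_mean: float = 0.43              # carrying capacity mean, t km^-2
    K_sd: float = 0.38                # carrying capacity SD, t km^-2


@dataclass
class DispersalParams:
    larval_speed: float = 2.0         # random-walk speed, cm s^-1
    pld: float = 90.0                 # planktonic larval duration, days
    e_fold_larvae: float = 156.0      # larval kernel e-folding scale, km
    e_fold_adult: float = 272.0       # adult kernel e-folding scale, km
    min_age_migration: int = 6        # age at which adults start migrating, yr


@dataclass
class FisheryParams:
    fmsy: float = 0.28                # fishing mortality at MSY, 1/yr
    quota_fraction: float = 2.0 / 3.0  # precautionary fraction of FMSY
    survey_fraction: float = 0.001    # fraction of EEZ cells surveyed
    min_length_catch: float = 38.0    # cm, below this fish are not targeted
    min_age_catch: int = 4            # yr
    moratorium_threshold: float = 10_000.0  # t; closure when biomass below
    price: float = 1.24               # landed price, CAD kg^-1


@dataclass
class EconParams:
    """Cost-benefit parameters.

    ``profitability_ratio`` is the mixed-fleet landed-value / operating-cost
    ratio (~1.6). ``distance_variable_share`` is the fraction of operating
    cost (fuel + labour) that scales with fishing distance relative to the
    Status-Quo baseline distance; it is not a published number and is swept in
    the sensitivity suite. ``baseline_distance`` is the Status-Quo
    catch-weighted mean distance; left ``None`` it is computed from a
    Status-Quo calibration run.
    """

    price: float = 1.24               # CAD kg^-1, shared with FisheryParams
    profitability_ratio: float = 1.6
    distance_variable_share: float = 0.6
    baseline_distance: float | None = None  # km
    sdr_set: tuple[float, ...] = (0.015, 0.03, 0.06)


def params_to_dict(p: Any) -> dict:
    """Flat ``field -> value`` mapping for logging and serialization."""
    return {f.name: getattr(p, f.name) for f in fields(p)}


def perturb(p: Any, name: str, value: Any):
    """Return a copy of parameter block ``p`` with ``name`` set to ``value``."""
    if name not in {f.name for f in fields(p)}:
        raise KeyError(name)
    return replace(p, **{name: value})
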