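"""RBE, CBE, RBE-weighted dose and photon-isoeffective dose.

The photon reference survival is the plain LQ curve S = exp(-alpha_g d -
beta0 d^2), whose alpha term alpha_g = alpha0 + beta0 zbar_dD(photon)
carries the photon field's domain dose-mean (0.0634 /Gy for the reference
60Co field and parameter set).  Inverting it at the survival level S reached
by a test field at kerma dose D gives

    RBE or CBE = [-alpha_g + sqrt(alpha_g^2 - 4 beta0 ln S)] / (2 beta0 D),

and the numerator alone (divided by 2 beta0) is the photon-isoeffective
dose.  "CBE" is reserved for the boron component, whose effectiveness
depends on the compound's microdistribution through kappa_B and the mixed
single-event PDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .microdose import mix_compartment_pds
from .survival import SMKParams, SurvivalModel
from .transport import CompartmentWeights, NucleusDoseCoefficients, kappa_B

__all__ = [
    "PhotonReference",
    "alpha_gamma",
    "rbe_cbe",
    "photon_isoeffective_dose",
    "dose_at_sf",
    "rbe_at_sf",
    "rbe_weighted_dose",
    "JCDS_FACTORS",
    "effectiveness_report",
    "build_boron_model",
]

#: fixed RBE/CBE constants of the JAEA computational dosimetry system (JCDS)
JCDS_FACTORS = {
    "BPA": {"boron": 3.8, "hydrogen": 2.5, "nitrogen": 2.5, "photon": 1.0},
    "BSH": {"boron": 2.5, "hydrogen": 2.5, "nitrogen": 2.5, "photon": 1.0},
}


@dataclass(frozen=True)
class PhotonReference:
    """LQ parameters of the reference photon field."""

    alpha_gamma: float  # 1/Gy
    beta0: float        # 1/Gy^2, shared with the SMK beta0

    def __post_init__(self) -> None:
        if self.alpha_gamma <= 0 or self.beta0 < 0:
            raise ValueError("photon reference parameters must be positive")

    def sf(self, dose: float) -> float:
        return float(np.exp(-self.alpha_gamma * dose - self.beta0 * dose**2))


def alpha_gamma(params: SMKParams, photon_zdD: float) -> float:
    """Photon alpha term alpha0 + beta0 zbar_dD(photon)."""
    if photon_zdD < 0:
        raise ValueError("photon domain dose-mean must be non-negative")
    return params.alpha0 + params.beta0 * photon_zdD


def photon_isoeffective_dose(survival: float, ref: PhotonReference) -> float:
    """Photon dose giving the same survival; 0 at S = 1."""
    if not 0 < survival <= 1:
        raise ValueError("survival must lie in (0, 1]")
    if survival == 1.0:
        return 0.0
    logs = np.log(survival)
    if ref.beta0 < 1e-12:
        return -logs / ref.alpha_gamma
    disc = ref.alpha_gamma**2 - 4.0 * ref.beta0 * logs
    return (-ref.alpha_gamma + np.sqrt(disc)) / (2.0 * ref.beta0)


def rbe_cbe(survival: float, dose: float, ref: PhotonReference) -> float:
    """Effectiveness of a field reaching *survival* at kerma dose *dose*."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if not 0 < survival < 1:
        raise ValueError("survival must lie in (0, 1)")
    return photon_isoeffective_dose(survival, ref) / dose


def dose_at_sf(survival_fn: Callable[[float], float], sf_level: float,
               d_max: float = 400.0, xtol: float = 1e-4) -> float:
    """Dose at which the survival curve crosses *sf_level* (bisection)."""
    if not 0 < sf_level < 1:
        raise ValueError("sf level must lie in (0, 1)")
    d_hi = 1.0
    while survival_fn(d_hi) > sf_level:
        d_hi *= 2.0
        if d_hi > d_max:
            raise ValueError(f"survival does not reach {sf_level} below {d_max} Gy")
    return brentq(lambda d: survival_fn(d) - sf_level, d_hi / 2.0 if d_hi > 1
                  else 1e-9, d_hi, xtol=xtol)


def rbe_at_sf(survival_fn: Callable[[float], float], sf_level: float,
              ref: PhotonReference, d_max: float = 400.0) -> float:
    """RBE (or CBE, for the boron component) at a fixed survival level."""
    d_star = dose_at_sf(survival_fn, sf_level, d_max=d_max)
    return rbe_cbe(sf_level, d_star, ref)


def rbe_weighted_dose(component_kerma: dict, factors: dict) -> float:
    """Fixed-factor weighted dose sum_i factor_i D_i (Gy-equivalent)."""
    total = 0.0
    for name, d in component_kerma.items():
        if d == 0:
            continue
        if name not in factors:
            raise KeyError(f"no RBE/CBE factor supplied for component {name!r}")
        total += factors[name] * d
    return total


def effectiveness_report(survival_fns: dict, ref: PhotonReference,
                         levels=(0.5, 0.1, 0.01)) -> pd.DataFrame:
    """RBE/CBE at fixed survival levels for each component or condition.

    Rows follow the insertion order of *survival_fns*; columns are labelled
    RBE_50 / RBE_10 / RBE_1 style by survival percentage.
    """
    cols = {f"RBE_{level * 100:g}": level for level in levels}
    rows = {}
    for name, fn in survival_fns.items():
        rows[name] = {col: rbe_at_sf(fn, level, ref)
                      for col, level in cols.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def build_boron_model(params: SMKParams, coeffs: NucleusDoseCoefficients,
                      nucleus_pds: dict, domain_pds: dict,
                      weights: CompartmentWeights, x: float = 1.0,
                      dose_rate_gy_h: float | None = None,
                      irradiation_time_h: float | None = None,
                      n_grid: int = 2**13) -> SurvivalModel:
    """Survival model of the pure boron component for one compound.

    Mixes the per-compartment nucleus and domain PDs with the compound's
    10B weights (scaled by the concentration factor x) and attaches the
    kappa_B conversion from boron kerma dose to mean nucleus dose.
    """
    w = weights.scaled(x)
    f_n1 = mix_compartment_pds(nucleus_pds, w)
    zdD = mix_compartment_pds(domain_pds, w).z_D
    kap = kappa_B(coeffs, weights, x)
    return SurvivalModel(params=params, f_n1=f_n1, zdD=zdD, kappa=kap,
                         dose_rate_gy_h=dose_rate_gy_h,
                         irradiation_time_h=irradiation_time_h, n_grid=n_grid)
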