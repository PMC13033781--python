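"""Gas-liquid partitioning of N2O between headspace and medium.

Dissolved N2O is computed from instantaneous Henry's-law equilibrium with
the Weiss & Price (1980)-type solubility function evaluated at salinity 0
(the BG11_0 medium is dilute freshwater). Vials are shaken at 80 rpm, so no
kinetic mass-transfer term is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .vial_gas import GasState, VialConfig, headspace_capacity, moles_of

__all__ = [
    "SolubilityModel",
    "WEISS_PRICE_N2O",
    "henry_constant_n2o",
    "dissolved_amount",
    "total_pool",
    "n2o_capacity",
]


@dataclass(frozen=True)
class SolubilityModel:
    """Coefficients of ln K0 = a1 + a2 (100/T) + a3 ln(T/100) + S [b1 + b2 (T/100) + b3 (T/100)^2].

    K0 is the solubility in mol L-1 atm-1; the b-terms vanish at the
    default salinity of 0 permil.
    """

    a1: float
    a2: float
    a3: float
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    salinity: float = 0.0
    t_min_k: float = 273.15
    t_max_k: float = 313.15

    def k0(self, temperature_k: float) -> float:
        if not (self.t_min_k <= temperature_k <= self.t_max_k):
            raise ValueError(
                f"temperature {temperature_k} K outside valid range "
                f"[{self.t_min_k}, {self.t_max_k}] K"
            )
        t100 = temperature_k / 100.0
        ln_k0 = (
            self.a1
            + self.a2 / t100
            + self.a3 * math.log(t100)
            + self.salinity * (self.b1 + self.b2 * t100 + self.b3 * t100 * t100)
        )
        return math.exp(ln_k0)


#: Freshwater N2O solubility fit (mol L-1 atm-1 form, salinity 0).
WEISS_PRICE_N2O = SolubilityModel(
    a1=-62.7062,
    a2=97.3066,
    a3=24.1406,
    b1=-0.058420,
    b2=0.033193,
    b3=-0.0051313,
)


def henry_constant_n2o(temperature_k: float, model: SolubilityModel = WEISS_PRICE_N2O) -> float:
    """N2O solubility K0(T) in mol L-1 atm-1 (freshwater default)."""
    return model.k0(temperature_k)


def dissolved_amount(state: GasState, vial: VialConfig, k0: float) -> float:
    """Dissolved N2O at equilibrium, umol: n = x P K0 V_liq."""
    p = state.x("N2O_46") * vial.pressure_atm
    return _dissolved_from_partial(p, vial, k0)


def _dissolved_from_partial(partial_atm: float, vial: VialConfig, k0: float) -> float:
    return 1e6 * partial_atm * k0 * (vial.liquid_volume_ml / 1000.0)


def total_pool(state: GasState, vial: VialConfig, k0: float, species: str = "N2O_46") -> float:
    """Headspace plus dissolved amount of an N2O isotopologue, umol."""
    gas = moles_of(state, species, vial)
    p = state.x(species) * vial.pressure_atm
    return gas + _dissolved_from_partial(p, vial, k0)


def n2o_capacity(vial: VialConfig, k0: float) -> float:
    """Combined two-phase capacity for N2O, umol per atm partial pressure.

    n_total = p * [V_head/(R T) + K0 V_liq]; dividing the total pool by
    this capacity recovers the equilibrium partial pressure.
    """
    return headspace_capacity(vial) + 1e6 * k0 * (vial.liquid_volume_ml / 1000.0)
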