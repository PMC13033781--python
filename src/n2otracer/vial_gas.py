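"""Deterministic headspace-gas accounting for a sealed incubation vial.

The experimental unit is a 100 mL serum vial holding 30 mL of medium at
25 degC and 1 atm total pressure. Gas mixtures are prepared volumetrically
(e.g. 95 mL N2 + 5 mL CO2), spiked with small volumes of labeled N2O, and
converted to molar amounts with the ideal gas law.

Two volume bases coexist deliberately: mixing ratios (ppm) refer to the
introduced-gas volume (nominally 100 mL, the basis on which a 0.1 mL spike
of 10% N2O reads "100 ppm"), while molar amounts use the actual headspace
volume (70 mL once the medium is in place). ``VialConfig`` carries both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .species import NOMINAL_N_MASS, R_L_ATM, SPECIES, n_atoms

__all__ = [
    "VialConfig",
    "GasState",
    "mixture_from_volumes",
    "apply_spike",
    "moles_of",
    "headspace_capacity",
    "nitrogen_mass",
    "ppm",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class VialConfig:
    """Geometry and state of one sealed incubation vial.

    Parameters
    ----------
    total_volume_ml
        Nominal vial volume (introduced-gas basis for mixing ratios), mL.
    liquid_volume_ml
        Medium volume, mL. Headspace volume is the difference.
    temperature_k
        Incubation temperature, K.
    pressure_atm
        Total headspace pressure, atm. Held fixed; sampling-induced
        pressure changes are ignored.
    """

    total_volume_ml: float = 100.0
    liquid_volume_ml: float = 30.0
    temperature_k: float = 298.15
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.total_volume_ml <= 0:
            raise ValueError("total_volume_ml must be positive")
        if self.liquid_volume_ml < 0:
            raise ValueError("liquid_volume_ml must be non-negative")
        if self.headspace_volume_ml <= 0:
            raise ValueError("headspace volume must be positive (liquid >= total)")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be positive")
        if self.pressure_atm <= 0:
            raise ValueError("pressure_atm must be positive")

    @property
    def headspace_volume_ml(self) -> float:
        return self.total_volume_ml - self.liquid_volume_ml


@dataclass(frozen=True)
class GasState:
    """Mole fractions of all headspace species; a simplex over the vocabulary."""

    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        for name, x in self.fractions.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"fraction of {name} out of [0, 1]: {x}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"mole fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "fractions", dict(self.fractions))

    def x(self, species: str) -> float:
        """Mole fraction of *species* (0 if absent)."""
        if species not in SPECIES:
            raise ValueError(f"unknown species: {species!r}")
        return self.fractions.get(species, 0.0)


def mixture_from_volumes(component_volumes: Mapping[str, float]) -> GasState:
    """Gas state from component volumes at equal pressure (v_i / sum v)."""
    unknown = set(component_volumes) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    if any(v < 0 for v in component_volumes.values()):
        raise ValueError("component volumes must be non-negative")
    total = sum(component_volumes.values())
    if total <= 0:
        raise ValueError("at least one component volume must be positive")
    return GasState({s: v / total for s, v in component_volumes.items() if v > 0})


def apply_spike(
    base: GasState,
    base_volume_ml: float,
    spike_volume_ml: float,
    spike_purity: float,
    spike_species: str,
) -> GasState:
    """Add a small gas spike to a base mixture and renormalize.

    The spike contributes ``spike_volume * purity`` of the spiked species;
    its carrier is assumed to match the base composition, so the remaining
    species are rescaled proportionally to fill the simplex.
    """
    if spike_volume_ml < 0:
        raise ValueError("spike volume must be non-negative")
    if not (0.0 <= spike_purity <= 1.0):
        raise ValueError("spike purity must be in [0, 1]")
    if base_volume_ml <= 0:
        raise ValueError("base volume must be positive")
    if spike_species not in SPECIES:
        raise ValueError(f"unknown species: {spike_species!r}")
    if spike_volume_ml == 0:
        return base

    total = base_volume_ml + spike_volume_ml
    x_spike = (base.x(spike_species) * base_volume_ml + spike_volume_ml * spike_purity) / total
    others = {s: x for s, x in base.fractions.items() if s != spike_species}
    other_sum = sum(others.values())
    scale = (1.0 - x_spike) / other_sum if other_sum > 0 else 0.0
    fractions = {s: x * scale for s, x in others.items()}
    fractions[spike_species] = x_spike
    return GasState(fractions)


def headspace_capacity(vial: VialConfig) -> float:
    """Headspace molar capacity, umol per atm of partial pressure (V/RT)."""
    v_l = vial.headspace_volume_ml / 1000.0
    return 1e6 * v_l / (R_L_ATM * vial.temperature_k)


def moles_of(state: GasState, species: str, vial: VialConfig) -> float:
    """Headspace amount of *species* in umol: n = x P V / (R T)."""
    return state.x(species) * vial.pressure_atm * headspace_capacity(vial)


def nitrogen_mass(amount_umol: float, species: str) -> float:
    """Convert a molar amount of a nitrogenous gas to ug-N.

    Uses the nominal mass convention (14 g/mol per N atom for every
    isotopologue), so 1 umol of 30N2 and 1 umol of 46N2O are both 28 ug-N.
    """
    atoms = n_atoms(species)
    if atoms == 0:
        raise ValueError(f"{species!r} contains no nitrogen")
    return amount_umol * atoms * NOMINAL_N_MASS


def ppm(state: GasState, species: str) -> float:
    """Mixing ratio of *species* in ppmv."""
    return state.x(species) * 1e6
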