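"""Controlled vocabulary and physical constants shared across the package.

Species names are fixed strings used in every gas state, time series, CSV
file and scenario config. Isotopologues are distinguished by nominal
molecular mass (``N2_30`` = 15N15N, ``N2O_46`` = 15N15N16O).
"""

from __future__ import annotations

#: Headspace species tracked by the vial accounting.
SPECIES: tuple[str, ...] = (
    "He",
    "N2_28",
    "N2_30",
    "O2",
    "CO2",
    "N2O_44",
    "N2O_46",
    "C2H2",
    "C2H4",
)

#: Nitrogen atoms per molecule (species absent here carry no nitrogen).
N_ATOMS: dict[str, int] = {
    "N2_28": 2,
    "N2_30": 2,
    "N2O_44": 2,
    "N2O_46": 2,
}

#: 15N atoms per molecule under the no-scrambling convention (no 29N2, no 45N2O).
N15_ATOMS: dict[str, int] = {
    "N2_30": 2,
    "N2O_46": 2,
}

#: Nominal nitrogen atomic mass used for ALL isotopologues when reporting
#: ug-N (standard biogeochemistry convention; keeps unit comparability).
NOMINAL_N_MASS: float = 14.0  # g/mol per N atom

#: Natural 15N atom fraction (atmospheric N2, 0.366 atom%).
NATURAL_ABUNDANCE_15N: float = 0.00366

#: Gas constant in vial-friendly units.
R_L_ATM: float = 0.0820574  # L atm / (mol K)

#: Non-gas measurement channels allowed in time series files.
BIOMASS_VARIABLES: tuple[str, ...] = (
    "biomass_dry_g",
    "biomass_N_ug",
    "biomass_atom15",
    "sink_15N_ug",
)

#: Full variable vocabulary for long-format time series.
VOCABULARY: tuple[str, ...] = SPECIES + BIOMASS_VARIABLES

#: Unit strings (ASCII) attached to each variable in long-format output.
VARIABLE_UNITS: dict[str, str] = {
    **{s: "mole_fraction" for s in SPECIES},
    "biomass_dry_g": "g",
    "biomass_N_ug": "ug-N",
    "biomass_atom15": "atom_fraction",
    "sink_15N_ug": "ug-N",
}


def n_atoms(species: str) -> int:
    """Nitrogen atoms per molecule of *species*; 0 for nitrogen-free gases."""
    return N_ATOMS.get(species, 0)
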