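"""15N bookkeeping across gas isotopologues and biomass.

An :class:`IsotopePool` is a nitrogen mass (nominal ug-N) with its 15N atom
fraction, the form in which IR-MS biomass readings enter the pipeline.
The tracer is doubly labeled 46N2O (both N atoms 15N); 29N2 and 45N2O are
not tracked because isotopic scrambling is assumed absent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .species import NATURAL_ABUNDANCE_15N

__all__ = [
    "IsotopePool",
    "atom_excess",
    "excess_15N_mass",
    "tracer_derived_mass",
    "mix_pools",
    "isotopologue_split",
]


@dataclass(frozen=True)
class IsotopePool:
    """A nitrogen mass (ug-N, nominal convention) with its 15N atom fraction."""

    total_n_ug: float
    atom15: float

    def __post_init__(self) -> None:
        if self.total_n_ug < 0:
            raise ValueError("total_n_ug must be non-negative")
        if not (0.0 <= self.atom15 <= 1.0):
            raise ValueError("atom15 must be in [0, 1]")

    @property
    def n15_ug(self) -> float:
        """15N mass in the pool, ug (nominal convention)."""
        return self.total_n_ug * self.atom15


def atom_excess(pool: IsotopePool, baseline: float = NATURAL_ABUNDANCE_15N) -> float:
    """15N atom fraction above the unlabeled baseline.

    Negative values (possible with measurement bias) are retained, never
    clipped — they are what produces >100% budget closures downstream.
    """
    if not (0.0 <= baseline < 1.0):
        raise ValueError("baseline must be in [0, 1)")
    return pool.atom15 - baseline


def excess_15N_mass(pool: IsotopePool, baseline: float = NATURAL_ABUNDANCE_15N) -> float:
    """Excess 15N mass over baseline, ug-N: total_N x (atom15 - baseline)."""
    return pool.total_n_ug * atom_excess(pool, baseline)


def tracer_derived_mass(
    pool: IsotopePool,
    baseline: float = NATURAL_ABUNDANCE_15N,
    tracer_atom15: float = 1.0,
) -> float:
    """Nitrogen mass in the pool that originated from the tracer, ug-N.

    Two-end-member mixing between unlabeled nitrogen at *baseline* and
    tracer nitrogen at *tracer_atom15* (1.0 for the doubly labeled spike):

        m_tracer = total_N * (atom15 - baseline) / (tracer_atom15 - baseline)

    This is the budget's "fixed" term; unlike :func:`excess_15N_mass` it
    counts the tracer atoms that happen to sit at the baseline share, which
    is what makes a sink-free, bias-free budget close at exactly 100%.
    """
    if tracer_atom15 <= baseline:
        raise ValueError("tracer_atom15 must exceed baseline")
    return pool.total_n_ug * atom_excess(pool, baseline) / (tracer_atom15 - baseline)


def mix_pools(a: IsotopePool, b: IsotopePool) -> IsotopePool:
    """Combine two pools with exact 15N mass conservation.

    The mixture's atom fraction is the mass-weighted mean; mixing with an
    empty pool is the identity, and two empty pools return an empty pool at
    natural abundance.
    """
    total = a.total_n_ug + b.total_n_ug
    if total == 0:
        return IsotopePool(0.0, NATURAL_ABUNDANCE_15N)
    atom15 = (a.n15_ug + b.n15_ug) / total
    return IsotopePool(total, atom15)


def isotopologue_split(p28: float, p30: float) -> float:
    """Fraction of the N2-fixation flux drawn from 30N2.

    Nitrogenase does not discriminate between isotopologues here, so the
    flux splits in proportion to partial pressures (or amounts — any common
    basis). Raises if the total N2 pool is empty.
    """
    if p28 < 0 or p30 < 0:
        raise ValueError("partial pressures must be non-negative")
    total = p28 + p30
    if total <= 0:
        raise ValueError("isotopologue_split undefined for an empty N2 pool")
    return p30 / total
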