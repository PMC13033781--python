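"""Forward simulation of a closed-vial 15N2O incubation.

The generator is the stand-in for the study's raw instrument data. It
integrates a two-step transfer chain

    46N2O --(nitrogenase reduction)--> 30N2 --(N2 fixation)--> biomass 15N

inside a sealed vial, together with photoautotrophic growth, O2
accumulation from photosynthesis, an unmeasured sink that diverts a fixed
fraction of the reduced nitrogen, and gas-liquid partitioning of N2O at
every step. A measurement layer replicates the trajectory and adds
seeded instrument noise plus an optional additive bias on the biomass
atom-fraction channel (the minimal representation of the over-closure
artifact seen with N2-based headspaces).

Rate laws
---------
``empirical_first_order`` (default for packaged runs): the volumetric N2O
consumption is first order in the N2O partial pressure with an effective,
biomass-specific constant ``k_red`` (ug-N per g dry biomass per day per
atm). ``competitive_MM`` is an exploratory mode in which N2O reduction and
N2 fixation are competitive Michaelis-Menten partners on nitrogenase:

    v_red = Vmax_red * p46 / (K_N2O (1 + p28/Km_N2) + p46)
    v_fix = Vmax_fix * pN2 / (Km_N2 (1 + p46/K_N2O) + pN2)

with the printed Km_N2 = 0.04 atm; K_N2O is never printed and stays a free
scenario parameter. With acetylene in the headspace, N2 fixation is
replaced by Michaelis-Menten ethylene production (Ks = 0.005 atm) and N2O
reduction is inhibited (acetylene occupies nitrogenase).

Integration uses fixed-step classical RK4 (default step 0.01 day). RK4
preserves linear invariants exactly, so total 15N and 14N are conserved to
floating-point rounding — the property the budget accountancy relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .equilibrium import henry_constant_n2o, n2o_capacity
from .isotopes import isotopologue_split
from .species import NATURAL_ABUNDANCE_15N
from .timeseries import TimeSeries
from .vial_gas import GasState, VialConfig, headspace_capacity

__all__ = [
    "RunScenario",
    "simulate",
    "measure",
    "DEFAULT_NOISE_SD",
    "INSTRUMENT_OF",
    "competitive_reduction_rate",
]

#: Which instrument reads which channel (drives the noise model).
INSTRUMENT_OF: Mapping[str, str] = {
    "N2O_44": "gc_ecd",
    "N2O_46": "gc_ecd",
    "O2": "gc_ecd",
    "N2_28": "gc_ms",
    "N2_30": "gc_ms",
    "C2H2": "gc_fid",
    "C2H4": "gc_fid",
    "biomass_atom15": "irms_atom",
    "biomass_N_ug": "irms_n",
    "biomass_dry_g": "balance",
}

#: Default per-instrument noise. Relative (fractional sd) everywhere except
#: the IR-MS atom-fraction channel, which gets additive sd in atom fraction.
DEFAULT_NOISE_SD: Mapping[str, float] = {
    "gc_ecd": 0.02,
    "gc_ms": 0.03,
    "gc_fid": 0.02,
    "irms_atom": 2e-4,
    "irms_n": 0.03,
    "balance": 0.05,
}

_ADDITIVE_INSTRUMENTS = frozenset({"irms_atom"})


@dataclass(frozen=True)
class RunScenario:
    """Full parameterization of one simulated incubation."""

    name: str
    vial: VialConfig
    initial_gas: GasState
    initial_biomass_g: float
    biomass_n_fraction: float = 0.10  # g-N per g dry biomass at inoculation
    initial_atom15: float = NATURAL_ABUNDANCE_15N
    growth_rate: float = 0.0  # d-1, light-period specific growth rate
    light_duty_cycle: float = 0.5  # 12 h light : 12 h dark
    diel_switching: bool = False  # square-wave light instead of duty factor
    rate_law_mode: str = "empirical_first_order"
    k_red: float = 0.0  # ug-N g-1 d-1 atm-1, effective N2O consumption constant
    vmax_red: float = 0.0  # ug-N g-1 d-1 (competitive_MM mode)
    k_n2o: float = 0.04  # atm; nitrogenase half-saturation for N2O (not printed; free)
    km_n2: float = 0.04  # atm; nitrogenase half-saturation for N2
    ks_c2h2: float = 0.005  # atm; half-saturation for acetylene
    vmax_fix: float = 0.0  # ug-N g-1 d-1, N2 fixation Vmax
    vmax_ara: float = 0.0  # umol C2H4 g-1 d-1, ethylene production Vmax
    o2_yield: float = 41700.0  # umol O2 per g of new dry biomass (~1 mol O2/mol C)
    o2_inhibition_k: float | None = None  # atm; optional 1/(1+pO2/K) factor on v_red
    sink_fraction: float = 0.0  # share of reduced N routed to an unmeasured pool
    atom15_bias: float = 0.0  # additive measurement bias on biomass atom fraction
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    sampling_days: tuple[float, ...] = tuple(float(d) for d in range(18))
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_law_mode not in ("empirical_first_order", "competitive_MM"):
            raise ValueError(f"unknown rate_law_mode: {self.rate_law_mode!r}")
        for attr in (
            "initial_biomass_g",
            "growth_rate",
            "k_red",
            "vmax_red",
            "k_n2o",
            "km_n2",
            "ks_c2h2",
            "vmax_fix",
            "vmax_ara",
            "o2_yield",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if not (0.0 <= self.sink_fraction < 1.0):
            raise ValueError("sink_fraction must be in [0, 1)")
        if not (0.0 <= self.light_duty_cycle <= 1.0):
            raise ValueError("light_duty_cycle must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.sampling_days) < 1 or any(d < 0 for d in self.sampling_days):
            raise ValueError("sampling_days must be non-negative")
        unknown = set(self.noise_sd) - set(DEFAULT_NOISE_SD)
        if unknown:
            raise ValueError(f"unknown instruments in noise_sd: {sorted(unknown)}")

    def with_(self, **kwargs) -> "RunScenario":
        return replace(self, **kwargs)


def competitive_reduction_rate(
    p46: float, p28: float, vmax_red: float, k_n2o: float, km_n2: float
) -> float:
    """Biomass-specific N2O reduction rate under competitive MM kinetics, ug-N/g/day."""
    p46 = max(p46, 0.0)
    p28 = max(p28, 0.0)
    return vmax_red * p46 / (k_n2o * (1.0 + p28 / km_n2) + p46)


# State vector layout for the integrator.
_I_N46, _I_N30, _I_N28, _I_O2, _I_C2H2, _I_C2H4, _I_B, _I_BIO14, _I_BIO15, _I_SINK15 = range(10)


def _initial_state(scen: RunScenario, head_cap: float, cap46: float) -> np.ndarray:
    g = scen.initial_gas
    p = scen.vial.pressure_atm
    bio_n = scen.initial_biomass_g * scen.biomass_n_fraction * 1e6  # ug-N
    y = np.zeros(10)
    y[_I_N46] = g.x("N2O_46") * p * cap46  # both phases, equilibrated at t=0
    y[_I_N30] = g.x("N2_30") * p * head_cap
    y[_I_N28] = g.x("N2_28") * p * head_cap
    y[_I_O2] = g.x("O2") * p * head_cap
    y[_I_C2H2] = g.x("C2H2") * p * head_cap
    y[_I_C2H4] = g.x("C2H4") * p * head_cap
    y[_I_B] = scen.initial_biomass_g
    y[_I_BIO15] = bio_n * scen.initial_atom15
    y[_I_BIO14] = bio_n - y[_I_BIO15]
    return y


def _mu_at(scen: RunScenario, t: float) -> float:
    """Effective specific growth rate at time t (duty factor or diel square wave)."""
    if not scen.diel_switching:
        return scen.growth_rate * scen.light_duty_cycle
    return scen.growth_rate if (t - math.floor(t)) < scen.light_duty_cycle else 0.0


def _rhs(t: float, y: np.ndarray, scen: RunScenario, head_cap: float, cap46: float) -> np.ndarray:
    b_nat = NATURAL_ABUNDANCE_15N
    p46 = max(y[_I_N46], 0.0) / cap46
    p30 = max(y[_I_N30], 0.0) / head_cap
    p28 = max(y[_I_N28], 0.0) / head_cap
    p_o2 = max(y[_I_O2], 0.0) / head_cap
    p_c2h2 = max(y[_I_C2H2], 0.0) / head_cap
    biomass = max(y[_I_B], 0.0)
    acetylene_mode = scen.initial_gas.x("C2H2") > 0

    # N2O reduction (46N2O -> 30N2), biomass-specific rate in ug-N/g/day
    if scen.rate_law_mode == "empirical_first_order":
        v_red = scen.k_red * p46
    else:
        v_red = competitive_reduction_rate(p46, p28, scen.vmax_red, scen.k_n2o, scen.km_n2)
    if acetylene_mode:
        v_red = 0.0  # acetylene occupies nitrogenase
    if scen.o2_inhibition_k is not None:
        v_red /= 1.0 + p_o2 / scen.o2_inhibition_k
    red_flux = v_red * biomass / 28.0  # umol N2O / day

    # N2 fixation or ethylene production
    eth_flux = 0.0
    fix_flux = 0.0
    f30 = 0.0
    if acetylene_mode:
        eth_flux = scen.vmax_ara * p_c2h2 / (scen.ks_c2h2 + p_c2h2) * biomass  # umol/day
    else:
        p_n2 = p28 + p30
        if p_n2 > 0.0 and scen.vmax_fix > 0.0:
            v_fix = scen.vmax_fix * p_n2 / (scen.km_n2 * (1.0 + p46 / scen.k_n2o) + p_n2)
            fix_flux = v_fix * biomass / 28.0  # umol N2 / day
            f30 = isotopologue_split(p28, p30)

    growth = _mu_at(scen, t) * biomass  # g/day

    dy = np.zeros(10)
    dy[_I_N46] = -red_flux
    dy[_I_N30] = (1.0 - scen.sink_fraction) * red_flux - fix_flux * f30
    dy[_I_N28] = -fix_flux * (1.0 - f30)
    dy[_I_O2] = scen.o2_yield * growth
    dy[_I_C2H2] = -eth_flux
    dy[_I_C2H4] = eth_flux
    dy[_I_B] = growth
    # biomass N gains: 30N2-derived nitrogen is pure 15N; ambient-N2-derived
    # nitrogen carries the natural 15N abundance (the 28N2 pool stands for
    # ambient N2, whose minor isotopologues are not tracked individually)
    dy[_I_BIO15] = 28.0 * fix_flux * (f30 + (1.0 - f30) * b_nat)
    dy[_I_BIO14] = 28.0 * fix_flux * (1.0 - f30) * (1.0 - b_nat)
    dy[_I_SINK15] = scen.sink_fraction * red_flux * 28.0
    return dy


def simulate(scenario: RunScenario, step: float = 0.01) -> TimeSeries:
    """Integrate a scenario and return the noise-free state trajectory.

    The output is a long-format :class:`TimeSeries` with replicate id 0,
    sampled at ``scenario.sampling_days``. Gas channels are reported as
    headspace mole fractions (N2O_46 from its two-phase pool via the
    equilibrium capacity), biomass as dry mass, total N and atom fraction,
    and the unmeasured sink as a 15N mass (dropped by :func:`measure`).
    """
    if step <= 0 or step > 0.01 + 1e-12:
        raise ValueError("step must be positive and <= 0.01 day")
    scen = scenario
    vial = scen.vial
    k0 = henry_constant_n2o(vial.temperature_k)
    head_cap = headspace_capacity(vial)
    cap46 = n2o_capacity(vial, k0)
    y = _initial_state(scen, head_cap, cap46)

    days = sorted(set(scen.sampling_days))
    records = []
    t = 0.0
    if days[0] == 0.0:
        records.append((0.0, y.copy()))
        targets = days[1:]
    else:
        targets = days
    for target in targets:
        span = target - t
        n_steps = max(1, math.ceil(span / step - 1e-9))
        h = span / n_steps
        for _ in range(n_steps):
            k1 = _rhs(t, y, scen, head_cap, cap46)
            k2 = _rhs(t + h / 2, y + h / 2 * k1, scen, head_cap, cap46)
            k3 = _rhs(t + h / 2, y + h / 2 * k2, scen, head_cap, cap46)
            k4 = _rhs(t + h, y + h * k3, scen, head_cap, cap46)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        t = target
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"integration diverged at day {t} (state: {y!r})")
        records.append((t, y.copy()))

    p_total = vial.pressure_atm
    const_fracs = {
        s: scen.initial_gas.x(s)
        for s in ("He", "CO2", "N2O_44")
        if scen.initial_gas.x(s) > 0
    }
    rows = []
    vial_id = f"{scen.name}-sim"
    for day, state in records:
        fracs = dict(const_fracs)
        fracs["N2O_46"] = state[_I_N46] / cap46 / p_total
        fracs["N2_30"] = state[_I_N30] / head_cap / p_total
        if scen.initial_gas.x("N2_28") > 0 or state[_I_N28] > 0:
            fracs["N2_28"] = state[_I_N28] / head_cap / p_total
        if scen.initial_gas.x("O2") > 0 or state[_I_O2] > 0:
            fracs["O2"] = state[_I_O2] / head_cap / p_total
        if scen.initial_gas.x("C2H2") > 0:
            fracs["C2H2"] = state[_I_C2H2] / head_cap / p_total
            fracs["C2H4"] = state[_I_C2H4] / head_cap / p_total
        for var, val in fracs.items():
            rows.append((vial_id, scen.name, 0, day, var, val))
        bio_n = state[_I_BIO14] + state[_I_BIO15]
        rows.append((vial_id, scen.name, 0, day, "biomass_dry_g", state[_I_B]))
        rows.append((vial_id, scen.name, 0, day, "biomass_N_ug", bio_n))
        atom15 = state[_I_BIO15] / bio_n if bio_n > 0 else NATURAL_ABUNDANCE_15N
        rows.append((vial_id, scen.name, 0, day, "biomass_atom15", atom15))
        rows.append((vial_id, scen.name, 0, day, "sink_15N_ug", state[_I_SINK15]))
    return TimeSeries.from_records(rows)


def measure(
    ts: TimeSeries, scenario: RunScenario, include_noise: bool = True
) -> TimeSeries:
    """Turn a state trajectory into replicated, noisy measurements.

    Each of ``scenario.replicates`` vials receives independent Gaussian
    noise per instrument channel (relative sd for GC and balance channels,
    additive sd for the IR-MS atom fraction); ``scenario.atom15_bias`` is
    always added to the biomass atom-fraction channel. The unmeasurable
    sink channel is dropped. Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    sd_of = {**DEFAULT_NOISE_SD, **dict(scenario.noise_sd)}
    base = ts.data[ts.data["variable"] != "sink_15N_ug"]
    frames = []
    for rep in range(1, scenario.replicates + 1):
        df = base.copy()
        df["replicate"] = rep
        values = df["value"].to_numpy(copy=True)
        for i, var in enumerate(df["variable"]):
            v = values[i]
            if var == "biomass_atom15":
                v = v + scenario.atom15_bias
            instrument = INSTRUMENT_OF.get(var)
            if include_noise and instrument is not None:
                sd = sd_of.get(instrument, 0.0)
                if sd > 0:
                    if instrument in _ADDITIVE_INSTRUMENTS:
                        v = v + rng.normal(0.0, sd)
                    else:
                        v = v * (1.0 + rng.normal(0.0, sd))
            if var == "biomass_atom15":
                v = min(max(v, 0.0), 1.0)
            values[i] = v
        df["value"] = values
        df["vial_id"] = [f"{scenario.name}-{rep}"] * len(df)
        frames.append(df)
    import pandas as pd

    return TimeSeries(pd.concat(frames, ignore_index=True))
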