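"""Packaged incubation scenarios mirroring the study's experimental runs.

The scenarios encode the stated experimental world: 100 mL vials with
30 mL of modified BG11_0 medium at 25 degC, a 12 h light:dark cycle,
triplicate vials, and a 0.1 mL spike of 10% (v/v) doubly labeled 46N2O
into the nominal 100 mL gas volume (100 ppm).

* Run A  — N2 (95 mL) / CO2 (5 mL) + 100 ppm 46N2O, washed inoculum
* Run B  — He (95 mL) / CO2 (5 mL) + 100 ppm 46N2O, washed inoculum
* Run C  — as Run B but without biomass (blank control)
* ARA    — He (85 mL) / CO2 (5 mL) / acetylene (10 mL), 12-day assay
* O2 series — He:O2:CO2 of 95:0:5, 90:5:5, 75:20:5, 65:30:5 + 100 ppm spike

Effective rate constants, the Run B sink fraction and the Run A
atom-fraction bias are *calibrated at construction time* so that the
analysis pipeline applied to the noise-free scenarios reproduces the
study's printed summary statistics: specific N2O consumption rates of
4.87e1 (Run A, N2-based) and 1.27e2 (Run B, He-based) ug-N/g/day, an
N2-fixation rate of 2.46e4 ug-N/g/day from the acetylene assay, and budget
closures of 74% (Run B) and 127% (Run A). Calibration is a deterministic
1-D root find through the actual simulate-then-fit pipeline.
"""

from __future__ import annotations

from functools import lru_cache

from scipy.optimize import brentq

from .analysis import (
    ara_to_fixation,
    nitrogen_amount_series,
    specific_consumption_rate,
    specific_ethylene_rate,
)
from .isotopes import IsotopePool
from .simulate import RunScenario, simulate
from .species import NATURAL_ABUNDANCE_15N
from .vial_gas import GasState, VialConfig, apply_spike, mixture_from_volumes

__all__ = [
    "packaged_scenarios",
    "spike_100ppm",
    "PRINTED_RATE_RUN_A",
    "PRINTED_RATE_RUN_B",
    "PRINTED_RATE_ARA",
    "PRINTED_CLOSURE_RUN_A",
    "PRINTED_CLOSURE_RUN_B",
]

# Printed summary statistics the packaged scenarios are calibrated against.
PRINTED_RATE_RUN_A = 4.87e1  # ug-N/g/day, N2-based headspace
PRINTED_RATE_RUN_B = 1.27e2  # ug-N/g/day, He-based headspace
PRINTED_RATE_ARA = 2.46e4  # ug-N/g/day, acetylene-reduction derived
PRINTED_CLOSURE_RUN_B = 74.0  # percent; 26% missing
PRINTED_CLOSURE_RUN_A = 127.0  # percent; over-closure from biomass-channel bias

_VIAL = VialConfig(total_volume_ml=100.0, liquid_volume_ml=30.0, temperature_k=298.15)

#: Inoculum for runs A-C: 1 mL of washed suspension at OD730 = 0.47,
#: converted with 0.30 g dry weight per liter per OD unit.
_INOCULUM_AB_G = 1e-3 * 0.47 * 0.30
#: Inoculum for the fixation/ARA assays: 0.2 mL at OD730 = 0.1.
_INOCULUM_ARA_G = 0.2e-3 * 0.1 * 0.30

_FIT_WINDOW = (0.0, 17.0)
_ARA_WINDOW = (0.0, 12.0)


def spike_100ppm(base: GasState, base_volume_ml: float = 100.0) -> GasState:
    """The documented spike: 0.1 mL of 10% 46N2O into the nominal gas volume."""
    return apply_spike(base, base_volume_ml, 0.1, 0.10, "N2O_46")


def _run_gas(main_species: str) -> GasState:
    return spike_100ppm(mixture_from_volumes({main_species: 95.0, "CO2": 5.0}))


def _base_run(name: str, main_species: str, **overrides) -> RunScenario:
    defaults = dict(
        name=name,
        vial=_VIAL,
        initial_gas=_run_gas(main_species),
        initial_biomass_g=_INOCULUM_AB_G,
        growth_rate=0.05,
        sampling_days=tuple(float(d) for d in range(18)),
    )
    defaults.update(overrides)
    return RunScenario(**defaults)


def _ara_gas() -> GasState:
    return spike_100ppm(mixture_from_volumes({"He": 85.0, "CO2": 5.0, "C2H2": 10.0}))


@lru_cache(maxsize=1)
def _calibrated_constants() -> dict:
    """Solve the effective constants against the printed summary statistics."""
    # 1) ethylene Vmax from the acetylene assay target
    ara_proto = RunScenario(
        name="ARA",
        vial=_VIAL,
        initial_gas=_ara_gas(),
        initial_biomass_g=_INOCULUM_ARA_G,
        growth_rate=0.0,
        sampling_days=tuple(float(d) for d in range(13)),
    )

    def ara_misfit(vmax: float) -> float:
        ts = simulate(ara_proto.with_(vmax_ara=vmax))
        rate = ara_to_fixation(specific_ethylene_rate(ts, _VIAL, _ARA_WINDOW))
        return rate - PRINTED_RATE_ARA

    vmax_ara = brentq(ara_misfit, 1e2, 1e5, xtol=1e-6)
    # nitrogenase Vmax on the N2 basis, via the same 3:1 stoichiometry
    vmax_fix = ara_to_fixation(vmax_ara)

    # 2) effective first-order constants for Runs A and B
    def k_for(name: str, main_species: str, target: float, sink: float) -> float:
        proto = _base_run(name, main_species, sink_fraction=sink, vmax_fix=vmax_fix)

        def misfit(k: float) -> float:
            ts = simulate(proto.with_(k_red=k))
            return specific_consumption_rate(ts, "N2O_46", _VIAL, _FIT_WINDOW) - target

        return brentq(misfit, 1e4, 1e8, xtol=1e-2)

    k_b = k_for("RunB", "He", PRINTED_RATE_RUN_B, sink=0.26)
    k_a = k_for("RunA", "N2_28", PRINTED_RATE_RUN_A, sink=0.0)

    # 3) Run A biomass-channel bias producing the observed over-closure
    run_a = _base_run("RunA", "N2_28", k_red=k_a, vmax_fix=vmax_fix)
    ts_a = simulate(run_a)
    series = nitrogen_amount_series(ts_a, "N2O_46", _VIAL)
    consumed = float(series.iloc[0] - series.iloc[-1])
    total_n = float(ts_a.replicate_mean("biomass_N_ug").iloc[-1])
    surplus = (PRINTED_CLOSURE_RUN_A - 100.0) / 100.0  # closure above the exact budget
    bias_a = surplus * consumed * (1.0 - NATURAL_ABUNDANCE_15N) / total_n

    return {"vmax_ara": vmax_ara, "vmax_fix": vmax_fix, "k_a": k_a, "k_b": k_b, "bias_a": bias_a}


def packaged_scenarios(seed: int = 0) -> dict:
    """Calibrated scenarios for the study's incubations.

    Returns a dict with keys ``RunA``, ``RunB``, ``RunC_blank``, ``ARA``
    and ``O2_series`` (a tuple of four scenarios at 0/5/20/30% O2). The
    *seed* parameterizes the measurement layer only; noise-free
    trajectories are seed-independent.
    """
    c = _calibrated_constants()
    run_a = _base_run(
        "RunA",
        "N2_28",
        k_red=c["k_a"],
        vmax_fix=c["vmax_fix"],
        atom15_bias=c["bias_a"],
        seed=seed,
    )
    run_b = _base_run(
        "RunB",
        "He",
        k_red=c["k_b"],
        vmax_fix=c["vmax_fix"],
        sink_fraction=0.26,
        seed=seed + 1,
    )
    run_c = _base_run("RunC", "He", initial_biomass_g=0.0, k_red=c["k_b"], seed=seed + 2)
    ara = RunScenario(
        name="ARA",
        vial=_VIAL,
        initial_gas=_ara_gas(),
        initial_biomass_g=_INOCULUM_ARA_G,
        growth_rate=0.0,
        vmax_ara=c["vmax_ara"],
        sampling_days=tuple(float(d) for d in range(13)),
        seed=seed + 3,
    )
    o2_series = []
    for i, o2_ml in enumerate((0.0, 5.0, 20.0, 30.0)):
        volumes = {"He": 95.0 - o2_ml, "CO2": 5.0}
        if o2_ml > 0:
            volumes["O2"] = o2_ml
        o2_series.append(
            RunScenario(
                name=f"O2_run{i + 1}",
                vial=_VIAL,
                initial_gas=spike_100ppm(mixture_from_volumes(volumes)),
                initial_biomass_g=_INOCULUM_ARA_G,
                growth_rate=0.05,
                k_red=c["k_b"],
                vmax_fix=c["vmax_fix"],
                # uptake at 10% O2 was 89% of the anoxic rate: K = 0.1/(1/0.89 - 1)
                o2_inhibition_k=0.81,
                sampling_days=tuple(float(d) for d in range(13)),
                seed=seed + 4 + i,
            )
        )
    return {
        "RunA": run_a,
        "RunB": run_b,
        "RunC_blank": run_c,
        "ARA": ara,
        "O2_series": tuple(o2_series),
    }


def expected_run_a_budget_pool(ts_a) -> IsotopePool:
    """End-point biomass pool of a Run A trajectory (helper for budget checks)."""
    total_n = float(ts_a.replicate_mean("biomass_N_ug").iloc[-1])
    atom15 = float(ts_a.replicate_mean("biomass_atom15").iloc[-1])
    return IsotopePool(total_n, atom15)
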