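"""Rate estimation, run comparisons, nitrogen budget closure and statistics.

This is the analysis half of the tracer study: ordinary least-squares
fitting of gas consumption/production trends on replicate means, dry-mass
normalization to specific rates (ug-N per g dry biomass per day),
acetylene-reduction conversion with the 3:1 C2H4:N2 stoichiometry, and the
15N budget that partitions consumed N2O into emitted 30N2, biomass
15N-excess and a missing remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .equilibrium import henry_constant_n2o, n2o_capacity
from .isotopes import IsotopePool, tracer_derived_mass
from .species import NATURAL_ABUNDANCE_15N, NOMINAL_N_MASS, n_atoms
from .timeseries import TimeSeries
from .vial_gas import VialConfig, headspace_capacity

__all__ = [
    "RateEstimate",
    "BudgetReport",
    "nitrogen_amount_series",
    "molar_amount_series",
    "fit_consumption_rate",
    "fit_production_rate",
    "specific_consumption_rate",
    "specific_ethylene_rate",
    "mean_biomass",
    "percent_slowdown",
    "cumulative_retardation",
    "ara_to_fixation",
    "fixation_fraction",
    "per_cell_to_specific",
    "close_budget",
    "AnovaTukeyResult",
    "anova_tukey",
]


@dataclass(frozen=True)
class RateEstimate:
    """OLS fit of an amount-vs-time trend plus its dry-mass normalization."""

    slope: float  # signed, amount units per day
    intercept: float
    r_squared: float
    specific_rate: float  # |slope| / biomass
    fit_window: tuple[float, float]
    n_points: int
    unit: str = "ug-N/g/day"


@dataclass(frozen=True)
class BudgetReport:
    """Fate accounting of the added 46N2O tracer for one run."""

    consumed_n2o_ug: float  # gas + dissolved, initial minus final
    emitted_30n2_ug: float
    fixed_15n_ug: float  # tracer-derived biomass nitrogen
    closure_percent: float | None  # None when there is no net consumption
    missing_percent: float | None
    no_net_consumption: bool = False


def _amount_factor(species: str, vial: VialConfig, k0: float | None, include_dissolved: bool) -> float:
    """umol of *species* per unit mole fraction, optionally two-phase for N2O."""
    cap = headspace_capacity(vial)
    if include_dissolved and species in ("N2O_44", "N2O_46"):
        if k0 is None:
            k0 = henry_constant_n2o(vial.temperature_k)
        cap = n2o_capacity(vial, k0)
    return cap * vial.pressure_atm


def molar_amount_series(
    ts: TimeSeries,
    species: str,
    vial: VialConfig,
    k0: float | None = None,
    include_dissolved: bool = True,
) -> pd.Series:
    """Replicate-mean amount of a gas species per day, umol."""
    return ts.replicate_mean(species) * _amount_factor(species, vial, k0, include_dissolved)


def nitrogen_amount_series(
    ts: TimeSeries,
    species: str,
    vial: VialConfig,
    k0: float | None = None,
    include_dissolved: bool = True,
) -> pd.Series:
    """Replicate-mean nitrogen amount of a gas species per day, ug-N."""
    if n_atoms(species) == 0:
        raise ValueError(f"{species!r} carries no nitrogen")
    return (
        molar_amount_series(ts, species, vial, k0, include_dissolved)
        * n_atoms(species)
        * NOMINAL_N_MASS
    )


def mean_biomass(ts: TimeSeries, window: tuple[float, float]) -> float:
    """Mean dry biomass (g) over the sampled days inside *window*."""
    series = ts.replicate_mean("biomass_dry_g")
    series = series[(series.index >= window[0]) & (series.index <= window[1])]
    if series.empty:
        raise ValueError("no biomass observations inside the fit window")
    return float(series.mean())


def _ols(series: pd.Series, window: tuple[float, float]) -> tuple[float, float, float, int]:
    sel = series[(series.index >= window[0]) & (series.index <= window[1])]
    if len(sel) < 2:
        raise ValueError(f"need >= 2 time points in window {window}, got {len(sel)}")
    fit = stats.linregress(sel.index.to_numpy(), sel.to_numpy())
    r2 = float(fit.rvalue) ** 2 if np.isfinite(fit.rvalue) else 1.0
    return float(fit.slope), float(fit.intercept), r2, len(sel)


def fit_consumption_rate(
    ts: TimeSeries,
    species: str,
    window: tuple[float, float],
    biomass_g: float,
    vial: VialConfig,
    k0: float | None = None,
    include_dissolved: bool = True,
) -> RateEstimate:
    """Linear approximation of a declining gas trend, normalized by dry biomass.

    The fit runs on replicate means of the nitrogen amount (ug-N; gas plus
    dissolved for N2O) against day; the specific rate is |slope| / biomass
    in ug-N per g dry biomass per day.
    """
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    series = nitrogen_amount_series(ts, species, vial, k0, include_dissolved)
    slope, intercept, r2, n = _ols(series, window)
    return RateEstimate(slope, intercept, r2, abs(slope) / biomass_g, tuple(window), n)


def fit_production_rate(
    ts: TimeSeries,
    species: str,
    window: tuple[float, float],
    biomass_g: float,
    vial: VialConfig,
) -> RateEstimate:
    """OLS slope of a rising gas amount (umol/day), normalized by dry biomass."""
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    series = molar_amount_series(ts, species, vial, include_dissolved=False)
    slope, intercept, r2, n = _ols(series, window)
    return RateEstimate(
        slope, intercept, r2, abs(slope) / biomass_g, tuple(window), n, unit="umol/g/day"
    )


def specific_consumption_rate(
    ts: TimeSeries,
    species: str,
    vial: VialConfig,
    window: tuple[float, float] = (0.0, 17.0),
    k0: float | None = None,
) -> float:
    """Specific consumption rate (ug-N/g/day) using the window-mean biomass."""
    biomass = mean_biomass(ts, window)
    return fit_consumption_rate(ts, species, window, biomass, vial, k0).specific_rate


def specific_ethylene_rate(
    ts: TimeSeries,
    vial: VialConfig,
    window: tuple[float, float] = (0.0, 12.0),
) -> float:
    """Specific ethylene production rate (umol C2H4/g/day), window-mean biomass."""
    biomass = mean_biomass(ts, window)
    return fit_production_rate(ts, "C2H4", window, biomass, vial).specific_rate


def percent_slowdown(rate_a: float, rate_b: float) -> float:
    """Percent by which rate_a falls short of the reference rate_b."""
    if rate_b <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (1.0 - rate_a / rate_b)


def cumulative_retardation(
    ts_a: TimeSeries,
    ts_b: TimeSeries,
    species: str,
    day: float,
    vial: VialConfig,
    k0: float | None = None,
) -> float:
    """Percent reduction in cumulative consumption of run A relative to run B at *day*.

    consumed = initial amount minus the amount at *day* (gas + dissolved).
    """
    consumed = []
    for ts in (ts_a, ts_b):
        series = nitrogen_amount_series(ts, species, vial, k0)
        if day not in series.index:
            raise ValueError(f"day {day} not sampled in series")
        consumed.append(series.iloc[0] - series.loc[day])
    if consumed[1] <= 0:
        raise ValueError("reference run shows no net consumption")
    return 100.0 * (1.0 - consumed[0] / consumed[1])


def ara_to_fixation(ethylene_rate: float, ratio: float = 3.0) -> float:
    """Convert an ethylene production rate to an N2-fixation equivalent.

    ``ethylene_rate`` is in umol C2H4 per g per day; the molar conversion
    C2H4:N2 = *ratio* (3:1 by default) gives umol N2, reported as ug-N
    (x 28 under the nominal-mass convention).
    """
    if ethylene_rate < 0:
        raise ValueError("ethylene rate must be non-negative")
    if ratio <= 0:
        raise ValueError("conversion ratio must be positive")
    return ethylene_rate / ratio * 2 * NOMINAL_N_MASS


def fixation_fraction(n2o_rate: float, n2_rate: float) -> float:
    """N2O fixation rate as a percentage of the N2 fixation rate."""
    if n2_rate <= 0:
        raise ValueError("N2 fixation rate must be positive")
    return 100.0 * n2o_rate / n2_rate


def per_cell_to_specific(rate_per_cell_g: float, cell_dry_mass_pg: float = 0.28) -> float:
    """Convert a per-cell rate (g-N/cell/day) to ug-N per g dry biomass per day.

    The default 0.28 pg dry weight per cell is the standard bacterial
    cell-mass assumption used for literature rate comparisons.
    """
    if cell_dry_mass_pg <= 0:
        raise ValueError("cell dry mass must be positive")
    return rate_per_cell_g / (cell_dry_mass_pg * 1e-12) * 1e6


def _final_biomass_pool(ts: TimeSeries, day: float) -> IsotopePool:
    total_n = ts.replicate_mean("biomass_N_ug")
    atom15 = ts.replicate_mean("biomass_atom15")
    if day not in total_n.index or day not in atom15.index:
        raise ValueError(f"no biomass observation at day {day}")
    return IsotopePool(float(total_n.loc[day]), float(min(max(atom15.loc[day], 0.0), 1.0)))


def close_budget(
    ts: TimeSeries,
    vial: VialConfig,
    biomass_pool: IsotopePool | None = None,
    k0: float | None = None,
    baseline: float = NATURAL_ABUNDANCE_15N,
    species: str = "N2O_46",
    initial_day: float | None = None,
    final_day: float | None = None,
) -> BudgetReport:
    """Nitrogen budget for one run: consumed vs (emitted + fixed).

    consumed: drop of the two-phase N2O pool between the first and last
    sampled day (ug-N). emitted: 30N2 in the headspace at the end. fixed:
    tracer-derived nitrogen in the end-point biomass pool (from its total N
    and 15N atom fraction). closure = 100 (emitted + fixed) / consumed;
    values above 100% arise from measurement bias and are reported as-is.
    """
    series = nitrogen_amount_series(ts, species, vial, k0)
    d0 = series.index[0] if initial_day is None else initial_day
    d1 = series.index[-1] if final_day is None else final_day
    consumed = float(series.loc[d0] - series.loc[d1])
    emitted_series = nitrogen_amount_series(ts, "N2_30", vial, include_dissolved=False)
    emitted = float(emitted_series.loc[d1] - emitted_series.loc[d0])
    if biomass_pool is None:
        biomass_pool = _final_biomass_pool(ts, d1)
    fixed = tracer_derived_mass(biomass_pool, baseline)
    if consumed <= 0:
        return BudgetReport(consumed, emitted, fixed, None, None, no_net_consumption=True)
    closure = 100.0 * (emitted + fixed) / consumed
    return BudgetReport(consumed, emitted, fixed, closure, 100.0 - closure)


# ---------------------------------------------------------------------------
# Group statistics: one-way ANOVA + Tukey HSD with compact letter display


@dataclass(frozen=True)
class AnovaTukeyResult:
    means: Mapping[str, float]
    f_statistic: float
    p_value: float
    tukey_p: Mapping[tuple[str, str], float]
    letters: Mapping[str, str]
    alpha: float


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD and a compact letter display.

    Groups sharing no letter differ at *alpha*. Letters come from a
    maximal-clique cover of the non-significant-pairs graph, ordered by
    group mean (alphabetical tie-break), so the display is deterministic.
    Fully degenerate input (every observation identical) returns p = 1 and
    a single shared letter.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = {k: np.asarray(groups[k], dtype=float) for k in names}
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("each group needs at least two replicates")
    means = {k: float(v.mean()) for k, v in samples.items()}

    all_values = np.concatenate(list(samples.values()))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if np.ptp(all_values) == 0.0:
        tukey_p = {pair: 1.0 for pair in pairs}
        return AnovaTukeyResult(means, 0.0, 1.0, tukey_p, {k: "a" for k in names}, alpha)

    msw = float(np.mean([np.var(v, ddof=1) for v in samples.values()]))
    if msw == 0.0:
        # zero within-group variance but distinct means: everything separable
        f, p = float("inf"), 0.0
        tukey_p = {(a, b): (1.0 if means[a] == means[b] else 0.0) for a, b in pairs}
    else:
        f, p = stats.f_oneway(*samples.values())
        hsd = stats.tukey_hsd(*samples.values())
        tukey_p = {
            (a, b): float(hsd.pvalue[names.index(a), names.index(b)]) for a, b in pairs
        }

    order = sorted(names, key=lambda k: (means[k], k))
    graph = nx.Graph()
    graph.add_nodes_from(order)
    for (a, b), pv in tukey_p.items():
        if pv >= alpha:
            graph.add_edge(a, b)
    cliques = [tuple(sorted(c, key=order.index)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: tuple(order.index(m) for m in c))
    letters: dict[str, list[str]] = {k: [] for k in names}
    for i, clique in enumerate(cliques):
        symbol = chr(ord("a") + i)
        for member in clique:
            letters[member].append(symbol)
    return AnovaTukeyResult(
        means, float(f), float(p), tukey_p, {k: "".join(sorted(v)) for k, v in letters.items()}, alpha
    )
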