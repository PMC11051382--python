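"""Scenario drivers: graphite-addition sweeps, temperature and pressure sweeps,
H/C/N/O sensitivity grids, the oxygen-fugacity (QFM-deviation) diagnostic, and
the methyl-isocyanide estimator.

These reproduce the experiment designs behind the nitrile/isonitrile yield
figures: a nitrogen-bearing magmatic gas at fixed T and P with graphite added
from zero to beyond saturation, solved with the equilibrium module and/or the
reduced kinetics network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, number_density_cm3
from .equilibrium import (ElementBudget, GasState, SolverOptions,
                          equilibrate_with_graphite, mixing_ratios_to_elements)
from .fixtures import reduced_network_text, table1_gas
from .kinetics import integrate, parse_network
from .thermo import (ReactionStoichiometry, ThermoTable, load_default_table,
                     reaction_delta_g)
from .constants import R_GAS

__all__ = [
    "ScenarioConfig",
    "SweepResult",
    "QfmDiagnostic",
    "QFM_FROST_1991",
    "graphite_sweep",
    "temperature_sweep",
    "sensitivity_grid",
    "qfm_deviation",
    "ch3nc_estimate",
]

TRACKED_SPECIES = ("HCN", "HNC", "HC3N", "C4H2", "CO", "CO2", "H2O", "H2",
                   "N2", "CH4", "C2H2", "NH3", "O2")


@dataclass(frozen=True)
class QfmParameterization:
    """log10 fO2 at the quartz-fayalite-magnetite buffer:
    A/T + B + C (P-1)/T, with T in K and P in bar."""

    a: float
    b: float
    c: float
    name: str = "custom"

    def log10_fo2(self, t_kelvin: float, p_bar: float) -> float:
        return self.a / t_kelvin + self.b + self.c * (p_bar - 1.0) / t_kelvin


QFM_FROST_1991 = QfmParameterization(a=-25096.3, b=8.735, c=0.110, name="Frost-1991")


@dataclass
class QfmDiagnostic:
    log_fo2: float
    qfm_reference: float
    deviation: float
    parameterization: str = QFM_FROST_1991.name


@dataclass(frozen=True)
class ScenarioConfig:
    """Run configuration for the sweep drivers.

    Temperatures are taken in Celsius at this interface (converted to Kelvin
    internally); ``nitrogen_fraction`` is the N2 mole fraction imposed on the
    base gas (the fiducial gas already carries 0.057).
    """

    t_celsius: float = 1700.0
    p_bar: float = 100.0
    base_composition: GasState | ElementBudget | None = None
    nitrogen_fraction: float = 0.057
    graphite_grid: tuple | None = None      # carbon atom fractions of total atoms
    model: str = "equilibrium"              # kinetics | equilibrium | both
    vapor_pressure_variant: str | None = None   # default: per-model choice
    saturated_carbon_fraction: float = 0.9  # grid top / saturated-solve setting
    hc3n_mode: str = "eq6"
    t_end_seconds: float = 86400.0
    tau_graphite: float = 1.0e-8
    qfm: QfmParameterization = QFM_FROST_1991

    def __post_init__(self):
        if not 0 <= self.nitrogen_fraction < 1:
            raise ValueError("nitrogen_fraction must be in [0, 1)")
        if self.graphite_grid is not None:
            grid = tuple(self.graphite_grid)
            if len(grid) == 0 or list(grid) != sorted(grid):
                raise ValueError("graphite_grid must be non-empty and sorted")
        if self.model not in ("kinetics", "equilibrium", "both"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def t_kelvin(self) -> float:
        return celsius_to_kelvin(self.t_celsius)

    def base_gas(self) -> GasState:
        base = self.base_composition
        if base is None:
            base = table1_gas()
        if isinstance(base, ElementBudget):
            raise TypeError("base_composition is an element budget; use base_budget()")
        if abs(base.mixing_ratios.get("N2", 0.0) - self.nitrogen_fraction) > 1e-12:
            others = {k: v for k, v in base.mixing_ratios.items() if k != "N2"}
            scale = (1.0 - self.nitrogen_fraction) / sum(others.values())
            ratios = {k: v * scale for k, v in others.items()}
            if self.nitrogen_fraction > 0:
                ratios["N2"] = self.nitrogen_fraction
            base = GasState(t_kelvin=self.t_kelvin, p_bar=self.p_bar,
                            mixing_ratios=ratios)
        return base

    def base_budget(self, table: ThermoTable | None = None) -> ElementBudget:
        base = self.base_composition
        if isinstance(base, ElementBudget):
            return base
        return mixing_ratios_to_elements(self.base_gas(), table)

    def solver_options(self, model: str) -> SolverOptions:
        variant = self.vapor_pressure_variant or (
            "kinetics" if model == "kinetics" else "equilibrium")
        return SolverOptions(hc3n_mode=self.hc3n_mode, vapor_pressure_variant=variant)


@dataclass
class SweepResult:
    """Per-grid-point mixing-ratio series for one or both models."""

    axis_name: str
    axis_values: np.ndarray
    series: dict            # (model, species) -> np.ndarray
    qfm_deviation: dict     # model -> np.ndarray
    saturated: dict         # model -> np.ndarray of bool
    graphite_fraction: dict # model -> np.ndarray
    meta: dict = field(default_factory=dict)

    def species_series(self, species: str, model: str = "equilibrium") -> np.ndarray:
        return self.series[(model, species)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        models = sorted({m for m, _ in self.series})
        for model in models:
            for i, x in enumerate(self.axis_values):
                row = {"model": model, self.axis_name: x,
                       "qfm_deviation": self.qfm_deviation[model][i],
                       "saturated": bool(self.saturated[model][i]),
                       "graphite_fraction": self.graphite_fraction[model][i]}
                for (m, sp), arr in self.series.items():
                    if m == model:
                        row[sp] = arr[i]
                rows.append(row)
        return pd.DataFrame(rows)


def qfm_deviation(gas: GasState, qfm: QfmParameterization = QFM_FROST_1991) -> QfmDiagnostic:
    """Deviation of the gas's oxygen fugacity from the QFM buffer, in log10 units.

    fO2 is the O2 partial pressure (ideal gas); the gas must carry an O2 entry,
    however tiny — run an equilibrium solve first if it does not.
    """
    x_o2 = gas.mixing_ratios.get("O2", 0.0)
    if x_o2 <= 0:
        raise ValueError("gas has no O2 mixing ratio; run an equilibrium solve first")
    log_fo2 = math.log10(x_o2 * gas.p_bar)
    ref = qfm.log10_fo2(gas.t_kelvin, gas.p_bar)
    return QfmDiagnostic(log_fo2=log_fo2, qfm_reference=ref,
                         deviation=log_fo2 - ref, parameterization=qfm.name)


def _record(series, qfm_dev, sat, gfrac, model, i, gas, saturated, graphite_fraction,
            cfg, species_names):
    for sp in species_names:
        series[(model, sp)][i] = gas.mixing_ratios.get(sp, 0.0)
    try:
        qfm_dev[model][i] = qfm_deviation(gas, cfg.qfm).deviation
    except ValueError:
        qfm_dev[model][i] = np.nan
    sat[model][i] = saturated
    gfrac[model][i] = graphite_fraction


def _kinetics_point(cfg, table, base_gas, x_carbon, network):
    """One kinetics grid point: integrate the reduced network from the base gas
    with the added carbon supplied as a solid graphite reservoir."""
    t_k, p = cfg.t_kelvin, cfg.p_bar
    n_tot0 = number_density_cm3(p, t_k)
    per_mol = mixing_ratios_to_elements(base_gas, table)   # atoms per molecule
    alpha0 = per_mol.total()
    c0 = per_mol.abundances.get("C", 0.0)
    n_other = n_tot0 * (alpha0 - c0)              # non-carbon atoms per cm^3
    c_target = x_carbon / (1.0 - x_carbon) * n_other
    reservoir = max(c_target - n_tot0 * c0, 0.0)
    traj = integrate(network, base_gas, t_k, p, t_end=cfg.t_end_seconds,
                     table=table, initial_solid_carbon=reservoir,
                     tau_graphite=cfg.tau_graphite,
                     vapor_pressure_variant=cfg.vapor_pressure_variant or "kinetics")
    mix = traj.mixing_ratios(-1)
    gas = GasState(t_kelvin=t_k, p_bar=traj.final_pressure_bar(),
                   mixing_ratios={k: v / sum(mix.values()) for k, v in mix.items()})
    solid_end = float(traj.solid_carbon[-1]) if traj.solid_carbon is not None else 0.0
    saturated = solid_end > 1e-6 * c_target if c_target > 0 else False
    gfrac = solid_end / c_target if c_target > 0 else 0.0
    return gas, saturated, gfrac


def graphite_sweep(cfg: ScenarioConfig, table: ThermoTable | None = None) -> SweepResult:
    """Mixing ratios vs added graphite (carbon atom fraction of total atoms).

    The first grid point defaults to the base gas's own carbon fraction (zero
    addition); the equilibrium branch clamps carbon at saturation, the kinetics
    branch integrates the reduced network with the added carbon as a solid
    reservoir.
    """
    table = table or load_default_table()
    budget = cfg.base_budget(table).normalized()
    x0 = budget.fraction("C")
    if cfg.graphite_grid is not None:
        grid = np.asarray(cfg.graphite_grid, dtype=float)
    else:
        grid = np.linspace(x0, cfg.saturated_carbon_fraction, 16)
    models = ("equilibrium", "kinetics") if cfg.model == "both" else (cfg.model,)
    species_names = set(TRACKED_SPECIES)
    if "equilibrium" in models:
        from .equilibrium import default_species_set
        species_names |= set(default_species_set(table, budget.elements()))
    network = None
    if "kinetics" in models:
        network = parse_network(reduced_network_text(), table)
        species_names |= set(network.species)
    species_names = sorted(species_names)

    n = len(grid)
    series = {(m, sp): np.full(n, np.nan) for m in models for sp in species_names}
    qfm_dev = {m: np.full(n, np.nan) for m in models}
    sat = {m: np.zeros(n, dtype=bool) for m in models}
    gfrac = {m: np.zeros(n) for m in models}

    base_gas = cfg.base_gas() if not isinstance(cfg.base_composition, ElementBudget) else None
    for i, x in enumerate(grid):
        bud_x = budget.with_carbon_fraction(float(x)) if x > 0 else budget
        for model in models:
            try:
                if model == "equilibrium":
                    res = equilibrate_with_graphite(
                        bud_x, cfg.t_kelvin, cfg.p_bar, table=table,
                        options=cfg.solver_options(model))
                    _record(series, qfm_dev, sat, gfrac, model, i, res.gas,
                            res.saturated, res.graphite_fraction, cfg, species_names)
                else:
                    if base_gas is None:
                        raise TypeError("kinetics sweep requires a GasState base")
                    gas, s_flag, g_fr = _kinetics_point(cfg, table, base_gas,
                                                        float(x), network)
                    _record(series, qfm_dev, sat, gfrac, model, i, gas,
                            s_flag, g_fr, cfg, species_names)
            except Exception as exc:
                raise RuntimeError(
                    f"{model} solve failed at carbon fraction {x:.4f}: {exc}") from exc
    return SweepResult(axis_name="carbon_fraction", axis_values=grid, series=series,
                       qfm_deviation=qfm_dev, saturated=sat, graphite_fraction=gfrac,
                       meta={"t_celsius": cfg.t_celsius, "p_bar": cfg.p_bar,
                             "model": cfg.model})


def temperature_sweep(cfg: ScenarioConfig, t_grid_celsius: Sequence[float],
                      table: ThermoTable | None = None) -> SweepResult:
    """Graphite-saturated solve per temperature (carbon fraction held at
    ``cfg.saturated_carbon_fraction``, beyond saturation across the grid)."""
    table = table or load_default_table()
    budget = cfg.base_budget(table).normalized()
    grid = np.asarray(list(t_grid_celsius), dtype=float)
    model = "equilibrium" if cfg.model == "both" else cfg.model
    species_names = sorted(TRACKED_SPECIES)
    n = len(grid)
    series = {(model, sp): np.full(n, np.nan) for sp in species_names}
    qfm_dev = {model: np.full(n, np.nan)}
    sat = {model: np.zeros(n, dtype=bool)}
    gfrac = {model: np.zeros(n)}
    bud_sat = budget.with_carbon_fraction(cfg.saturated_carbon_fraction)
    for i, t_c in enumerate(grid):
        cfg_t = replace(cfg, t_celsius=float(t_c))
        try:
            res = equilibrate_with_graphite(bud_sat, cfg_t.t_kelvin, cfg.p_bar,
                                            table=table,
                                            options=cfg_t.solver_options(model))
        except Exception as exc:
            raise RuntimeError(f"solve failed at {t_c} C: {exc}") from exc
        _record(series, qfm_dev, sat, gfrac, model, i, res.gas, res.saturated,
                res.graphite_fraction, cfg_t, species_names)
    return SweepResult(axis_name="t_celsius", axis_values=grid, series=series,
                       qfm_deviation=qfm_dev, saturated=sat, graphite_fraction=gfrac,
                       meta={"p_bar": cfg.p_bar, "model": model,
                             "carbon_fraction": cfg.saturated_carbon_fraction})


def sensitivity_grid(element_ranges: Mapping[str, Sequence[float]],
                     t_grid_celsius: Sequence[float],
                     p_grid_bar: Sequence[float],
                     cfg: ScenarioConfig | None = None,
                     table: ThermoTable | None = None,
                     max_points_per_axis: int = 5) -> pd.DataFrame:
    """Cross-product of graphite-clamped equilibrium solves; tidy long table.

    ``element_ranges`` maps element -> abundance values (relative atoms).
    Points where the solver fails are retained with ``error`` filled in.
    """
    import itertools

    cfg = cfg or ScenarioConfig()
    table = table or load_default_table()
    for name, axis in [("temperature", t_grid_celsius), ("pressure", p_grid_bar),
                       *element_ranges.items()]:
        if len(axis) > max_points_per_axis:
            raise ValueError(f"{name} axis exceeds {max_points_per_axis} points")
    elements = sorted(element_ranges)
    rows = []
    for t_c, p in itertools.product(t_grid_celsius, p_grid_bar):
        cfg_tp = replace(cfg, t_celsius=float(t_c), p_bar=float(p))
        for combo in itertools.product(*(element_ranges[e] for e in elements)):
            row = {"t_celsius": t_c, "p_bar": p,
                   **{f"n_{e}": v for e, v in zip(elements, combo)}}
            try:
                budget = ElementBudget(dict(zip(elements, combo)))
                res = equilibrate_with_graphite(
                    budget, cfg_tp.t_kelvin, float(p), table=table,
                    options=cfg_tp.solver_options("equilibrium"))
                row.update({sp: res.gas.mixing_ratios.get(sp, 0.0)
                            for sp in TRACKED_SPECIES})
                row["saturated"] = res.saturated
                row["graphite_fraction"] = res.graphite_fraction
                row["error"] = ""
            except Exception as exc:   # retain partial results
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def ch3nc_estimate(t_kelvin: float, hcn: float, ch4: float, h2: float,
                   delta_g_kj: float | None = None,
                   table: ThermoTable | None = None) -> float:
    """Methyl isocyanide mixing ratio via the isomer-exchange estimator.

    [CH3NC] = exp(-DrG/RT) * [HCN][CH4]/[H2] for HCN + CH4 -> CH3NC + H2;
    ``delta_g_kj`` defaults to the packaged-table reaction free energy at T.
    CH3NC is estimator-only: it is never inserted into the network or solver.
    """
    for name, v in (("hcn", hcn), ("ch4", ch4), ("h2", h2)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be a fraction in [0, 1]")
    if h2 <= 0:
        raise ValueError("H2 fraction must be positive")
    if delta_g_kj is None:
        table = table or load_default_table()
        rxn = ReactionStoichiometry(reactants={"HCN": 1, "CH4": 1},
                                    products={"CH3NC": 1, "H2": 1})
        delta_g_kj = reaction_delta_g(rxn, table, t_kelvin)
    return math.exp(-delta_g_kj * 1000.0 / (R_GAS * t_kelvin)) * hcn * ch4 / h2
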