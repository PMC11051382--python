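"""Gas-phase chemical equilibrium with graphite condensation.

The solver uses the element-potential (Lagrange-multiplier) formulation: at
equilibrium every gas species' partial pressure is

    p_i = exp(-g_i + sum_e a_ie * lam_e),        g_i = mu0_i/(R T),

where ``a_ie`` are atom counts and ``lam_e`` dimensionless element potentials.
Mass action is then satisfied by construction and the unknowns are one
potential per element plus a budget scale.  Newton iteration with step damping
in log space handles the stiff dynamic range (1e-10 ... 0.35 mixing ratios).

Graphite: if the unconstrained solution puts the carbon-monomer partial
pressure above the saturation vapor pressure, the carbon potential is pinned at
``lam_C = g_C + ln p_vap`` (carbon activity 1) and the excess carbon is
assigned to a solid reservoir.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .thermo import (ThermoTable, VaporPressureFit, graphite_vapor_pressure,
                     hc3n_ln_mass_action, load_default_table)

__all__ = [
    "ElementBudget",
    "GasState",
    "EquilibriumResult",
    "ConvergenceError",
    "SolverOptions",
    "mixing_ratios_to_elements",
    "solve_gas_equilibrium",
    "equilibrate_with_graphite",
    "find_saturation_threshold",
    "default_species_set",
]


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass(frozen=True)
class ElementBudget:
    """Relative atom abundances per element (any positive normalization)."""

    abundances: Mapping[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("element abundances must be non-negative")
        if self.total() <= 0:
            raise ValueError("element budget must have positive total abundance")

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def normalized(self) -> "ElementBudget":
        tot = self.total()
        return ElementBudget({e: v / tot for e, v in self.abundances.items() if v > 0})

    def elements(self) -> list:
        return [e for e, v in self.abundances.items() if v > 0]

    def fraction(self, element: str) -> float:
        return self.abundances.get(element, 0.0) / self.total()

    def with_carbon_fraction(self, x: float) -> "ElementBudget":
        """Budget whose carbon atom fraction of total atoms is ``x``; the other
        elements keep their mutual ratios."""
        if not 0 <= x < 1:
            raise ValueError("carbon fraction must be in [0, 1)")
        others = {e: v for e, v in self.abundances.items() if e != "C" and v > 0}
        tot_others = sum(others.values())
        if tot_others == 0:
            raise ValueError("budget has no non-carbon elements")
        scale = (1.0 - x) / tot_others
        out = {e: v * scale for e, v in others.items()}
        if x > 0:
            out["C"] = x
        return ElementBudget(out)


@dataclass
class GasState:
    """Temperature/pressure-stamped gas composition (mole fractions)."""

    t_kelvin: float
    p_bar: float
    mixing_ratios: dict

    def __post_init__(self):
        if any(v < 0 for v in self.mixing_ratios.values()):
            raise ValueError("mixing ratios must be non-negative")
        tot = sum(self.mixing_ratios.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"mixing ratios must sum to 1 (got {tot!r})")

    def partial_pressure(self, name: str) -> float:
        return self.mixing_ratios.get(name, 0.0) * self.p_bar

    def __getitem__(self, name: str) -> float:
        return self.mixing_ratios.get(name, 0.0)


@dataclass
class EquilibriumResult:
    gas: GasState
    graphite_fraction: float          # fraction of total carbon atoms condensed
    saturated: bool
    residuals: dict                   # per-element relative conservation residuals
    carbon_activity: float = 0.0      # p_C / p_vap at the solution


def mixing_ratios_to_elements(gas: GasState, table: ThermoTable | None = None) -> ElementBudget:
    """Per-element atom counts per gas molecule, summed over species."""
    table = table or load_default_table()
    if not gas.mixing_ratios or sum(gas.mixing_ratios.values()) == 0:
        raise ValueError("empty gas state")
    counts: dict = {}
    for sp, x in gas.mixing_ratios.items():
        comp = table[sp].composition
        for el, n in comp.items():
            counts[el] = counts.get(el, 0.0) + x * n
    return ElementBudget(counts)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs for the equilibrium solve."""

    max_iter: int = 200
    tol: float = 1.0e-13            # max-norm of log-space residuals
    max_step: float = 3.0           # Newton step clip (log units)
    restarts: int = 5
    hc3n_mode: str = "eq6"          # "eq6": mass-action fit; "table": NASA row
    vapor_pressure_variant: str = "equilibrium"
    vapor_pressure_fit: VaporPressureFit | None = None
    seed: int = 0                   # perturbation seed for restarts


DEFAULT_EXCLUDED = ("CH3NC",)       # estimator-only species, never equilibrated


def default_species_set(table: ThermoTable, elements: Iterable[str]) -> list:
    """All gas species of ``table`` composed solely of ``elements``."""
    els = set(elements)
    out = []
    for name in table.names():
        sp = table[name]
        if sp.phase != "gas" or name in DEFAULT_EXCLUDED:
            continue
        if set(sp.composition) <= els:
            out.append(name)
    return out


def _g_vector(species: Sequence[str], table: ThermoTable, t_kelvin: float,
              hc3n_mode: str) -> np.ndarray:
    g = np.empty(len(species))
    for i, name in enumerate(species):
        if name == "HC3N" and hc3n_mode == "eq6":
            g[i] = (table.g_rt("H", t_kelvin) + 3 * table.g_rt("C", t_kelvin)
                    + table.g_rt("N", t_kelvin) - hc3n_ln_mass_action(t_kelvin))
        else:
            g[i] = table.g_rt(name, t_kelvin)
    return g


def _stoich_matrix(species: Sequence[str], elements: Sequence[str],
                   table: ThermoTable) -> np.ndarray:
    a = np.zeros((len(species), len(elements)))
    for i, name in enumerate(species):
        for j, el in enumerate(elements):
            a[i, j] = table[name].composition.get(el, 0)
    return a


def _newton(g, a, b, ln_p_total, fixed=None, options=SolverOptions()):
    """Damped Newton on log residuals.

    Unknowns: element potentials lam (free elements only) and ln-scale sigma.
    ``fixed`` maps element index -> pinned potential value (graphite clamp);
    pinned elements drop their conservation equation.
    Returns (lam_full, sigma, p, residual_dict_ready).
    """
    fixed = fixed or {}
    n_sp, n_el = a.shape
    free = [j for j in range(n_el) if j not in fixed]
    rng = np.random.default_rng(options.seed)

    def p_of(lam_full, sigma):
        expo = -g + a @ lam_full
        return np.exp(np.clip(expo, -745.0, 700.0))

    def residuals(lam_full, sigma):
        p = p_of(lam_full, sigma)
        r = []
        for j in free:
            gas_e = float(a[:, j] @ p)
            r.append(math.log(max(gas_e, 1e-300)) - math.log(b[j]) - sigma)
        r.append(math.log(max(float(p.sum()), 1e-300)) - ln_p_total)
        return np.array(r), p

    # initial guess: potentials that put every species near equal abundance
    lam_full = np.zeros(n_el)
    target = g + (ln_p_total - math.log(n_sp))
    sol, *_ = np.linalg.lstsq(a, target, rcond=None)
    lam_full[:] = sol
    for j, v in fixed.items():
        lam_full[j] = v
    sigma = 0.0

    best = None
    for attempt in range(options.restarts + 1):
        if attempt > 0:
            lam_full = lam_full + rng.normal(scale=0.5 * attempt, size=n_el)
            for j, v in fixed.items():
                lam_full[j] = v
            sigma = float(sigma + rng.normal(scale=0.5))
        r, p = residuals(lam_full, sigma)
        norm = np.max(np.abs(r))
        for _ in range(options.max_iter):
            if not np.isfinite(norm):
                break
            if norm < options.tol:
                return lam_full, sigma, p
            # Jacobian
            n_free = len(free)
            jac = np.zeros((n_free + 1, n_free + 1))
            for row, j in enumerate(free):
                gas_e = float(a[:, j] @ p)
                for col, k in enumerate(free):
                    jac[row, col] = float((a[:, j] * a[:, k]) @ p) / max(gas_e, 1e-300)
                jac[row, n_free] = -1.0
            ptot = max(float(p.sum()), 1e-300)
            for col, k in enumerate(free):
                jac[n_free, col] = float(a[:, k] @ p) / ptot
            jac[n_free, n_free] = 0.0
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -r, rcond=None)[0]
            big = np.max(np.abs(step))
            if big > options.max_step:
                step = step * (options.max_step / big)
            # line search
            scale = 1.0
            for _ in range(40):
                lam_try = lam_full.copy()
                for col, k in enumerate(free):
                    lam_try[k] += scale * step[col]
                sig_try = sigma + scale * step[-1]
                r_try, p_try = residuals(lam_try, sig_try)
                norm_try = np.max(np.abs(r_try))
                if np.isfinite(norm_try) and (norm_try < norm or norm_try < options.tol):
                    lam_full, sigma, r, p, norm = lam_try, sig_try, r_try, p_try, norm_try
                    break
                scale *= 0.5
            else:
                break  # line search stalled -> restart
        if best is None or norm < best[0]:
            best = (norm, lam_full.copy(), sigma, p.copy(), r.copy())
    norm, lam_full, sigma, p, r = best
    if norm < 1e-9:  # accept near-converged solutions from the best attempt
        return lam_full, sigma, p
    raise ConvergenceError(
        f"equilibrium solver did not converge (residual max-norm {norm:.3e})",
        residuals={"max_norm": float(norm)})


def _solve(budget, t_kelvin, p_bar, species, table, options, clamp_carbon):
    budget = budget.normalized()
    elements = sorted(budget.elements())
    if species is None:
        species = default_species_set(table, elements)
    for name in species:
        if set(table[name].composition) - set(elements):
            raise ValueError(f"species {name} contains elements outside the budget")
    g = _g_vector(species, table, t_kelvin, options.hc3n_mode)
    a = _stoich_matrix(species, elements, table)
    b = np.array([budget.abundances[e] for e in elements])
    fixed = {}
    p_vap = None
    if clamp_carbon:
        if "C" not in elements:
            raise ValueError("cannot clamp carbon: budget has no carbon")
        p_vap = graphite_vapor_pressure(t_kelvin, options.vapor_pressure_variant,
                                        fit=options.vapor_pressure_fit)
        j_c = elements.index("C")
        i_c = species.index("C")
        fixed[j_c] = g[i_c] + math.log(p_vap)
    lam, sigma, p = _newton(g, a, b, math.log(p_bar), fixed=fixed, options=options)
    return elements, species, a, b, lam, sigma, p, p_vap


def _gas_state(species, p, t_kelvin, p_bar) -> GasState:
    ptot = float(p.sum())
    x = {sp: float(pi / ptot) for sp, pi in zip(species, p)}
    # exact renormalization against rounding
    s = sum(x.values())
    x = {k: v / s for k, v in x.items()}
    return GasState(t_kelvin=t_kelvin, p_bar=p_bar, mixing_ratios=x)


def _conservation_residuals(elements, a, b, p, sigma, extra=None):
    res = {}
    for j, el in enumerate(elements):
        gas_e = float(a[:, j] @ p) + (extra.get(el, 0.0) if extra else 0.0)
        res[el] = gas_e / (b[j] * math.exp(sigma)) - 1.0
    return res


def solve_gas_equilibrium(budget: ElementBudget, t_kelvin: float, p_bar: float,
                          species_set: Sequence[str] | None = None,
                          table: ThermoTable | None = None,
                          options: SolverOptions = SolverOptions()) -> GasState:
    """Unconstrained gas-phase equilibrium for an element budget at fixed T, P."""
    table = table or load_default_table()
    elements, species, a, b, lam, sigma, p, _ = _solve(
        budget, t_kelvin, p_bar, list(species_set) if species_set else None,
        table, options, clamp_carbon=False)
    return _gas_state(species, p, t_kelvin, p_bar)


def equilibrate_with_graphite(budget: ElementBudget, t_kelvin: float, p_bar: float,
                              species_set: Sequence[str] | None = None,
                              table: ThermoTable | None = None,
                              options: SolverOptions = SolverOptions()) -> EquilibriumResult:
    """Equilibrium with the carbon-monomer pressure clamped at graphite saturation.

    Below saturation this equals :func:`solve_gas_equilibrium` with
    ``graphite_fraction`` 0; above it, carbon activity is pinned at 1 and the
    excess carbon is condensed.
    """
    table = table or load_default_table()
    species_list = list(species_set) if species_set else None
    p_vap = graphite_vapor_pressure(t_kelvin, options.vapor_pressure_variant,
                                    fit=options.vapor_pressure_fit)
    elements, species, a, b, lam, sigma, p, _ = _solve(
        budget, t_kelvin, p_bar, species_list, table, options, clamp_carbon=False)
    p_c = p[species.index("C")] if "C" in species else 0.0
    if p_c <= p_vap:
        gas = _gas_state(species, p, t_kelvin, p_bar)
        res = _conservation_residuals(elements, a, b, p, sigma)
        return EquilibriumResult(gas=gas, graphite_fraction=0.0, saturated=False,
                                 residuals=res, carbon_activity=p_c / p_vap)
    elements, species, a, b, lam, sigma, p, p_vap = _solve(
        budget, t_kelvin, p_bar, species_list, table, options, clamp_carbon=True)
    j_c = elements.index("C")
    gas_c = float(a[:, j_c] @ p)
    total_c = b[j_c] * math.exp(sigma)
    graphite = total_c - gas_c
    if graphite < 0:
        # clamped solve wants more carbon than the budget holds: not saturated
        # after all (can happen within roundoff of the threshold)
        graphite = 0.0
    gas = _gas_state(species, p, t_kelvin, p_bar)
    res = _conservation_residuals(elements, a, b, p, sigma, extra={"C": graphite})
    p_c = p[species.index("C")]
    return EquilibriumResult(gas=gas, graphite_fraction=float(graphite / total_c),
                             saturated=True, residuals=res,
                             carbon_activity=p_c / p_vap)


def find_saturation_threshold(base: ElementBudget, t_kelvin: float, p_bar: float,
                              species_set: Sequence[str] | None = None,
                              table: ThermoTable | None = None,
                              options: SolverOptions = SolverOptions(),
                              x_max: float = 0.999, tol: float = 1.0e-3) -> float:
    """Smallest carbon atom fraction (of total atoms) at which graphite saturates.

    Bisection over the carbon fraction ``x``; the budget's non-carbon element
    ratios are held fixed while carbon is added.  Raises if the base budget is
    already saturated.
    """
    table = table or load_default_table()

    def saturated_at(x: float) -> bool:
        bud = base.with_carbon_fraction(x)
        res = equilibrate_with_graphite(bud, t_kelvin, p_bar, species_set, table, options)
        return res.saturated and res.graphite_fraction > 0

    x_lo = base.normalized().fraction("C")
    if saturated_at(x_lo):
        raise ValueError("base budget is already graphite-saturated at zero addition")
    if not saturated_at(x_max):
        raise ValueError(f"no saturation up to carbon fraction {x_max}")
    x_hi = x_max
    while x_hi - x_lo > tol:
        mid = 0.5 * (x_lo + x_hi)
        if saturated_at(mid):
            x_hi = mid
        else:
            x_lo = mid
    return 0.5 * (x_lo + x_hi)
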