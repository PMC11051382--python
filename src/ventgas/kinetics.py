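"""Reversible reaction-network kinetics with equilibrium-enforcing reverse rates.

Each reversible reaction carries a forward rate constant (modified Arrhenius
``k+ = A (T/300)^n exp(-Ea/T)``, Ea in Kelvin, cm^3-molecule-s units implied by
reaction order); the reverse constant is derived from the thermochemical
equilibrium constant, ``k- = k+ / Kc``, so every network relaxes to the same
equilibrium the thermodynamics dictate regardless of the forward-rate choices.

Gas <-> graphite exchange is a zero-dimensional solid reservoir: condensation
``C(g) -> C(s)`` at rate ``n_C / tau`` and evaporation at the rate that pins
the steady-state carbon concentration at the saturation value
``p_vap / (kB T)`` while solid remains.

Integration is constant-T, constant-volume (box) with a stiff BDF solver.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
import numpy as np
from scipy.integrate import solve_ivp

from .constants import number_density_cm3
from .equilibrium import GasState
from .thermo import (ReactionStoichiometry, ThermoTable, graphite_vapor_pressure,
                     load_default_table)

__all__ = [
    "Reaction",
    "Network",
    "Trajectory",
    "NetworkParseError",
    "IntegrationError",
    "parse_network",
    "reverse_rate_constant",
    "graphite_exchange_rates",
    "integrate",
    "time_to_equilibrium",
    "NOT_CONVERGED",
]

NOT_CONVERGED = math.inf     # sentinel returned by time_to_equilibrium


class NetworkParseError(ValueError):
    pass


class IntegrationError(RuntimeError):
    def __init__(self, msg, last_state=None):
        super().__init__(msg)
        self.last_state = last_state


@dataclass(frozen=True)
class Reaction:
    """Stoichiometry + forward rate law; reverse rate implied by thermochemistry."""

    stoichiometry: ReactionStoichiometry
    forward_rate: tuple          # (A, n, Ea[K]) modified Arrhenius
    reversible: bool = True

    def k_forward(self, t_kelvin: float) -> float:
        a, n, ea = self.forward_rate
        return a * (t_kelvin / 300.0) ** n * math.exp(-ea / t_kelvin)

    def delta_nu(self) -> int:
        return (sum(self.stoichiometry.products.values())
                - sum(self.stoichiometry.reactants.values()))


@dataclass
class Network:
    reactions: list
    includes_graphite_exchange: bool = False

    @property
    def species(self) -> list:
        seen: dict = {}
        for rxn in self.reactions:
            for sp in list(rxn.stoichiometry.reactants) + list(rxn.stoichiometry.products):
                seen[sp] = True
        return list(seen)

    def to_text(self) -> str:
        """Serialize to the reaction-list dialect (parse_network round-trips)."""
        lines = [f"# species: {len(self.species)}",
                 f"# reactions: {len(self.reactions)}",
                 f"# graphite_exchange: {'true' if self.includes_graphite_exchange else 'false'}"]
        for rxn in self.reactions:
            def side(d):
                return " + ".join(f"{nu} {sp}" if nu > 1 else sp
                                  for sp, nu in d.items())
            arrow = "<=>" if rxn.reversible else "->"
            a, n, ea = rxn.forward_rate
            lines.append(f"{side(rxn.stoichiometry.reactants)} {arrow} "
                         f"{side(rxn.stoichiometry.products)} ; A={a!r} n={n!r} Ea={ea!r}")
        return "\n".join(lines) + "\n"

    def validate(self, table: ThermoTable) -> None:
        keys = set()
        for i, rxn in enumerate(self.reactions):
            imbalance = rxn.stoichiometry.element_imbalance(table)
            if imbalance:
                raise NetworkParseError(f"reaction {i}: element imbalance {imbalance}")
            key = (frozenset(rxn.stoichiometry.reactants.items()),
                   frozenset(rxn.stoichiometry.products.items()))
            if key in keys or (key[1], key[0]) in keys:
                raise NetworkParseError(f"reaction {i}: duplicate reaction")
            keys.add(key)


@dataclass
class Trajectory:
    times: np.ndarray            # s, strictly increasing
    states: np.ndarray           # (n_times, n_species) concentrations, cm^-3
    species: list
    t_kelvin: float
    p_bar: float                 # initial total pressure
    solid_carbon: np.ndarray | None = None    # cm^-3-equivalent reservoir

    def mixing_ratios(self, index: int = -1) -> dict:
        n = self.states[index]
        tot = n.sum()
        return {sp: float(v / tot) for sp, v in zip(self.species, n)}

    def final_pressure_bar(self) -> float:
        from .constants import BAR_TO_PA, K_BOLTZMANN
        n_tot = float(self.states[-1].sum()) * 1e6          # m^-3
        return n_tot * K_BOLTZMANN * self.t_kelvin / BAR_TO_PA


# ------------------------------------------------------------------ parsing
_RATE_RE = re.compile(r"A\s*=\s*([-\d.eE+]+)\s+n\s*=\s*([-\d.eE+]+)\s+Ea\s*=\s*([-\d.eE+]+)")


def _parse_side(text: str, lineno: int) -> dict:
    out: dict = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise NetworkParseError(f"line {lineno}: empty species term")
        m = re.match(r"^(\d+)\s+(.*)$", term)
        nu, name = (int(m.group(1)), m.group(2).strip()) if m else (1, term)
        out[name] = out.get(name, 0) + nu
    return out


def parse_network(text: str, table: ThermoTable | None = None) -> Network:
    """Parse the repo reaction-list dialect.

    One reaction per line: ``R1 + 2 R2 <=> P1 + P2 ; A=<val> n=<val> Ea=<val>``
    (``->`` for irreversible).  ``#`` starts a comment; header comments of the
    form ``# key: value`` declare fixture metadata (``species``, ``reactions``
    counts are checked, ``graphite_exchange`` sets the flag).
    """
    table = table or load_default_table()
    reactions = []
    meta: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            m = re.match(r"#\s*([\w_]+)\s*:\s*(\S+)", line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        if not line:
            continue
        if ";" in line:
            eqn, ratepart = line.split(";", 1)
            m = _RATE_RE.search(ratepart)
            if not m:
                raise NetworkParseError(f"line {lineno}: bad rate spec {ratepart!r}")
            rate = (float(m.group(1)), float(m.group(2)), float(m.group(3)))
        else:
            eqn, rate = line, (0.0, 0.0, 0.0)
        if "<=>" in eqn:
            lhs, rhs = eqn.split("<=>")
            reversible = True
        elif "->" in eqn:
            lhs, rhs = eqn.split("->")
            reversible = False
        else:
            raise NetworkParseError(f"line {lineno}: no reaction arrow in {eqn!r}")
        try:
            stoich = ReactionStoichiometry(reactants=_parse_side(lhs, lineno),
                                           products=_parse_side(rhs, lineno))
        except ValueError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
        for sp in list(stoich.reactants) + list(stoich.products):
            if sp not in table:
                raise NetworkParseError(f"line {lineno}: unknown species {sp!r}")
        imbalance = stoich.element_imbalance(table)
        if imbalance:
            raise NetworkParseError(f"line {lineno}: element imbalance {imbalance}")
        reactions.append(Reaction(stoichiometry=stoich, forward_rate=rate,
                                  reversible=reversible))
    net = Network(reactions=reactions,
                  includes_graphite_exchange=meta.get("graphite_exchange", "false")
                  in ("true", "True", "1"))
    net.validate(table)
    for key, attr in (("species", len(net.species)), ("reactions", len(net.reactions))):
        if key in meta and int(meta[key]) != attr:
            raise NetworkParseError(
                f"header declares {meta[key]} {key}, parsed {attr}")
    return net


# ------------------------------------------------------------------ rates
def _ln_kc(rxn: Reaction, table: ThermoTable, t_kelvin: float) -> float:
    """ln of the concentration-units equilibrium constant."""
    g = 0.0
    for sp, nu in rxn.stoichiometry.net_coefficients().items():
        g += nu * table.g_rt(sp, t_kelvin)
    ln_kp = -g                                  # activities in bar
    n_std = number_density_cm3(1.0, t_kelvin)   # cm^-3 at 1 bar
    return ln_kp + rxn.delta_nu() * math.log(n_std)


def reverse_rate_constant(rxn: Reaction, t_kelvin: float, k_forward: float,
                          table: ThermoTable | None = None) -> float:
    """k- = k+ / Kc; units implied by the reverse reaction order."""
    if not rxn.reversible:
        raise ValueError("reaction is irreversible; no reverse rate")
    table = table or load_default_table()
    ln_kc = _ln_kc(rxn, table, t_kelvin)
    return k_forward * math.exp(min(max(-ln_kc, -700.0), 700.0))


def graphite_exchange_rates(t_kelvin: float, tau_seconds: float = 1.0e-8,
                            variant: str = "kinetics") -> tuple:
    """(condensation rate constant s^-1, evaporation rate cm^-3 s^-1).

    The ratio pins the steady-state gas-phase carbon concentration at the
    saturation value ``p_vap/(kB T)``; the absolute scale is the configurable
    relaxation timescale ``tau``.
    """
    warnings: list = []
    p_vap = graphite_vapor_pressure(t_kelvin, variant, warn_out_of_window=warnings)
    if warnings:
        raise ValueError(warnings[0])
    k_cond = 1.0 / tau_seconds
    n_sat = number_density_cm3(p_vap, t_kelvin)
    return k_cond, k_cond * n_sat


# ------------------------------------------------------------------ integration
def integrate(net: Network, initial: GasState, t_kelvin: float, p_bar: float,
              t_end: float = 86400.0, table: ThermoTable | None = None,
              initial_solid_carbon: float = 0.0, tau_graphite: float = 1.0e-8,
              vapor_pressure_variant: str = "kinetics",
              n_samples: int = 60, floor_fraction: float = 1e-30,
              rtol: float = 1e-8, atol: float = 1e-20) -> Trajectory:
    """Integrate the network ODEs from ``initial`` to ``t_end`` seconds.

    Constant temperature and volume; the box is filled to ``p_bar`` at t=0.
    Species of the network absent from ``initial`` start at a floor value.
    ``initial_solid_carbon`` is a graphite reservoir in carbon atoms per cm^3
    (only used when the network includes graphite exchange).
    """
    table = table or load_default_table()
    species = net.species
    idx = {sp: i for i, sp in enumerate(species)}
    n_tot0 = number_density_cm3(p_bar, t_kelvin)
    y0 = np.full(len(species), floor_fraction * n_tot0)
    for sp, x in initial.mixing_ratios.items():
        if sp in idx and x > 0:
            y0[idx[sp]] = x * n_tot0

    # Work in density-scaled variables (n / n_tot0, O(1)): opposing forward and
    # reverse fluxes near equilibrium otherwise reach ~1e19 cm^-3 s^-1 and
    # their difference drowns in roundoff, wrecking the finite-difference
    # Jacobians of the stiff solver.
    scale = n_tot0
    y0 = y0 / scale
    rxn_data = []
    for rxn in net.reactions:
        kf = rxn.k_forward(t_kelvin)
        re_idx = [(idx[sp], nu) for sp, nu in rxn.stoichiometry.reactants.items()]
        pr_idx = [(idx[sp], nu) for sp, nu in rxn.stoichiometry.products.items()]
        kr = 0.0
        if rxn.reversible and kf > 0:
            kr = reverse_rate_constant(rxn, t_kelvin, kf, table)
        order_f = sum(nu for _, nu in re_idx)
        order_r = sum(nu for _, nu in pr_idx)
        rxn_data.append((kf * scale ** (order_f - 1), kr * scale ** (order_r - 1),
                         re_idx, pr_idx))

    has_solid = net.includes_graphite_exchange
    if has_solid:
        if "C" not in idx:
            raise NetworkParseError("graphite exchange requires gas-phase species C")
        k_cond, evap = graphite_exchange_rates(t_kelvin, tau_graphite,
                                               vapor_pressure_variant)
        n_sat = evap / k_cond / scale
        i_c = idx["C"]
        y0 = np.append(y0, max(initial_solid_carbon, 0.0) / scale)

    n_gas = len(species)

    def chem_rhs(n, dy):
        for kf, kr, re_idx, pr_idx in rxn_data:
            fwd = kf
            for i, nu in re_idx:
                fwd *= n[i] ** nu
            rev = kr
            if kr > 0:
                for i, nu in pr_idx:
                    rev *= n[i] ** nu
            net_rate = fwd - rev
            for i, nu in re_idx:
                dy[i] -= nu * net_rate
            for i, nu in pr_idx:
                dy[i] += nu * net_rate

    # Graphite exchange is a saturation-adjustment flux k_cond (n_C - n_sat):
    # with solid present it acts both ways (evaporation down to, condensation
    # above, the saturation concentration); with the reservoir exhausted only
    # supersaturation condenses.  The regimes are switched by integrator events.
    def make_rhs(solid_present):
        def rhs(t, y):
            n = np.maximum(y[:n_gas], 0.0)
            dy = np.zeros_like(y)
            chem_rhs(n, dy)
            if has_solid:
                if solid_present:
                    flux = k_cond * (n[i_c] - n_sat)
                else:
                    flux = k_cond * max(n[i_c] - n_sat, 0.0)
                dy[i_c] -= flux
                dy[n_gas] = flux
            return dy
        return rhs

    t_eval = np.concatenate([[0.0], np.geomspace(max(t_end * 1e-10, 1e-8),
                                                 t_end, n_samples)])
    times = [np.array([0.0])]
    states = [y0[None, :].copy()]
    t_cur, y_cur = 0.0, y0.copy()
    guard = 0
    while t_cur < t_end:
        guard += 1
        if guard > 50:
            raise IntegrationError("too many graphite on/off phase switches",
                                   last_state=y_cur)
        solid_present = has_solid and y_cur[n_gas] > 0.0
        events = None
        if has_solid and solid_present:
            def solid_gone(t, y):
                return y[n_gas]
            solid_gone.terminal = True
            solid_gone.direction = -1
            events = [solid_gone]
        elif has_solid:
            # solid may regrow during supersaturation; once the gas drops back
            # below saturation with solid present, evaporation must resume
            def subsaturated_again(t, y):
                return y[i_c] - n_sat if y[n_gas] > 0 else 1.0
            subsaturated_again.terminal = True
            subsaturated_again.direction = -1
            events = [subsaturated_again]
        # autonomous RHS: integrate each phase from a shifted origin so the
        # stiff restart step is not limited by float spacing at large t
        mask = (t_eval > t_cur) & (t_eval <= t_end)
        sol = solve_ivp(make_rhs(solid_present), (0.0, t_end - t_cur), y_cur,
                        method="BDF", t_eval=t_eval[mask] - t_cur, events=events,
                        rtol=rtol, atol=atol / scale)
        sol.t = sol.t + t_cur
        if sol.t_events:
            sol.t_events = [te + t_cur for te in sol.t_events]
        if sol.status == -1:
            y_arr = np.asarray(sol.y)
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   last_state=y_arr[:, -1] if y_arr.size else y_cur)
        if sol.t.size:
            times.append(sol.t)
            states.append(sol.y.T)
        if sol.status == 1:      # regime switch
            t_cur = float(sol.t_events[0][0])
            y_cur = sol.y_events[0][0].copy()
            if solid_present:    # reservoir exhausted
                y_cur[n_gas] = 0.0
        else:
            break
    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[keep]
    gas_states = np.maximum(y_all[:, :n_gas], 0.0) * scale
    solid = y_all[:, n_gas] * scale if has_solid else None
    return Trajectory(times=t_all, states=gas_states, species=species,
                      t_kelvin=t_kelvin, p_bar=p_bar, solid_carbon=solid)


def time_to_equilibrium(traj: Trajectory, reference: GasState, tol: float,
                        floor: float = 1e-10) -> float:
    """First sampled time at which the max relative deviation of the trajectory's
    mixing ratios from ``reference`` (species above ``floor``) is < tol.
    Returns the NOT_CONVERGED sentinel (inf) if never reached."""
    ref = {sp: x for sp, x in reference.mixing_ratios.items() if x > floor}
    for k, t in enumerate(traj.times):
        mix = traj.mixing_ratios(k)
        dev = max(abs(mix.get(sp, 0.0) - x) / x for sp, x in ref.items())
        if dev < tol:
            return float(t)
    return NOT_CONVERGED
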