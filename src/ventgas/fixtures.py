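"""Synthetic inputs for every stage: the fiducial magmatic-gas composition,
random element budgets, and random reversible toy networks whose equilibria are
computable by an independent brute-force oracle.

All generators are deterministic given a :class:`FixtureSpec` seed (PCG64 via
``numpy.random.default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
import numpy as np

from .constants import celsius_to_kelvin
from .equilibrium import ElementBudget, GasState
from .thermo import ThermoSpecies, ThermoTable

__all__ = [
    "FixtureSpec",
    "TABLE1_MIXING_RATIOS",
    "table1_gas",
    "table1_budget",
    "random_budget",
    "toy_network",
    "ToyNetworkResult",
    "reduced_network_text",
]

# Fiducial initial gas: 1700 degC, 100 bar, QFM-1 magmatic gas with 5.7% N2.
# Printed ratios sum to ~0.997; the residual is assigned proportionally so the
# state normalizes exactly.
TABLE1_MIXING_RATIOS = {
    "CO": 0.35,
    "H2": 0.10,
    "N2": 0.057,
    "O2": 7.6e-10,
    "CH4": 1.4e-6,
    "CO2": 0.23,
    "H2O": 0.26,
}
TABLE1_T_KELVIN = celsius_to_kelvin(1700.0)   # 1973.15 K
TABLE1_P_BAR = 100.0


def table1_gas() -> GasState:
    """The fiducial initial gas state (T=1973.15 K, P=100 bar), normalized."""
    tot = sum(TABLE1_MIXING_RATIOS.values())
    ratios = {k: v / tot for k, v in TABLE1_MIXING_RATIOS.items()}
    return GasState(t_kelvin=TABLE1_T_KELVIN, p_bar=TABLE1_P_BAR, mixing_ratios=ratios)


def table1_budget() -> ElementBudget:
    """Element budget implied by the fiducial gas (H:0.72, C:0.58, N:0.114, O:1.07
    atoms per molecule before normalization)."""
    from .equilibrium import mixing_ratios_to_elements
    return mixing_ratios_to_elements(table1_gas())


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible fixture parameters; identical spec -> identical fixture."""

    seed: int = 0
    n_species: int = 4
    element_palette: tuple = ("H", "C", "N", "O")
    rate_scale: float = 1.0       # s^-1, forward-rate magnitude for toy networks
    log10_range: tuple = (-2.0, 0.0)   # random-budget abundance bounds


def random_budget(spec: FixtureSpec) -> ElementBudget:
    """Log-uniform random element abundances over ``spec.log10_range``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.log10_range
    vals = 10.0 ** rng.uniform(lo, hi, size=len(spec.element_palette))
    return ElementBudget(dict(zip(spec.element_palette, vals)))


# ------------------------------------------------------------- toy networks
@dataclass
class ToyNetworkResult:
    network: "Network"                  # ventgas.kinetics.Network
    table: ThermoTable                  # synthetic thermo for the toy species
    equilibrium: dict                   # species -> mixing ratio (oracle)
    t_kelvin: float
    p_bar: float


def _toy_table(names, comps, rng, t_kelvin) -> ThermoTable:
    """Synthetic constant-Cp thermo rows spanning 200-6000 K."""
    table = ThermoTable(version="toy")
    for name, comp in zip(names, comps):
        a1 = rng.uniform(2.5, 5.5)
        a6 = rng.uniform(-3.0, 3.0) * t_kelvin       # H/R offset
        a7 = rng.uniform(5.0, 15.0)
        coeffs = (a1, 0.0, 0.0, 0.0, 0.0, a6, a7)
        table.add(ThermoSpecies(name=name, composition=comp, phase="gas",
                                coeff_sets=((200.0, 6000.0, coeffs),),
                                source_note="synthetic toy species"))
    return table


def _balanced_reactions(names, comps):
    """Enumerate element-balanced, mole-conserving candidate reactions with <=2
    species a side, coefficients <=2, and no species on both sides.

    Mole conservation keeps toy kinetics at constant pressure, so the packaged
    oracle equilibrium is directly the integration endpoint reference."""
    import itertools

    def atoms(multiset):
        out = {}
        for sp, nu in multiset:
            for el, n in comps[names.index(sp)].items():
                out[el] = out.get(el, 0) + nu * n
        return out

    sides = []
    for k in (1, 2):
        for combo in itertools.combinations(names, k):
            for coeffs in itertools.product((1, 2), repeat=k):
                sides.append(tuple(zip(combo, coeffs)))
    found = []
    for i, lhs in enumerate(sides):
        for rhs in sides[i + 1:]:
            if {s for s, _ in lhs} & {s for s, _ in rhs}:
                continue
            if sum(nu for _, nu in lhs) != sum(nu for _, nu in rhs):
                continue
            if atoms(lhs) == atoms(rhs):
                found.append((dict(lhs), dict(rhs)))
    return found


def _oracle_equilibrium(g, p_total, nu_matrix, n0):
    """Brute-force equilibrium: dense-grid Gibbs minimization over reaction
    extents, iteratively zoomed.  Independent of the element-potential solver.

    ``n0``: any element-conserving starting composition (moles), ``nu_matrix``
    rows are net stoichiometric vectors of an independent reaction basis.
    """
    n_rxn = nu_matrix.shape[0]

    def gibbs_batch(extents):
        n = n0[None, :] + extents @ nu_matrix          # (m, n_species)
        bad = (n < 0).any(axis=1)
        n = np.maximum(n, 1e-300)
        ntot = n.sum(axis=1, keepdims=True)
        vals = np.sum(n * (g[None, :] + np.log(n / ntot) + math.log(p_total)),
                      axis=1)
        vals[bad] = np.inf
        return vals

    # the Gibbs surface is strictly convex over the feasible extent polytope,
    # so a zoomed dense grid converges to the unique minimum; the window only
    # shrinks once the best point is interior to the current grid
    centre = np.zeros(n_rxn)
    width = np.full(n_rxn, 2.0)   # extents in mole units; budget is O(1)
    pts = 11 if n_rxn <= 2 else 9
    best = (np.inf, centre.copy())
    for _ in range(140):
        axes = [np.linspace(c - w, c + w, pts) for c, w in zip(centre, width)]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([gr.ravel() for gr in grids], axis=1)
        vals = gibbs_batch(flat)
        k = int(np.argmin(vals))
        if not math.isfinite(vals[k]):
            width *= 0.5
            continue
        if vals[k] < best[0]:
            best = (float(vals[k]), flat[k].copy())
        centre = flat[k].copy()
        idx = np.unravel_index(k, (pts,) * n_rxn)
        on_edge = any(i == 0 or i == pts - 1 for i in idx)
        width *= 1.0 if on_edge else 0.5
        if np.max(width) < 1e-13:
            break
    n = np.maximum(n0 + nu_matrix.T @ best[1], 0.0)
    return n / n.sum()


def toy_network(spec: FixtureSpec):
    """Random element-balanced reversible network plus its reference equilibrium.

    Returns a :class:`ToyNetworkResult` whose ``equilibrium`` comes from a
    dense-grid Gibbs-minimization oracle (brute force; requires
    ``spec.n_species <= 8``).
    """
    from .kinetics import Network, Reaction
    from .thermo import ReactionStoichiometry

    if spec.n_species > 8:
        raise ValueError("toy networks are limited to 8 species (brute-force oracle)")
    rng = np.random.default_rng(spec.seed)
    t_kelvin, p_bar = 1500.0, 1.0

    for _ in range(400):  # retry until a connected, full-rank network appears
        n_el = max(1, min(len(spec.element_palette), spec.n_species // 2))
        elements = list(spec.element_palette[:n_el])
        comps, names = [], []
        for i in range(spec.n_species):
            comp = {}
            for el in elements:
                n = int(rng.integers(0, 3))
                if n:
                    comp[el] = n
            if not comp:
                comp[elements[int(rng.integers(0, n_el))]] = 1
            comps.append(comp)
            names.append(f"S{i}")
        candidates = _balanced_reactions(names, comps)
        rng.shuffle(candidates)
        if not candidates:
            continue
        # greedily keep reactions that add rank
        chosen, vecs = [], []
        for lhs, rhs in candidates:
            vec = np.zeros(len(names))
            for sp, nu in rhs.items():
                vec[names.index(sp)] += nu
            for sp, nu in lhs.items():
                vec[names.index(sp)] -= nu
            trial = vecs + [vec]
            if np.linalg.matrix_rank(np.array(trial)) == len(trial):
                chosen.append((lhs, rhs))
                vecs.append(vec)
        covered = {sp for lhs, rhs in chosen for sp in list(lhs) + list(rhs)}
        if len(chosen) == 0 or covered != set(names):
            continue
        # the basis must span the whole composition space modulo element
        # conservation, so the network equilibrium is the full equilibrium
        comp_m = np.array([[c.get(el, 0) for el in elements] for c in comps])
        if len(vecs) != spec.n_species - np.linalg.matrix_rank(comp_m):
            continue
        table = _toy_table(names, comps, rng, t_kelvin)
        from .constants import number_density_cm3
        n_ref = number_density_cm3(p_bar, t_kelvin)
        reactions = []
        for lhs, rhs in chosen:
            stoich = ReactionStoichiometry(reactants=lhs, products=rhs)
            order = sum(lhs.values())
            # scale by density so pseudo-first-order rates are ~rate_scale s^-1
            a_fwd = (spec.rate_scale * 10.0 ** rng.uniform(-1, 1)
                     / n_ref ** (order - 1))
            reactions.append(Reaction(stoichiometry=stoich,
                                      forward_rate=(a_fwd, 0.0, 0.0),
                                      reversible=True))
        net = Network(reactions=reactions, includes_graphite_exchange=False)

        # oracle equilibrium from an equal-abundance start
        g = np.array([table.g_rt(nm, t_kelvin) for nm in names])
        n0 = np.full(len(names), 1.0 / len(names))
        nu_matrix = np.array(vecs)
        x = _oracle_equilibrium(g, p_bar, nu_matrix, n0)
        eq = {nm: float(xi) for nm, xi in zip(names, x)}
        return ToyNetworkResult(network=net, table=table, equilibrium=eq,
                                t_kelvin=t_kelvin, p_bar=p_bar)
    raise RuntimeError("failed to generate a connected toy network")


def reduced_network_text() -> str:
    """The packaged reduced H/C/N/O reaction-network fixture (plain text)."""
    ref = resources.files("ventgas.data").joinpath("reduced_network.txt")
    return ref.read_text()
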