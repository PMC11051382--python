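"""NASA-7 thermochemistry: species free energies, reaction energetics, equilibrium
constants, the cyanoacetylene mass-action constant, and graphite vapor pressures.

The packaged coefficient table (``data/thermo_hcno.csv``) covers ~34 H/C/N/O gas
species.  Standard state is the ideal gas at 1 bar; activities are partial
pressures in bar.  All dimensionless free energies here are ``g = G/(R T)``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .constants import R_GAS

__all__ = [
    "ThermoSpecies",
    "ThermoTable",
    "ReactionStoichiometry",
    "VaporPressureFit",
    "GRAPHITE_VP_KINETICS",
    "GRAPHITE_VP_EQUILIBRIUM",
    "gibbs_of_formation",
    "reaction_delta_g",
    "equilibrium_constant",
    "hc3n_ln_mass_action",
    "graphite_vapor_pressure",
    "load_default_table",
]

REFERENCE_SPECIES = {"H": ("H2", 2), "O": ("O2", 2), "N": ("N2", 2)}


class TemperatureRangeError(ValueError):
    """Raised when a species polynomial is evaluated outside its fitted range."""


@dataclass(frozen=True)
class ThermoSpecies:
    """One species: elemental makeup, phase and piecewise NASA-7 coefficients.

    ``coeff_sets`` is a list of ``(T_low, T_high, (c1..c7))`` with contiguous,
    non-overlapping temperature ranges.
    """

    name: str
    composition: Mapping[str, int]
    phase: str = "gas"
    coeff_sets: tuple = ()
    source_note: str = ""

    def __post_init__(self):
        if not self.composition or any(n <= 0 for n in self.composition.values()):
            raise ValueError(f"{self.name}: composition must be non-empty with positive counts")
        if self.phase not in ("gas", "solid"):
            raise ValueError(f"{self.name}: phase must be gas or solid")
        ranges = sorted(self.coeff_sets)
        for (lo1, hi1, _), (lo2, hi2, _) in zip(ranges, ranges[1:]):
            if hi1 > lo2 + 1e-9:
                raise ValueError(f"{self.name}: overlapping coefficient ranges")

    def _coeffs(self, t_kelvin: float):
        for lo, hi, c in self.coeff_sets:
            if lo <= t_kelvin <= hi:
                return c
        raise TemperatureRangeError(
            f"T={t_kelvin} K outside coefficient ranges for species {self.name!r}"
        )

    def cp_r(self, t_kelvin: float) -> float:
        """Heat capacity Cp/R."""
        c = self._coeffs(t_kelvin)
        t = t_kelvin
        return c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3 + c[4] * t**4

    def h_rt(self, t_kelvin: float) -> float:
        """Enthalpy H/(R T), including the formation enthalpy offset (a6)."""
        c = self._coeffs(t_kelvin)
        t = t_kelvin
        return (c[0] + c[1] / 2 * t + c[2] / 3 * t**2 + c[3] / 4 * t**3
                + c[4] / 5 * t**4 + c[5] / t)

    def s_r(self, t_kelvin: float) -> float:
        """Absolute entropy S/R."""
        c = self._coeffs(t_kelvin)
        t = t_kelvin
        return (c[0] * math.log(t) + c[1] * t + c[2] / 2 * t**2 + c[3] / 3 * t**3
                + c[4] / 4 * t**4 + c[6])

    def g_rt(self, t_kelvin: float) -> float:
        """Standard-state chemical potential mu0/(R T) = H/(R T) - S/R."""
        return self.h_rt(t_kelvin) - self.s_r(t_kelvin)


@dataclass
class ThermoTable:
    """Collection of :class:`ThermoSpecies`, keyed by name."""

    species: dict = field(default_factory=dict)
    version: str = "unversioned"

    def add(self, sp: ThermoSpecies) -> None:
        if sp.name in self.species:
            raise ValueError(f"duplicate species {sp.name!r}")
        self.species[sp.name] = sp

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def __getitem__(self, name: str) -> ThermoSpecies:
        try:
            return self.species[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in thermo table") from None

    def names(self) -> list:
        return list(self.species)

    def g_rt(self, name: str, t_kelvin: float) -> float:
        return self[name].g_rt(t_kelvin)

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path_or_lines, version: str = "unversioned") -> "ThermoTable":
        """Read the repo CSV dialect: one row per coefficient range.

        Columns: name, composition ("H:1 C:1"), phase, T_low, T_high, c1..c7,
        source_note.
        """
        if hasattr(path_or_lines, "read") or isinstance(path_or_lines, list):
            rows = list(csv.DictReader(path_or_lines))
        else:
            with open(path_or_lines, newline="") as fh:
                rows = list(csv.DictReader(fh))
        grouped: dict = {}
        for r in rows:
            comp = {}
            for tok in r["composition"].split():
                el, n = tok.split(":")
                comp[el] = int(n)
            key = r["name"]
            grouped.setdefault(key, {"comp": comp, "phase": r["phase"],
                                     "note": r.get("source_note", ""), "ranges": []})
            coeffs = tuple(float(r[f"c{i}"]) for i in range(1, 8))
            grouped[key]["ranges"].append((float(r["T_low"]), float(r["T_high"]), coeffs))
        table = cls(version=version)
        for name, d in grouped.items():
            table.add(ThermoSpecies(name=name, composition=d["comp"], phase=d["phase"],
                                    coeff_sets=tuple(sorted(d["ranges"])),
                                    source_note=d["note"]))
        return table

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "species": [
                {"name": sp.name, "composition": dict(sp.composition), "phase": sp.phase,
                 "coeff_sets": [[lo, hi, list(c)] for lo, hi, c in sp.coeff_sets],
                 "source_note": sp.source_note}
                for sp in self.species.values()
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ThermoTable":
        payload = json.loads(text)
        table = cls(version=payload.get("version", "unversioned"))
        for d in payload["species"]:
            table.add(ThermoSpecies(
                name=d["name"], composition=d["composition"], phase=d["phase"],
                coeff_sets=tuple((lo, hi, tuple(c)) for lo, hi, c in d["coeff_sets"]),
                source_note=d.get("source_note", "")))
        return table


_DEFAULT_TABLE = None


def load_default_table() -> ThermoTable:
    """The packaged H/C/N/O table (GRI-Mech 3.0 transcription + RRHO-constructed rows)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("ventgas.data").joinpath("thermo_hcno.csv")
        with ref.open("r", newline="") as fh:
            _DEFAULT_TABLE = ThermoTable.from_csv(list(fh), version="hcno-1")
    return _DEFAULT_TABLE


# ------------------------------------------------------------------ reactions
@dataclass(frozen=True)
class ReactionStoichiometry:
    """Element-balanced reaction: maps species -> positive integer coefficients."""

    reactants: Mapping[str, int]
    products: Mapping[str, int]

    def __post_init__(self):
        if set(self.reactants) & set(self.products):
            both = set(self.reactants) & set(self.products)
            raise ValueError(f"species on both sides of reaction: {sorted(both)}")
        for side in (self.reactants, self.products):
            if any(v <= 0 or int(v) != v for v in side.values()):
                raise ValueError("stoichiometric coefficients must be positive integers")

    def net_coefficients(self) -> dict:
        out: dict = {}
        for sp, nu in self.products.items():
            out[sp] = out.get(sp, 0) + nu
        for sp, nu in self.reactants.items():
            out[sp] = out.get(sp, 0) - nu
        return out

    def element_imbalance(self, table: ThermoTable) -> dict:
        counts: dict = {}
        for sp, nu in self.net_coefficients().items():
            for el, n in table[sp].composition.items():
                counts[el] = counts.get(el, 0) + nu * n
        return {el: v for el, v in counts.items() if v != 0}

    def reversed(self) -> "ReactionStoichiometry":
        return ReactionStoichiometry(reactants=self.products, products=self.reactants)


def _check_reaction(rxn: ReactionStoichiometry, table: ThermoTable) -> None:
    imbalance = rxn.element_imbalance(table)
    if imbalance:
        raise ValueError(f"reaction not element-balanced: {imbalance}")


def gibbs_of_formation(species: ThermoSpecies, t_kelvin: float,
                       table: ThermoTable | None = None,
                       graphite_variant: str = "equilibrium") -> float:
    """Dimensionless formation free energy DfG/(R T) from the reference elements.

    References: H2, O2, N2 ideal gas at 1 bar, and graphite for carbon.  The
    graphite chemical potential is tied to the gas-phase carbon atom through the
    saturation vapor pressure (mu_graphite = mu_C(g) + R T ln p_vap), i.e. the
    same convention the saturation clamp uses.  For reference elements the
    result is ~0 at every temperature.
    """
    table = table or load_default_table()
    g = species.g_rt(t_kelvin)
    for el, n in species.composition.items():
        if el == "C":
            mu_c = table["C"].g_rt(t_kelvin) + math.log(
                graphite_vapor_pressure(t_kelvin, graphite_variant))
            g -= n * mu_c
        elif el in REFERENCE_SPECIES:
            ref_name, atoms = REFERENCE_SPECIES[el]
            g -= n * table[ref_name].g_rt(t_kelvin) / atoms
        else:
            raise ValueError(f"no reference species defined for element {el!r}")
    return g


def reaction_delta_g(rxn: ReactionStoichiometry, table: ThermoTable,
                     t_kelvin: float) -> float:
    """Reaction free energy DrG in kJ/mol (products minus reactants).

    Reference-element offsets cancel for balanced reactions, so this is computed
    directly from the standard-state chemical potentials.
    """
    _check_reaction(rxn, table)
    g = sum(nu * table.g_rt(sp, t_kelvin) for sp, nu in rxn.net_coefficients().items())
    return g * R_GAS * t_kelvin / 1000.0


def equilibrium_constant(rxn: ReactionStoichiometry, table: ThermoTable,
                         t_kelvin: float) -> float:
    """Keq = exp(-DrG/(R T)), activities referenced to the 1 bar standard state."""
    drg_kj = reaction_delta_g(rxn, table, t_kelvin)
    return math.exp(-drg_kj * 1000.0 / (R_GAS * t_kelvin))


def hc3n_ln_mass_action(t_kelvin: float) -> float:
    """ln K for assembling HC3N from neutral atoms (H + 3 C + N -> HC3N).

    Polynomial fit in T (K); activities in bar.  Valid roughly 500-6000 K.
    """
    if t_kelvin <= 0:
        raise ValueError("temperature must be positive")
    t = t_kelvin
    return 2.96e5 / t - 4.83 * math.log(t) - 28.47 + 1.91e-3 * t - 1.10e-7 * t**2


# ------------------------------------------------------- graphite saturation
@dataclass(frozen=True)
class VaporPressureFit:
    """log10 p_vap(bar) = a - b/T - c/T^2 for carbon monomer over graphite."""

    a: float
    b: float
    c: float
    t_low: float = 1000.0
    t_high: float = 4500.0

    def log10_p(self, t_kelvin: float) -> float:
        return self.a - self.b / t_kelvin - self.c / t_kelvin**2

    def p_bar(self, t_kelvin: float) -> float:
        return 10.0 ** self.log10_p(t_kelvin)

    def in_window(self, t_kelvin: float) -> bool:
        return self.t_low <= t_kelvin <= self.t_high


# The quadratic term is read as c/T^2 (standard extended Clausius form); the
# effective sublimation enthalpies then match carbon-atom sublimation
# (~680-720 kJ/mol) and the equilibrium fit reproduces exp(-DfG(C,g)/RT) from
# standard tables to ~0.01 dex at 2000 K.  Coefficients are overridable.
GRAPHITE_VP_KINETICS = VaporPressureFit(a=6.455, b=2.7709e4, c=1.0e7)
GRAPHITE_VP_EQUILIBRIUM = VaporPressureFit(a=4.855, b=2.5709e4, c=1.0e7)

_VARIANTS = {"kinetics": GRAPHITE_VP_KINETICS, "equilibrium": GRAPHITE_VP_EQUILIBRIUM}


def graphite_vapor_pressure(t_kelvin: float, variant: str = "equilibrium",
                            fit: VaporPressureFit | None = None,
                            warn_out_of_window: list | None = None) -> float:
    """Saturation vapor pressure of carbon monomer over graphite, in bar.

    ``variant`` selects the coefficient set used by the kinetics or the
    equilibrium model; a custom :class:`VaporPressureFit` overrides both.
    Outside the 1000-4500 K validity window the fit is still evaluated and the
    optional ``warn_out_of_window`` list receives a message (no exception).
    """
    if fit is None:
        try:
            fit = _VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown vapor-pressure variant {variant!r}") from None
    if not fit.in_window(t_kelvin) and warn_out_of_window is not None:
        warn_out_of_window.append(
            f"T={t_kelvin} K outside graphite vapor-pressure fit window "
            f"[{fit.t_low}, {fit.t_high}] K")
    return fit.p_bar(t_kelvin)
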