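"""Network parsing, detailed-balance reverse rates, stiff integration,
graphite exchange, and relaxation to the equilibrium solver's answer."""

import math

import numpy as np
import pytest

from ventgas.constants import number_density_cm3
from ventgas.equilibrium import ElementBudget, GasState, SolverOptions, \
    equilibrate_with_graphite, mixing_ratios_to_elements, solve_gas_equilibrium
from ventgas.fixtures import FixtureSpec, reduced_network_text, toy_network
from ventgas.kinetics import (NOT_CONVERGED, NetworkParseError, Reaction,
                              graphite_exchange_rates, integrate, parse_network,
                              reverse_rate_constant, time_to_equilibrium)
from ventgas.thermo import (ReactionStoichiometry, ThermoSpecies, ThermoTable,
                            graphite_vapor_pressure)

T1700 = 1973.15


def two_species_table(ln_keq: float, t_kelvin: float = 1000.0) -> ThermoTable:
    """Synthetic A<=>B system with Keq = exp(ln_keq) at every temperature."""
    table = ThermoTable(version="ab")
    for name, a7 in (("A", 0.0), ("B", ln_keq)):
        # constant g/RT = -a7 (h=0, s/R=a7), so Keq(A->B) = exp(a7_B)
        coeffs = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, a7)
        table.add(ThermoSpecies(name=name, composition={"H": 1}, phase="gas",
                                coeff_sets=((200.0, 6000.0, coeffs),),
                                source_note="synthetic"))
    return table


class TestParsing:
    def test_single_line(self, table):
        net = parse_network("H2 + CO2 <=> H2O + CO ; A=1e-12 n=0 Ea=0", table)
        assert len(net.reactions) == 1 and sorted(net.species) == ["CO", "CO2", "H2", "H2O"]
        assert net.reactions[0].reversible

    def test_same_species_both_sides_rejected(self, table):
        with pytest.raises(NetworkParseError):
            parse_network("C2H2 -> C2H2 ; A=1 n=0 Ea=0", table)

    def test_element_imbalance_reports_line_number(self, table):
        with pytest.raises(NetworkParseError, match="line 2"):
            parse_network("H2 <=> H + H ; A=1 n=0 Ea=0\nCH4 <=> CO ; A=1 n=0 Ea=0",
                          table)

    def test_reduced_fixture_matches_header_counts(self, table):
        net = parse_network(reduced_network_text(), table)
        # counts declared in the fixture header (parse_network cross-checks)
        assert len(net.species) == 19
        assert len(net.reactions) == 17
        assert net.includes_graphite_exchange
        # enough independent reactions to span composition space
        names = net.species
        m = np.zeros((len(net.reactions), len(names)))
        for i, rxn in enumerate(net.reactions):
            for sp, nu in rxn.stoichiometry.net_coefficients().items():
                m[i, names.index(sp)] = nu
        assert np.linalg.matrix_rank(m) == len(names) - 4

    def test_round_trip(self, table):
        net = parse_network(reduced_network_text(), table)
        again = parse_network(net.to_text(), table)
        assert len(again.reactions) == len(net.reactions)
        for a, b in zip(net.reactions, again.reactions):
            assert a.stoichiometry == b.stoichiometry
            assert a.forward_rate == b.forward_rate


class TestReverseRates:
    def test_unit_keq_gives_equal_rates(self):
        table = two_species_table(0.0)
        rxn = Reaction(ReactionStoichiometry({"A": 1}, {"B": 1}), (2.5, 0.0, 0.0))
        assert reverse_rate_constant(rxn, 1000.0, 2.5, table) == pytest.approx(2.5)

    def test_ratio_recovers_keq(self, table):
        rxn = Reaction(ReactionStoichiometry({"CO": 1, "H2O": 1},
                                             {"CO2": 1, "H2": 1}), (1e-12, 0.0, 0.0))
        kf = rxn.k_forward(1600.0)
        kr = reverse_rate_constant(rxn, 1600.0, kf, table)
        from ventgas.thermo import equilibrium_constant
        assert kf / kr == pytest.approx(equilibrium_constant(
            rxn.stoichiometry, table, 1600.0), rel=1e-12)

    def test_half_keq(self):
        # DrG = -RT ln 2  ->  k-/k+ = 0.5
        table = two_species_table(math.log(2.0))
        rxn = Reaction(ReactionStoichiometry({"A": 1}, {"B": 1}), (1.0, 0.0, 0.0))
        assert reverse_rate_constant(rxn, 1000.0, 1.0, table) == pytest.approx(0.5)

    def test_irreversible_rejected(self, table):
        rxn = Reaction(ReactionStoichiometry({"HCN": 1}, {"HNC": 1}),
                       (1.0, 0.0, 0.0), reversible=False)
        with pytest.raises(ValueError):
            reverse_rate_constant(rxn, 1000.0, 1.0, table)


class TestGraphiteExchange:
    def test_ratio_pins_saturation_concentration(self):
        k_cond, evap = graphite_exchange_rates(2000.0, tau_seconds=1e-8,
                                               variant="kinetics")
        n_sat = number_density_cm3(graphite_vapor_pressure(2000.0, "kinetics"), 2000.0)
        assert evap / k_cond == pytest.approx(n_sat, rel=1e-12)
        assert k_cond == pytest.approx(1e8)

    def test_out_of_window_rejected(self):
        with pytest.raises(ValueError):
            graphite_exchange_rates(500.0)


class TestIntegration:
    def test_two_species_relaxation_matches_closed_form(self):
        """A<=>B with k+=1, Keq=2: steady state [B]/[A]=2, e-folding 1/1.5 s."""
        table = two_species_table(math.log(2.0), 1000.0)
        net = parse_network("A <=> B ; A=1.0 n=0 Ea=0", table)
        gas = GasState(1000.0, 1.0, {"A": 1.0})
        traj = integrate(net, gas, 1000.0, 1.0, t_end=20.0, table=table,
                         n_samples=200)
        mix = traj.mixing_ratios(-1)
        assert mix["B"] / mix["A"] == pytest.approx(2.0, rel=1e-6)
        # analytic relaxation: x_B(t) = (2/3)(1 - exp(-1.5 t))
        k = np.searchsorted(traj.times, 1.0)
        t_k = traj.times[k]
        x_b = traj.states[k, traj.species.index("B")] / traj.states[k].sum()
        assert x_b == pytest.approx((2 / 3) * (1 - math.exp(-1.5 * t_k)), rel=1e-5)

    def test_time_to_equilibrium_is_about_five_efolds(self):
        table = two_species_table(math.log(2.0), 1000.0)
        net = parse_network("A <=> B ; A=1.0 n=0 Ea=0", table)
        gas = GasState(1000.0, 1.0, {"A": 1.0})
        traj = integrate(net, gas, 1000.0, 1.0, t_end=40.0, table=table,
                         n_samples=400)
        ref = GasState(1000.0, 1.0, {"A": 1 / 3, "B": 2 / 3})
        t_eq = time_to_equilibrium(traj, ref, tol=math.exp(-5.0))
        # deviation of A decays as 2 exp(-1.5 t); crossing e^-5 at t ~ 3.8 s
        expected = (5.0 + math.log(2.0)) / 1.5
        assert t_eq == pytest.approx(expected, rel=0.15)   # log-sampled grid

    def test_zero_rate_network_is_constant_and_never_converges(self):
        table = two_species_table(math.log(2.0), 1000.0)
        net = parse_network("A <=> B ; A=0.0 n=0 Ea=0", table)
        gas = GasState(1000.0, 1.0, {"A": 1.0})
        traj = integrate(net, gas, 1000.0, 1.0, t_end=10.0, table=table)
        assert np.allclose(traj.states, traj.states[0])
        ref = GasState(1000.0, 1.0, {"A": 1 / 3, "B": 2 / 3})
        assert time_to_equilibrium(traj, ref, tol=1e-3) == NOT_CONVERGED

    def test_already_equilibrated_returns_first_sample(self):
        table = two_species_table(math.log(2.0), 1000.0)
        net = parse_network("A <=> B ; A=1.0 n=0 Ea=0", table)
        ref = GasState(1000.0, 1.0, {"A": 1 / 3, "B": 2 / 3})
        traj = integrate(net, ref, 1000.0, 1.0, t_end=10.0, table=table)
        assert time_to_equilibrium(traj, ref, tol=1e-4) == traj.times[0]


@pytest.fixture(scope="module")
def reduced_run(table, fiducial_gas):
    net = parse_network(reduced_network_text(), table)
    n0 = number_density_cm3(100.0, T1700)
    traj = integrate(net, fiducial_gas, T1700, 100.0, t_end=86400.0,
                     table=table, initial_solid_carbon=0.8 * n0)
    return net, traj


class TestMagmaticRelaxation:
    def test_element_conservation_with_solid(self, reduced_run, table):
        net, traj = reduced_run
        comp = np.array([[table[sp].composition.get(el, 0) for sp in traj.species]
                         for el in "HCNO"])
        totals = traj.states @ comp.T
        totals[:, 1] += traj.solid_carbon          # condensed carbon counts
        for j in range(4):
            assert np.max(np.abs(totals[:, j] / totals[0, j] - 1.0)) < 1e-8

    def test_nonnegative_concentrations(self, reduced_run):
        _, traj = reduced_run
        assert np.all(traj.states >= 0)

    def test_endpoint_matches_graphite_equilibrium(self, reduced_run, table,
                                                   fiducial_gas):
        """One day of kinetics relaxes onto the clamped-equilibrium solution
        when both use the same graphite vapor pressure."""
        net, traj = reduced_run
        n0 = number_density_cm3(100.0, T1700)
        bud = {el: v * n0 for el, v in
               mixing_ratios_to_elements(fiducial_gas, table).abundances.items()}
        bud["C"] += 0.8 * n0
        res = equilibrate_with_graphite(
            ElementBudget(bud), T1700, traj.final_pressure_bar(),
            species_set=net.species, table=table,
            options=SolverOptions(vapor_pressure_variant="kinetics",
                                  hc3n_mode="table"))
        mix = traj.mixing_ratios(-1)
        for sp, x_eq in res.gas.mixing_ratios.items():
            if x_eq > 1e-10:
                assert mix[sp] == pytest.approx(x_eq, rel=0.01), sp

    def test_vapor_pressure_variant_controls_the_endpoint_gap(self, table,
                                                              fiducial_gas):
        """Kinetics run with the equilibrium-variant vapor pressure lands on the
        equilibrium model's answer; with its own variant a gap remains."""
        net = parse_network(reduced_network_text(), table)
        n0 = number_density_cm3(100.0, T1700)
        bud = {el: v * n0 for el, v in
               mixing_ratios_to_elements(fiducial_gas, table).abundances.items()}
        bud["C"] += 0.8 * n0

        def endpoint(variant):
            traj = integrate(net, fiducial_gas, T1700, 100.0, t_end=86400.0,
                             table=table, initial_solid_carbon=0.8 * n0,
                             vapor_pressure_variant=variant)
            return traj.mixing_ratios(-1)

        eq_model = equilibrate_with_graphite(
            ElementBudget(bud), T1700, 100.0, species_set=net.species, table=table,
            options=SolverOptions(vapor_pressure_variant="equilibrium",
                                  hc3n_mode="table"))
        hcn_eq_model = eq_model.gas["HCN"]
        hcn_same = endpoint("equilibrium")["HCN"]
        hcn_gap = endpoint("kinetics")["HCN"]
        assert hcn_same == pytest.approx(hcn_eq_model, rel=0.05)
        assert hcn_gap / hcn_eq_model > 2.0      # the divergence the variants cause


class TestToyNetworks:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_endpoint_matches_brute_force_oracle(self, seed):
        """Random reversible networks relax to the dense-grid Gibbs minimum."""
        toy = toy_network(FixtureSpec(seed=seed, n_species=4, rate_scale=10.0))
        names = toy.network.species
        x0 = {nm: 1.0 / len(names) for nm in names}
        gas = GasState(toy.t_kelvin, toy.p_bar, x0)
        traj = integrate(toy.network, gas, toy.t_kelvin, toy.p_bar, t_end=1.0e6,
                         table=toy.table)
        mix = traj.mixing_ratios(-1)
        for nm, x_ref in toy.equilibrium.items():
            if x_ref > 1e-6:
                assert mix[nm] == pytest.approx(x_ref, rel=0.01), (seed, nm)

    def test_element_potential_solver_agrees_with_oracle(self):
        toy = toy_network(FixtureSpec(seed=7, n_species=4))
        names = toy.network.species
        budget = {}
        for nm in names:
            for el, k in toy.table[nm].composition.items():
                budget[el] = budget.get(el, 0.0) + k / len(names)
        gas = solve_gas_equilibrium(ElementBudget(budget), toy.t_kelvin, toy.p_bar,
                                    species_set=names, table=toy.table)
        for nm, x_ref in toy.equilibrium.items():
            if x_ref > 1e-6:
                assert gas[nm] == pytest.approx(x_ref, rel=0.01)
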