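import pytest

from ventgas import load_default_table, table1_budget, table1_gas

T1700_K = 1973.15
P_FIDUCIAL = 100.0


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def base_budget():
    return table1_budget().normalized()


@pytest.fixture(scope="session")
def fiducial_gas():
    return table1_gas()


@pytest.fixture(scope="session")
def saturated_result(base_budget, table):
    """Graphite-saturated equilibrium at 1700 C, 100 bar (shared by many tests)."""
    from ventgas import equilibrate_with_graphite
    return equilibrate_with_graphite(base_budget.with_carbon_fraction(0.9),
                                     T1700_K, P_FIDUCIAL, table=table)
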