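"""Physical constants (SI / CODATA-2018) and unit conversions."""

R_GAS = 8.31446261815324        # J mol^-1 K^-1
K_BOLTZMANN = 1.380649e-23      # J K^-1
N_AVOGADRO = 6.02214076e23      # mol^-1
P_STANDARD_BAR = 1.0            # standard-state pressure, bar
BAR_TO_PA = 1.0e5
CELSIUS_OFFSET = 273.15

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def number_density_cm3(p_bar: float, t_k: float) -> float:
    """Ideal-gas number density (cm^-3) at pressure p_bar and temperature t_k."""
    return p_bar * BAR_TO_PA / (K_BOLTZMANN * t_k) * 1.0e-6
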