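"""Physical constants and unit conversions (CODATA 2018).

All unit conversions used anywhere in the package live here.  Internal
units are Angstrom (length), eV (energy), Debye (transition dipole) and
s^-1 (rates).
"""

import math

# SI base constants
PLANCK_J_S = 6.62607015e-34        # h, J s (exact)
SPEED_OF_LIGHT_M_S = 2.99792458e8  # c, m/s (exact)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # epsilon_0, F/m
ELEMENTARY_CHARGE_C = 1.602176634e-19   # e, C (exact)
ELECTRON_MASS_KG = 9.1093837015e-31     # m_e, kg

# Derived conversions
EV_TO_JOULE = ELEMENTARY_CHARGE_C
HC_EV_NM = (PLANCK_J_S * SPEED_OF_LIGHT_M_S / EV_TO_JOULE) * 1e9  # 1239.841984...
DEBYE_TO_C_M = 1e-21 / SPEED_OF_LIGHT_M_S  # 3.33564e-30 C m per Debye
EV_TO_WAVENUMBER = EV_TO_JOULE / (PLANCK_J_S * SPEED_OF_LIGHT_M_S * 100.0)  # cm^-1 per eV

# Forster-radius prefactors, R0^6 [A^6] = C * kappa^2 * n^-4 * Q_D * J
# with J in nm^4 M^-1 cm^-1.  Two printed conventions of the same
# constant: the sixth-root form (0.211) and the sixth-power form
# (8.79e-5); they differ by ~0.07% in R0 due to rounding.
FORSTER_PREFACTOR = {
    "eq3": 0.211 ** 6,
    "eq4": 8.79e-5,
}


def wavelength_nm_from_ev(energy_ev: float) -> float:
    """Vertical-transition wavelength lambda = hc/E."""
    return HC_EV_NM / energy_ev


def energy_ev_from_nm(wavelength_nm: float) -> float:
    return HC_EV_NM / wavelength_nm


def dipole_debye_from_osc_strength(f: float, energy_ev: float) -> float:
    """|mu| in Debye from oscillator strength and transition energy.

    f = (8 pi^2 m_e nu) / (3 h e^2) * |mu|^2 with nu = E/h.
    """
    nu = energy_ev * EV_TO_JOULE / PLANCK_J_S
    mu2_si = f * 3 * PLANCK_J_S * ELEMENTARY_CHARGE_C ** 2 / (
        8 * math.pi ** 2 * ELECTRON_MASS_KG * nu)
    return math.sqrt(mu2_si) / DEBYE_TO_C_M


def osc_strength_from_dipole(mu_debye: float, energy_ev: float) -> float:
    """Inverse of :func:`dipole_debye_from_osc_strength`."""
    nu = energy_ev * EV_TO_JOULE / PLANCK_J_S
    mu2_si = (mu_debye * DEBYE_TO_C_M) ** 2
    return mu2_si * 8 * math.pi ** 2 * ELECTRON_MASS_KG * nu / (
        3 * PLANCK_J_S * ELEMENTARY_CHARGE_C ** 2)
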