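"""Physical constants and the internal unit system.

Internal units throughout the package: length in angstrom (A), angle in
radian, time in millisecond, energy in units of kT at the run temperature
(default 310 K).  Friction coefficients are accepted in SI-flavoured units
(kg/s for translation, kg.A^2/s for rotation) and converted to diffusion
constants in A^2/ms and rad^2/ms via the Einstein relation D = kT / zeta.
"""

from __future__ import annotations

K_BOLTZMANN = 1.380649e-23  # J/K
E_CHARGE = 1.602176634e-19  # C
COULOMB_EV_A = 14.399645  # e^2/(4 pi eps0), in eV.A

DEFAULT_TEMPERATURE = 310.0  # K


def kt_joule(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in joule."""
    return K_BOLTZMANN * temperature


def kt_millivolt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kT expressed as the membrane potential (mV) that moves one
    elementary charge through an energy of kT."""
    return kt_joule(temperature) / E_CHARGE * 1e3


def coulomb_constant_kt(eps: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Coulomb prefactor q1*q2/(4 pi eps0 eps r) in kT.A for charges in e,
    distances in A."""
    ev_per_kt = kt_joule(temperature) / E_CHARGE  # eV per kT
    return COULOMB_EV_A / eps / ev_per_kt


def diffusion_z(zeta_z_kg_s: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Translational diffusion constant in A^2/ms from a friction in kg/s.

    D = kT/zeta; kT [J = kg m^2/s^2] * 1e20 [A^2/m^2] / 1e3 [ms/s].
    """
    return kt_joule(temperature) / zeta_z_kg_s * 1e20 / 1e3


def diffusion_phi(zeta_phi_kg_a2_s: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Rotational diffusion constant in rad^2/ms from a friction in kg.A^2/s."""
    kt_kg_a2_s2 = kt_joule(temperature) * 1e20  # kg A^2/s^2
    return kt_kg_a2_s2 / zeta_phi_kg_a2_s / 1e3
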