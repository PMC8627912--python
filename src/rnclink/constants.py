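"""Physical constants and package-wide defaults.

Energies are in kcal/mol throughout; temperatures in kelvin; NMR frequencies
in rad/s unless stated otherwise.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default sample temperature (K); all experimental defaults refer to 283 K.
T_DEFAULT = 283.0

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8

#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = -2.71261804e7

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: mu_0 / 4 pi, T m A^-1 / (4 pi).
MU0_OVER_4PI = 1.0e-7

#: Default 15N scale factor for combined (1H, 15N) chemical-shift metrics.
N15_WEIGHT_DEFAULT = 0.14

#: Default rigid-limit bound-state DD/CSA cross-correlated relaxation rate
#: for a nascent chain rigidly attached to a 70S particle, s^-1.
ETA_BOUND_DEFAULT = 7000.0

#: Coulomb constant e^2 / (4 pi eps_0), kcal mol^-1 nm e^-2 (vacuum).
COULOMB_KCAL_NM = 33.206


def rt_kcal(temperature: float = T_DEFAULT) -> float:
    """Thermal energy R*T in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * float(temperature)
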