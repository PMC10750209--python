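"""Physical constants and unit helpers.

The package-wide unit convention is: positions in mm, magnetic fields in mT,
gradients in T/m (numerically equal to mT/mm, which keeps field arithmetic
trivial), frequencies in Hz, time in s, temperatures in K or degC as stated
per argument, volumetric power in W/m^3.
"""

import numpy as np

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A
KB = 1.380649e-23  # Boltzmann constant, J/K

#: density of the iron-oxide core (maghemite-like), kg/m^3
CORE_DENSITY = 4860.0
#: iron mass fraction of the oxide core
IRON_MASS_FRACTION = 0.7

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def mT_to_T(b_mT):
    return np.asarray(b_mT) * 1e-3


def mT_to_Am(b_mT):
    """Convert a flux-density amplitude in mT to an H-field in A/m."""
    return np.asarray(b_mT) * 1e-3 / MU0
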