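"""Physical constants and unit conversions.

Internal unit system: lengths in Å, time in fs, mass in amu, energies in
kJ/mol, charge in a.u., wavenumbers in cm^-1.
"""

import numpy as np

#: Speed of light in cm/fs (2.99792458e10 cm/s * 1e-15 s/fs).
C_CM_PER_FS = 2.99792458e-5

#: Atomic masses (amu).
DEFAULT_MASSES = {"O": 15.999, "H": 1.008}

#: O-H reduced mass (amu).
OH_REDUCED_MASS = (DEFAULT_MASSES["O"] * DEFAULT_MASSES["H"]) / (
    DEFAULT_MASSES["O"] + DEFAULT_MASSES["H"]
)


def wavenumber_to_angular(nu_cm):
    """cm^-1 -> angular frequency in rad/fs."""
    return 2.0 * np.pi * C_CM_PER_FS * np.asarray(nu_cm)


def angular_to_wavenumber(omega_rad_fs):
    """rad/fs -> cm^-1."""
    return np.asarray(omega_rad_fs) / (2.0 * np.pi * C_CM_PER_FS)
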