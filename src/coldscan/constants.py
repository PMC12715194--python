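"""Physical constants and unit helpers.

All thermodynamic arithmetic in the package is carried out in Kelvin and
kcal/mol; Celsius is accepted only at I/O boundaries.
"""

import numpy as np

#: Gas constant in kcal/(mol.K)
R_KCAL = 1.98720425e-3

#: 0 degrees Celsius in Kelvin
ZERO_C_K = 273.15


def celsius_to_kelvin(t_c):
    """Convert Celsius to Kelvin (scalar or array)."""
    return np.asarray(t_c, dtype=float) + ZERO_C_K


def kelvin_to_celsius(t_k):
    """Convert Kelvin to Celsius (scalar or array)."""
    return np.asarray(t_k, dtype=float) - ZERO_C_K
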