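"""Physical constants and configurable defaults.

Every quantity here is either a true physical constant or a convention the
pipeline must apply consistently; the configurable ones are surfaced as keyword
arguments throughout so a run can override them, and the chosen values are
recorded in outputs.
"""

import numpy as np

#: speed of light in vacuum (cm/ns)
C_VACUUM_CM_PER_NS = 29.9792458

#: natural log of 10, the decadic/Napierian bridge in the Beer-Lambert algebra
LN10 = float(np.log(10.0))

#: default tissue refractive index
DEFAULT_N_TISSUE = 1.4

#: decadic extinction coefficient of plasma-bound ICG at 805 nm (uM^-1 cm^-1).
#: Literature value for indocyanine green bound to plasma proteins; always
#: configurable and always recorded alongside concentration outputs.
DEFAULT_EPS_ICG = 0.186

#: soft-tissue mass density (g/mL) used in the flow unit bridge
DEFAULT_RHO_TISSUE = 1.05

#: molar mass of indocyanine green (g/mol), for mg/L -> uM conversion of
#: dye-densitometer arterial curves
ICG_MOLAR_MASS_G_PER_MOL = 774.96

#: ratio of (Napierian-measurement-derived) absorption to decadic extinction for
#: India ink: eps_a = 0.885 * eps_e
INK_ABSORPTION_EXTINCTION_RATIO = 0.885


def flow_scale(bf_ml_min_100g: float, rho_g_per_ml: float = DEFAULT_RHO_TISSUE) -> float:
    """Convert blood flow in mL/min/100 g to the per-second rate constant f (s^-1).

    f = BF * rho / 6000, i.e. mL of blood per second per mL of tissue.
    """
    return bf_ml_min_100g * rho_g_per_ml / 6000.0


def flow_from_scale(f_per_s: float, rho_g_per_ml: float = DEFAULT_RHO_TISSUE) -> float:
    """Inverse of :func:`flow_scale`: f (s^-1) -> BF in mL/min/100 g."""
    return f_per_s * 6000.0 / rho_g_per_ml
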