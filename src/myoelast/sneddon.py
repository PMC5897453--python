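"""Sneddon cone contact mechanics.

For a rigid cone of half-opening angle alpha indenting an elastic half-space
to depth delta, the load is

    F = (2 / pi) * tan(alpha) * E / (1 - nu**2) * delta**2

with E the Young's modulus and nu the Poisson ratio. During an AFM approach
the piezo travel past contact is shared between indentation and cantilever
deflection: z - z0 = delta + F(delta) / k, a quadratic in delta that is
solved in closed form here.

Bench units: delta and z in nm, F in pN, k in pN/nm, E in Pa. The mixed-unit
prefactor carries a factor 1e-6 (Pa * nm**2 -> pN).
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

_PA_NM2_TO_PN = 1.0e-6


def cone_prefactor_pN_per_nm2(youngs_modulus_Pa: float, nu: float = 0.5,
                              half_angle_deg: float = 45.0) -> float:
    """Quadratic force-law coefficient c such that F[pN] = c * delta[nm]**2."""
    alpha = np.deg2rad(half_angle_deg)
    return (2.0 / np.pi) * np.tan(alpha) * youngs_modulus_Pa / (1.0 - nu ** 2) \
        * _PA_NM2_TO_PN


def modulus_from_prefactor_Pa(c_pN_per_nm2: float, nu: float = 0.5,
                              half_angle_deg: float = 45.0) -> float:
    """Inverse of :func:`cone_prefactor_pN_per_nm2`."""
    alpha = np.deg2rad(half_angle_deg)
    return c_pN_per_nm2 * np.pi * (1.0 - nu ** 2) / (2.0 * np.tan(alpha)) \
        / _PA_NM2_TO_PN


def sneddon_force_pN(delta_nm, youngs_modulus_Pa: float, nu: float = 0.5,
                     half_angle_deg: float = 45.0):
    """Cone load-indentation law; negative depths give zero force."""
    c = cone_prefactor_pN_per_nm2(youngs_modulus_Pa, nu, half_angle_deg)
    delta = np.asarray(delta_nm, dtype=float)
    return c * np.square(np.clip(delta, 0.0, None))


def indentation_from_separation_nm(separation_nm, youngs_modulus_Pa: float,
                                   spring_constant_pN_per_nm: float,
                                   nu: float = 0.5,
                                   half_angle_deg: float = 45.0):
    """Closed-form indentation for piezo travel past contact.

    Solves s = delta + (c/k) * delta**2 for delta >= 0 using the
    cancellation-stable root delta = 2 s / (1 + sqrt(1 + 4 a s)),
    a = c / k. Non-positive separations return 0.
    """
    c = cone_prefactor_pN_per_nm2(youngs_modulus_Pa, nu, half_angle_deg)
    a = c / spring_constant_pN_per_nm
    s = np.clip(np.asarray(separation_nm, dtype=float), 0.0, None)
    return 2.0 * s / (1.0 + np.sqrt(1.0 + 4.0 * a * s))
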