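"""Unit conversions and physical constants.

Internal convention everywhere in the package: Hartree atomic units
(energy in hartree, time in au, angles in radians, dipoles in au,
angular inertias in au of mass*length**2).  User-facing interfaces use
eV, femtoseconds and degrees.
"""

import math

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

AU_PER_FS = 41.341374575751
FS_PER_AU = 1.0 / AU_PER_FS

#: Boltzmann constant in hartree per kelvin.
KB_HARTREE = 3.166811563e-6

DEG_PER_RAD = 180.0 / math.pi
RAD_PER_DEG = math.pi / 180.0


def ev_to_hartree(x):
    return x * HARTREE_PER_EV


def hartree_to_ev(x):
    return x * EV_PER_HARTREE


def fs_to_au(t):
    return t * AU_PER_FS


def au_to_fs(t):
    return t * FS_PER_AU


def deg_to_rad(a):
    return a * RAD_PER_DEG


def rad_to_deg(a):
    return a * DEG_PER_RAD


def wrap_angle(a):
    """Wrap an angle (radians) into (-pi, pi]."""
    w = math.remainder(a, 2.0 * math.pi)
    if w <= -math.pi:
        w += 2.0 * math.pi
    return w
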