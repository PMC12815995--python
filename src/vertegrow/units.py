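"""Centralized unit conversions.

Internal conventions: lengths in mm, forces in N, stresses/pressures in MPa,
angles in radians inside numerics.  I/O boundaries use kPa and degrees.
Growth rates are µm/day; fluorochrome label distances are mm.
"""

from __future__ import annotations

import numpy as np

MM_PER_UM = 1e-3
UM_PER_MM = 1e3


def kpa_to_mpa(x):
    return np.asarray(x, dtype=float) * 1e-3 if np.ndim(x) else float(x) * 1e-3


def mpa_to_kpa(x):
    return np.asarray(x, dtype=float) * 1e3 if np.ndim(x) else float(x) * 1e3


def deg_to_rad(x):
    return np.deg2rad(x)


def rad_to_deg(x):
    return np.rad2deg(x)
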