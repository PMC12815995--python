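"""Reduced-order tether mechanics: pressures, stresses, and load curves.

A 10-degree correction about the disc center (flexible spine) barely
changes nucleus pressure; the same correction about the anterior edge
(stiff spine) compresses the nucleus and raises its pressure by ~0.3 MPa.
The pressure-load curve shows the apical angle passing from kyphotic to
lordotic as cable force grows.
"""

import numpy as np

from vertegrow import (
    HIGH_TENSION,
    LOW_TENSION,
    MotionSegment,
    TetherConstruct,
    equilibrium_angle,
    pressure_load_curve,
    realign,
)

segment = MotionSegment()  # h0 = 7 mm, r = 15 mm, calibrated defaults

for axis in ("flexible", "stiff"):
    base = realign(segment, 0.0, axis)
    corrected = realign(segment, 10.0, axis)
    print(
        f"{axis:8s}: p_np {base.p_np * 1e3:6.1f} -> "
        f"{corrected.p_np * 1e3:6.1f} kPa "
        f"(change {(corrected.p_np - base.p_np) * 1e3:+7.1f} kPa); "
        f"plate stress range [{corrected.sigma_gp.min():+.3f}, "
        f"{corrected.sigma_gp.max():+.3f}] MPa"
    )

# Equilibrium correction angles at the two study pretension levels.
for construct in (LOW_TENSION, HIGH_TENSION):
    theta, _ = equilibrium_angle(segment, construct, construct.pretension)
    print(
        f"pretension {construct.pretension:5.1f} N -> "
        f"equilibrium correction {theta:.2f} deg per disc"
    )

# The full load sweep: kyphotic -> neutral -> lordotic.
curve = pressure_load_curve(
    segment, TetherConstruct(), np.linspace(0.0, 80.0, 9)
)
print("\nload curve (initial wedge 10 deg):")
print(curve.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
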