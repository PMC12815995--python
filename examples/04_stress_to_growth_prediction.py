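"""From plate stress to predicted growth modulation.

The growth law is linear in stress around the homeostatic point (-0.15 MPa,
the resting stress under nucleus swelling pressure) and arrests completely
at 0.5 MPa compression.  Applying it station-wise to a realignment stress
field predicts the %GM a tether should produce.
"""

import numpy as np

from vertegrow import (
    GrowthLawParams,
    MotionSegment,
    growth_rate_at_stress,
    predict_modulation_from_stress,
    realign,
)

law = GrowthLawParams()  # g0 = 178 µm/day at -0.15 MPa
for sigma in (-0.15, 0.0, -0.325, -0.5, -0.6):
    print(f"  sigma {sigma:+.3f} MPa -> {growth_rate_at_stress(law, sigma):6.1f} µm/day")

segment = MotionSegment()
for axis in ("flexible", "stiff"):
    state = realign(segment, 10.0, axis)
    rates = growth_rate_at_stress(law, state.sigma_gp)
    arrested = int(np.sum(rates == 0.0))
    res = predict_modulation_from_stress(state, law)
    print(
        f"{axis:8s} 10 deg: predicted %GM {res.gm_percent:+7.1f}, "
        f"{arrested}/{rates.size} stations arrested"
    )
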