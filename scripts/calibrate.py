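"""Re-derive the shipped motion-segment calibration constants.

Solves the nucleus-pulposus compliance and centroid offset so the
reduced-order segment reproduces the three reference intradiscal pressures
(baseline 0.15 MPa; -0.005 MPa flexible-axis change; +0.297 MPa stiff-axis
change at a 10-degree correction), then prints the solution next to the
constants shipped in vertegrow.mechanics.  Run after changing segment
geometry defaults.

Usage:  python scripts/calibrate.py
"""

from __future__ import annotations

from vertegrow.mechanics import (
    DEFAULT_NP_COMPLIANCE_PER_MPA,
    DEFAULT_NP_OFFSET_MM,
    calibrate_defaults,
)


def main() -> None:
    result = calibrate_defaults()
    print("calibration solution (default geometry, 10 deg):")
    print(f"  swelling pressure p0      = {result.p0!r} MPa")
    print(f"  NP compliance C           = {result.C!r} /MPa")
    print(f"  NP centroid offset delta  = {result.delta!r} mm")
    print(f"  residuals (flex, stiff)   = {result.residuals}")
    print(f"  stiff peak GP compression = {result.stiff_peak_compression_mpa:.4g} MPa")
    print("shipped constants:")
    print(f"  C     = {DEFAULT_NP_COMPLIANCE_PER_MPA!r}")
    print(f"  delta = {DEFAULT_NP_OFFSET_MM!r}")
    drift_c = abs(result.C - DEFAULT_NP_COMPLIANCE_PER_MPA)
    drift_d = abs(result.delta - DEFAULT_NP_OFFSET_MM)
    print(f"drift: |dC| = {drift_c:.3g}, |ddelta| = {drift_d:.3g}")
    if max(drift_c, drift_d) > 1e-9:
        raise SystemExit("shipped constants are stale; update mechanics.py")


if __name__ == "__main__":
    main()
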