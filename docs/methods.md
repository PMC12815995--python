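# Methods

This note documents the models implemented in `vertegrow`: their
equations, parameter provenance, calibration, numerical choices, and known
limitations. Units are mm, MPa, N, degrees at interfaces (radians
internally), µm/day for growth, kPa for reported pressures.

## 1. Measurement model

A physis is measured at `n` stations across the antero-posterior (AP)
width (`x = 0` anterior). Pulsed fluorochrome labeling gives a label
distance `d` (mm) per station over an interval `T` days (default 13, study
range 12–14); the local growth rate is `g = 1000·d/T` µm/day. The
measured unit is the element-wise **sum of two physes**: the proximal and
distal physes of the apical vertebra (control cohorts) or the two physes
facing a tethered disc (tethered cohorts).

Stations are rank-normalized to `[0, 1]` and assigned to regions of a
scheme; regions are half-open `[lo, hi)` with the last closed. The
default anatomical quarters scheme is ¼–½–¼: annulus fibrosus attachment
over the outer quarters, nucleus pulposus (NP) over the central half.

```
%GM = 100 · (mean anterior-quarter rate − mean posterior-quarter rate)
          / mean rate over all stations
```

The whole-physis mean is the all-station mean, not the mean of region
means. Cohort %GM is the mean of per-animal %GM (the published
−11 ± 17 % for kyphotic controls vs −9.55 % for the ratio of cohort-mean
rates confirms this convention). %GM is invariant to uniform rescaling of
all rates and antisymmetric under AP reversal whenever no rank-normalized
station falls exactly on a region boundary (a half-open boundary station
would otherwise change regions under reversal).

Group comparisons use two-tailed Student t-tests (pooled-variance
unpaired, or paired), significant at p ≤ 0.05.

## 2. Reduced-order motion segment

One vertebra–disc–vertebra unit: disc height `h0 = 7` mm, radius
`r = 15` mm, AP width `w = 2r = 30` mm, discretized into 40 stations.
Correction by an angle θ about an AP axis `x_rot` produces the affine
height-change field

```
dh(x) = −(x − x_rot)·tan θ        (θ > 0 closes the posterior side)
```

Two flexibility regimes set the axis: **flexible** — rotation about the
disc center (`x_rot = r`; mid-disc height preserved, anterior distracts,
posterior compresses); **stiff** — rotation about the anterior edge
(`x_rot = 0`; anterior height preserved, everything posterior of it loses
height). A `ContactError` is raised if any station height would close.

**NP pressure.** The NP is a pressurized compartment over the central half
of the footprint, shifted by a calibrated centroid offset δ. The fluid
volume displaced out of its footprint per unit depth is `V = −∫ dh dx`
over `[w/4 + δ, 3w/4 + δ]` (trapezoidal quadrature, exact for an affine
field), and

```
p_np = max(0, p0 + (V / V0) / C),     V0 = h0 · (footprint width)
```

with swelling pressure `p0` and compliance `C`. Compression of the NP
raises its pressure.

**Plate stress** (tension positive): `σ = E_af·dh/h0 − p0` under the
annulus quarters; `σ = −p_np` under the NP half. At θ = 0 the plate is
homeostatic everywhere: `σ = −p0 = −0.15` MPa.

**Calibration.** `p0 = 0.15` MPa is the baseline pressure target directly
(within the 0.1–0.21 MPa literature range). `(C, δ)` solve the 2×2 system
matching the two 10° correction responses — flexible −0.005 MPa, stiff
+0.297 MPa — giving `C = 1.25114 MPa⁻¹`, `δ = −0.24834` mm (a small
*anterior* offset; residuals < 1e-16, see `scripts/calibrate.py`). With a
centered NP the flexible rotation would change pressure by exactly zero;
the sign pair (slight drop under flexible, large rise under stiff)
requires the anterior shift. `E_af = 0.7` MPa was fixed once so that the
stiff 10° correction drives peak posterior annulus compression past the
0.5 MPa growth-arrest threshold (0.672 MPa) while the flexible correction
keeps all stations inside it (range −0.408 to +0.108 MPa) — the two
regimes the growth predictions require.

**Tether equilibrium.** A bilateral construct (`n_cables = 2`) acts along
a line `d = 10` mm posterior of the **disc center** (pedicle-screw
surrogate). About the rotation axis the applied moment is
`n_cables·F·(r + d − x_rot)`; the resisting moment integrates the stress
*change* (the baseline prestress is carried by the intact segment):
`M_int = −Σ (σ − (−p0))·(x − x_rot)·ΔA` with `ΔA = (w/n)·depth`,
effective depth = w. The equilibrium angle is found by Brent's method on
tan θ (xtol 1e-14) with a moment residual below 1e-8 N·mm; θ(5 N) ≈ 0.97°,
θ(25.6 N) ≈ 4.96° per disc, so the 5-disc high-tension construct corrects
≈ 25° immediately while low tension corrects ≈ 5° — the observed week-1
regime. The `pressure_load_curve` sweep passes the apical angle from
kyphotic through neutral to lordotic with non-increasing flexible-regime
NP pressure.

## 3. Growth law

Linear stress-modulated (Hueter-Volkmann) growth with hard arrest:

```
g(σ) = max(0, g0·(1 + β·(σ − σ_hom)))      and g(σ) = 0 for σ ≤ −0.5 MPa
```

with `g0 = 178` µm/day at the homeostatic `σ_hom = −0.15` MPa and
`β = 1/0.35` MPa⁻¹, chosen so the linear ramp reaches zero exactly at the
arrest threshold — the law is continuous everywhere, returns `g0` at rest,
`0.5·g0` at the ramp midpoint (−0.325 MPa), and exactly 0 at and beyond
0.5 MPa compression. Applying the law station-wise to a realignment
stress field and evaluating %GM on the predicted profile links mechanics
to the histological statistic: the flexible 10° field predicts strongly
positive %GM with every station still growing; the stiff field arrests 10
of 40 stations.

## 4. Synthetic cohort generator

The generator defines the study conditions; it is the forward model the
analysis pipeline must invert.

Per animal: a base measured-unit rate `~ Normal(mean, sd)` and a latent
%GM drawn from a Normal; each of the animal's two physes carries half the
base rate and the full %GM, so their sum does too. The station profile is

```
g(u) = base·(1 + a·φ(u)),    φ = smoothstep ramp (+1 anterior edge → 0)
                                − mirrored ramp (0 → −1 posterior edge)
```

with ramps confined to the outer `localization = 0.25` of the width (the
central physis is an unmodulated zone, matching the peripheral action of
the annulus). The amplitude `a` is solved exactly from the target %GM via
the scheme-specific gain of φ, so the generator is an **exact inverse** of
the analysis: station mean = base rate and quarters %GM = target, to
float precision. Station-level Normal measurement noise (sd 10 µm/day) is
added per physis and label distances re-derived from the noisy rates.

Non-negative rates bound realizable |%GM| at ≈ 107.5 (40 stations,
localization 0.25). Because one study cohort has %GM 53 ± 43, naive
clipping of Normal draws at that bound would bias the realized cohort mean
to ≈ 50 and break mean recovery. The generator therefore samples from a
Normal whose **post-clip (winsorized) mean equals the target**: the
pre-clip location is solved analytically from the closed-form winsorized
Normal mean (Brent root find). Zero-variance cohorts are unchanged.

Shipped presets carry the study cohort parameters: kyphotic 11-week
controls (n=5, 178 ± 21 µm/day, %GM −11 ± 17), age controls (188 ± 11,
−16 ± 17), single-level high tension (n=4, %GM 53 ± 43) and low tension
(−1 ± 15), multi-level low (n=3, 173 ± 28, 14 ± 11) and high (10 ± 10).
Auxiliary generators produce piecewise-linear Cobb series and truncated
Normal intradiscal pressures.

All sampling flows through `numpy.random.Generator`; replicate drivers
spawn independent child seeds via `SeedSequence`. 1000 replicate cohorts
analyze in ≈ 10 s per preset.

## 5. Longitudinal simulator

Explicit Euler, `dt = 1` day. State per day: vertebral wedge angles
(changed by growth), fixed natural disc wedges, the tether-driven disc
correction θ, and cable force F. Instrumented Cobb = Σ vertebral wedges +
Σ (natural disc wedge − θ).

Each step: (1) the current θ sets the plate-stress field (flexible
regime); (2) the growth law scales an intrinsic baseline profile (sum
178 µm/day, intrinsic %GM −10 from the control asymmetry) station-wise;
(3) each vertebral wedge changes by
`atan((dh_post − dh_ant)/w)` using quarter-region mean height increments
of its two physes; (4) the cable force follows the crimped fixed-length
construct,

```
ΔL_path = η·n_vert·dh_post  +  d·Δ(Cobb in radians)
F ← max(0, F + k_cable·ΔL_path),      k_cable = 5 N/mm
```

and (5) θ is re-solved from the new force. The first term is restrained
longitudinal growth re-tensioning the cable; the second is geometric
slackening as angular correction shortens the posterior path.

**Model hypothesis (anchorage efficiency).** η = 0.1 is the fraction of
posterior longitudinal growth actually restrained by the construct; the
remainder is absorbed by screw plow / implant migration and disc creep —
the load-limiting failure mode observed in vivo. The two limits both
contradict the observed behavior: η = 0 (pure geometric relaxation) makes
both arms go slack and rebound with no sustained modulation; η = 1 drives
both arms up to a ≈ 56 N equilibrium and the force never decays. At
η = 0.1 the behavior is emergent, not fitted point-wise: the high-tension
force decays monotonically (26.3 → 19.3 N over 28 days) while the
low-tension force rises toward the same growth-sustained level
(5 → 13.4 N); correction is load-dependent early (days 0–14: −2.30 vs
−0.87 °/day) and load-independent late (days 14–28: −0.53 vs −0.52
°/day), and the instantaneous %GM gap between arms shrinks from 45 to 13
points — the biphasic load-dependence.

Scenario defaults (level counts, initial wedges, moment arm, cable
stiffness are anatomical/order-of-magnitude choices, not measured):
*untreated* — 10 vertebrae / 9 discs, initial Cobb 44.2°, 92 days (ages
2 → 5 months), no construct: progresses monotonically to 75.5°;
*low/high tension* — 6 vertebrae / 5 tethered discs, instrumented Cobb
32°, 28 days, pretension 5 / 25.6 N.

## 6. Numerical and I/O conventions

- Root finds: Brent (`xtol = 1e-14`) for equilibrium angles and the
  winsorized-mean location; Powell-hybrid (`scipy.optimize.root`) for the
  2-parameter pressure calibration, residual tolerance 1e-4 (achieved
  ≈ 1e-17).
- Quadrature: trapezoidal on 201 points for the NP volume (exact for the
  affine field; verified against brute-force integration in tests).
- CSV via pandas with fixed column order; YAML configs validated with
  unknown-key rejection naming the offending path; JSON summaries with
  sorted keys; every CLI run writes a manifest (config SHA-256, seed,
  package version, output list, UTC timestamps).
- Internal mechanics in MPa/radians; interfaces report kPa/degrees.

## 7. Limitations

- The motion segment is a 1-D station model with an affine height field:
  no annulus fiber anisotropy, no poroelastic time dependence, no coupled
  axial compression from muscle tone or body weight.
- The calibration gives a unique (C, δ) for the default geometry; other
  geometries require re-running `scripts/calibrate.py`.
- The growth law is linear with a hard arrest; real physes show saturating
  tension response.
- The trajectory simulator treats all instrumented levels as identical and
  uses a single lumped cable; the low-tension force *rise* toward the
  growth-sustained equilibrium is a prediction of the anchorage-efficiency
  hypothesis, not an observed quantity.
- Synthetic cohorts model between-animal variation as independent Normals;
  real data have level- and animal-correlated structure.
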