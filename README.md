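# vertegrow

Vertebral growth modulation under posterior tethering: analysis of
fluorochrome-labelled regional physeal growth rates, a calibrated
reduced-order motion-segment model of tether-driven disc realignment, a
stress-modulated growth law with an arrest threshold, and a longitudinal
Cobb-angle simulator — together with a synthetic cohort generator that
mirrors the statistical structure of a hyperkyphotic porcine tethering
study.

Posterior vertebral body tethering corrects a growing kyphotic spine in two
phases: an immediate elastic correction as the cable rotates each disc, and
a slow growth-mediated correction as altered growth-plate stress modulates
anterior versus posterior physeal growth (the Hueter-Volkmann effect).
This package provides a self-contained, desk-scale model of that whole
chain: from tether force to disc stress, from stress to regional growth,
from regional growth to the %GM statistic measured by histology, and from
daily growth increments to longitudinal Cobb-angle trajectories.

## The central statistic

Regional growth is measured by pulsed fluorochrome labeling: the distance
between two mineralization fronts divided by the labeling interval is the
local growth rate (µm/day). Percent growth modulation compares the two ends
of the endplate under the anatomical quarters scheme (anterior ¼ — annulus,
central ½ — nucleus, posterior ¼ — annulus):

```
%GM = 100 · (anterior-quarter rate − posterior-quarter rate) / whole-physis mean
```

Positive %GM (anterior outgrowing posterior) is corrective in kyphosis.
The statistic is scale-invariant, so animals with different growth tempos
are directly comparable; cohort %GM is the mean of per-animal values.

## Quick start

```python
from vertegrow import (
    MotionSegment, cohort_preset, gen_cohort, gm_of_profile,
    predict_modulation_from_stress, realign,
)

# 1. Mechanics: a 10-degree correction about the disc center (flexible
#    spine) vs about the anterior edge (stiff spine).
seg = MotionSegment()                     # h0 = 7 mm, r = 15 mm, calibrated
flex = realign(seg, 10.0, "flexible")     # p_np: 150 -> 145 kPa
stiff = realign(seg, 10.0, "stiff")       # p_np: 150 -> 447 kPa

# 2. Stress -> growth: predicted modulation of each stress field.
predict_modulation_from_stress(flex).gm_percent    # +112.5  (all growing)
predict_modulation_from_stress(stiff).gm_percent   # +291.2  (10/40 arrested)

# 3. Synthetic cohorts and the measurement pipeline.
records = gen_cohort(cohort_preset("single_level_high", seed=1))
gms = [gm_of_profile(r.measured_unit()).gm_percent for r in records]
```

The `examples/` directory holds five short narrative scripts covering
cohort generation and recovery, the %GM statistic and region-scheme
dilution, realignment mechanics and load curves, stress-to-growth
prediction, and longitudinal Cobb trajectories. Each runs in seconds:

```bash
python examples/05_cobb_trajectories.py
```

## Command line

A thin CLI wraps the same library calls; every run writes a
`manifest.json` with the config hash, seed, and outputs:

```bash
vertegrow generate --preset multi_level_low --seed 11 --out runs/gen
vertegrow analyze --input runs/gen/growth.csv --out runs/ana
vertegrow simulate-mechanics --theta 10 --axis stiff --out runs/mech
vertegrow predict-modulation --theta 10 --out runs/pred
vertegrow simulate-growth --scenario all --out runs/traj
vertegrow replicate --preset single_level_high --n-replicates 1000 \
    --seed 7 --out runs/rep
```

## Tests

```bash
python -m pytest -q tests/
```

The suite (≈1 minute) covers unit oracles (hand-computed conversions,
t-tests, trigonometric height fields, quadrature cross-checks), property
tests (%GM antisymmetry and scale invariance via hypothesis), generator
exactness and seeding, file-schema validation and CLI error paths, and the
end-to-end study-level properties in `tests/test_acceptance.py`.

See `docs/methods.md` for the model equations, the calibration procedure,
parameter provenance, and known limitations.
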