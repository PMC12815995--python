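"""Synthetic animals and cohorts for the tethered-growth analysis pipeline.

The in-vivo study measured per-physis fluorochrome label distances across
the antero-posterior vertebral width, serial sagittal Cobb angles, and
apical intradiscal pressures.  No public dataset exists, so this module
generates records with the same statistical structure: per-animal base
growth rate and %GM drawn from cohort-level Normal distributions, a
deterministic peripheral modulation profile realizing the latent %GM
exactly, and additive station-level measurement noise.

Each record stores its latent (noiseless) parameters so that pipeline
recovery can be tested directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import optimize, stats

from . import metrics
from .profiles import PhysisProfile, station_positions
from .schemes import QUARTERS, RegionScheme
from .units import UM_PER_MM

logger = logging.getLogger("vertegrow.synthetic")

__all__ = [
    "LabelingSchedule",
    "CohortSpec",
    "AnimalRecord",
    "gen_growth_profile",
    "max_realizable_gm",
    "gen_animal",
    "gen_cohort",
    "gen_cobb_series",
    "gen_pressures",
    "COHORT_PRESETS",
    "cohort_preset",
]

DEFAULT_WIDTH_MM = 30.0  # AP vertebral width, 2 * disc radius (15 mm)
DEFAULT_N_STATIONS = 40  # >= 10 stations inside each quarter-width region


@dataclass(frozen=True)
class LabelingSchedule:
    """Fluorochrome pulse schedule: first label ``interval_days`` before the
    second (terminal) label.  The study used 12-14 days; default 13."""

    interval_days: float = 13.0

    def __post_init__(self):
        if self.interval_days <= 0:
            raise ValueError("labeling interval must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one study cohort.

    ``mean_vertebral_rate`` / ``sd_vertebral_rate`` describe the measured
    unit (sum of the two physes facing the apical vertebra or tethered
    disc), in µm/day.  ``target_gm_mean`` / ``target_gm_sd`` describe the
    per-animal %GM distribution; the realized (physically clipped) per-animal
    %GM values have mean equal to ``target_gm_mean``.
    ``modulation_localization`` is the fraction of the AP width at each end
    over which the modulation ramp acts.
    """

    name: str
    n_animals: int
    mean_vertebral_rate: float
    sd_vertebral_rate: float
    target_gm_mean: float
    target_gm_sd: float
    measurement_noise_sd: float = 10.0
    modulation_localization: float = 0.25
    labeling: LabelingSchedule = field(default_factory=LabelingSchedule)
    seed: int = 0
    n_stations: int = DEFAULT_N_STATIONS
    width_mm: float = DEFAULT_WIDTH_MM
    unit_kind: str = "apical_vertebra"  # or "tethered_space"

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.mean_vertebral_rate <= 0:
            raise ValueError("mean vertebral growth rate must be positive")
        for nm in ("sd_vertebral_rate", "target_gm_sd", "measurement_noise_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")
        if not (0.0 < self.modulation_localization <= 1.0):
            raise ValueError("modulation_localization must be in (0, 1]")


@dataclass
class AnimalRecord:
    """One synthetic animal: its measured physes plus optional Cobb series
    and disc pressures, with the latent generator truth attached."""

    id: str
    cohort: str
    physes: List[PhysisProfile]
    cobb_series: List[Tuple[float, float]] = field(default_factory=list)
    pressures: List[Tuple[str, float]] = field(default_factory=list)
    latent: dict = field(default_factory=dict)

    def __post_init__(self):
        days = [d for d, _ in self.cobb_series]
        if any(d2 < d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("cobb_series days must be non-decreasing")
        if any(p < 0 for _, p in self.pressures):
            raise ValueError("pressures must be non-negative")

    def measured_unit(self) -> PhysisProfile:
        """The analysis unit: element-wise sum of this animal's physes."""
        if not self.physes:
            raise ValueError("record has no physes")
        unit = self.physes[0]
        for p in self.physes[1:]:
            unit = unit.summed_with(p)
        return unit


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _modulation_shape(u: np.ndarray, localization: float) -> np.ndarray:
    """Antisymmetric peripheral shape on [0, 1]: +1 at the anterior edge
    ramping to 0 over ``localization``, 0 across the center, ramping to -1
    at the posterior edge.  Mean over a symmetric station grid is exactly 0.
    """
    ramp = np.clip(localization, 1e-9, 0.5)
    anterior = 1.0 - _smoothstep(u / ramp)
    posterior = 1.0 - _smoothstep((1.0 - u) / ramp)
    return anterior - posterior


def _shape_gm_gain(
    positions: np.ndarray, localization: float, scheme: RegionScheme
) -> float:
    """(anterior - posterior) region mean of the unit-amplitude shape."""
    u = (positions - positions[0]) / (positions[-1] - positions[0])
    phi = _modulation_shape(u, localization)
    idx = scheme.assign(u)
    ant = phi[idx == 0].mean()
    post = phi[idx == scheme.n_regions - 1].mean()
    return float(ant - post)


def max_realizable_gm(
    localization: float = 0.25,
    n_stations: int = DEFAULT_N_STATIONS,
    width_mm: float = DEFAULT_WIDTH_MM,
    scheme: RegionScheme = QUARTERS,
) -> float:
    """Largest |%GM| realizable with non-negative station rates.

    The profile is ``mean * (1 + (gm/100) / gain * shape)`` with
    ``|shape| <= 1``; non-negativity bounds the amplitude by the mean, so
    ``|%GM| <= 100 * gain``.
    """
    x = station_positions(n_stations, width_mm)
    return 100.0 * _shape_gm_gain(x, localization, scheme)


def gen_growth_profile(
    base_rate: float,
    gm_target: float,
    localization: float = 0.25,
    n_stations: int = DEFAULT_N_STATIONS,
    width_mm: float = DEFAULT_WIDTH_MM,
    interval_days: float = 13.0,
    scheme: RegionScheme = QUARTERS,
    vertebra: str = "",
    side: str = "",
) -> PhysisProfile:
    """Deterministic profile whose %GM under ``scheme`` equals ``gm_target``.

    The profile is flat at ``base_rate`` across the central physis with
    smoothstep ramps confined to the outer ``localization`` fraction at each
    end (modulation is peripheral; the central physis is an unmodulated
    zone).  The station mean equals ``base_rate`` exactly and the quarters
    %GM of the result equals ``gm_target`` exactly, making the generator an
    exact inverse of the analysis pipeline.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if n_stations < 4:
        raise ValueError("need at least 4 stations")
    x = station_positions(n_stations, width_mm)
    u = (x - x[0]) / (x[-1] - x[0])
    phi = _modulation_shape(u, localization)
    gain = _shape_gm_gain(x, localization, scheme)
    amplitude = (gm_target / 100.0) * base_rate / gain
    if abs(amplitude) > base_rate * (1.0 + 1e-12):
        raise ValueError(
            f"%GM target {gm_target:g} is not realizable with non-negative "
            f"rates at mean {base_rate:g} µm/day "
            f"(|%GM| must be <= {100.0 * gain:g})"
        )
    rates = base_rate + amplitude * phi
    rates = np.maximum(rates, 0.0)  # guard float round-off at the bound
    return PhysisProfile.from_rates(
        x, rates, interval_days=interval_days, vertebra=vertebra, side=side
    )


def _clipped_normal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Mean of clip(N(mu, sigma), lo, hi) (winsorized normal)."""
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    return (
        lo * stats.norm.cdf(a)
        + hi * stats.norm.sf(b)
        + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
        + sigma * (stats.norm.pdf(a) - stats.norm.pdf(b))
    )


def _gm_sampling_location(target: float, sigma: float, bound: float) -> float:
    """Pre-clip Normal location whose clipped mean equals ``target``.

    Per-animal %GM draws are clipped to the physically realizable band
    ``[-bound, bound]`` (non-negative rates); sampling from a Normal centred
    on ``target`` would therefore bias the realized cohort mean.  The
    location is shifted analytically so the realized mean hits the target.
    """
    if sigma == 0.0:
        return target
    if not (-bound < target < bound):
        raise ValueError(
            f"target %GM mean {target:g} outside realizable band ±{bound:g}"
        )
    f = lambda mu: _clipped_normal_mean(mu, sigma, -bound, bound) - target
    lo, hi = target - 10.0 * sigma, target + 10.0 * sigma
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def gen_animal(
    spec: CohortSpec, rng: np.random.Generator, animal_id: str = "animal-01"
) -> AnimalRecord:
    """Sample one animal from a cohort spec.

    Draws per-animal base rate ~ Normal(mean, sd) and per-animal %GM from
    the mean-corrected clipped Normal, splits the measured-unit rate evenly
    over the two constituent physes (each carrying the full %GM, so their
    sum does too), then adds independent station-level Normal measurement
    noise to each physis and re-derives label distances from the noisy
    rates.  Latent truth is recorded on the result.
    """
    bound = max_realizable_gm(
        spec.modulation_localization, spec.n_stations, spec.width_mm
    )
    base = float(
        rng.normal(spec.mean_vertebral_rate, spec.sd_vertebral_rate)
    )
    if base <= 0:
        logger.warning(
            "sampled non-positive base rate %.3g for %s; clamping", base, animal_id
        )
        base = 1e-6
    mu = _gm_sampling_location(spec.target_gm_mean, spec.target_gm_sd, bound)
    gm = float(rng.normal(mu, spec.target_gm_sd))
    clip_bound = bound * (1.0 - 1e-12)
    if abs(gm) > clip_bound:
        logger.debug(
            "sampled %%GM %.3g for %s outside realizable band ±%.3g; clipping",
            gm, animal_id, bound,
        )
        gm = float(np.clip(gm, -clip_bound, clip_bound))

    if spec.unit_kind == "tethered_space":
        tags = [("proximal_vertebra", "distal"), ("distal_vertebra", "proximal")]
    else:
        tags = [("apical", "proximal"), ("apical", "distal")]

    physes = []
    for vertebra, side in tags:
        clean = gen_growth_profile(
            base / 2.0,
            gm,
            localization=spec.modulation_localization,
            n_stations=spec.n_stations,
            width_mm=spec.width_mm,
            interval_days=spec.labeling.interval_days,
            vertebra=vertebra,
            side=side,
        )
        rates = clean.growth_rate
        if spec.measurement_noise_sd > 0:
            rates = rates + rng.normal(
                0.0, spec.measurement_noise_sd, size=rates.shape
            )
            n_neg = int(np.sum(rates < 0))
            if n_neg:
                logger.debug(
                    "%d noisy station rates below 0 for %s %s/%s; clamping",
                    n_neg, animal_id, vertebra, side,
                )
                rates = np.maximum(rates, 0.0)
        physes.append(
            PhysisProfile.from_rates(
                clean.positions,
                rates,
                interval_days=spec.labeling.interval_days,
                vertebra=vertebra,
                side=side,
            )
        )
    return AnimalRecord(
        id=animal_id,
        cohort=spec.name,
        physes=physes,
        latent={"base_rate_um_day": base, "gm_percent": gm},
    )


def gen_cohort(spec: CohortSpec, seed: Optional[int] = None) -> List[AnimalRecord]:
    """Generate ``spec.n_animals`` records, reproducible under the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return [
        gen_animal(spec, rng, animal_id=f"{spec.name}-{i + 1:02d}")
        for i in range(spec.n_animals)
    ]


def gen_cobb_series(
    start_deg: float,
    slope_deg_per_week,
    noise_sd: float,
    duration_days: float,
    phase_breaks_days=None,
    step_days: float = 7.0,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[float, float]]:
    """Piecewise-linear Cobb-angle series plus optional Normal noise.

    ``slope_deg_per_week`` gives one slope per phase; ``phase_breaks_days``
    are the interior phase boundaries (default: equal division of the
    duration).  Sampled every ``step_days`` from day 0 through the duration.
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    slopes = np.atleast_1d(np.asarray(slope_deg_per_week, dtype=float))
    n_phases = slopes.size
    if phase_breaks_days is None:
        breaks = np.linspace(0.0, duration_days, n_phases + 1)
    else:
        breaks = np.concatenate(
            ([0.0], np.asarray(phase_breaks_days, float), [duration_days])
        )
        if breaks.size != n_phases + 1 or np.any(np.diff(breaks) <= 0):
            raise ValueError("phase breaks must be increasing and match slopes")
    days = np.arange(0.0, duration_days + 0.5 * step_days, step_days)
    days[-1] = min(days[-1], duration_days)
    angles = np.empty_like(days)
    for i, day in enumerate(days):
        angle = start_deg
        for k in range(n_phases):
            seg = np.clip(day, breaks[k], breaks[k + 1]) - breaks[k]
            angle += slopes[k] * seg / 7.0
        angles[i] = angle
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        angles = angles + rng.normal(0.0, noise_sd, size=angles.shape)
    return list(zip(days.tolist(), angles.tolist()))


def gen_pressures(
    mean_kpa: float,
    sd_kpa: float,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Normal intradiscal pressure samples (kPa), truncated at 0."""
    if mean_kpa < 0:
        raise ValueError("mean pressure must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.maximum(rng.normal(mean_kpa, sd_kpa, size=n), 0.0)


#: Study cohorts with their published summary statistics.  Growth rates are
#: the 11-week (single-level, 2 weeks post-op) or 13-week (multi-level,
#: 2-4 weeks post-op) kyphotic apical rates; %GM parameters are the cohort
#: mean ± SD of per-animal %GM.
COHORT_PRESETS = {
    "kyphotic_11wk_control": dict(
        n_animals=5, mean_vertebral_rate=178.0, sd_vertebral_rate=21.0,
        target_gm_mean=-11.0, target_gm_sd=17.0, unit_kind="apical_vertebra",
    ),
    "control_11wk": dict(
        n_animals=5, mean_vertebral_rate=188.0, sd_vertebral_rate=11.0,
        target_gm_mean=-16.0, target_gm_sd=17.0, unit_kind="apical_vertebra",
    ),
    "single_level_high": dict(
        n_animals=4, mean_vertebral_rate=178.0, sd_vertebral_rate=21.0,
        target_gm_mean=53.0, target_gm_sd=43.0, unit_kind="tethered_space",
    ),
    "single_level_low": dict(
        n_animals=4, mean_vertebral_rate=178.0, sd_vertebral_rate=21.0,
        target_gm_mean=-1.0, target_gm_sd=15.0, unit_kind="tethered_space",
    ),
    "multi_level_low": dict(
        n_animals=3, mean_vertebral_rate=173.0, sd_vertebral_rate=28.0,
        target_gm_mean=14.0, target_gm_sd=11.0, unit_kind="tethered_space",
    ),
    "multi_level_high": dict(
        n_animals=3, mean_vertebral_rate=173.0, sd_vertebral_rate=28.0,
        target_gm_mean=10.0, target_gm_sd=10.0, unit_kind="tethered_space",
    ),
}


def cohort_preset(name: str, seed: int = 0, **overrides) -> CohortSpec:
    """Build a :class:`CohortSpec` from a named study preset."""
    if name not in COHORT_PRESETS:
        raise KeyError(
            f"unknown cohort preset '{name}'; "
            f"available: {sorted(COHORT_PRESETS)}"
        )
    params = dict(COHORT_PRESETS[name])
    params.update(overrides)
    return CohortSpec(name=name, seed=seed, **params)
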