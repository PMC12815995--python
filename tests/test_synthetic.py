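"""Synthetic cohort generator: exactness, bounds, and reproducibility."""

import numpy as np
import pytest
from scipy import integrate, stats

from vertegrow import (
    CohortSpec,
    cohort_preset,
    gen_cobb_series,
    gen_cohort,
    gen_growth_profile,
    gen_pressures,
    gm_of_profile,
    max_realizable_gm,
)
from vertegrow.synthetic import _clipped_normal_mean, _gm_sampling_location


class TestProfileGenerator:
    @pytest.mark.parametrize("target", [-60.0, -11.0, 0.0, 14.0, 53.0, 90.0])
    def test_gm_roundtrip_is_exact(self, target):
        prof = gen_growth_profile(89.0, target)
        assert gm_of_profile(prof).gm_percent == pytest.approx(
            target, abs=1e-9
        )

    def test_station_mean_equals_base_rate(self):
        prof = gen_growth_profile(123.0, 40.0)
        assert prof.growth_rate.mean() == pytest.approx(123.0, abs=1e-9)

    def test_rates_stay_nonnegative(self):
        bound = max_realizable_gm()
        prof = gen_growth_profile(100.0, bound * 0.999)
        assert np.all(prof.growth_rate >= 0.0)

    def test_unrealizable_target_raises(self):
        with pytest.raises(ValueError, match="not realizable"):
            gen_growth_profile(100.0, 400.0)

    def test_modulation_is_peripheral(self):
        # the central half is an unmodulated zone at the base rate
        prof = gen_growth_profile(100.0, 50.0, localization=0.25)
        u = prof.normalized()
        central = prof.growth_rate[(u >= 0.3) & (u <= 0.7)]
        np.testing.assert_allclose(central, 100.0, atol=1e-9)


class TestSamplingCorrectness:
    def test_clipped_normal_mean_matches_quadrature(self):
        mu, sigma, lo, hi = 53.0, 43.0, -107.0, 107.0
        closed = _clipped_normal_mean(mu, sigma, lo, hi)
        dens = lambda x: x * stats.norm.pdf(x, mu, sigma)
        body, _ = integrate.quad(dens, lo, hi)
        numeric = (
            lo * stats.norm.cdf((lo - mu) / sigma)
            + hi * stats.norm.sf((hi - mu) / sigma)
            + body
        )
        assert closed == pytest.approx(numeric, abs=1e-8)

    def test_sampling_location_compensates_clipping(self):
        bound = max_realizable_gm()
        mu = _gm_sampling_location(53.0, 43.0, bound)
        assert mu > 53.0  # upper-tail clipping pulls the mean down
        assert _clipped_normal_mean(mu, 43.0, -bound, bound) == pytest.approx(
            53.0, abs=1e-8
        )

    def test_target_outside_band_rejected(self):
        with pytest.raises(ValueError, match="realizable band"):
            _gm_sampling_location(150.0, 43.0, max_realizable_gm())


class TestCohortGeneration:
    def test_same_seed_reproduces_identically(self):
        spec = cohort_preset("single_level_high", seed=7)
        a, b = gen_cohort(spec), gen_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.latent == rb.latent
            for pa, pb in zip(ra.physes, rb.physes):
                np.testing.assert_array_equal(pa.growth_rate, pb.growth_rate)

    def test_different_seeds_differ(self):
        spec = cohort_preset("single_level_high")
        a = gen_cohort(spec, seed=1)
        b = gen_cohort(spec, seed=2)
        assert a[0].latent != b[0].latent

    def test_noiseless_cohort_recovers_targets_exactly(self):
        spec = CohortSpec(
            name="exact", n_animals=3, mean_vertebral_rate=178.0,
            sd_vertebral_rate=0.0, target_gm_mean=14.0, target_gm_sd=0.0,
            measurement_noise_sd=0.0,
        )
        for rec in gen_cohort(spec, seed=0):
            unit = rec.measured_unit()
            assert gm_of_profile(unit).gm_percent == pytest.approx(14.0, abs=1e-9)
            assert unit.growth_rate.mean() == pytest.approx(178.0, abs=1e-9)

    def test_summed_unit_carries_per_physis_gm(self):
        spec = cohort_preset("multi_level_low", measurement_noise_sd=0.0,
                             sd_vertebral_rate=0.0, target_gm_sd=0.0)
        rec = gen_cohort(spec, seed=3)[0]
        per_physis = [gm_of_profile(p).gm_percent for p in rec.physes]
        unit_gm = gm_of_profile(rec.measured_unit()).gm_percent
        assert unit_gm == pytest.approx(per_physis[0], abs=1e-9)
        assert unit_gm == pytest.approx(per_physis[1], abs=1e-9)

    def test_latent_truth_recorded(self):
        rec = gen_cohort(cohort_preset("single_level_low"), seed=5)[0]
        assert set(rec.latent) == {"base_rate_um_day", "gm_percent"}

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown cohort preset"):
            cohort_preset("no_such_cohort")

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="n_animals"):
            CohortSpec(name="x", n_animals=0, mean_vertebral_rate=100.0,
                       sd_vertebral_rate=1.0, target_gm_mean=0.0,
                       target_gm_sd=1.0)


class TestSeriesGenerators:
    def test_noiseless_cobb_series_is_piecewise_linear(self):
        series = gen_cobb_series(32.0, [-7.0, 7.0], 0.0, 28.0)
        days, angles = zip(*series)
        assert days == (0.0, 7.0, 14.0, 21.0, 28.0)
        # two phases of 14 days: down 14 deg then back up 14 deg
        assert angles[0] == pytest.approx(32.0)
        assert angles[2] == pytest.approx(18.0)
        assert angles[4] == pytest.approx(32.0)

    def test_bad_phase_breaks_rejected(self):
        with pytest.raises(ValueError, match="phase breaks"):
            gen_cobb_series(30.0, [1.0, 2.0], 0.0, 28.0,
                            phase_breaks_days=[20.0, 10.0])

    def test_pressures_truncated_at_zero(self):
        p = gen_pressures(5.0, 50.0, 200, seed=0)
        assert p.shape == (200,) and np.all(p >= 0.0)

    def test_negative_mean_pressure_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_pressures(-1.0, 1.0, 5)
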