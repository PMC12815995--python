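"""Regional growth rates and the %GM statistic."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from vertegrow import (
    HALVES,
    QUARTERS,
    THIRDS,
    PhysisProfile,
    cohort_compare,
    gm_of_profile,
    growth_modulation,
    growth_rate_from_labels,
    region_scheme_sensitivity,
    regionalize,
    station_positions,
    tethered_space,
)


def make_profile(rates, width=30.0):
    rates = np.asarray(rates, dtype=float)
    x = station_positions(rates.size, width)
    return PhysisProfile.from_rates(x, rates)


class TestLabelConversion:
    def test_scalar_conversion_matches_hand_calculation(self):
        # 2.4 mm over 13 days -> 2400/13 µm/day
        assert growth_rate_from_labels(2.4, 13.0) == pytest.approx(
            184.6153846, abs=1e-6
        )

    def test_array_conversion(self):
        out = growth_rate_from_labels(np.array([1.3, 2.6]), 13.0)
        np.testing.assert_allclose(out, [100.0, 200.0])

    def test_rejects_negative_distance(self):
        with pytest.raises(ValueError, match="non-negative"):
            growth_rate_from_labels(-0.1, 13.0)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError, match="interval"):
            growth_rate_from_labels(1.0, 0.0)


class TestRegionalize:
    def test_quarter_means_on_step_profile(self):
        # 40 stations: first 10 at 200, middle 20 at 150, last 10 at 100
        rates = np.concatenate([np.full(10, 200.0), np.full(20, 150.0),
                                np.full(10, 100.0)])
        rgr = regionalize(make_profile(rates), QUARTERS)
        assert rgr.anterior == pytest.approx(200.0)
        assert rgr.per_region_mean["middle"] == pytest.approx(150.0)
        assert rgr.posterior == pytest.approx(100.0)
        assert rgr.whole_physis_mean == pytest.approx(rates.mean())

    def test_whole_mean_is_station_mean_not_mean_of_regions(self):
        rates = np.concatenate([np.full(10, 300.0), np.full(30, 100.0)])
        rgr = regionalize(make_profile(rates), QUARTERS)
        assert rgr.whole_physis_mean == pytest.approx(150.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="no stations"):
            regionalize(make_profile([100.0, 100.0]), QUARTERS)

    def test_anterior_unossified_zone(self):
        rates = np.linspace(100, 200, 40)
        rgr = regionalize(
            make_profile(rates), QUARTERS, anterior_unossified_frac=0.1
        )
        u = np.linspace(0, 1, 40)
        assert rgr.anterior_unossified_mean == pytest.approx(
            rates[u < 0.1].mean()
        )

    def test_unossified_frac_out_of_range(self):
        with pytest.raises(ValueError, match="anterior_unossified_frac"):
            regionalize(make_profile(np.ones(40)), QUARTERS,
                        anterior_unossified_frac=1.5)


class TestGrowthModulation:
    def test_published_rate_triple(self):
        # anterior 174, posterior 191, whole mean 178 µm/day
        res = growth_modulation(174.0, 191.0, 178.0)
        assert res.gm_percent == pytest.approx(-9.5505618, abs=1e-6)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError, match="positive"):
            growth_modulation(10.0, 5.0, 0.0)

    @given(
        rates=st.lists(
            st.floats(min_value=1.0, max_value=500.0), min_size=8, max_size=64
        ),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scale_invariance(self, rates, scale):
        base = gm_of_profile(make_profile(rates)).gm_percent
        scaled = gm_of_profile(make_profile(np.array(rates) * scale)).gm_percent
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @given(
        rates=st.lists(
            st.floats(min_value=1.0, max_value=500.0), min_size=8, max_size=64
        )
    )
    def test_antisymmetry_under_ap_reversal(self, rates):
        # antisymmetry requires a grid where no rank-normalized station sits
        # exactly on a region boundary (half-open regions would then give the
        # anterior and posterior regions different station counts)
        assume((len(rates) - 1) % 4 != 0)
        forward = gm_of_profile(make_profile(rates)).gm_percent
        reverse = gm_of_profile(make_profile(np.array(rates)[::-1])).gm_percent
        assert reverse == pytest.approx(-forward, rel=1e-9, abs=1e-9)


class TestTetheredSpace:
    def test_sums_regions_elementwise(self):
        a = regionalize(make_profile(np.full(40, 80.0)))
        b = regionalize(make_profile(np.full(40, 100.0)))
        combined = tethered_space(a, b)
        assert combined.anterior == pytest.approx(180.0)
        assert combined.whole_physis_mean == pytest.approx(180.0)

    def test_scheme_mismatch_raises(self):
        a = regionalize(make_profile(np.full(40, 80.0)), QUARTERS)
        b = regionalize(make_profile(np.full(40, 80.0)), THIRDS)
        with pytest.raises(ValueError, match="scheme"):
            tethered_space(a, b)


class TestSchemeSensitivity:
    def test_peripheral_modulation_diluted_by_coarser_schemes(self):
        from vertegrow import gen_growth_profile

        profile = gen_growth_profile(100.0, 40.0, localization=0.25)
        df = region_scheme_sensitivity(profile, [QUARTERS, THIRDS, HALVES])
        gms = df["gm_percent"].to_numpy()
        assert abs(gms[0]) >= abs(gms[1]) >= abs(gms[2]) > 0


class TestCohortCompare:
    def test_unpaired_t_matches_hand_value(self):
        res = cohort_compare([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.significant == (res.p <= 0.05)

    def test_paired(self):
        res = cohort_compare([1.0, 2.0, 3.0], [2.0, 4.0, 5.0], paired=True)
        assert res.paired
        assert res.mean_a - res.mean_b == pytest.approx(-5.0 / 3.0)

    def test_degenerate_identical_groups(self):
        res = cohort_compare([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0 and not res.significant

    def test_degenerate_constant_shift(self):
        res = cohort_compare([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.significant

    def test_needs_two_observations(self):
        with pytest.raises(ValueError, match="two observations"):
            cohort_compare([1.0], [1.0, 2.0])
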