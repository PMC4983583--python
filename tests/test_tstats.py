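"""T-statistic variance ratios, null schemes, and standardized effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from traitassembly import tstats
from traitassembly.tstats import _Region, _null_t_ip_ic

from conftest import make_trait_table


def two_species_plot():
    # species A {10,12}, B {20,22}: ss_within = 4, ss_community = 104
    return make_trait_table(["P1"] * 4, ["A", "A", "B", "B"], [10, 12, 20, 22])


class TestVarianceComponents:
    def test_hand_sums(self):
        vc = tstats.variance_components(two_species_plot(), "P1")
        assert vc.ss_within_pop == pytest.approx(4.0)
        assert vc.ss_community == pytest.approx(104.0)
        assert tstats.t_ip_ic(vc) == pytest.approx(4 / 104)

    def test_single_species_community(self):
        t = make_trait_table(["P1"] * 3, ["A"] * 3, [1.0, 2.0, 4.0])
        vc = tstats.variance_components(t, "P1")
        assert vc.ss_within_pop == pytest.approx(vc.ss_community)
        assert tstats.t_ip_ic(vc) == pytest.approx(1.0)

    def test_zero_within_population_deviation(self):
        t = make_trait_table(["P1"] * 4, ["A", "A", "B", "B"], [5, 5, 9, 9])
        assert tstats.t_ip_ic(tstats.variance_components(t, "P1")) == pytest.approx(0.0)

    def test_degenerate_community_errors(self):
        t = make_trait_table(["P1"] * 3, ["A", "B", "C"], [7.0, 7.0, 7.0])
        with pytest.raises(ValueError, match="P1"):
            tstats.t_ip_ic(tstats.variance_components(t, "P1"))

    def test_region_equal_to_community_gives_unit_ratio(self):
        vc = tstats.variance_components(two_species_plot(), "P1")
        assert tstats.t_ic_ir(vc) == pytest.approx(1.0)

    def test_equal_population_means_give_zero_t_pc_pr(self):
        t = pd.concat(
            [
                make_trait_table(["P1"] * 4, ["A", "A", "B", "B"], [5, 7, 4, 8]),
                make_trait_table(["P2"] * 4, ["C", "C", "D", "D"], [1, 3, 11, 13]),
            ],
            ignore_index=True,
        )
        vc = tstats.variance_components(t, "P1")
        assert vc.var_pop_means_community == pytest.approx(0.0)
        assert tstats.t_pc_pr(vc) == pytest.approx(0.0)

    def test_layer_mixing_rejected(self):
        t = two_species_plot()
        t.loc[0, "layer"] = "shade"
        with pytest.raises(ValueError, match="layer"):
            tstats.variance_components(t, "P1")


@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
def test_invariance_to_affine_trait_changes(shift, scale):
    t = pd.concat(
        [
            make_trait_table(["P1"] * 4, ["A", "A", "B", "B"], [10, 12, 20, 22]),
            make_trait_table(["P2"] * 4, ["B", "B", "C", "C"], [15, 18, 30, 31]),
        ],
        ignore_index=True,
    )
    t2 = t.assign(log_lma=t["log_lma"] * scale + shift)
    for stat in tstats.STATISTICS:
        base = tstats.observed_statistic(t, stat)
        moved = tstats.observed_statistic(t2, stat)
        for p in base:
            assert moved[p] == pytest.approx(base[p], rel=1e-9)


def test_t_ip_ic_bounded_and_equals_anova_complement(default_traits):
    sun = default_traits[default_traits["layer"] == "sun"]
    obs = tstats.observed_statistic(sun, "t_ip_ic")
    for pid, val in obs.items():
        assert 0.0 <= val <= 1.0
        grp = sun[sun["plot_id"] == pid]
        x = grp["log_lma"].to_numpy()
        ss_between = sum(
            len(s) * (s["log_lma"].mean() - x.mean()) ** 2 for _, s in grp.groupby("species")
        )
        assert val == pytest.approx(1 - ss_between / ((x - x.mean()) ** 2).sum(), abs=1e-12)


class TestNullDistributions:
    def test_fixed_seed_reproducible(self):
        t = two_species_plot()
        a = tstats.null_distribution(t, "t_ip_ic", nperm=99, seed=5)
        b = tstats.null_distribution(t, "t_ip_ic", nperm=99, seed=5)
        assert np.array_equal(a["P1"], b["P1"])
        c = tstats.null_distribution(t, "t_ip_ic", nperm=99, seed=6)
        assert not np.array_equal(a["P1"], c["P1"])

    def test_identity_permutation_recovers_observed(self):
        class IdentityRng:
            def permuted(self, arr, axis=None):
                return np.array(arr)

        t = two_species_plot()
        region = _Region(t)
        nulls = _null_t_ip_ic(region, nperm=3, rng=IdentityRng())
        obs = tstats.observed_statistic(t, "t_ip_ic")["P1"]
        assert np.allclose(nulls["P1"], obs)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(KeyError):
            tstats.null_distribution(two_species_plot(), "t_bogus")

    def test_null_values_stay_in_unit_interval_for_t_ip_ic(self, default_traits):
        sun = default_traits[default_traits["layer"] == "sun"]
        nulls = tstats.null_distribution(sun, "t_ip_ic", nperm=99, seed=1)
        for arr in nulls.values():
            assert np.all((arr >= 0) & (arr <= 1))


class TestSES:
    def test_observed_at_null_mean_gives_zero(self):
        null = np.arange(1.0, 101.0)
        res = tstats.ses(50.5, null)
        assert res.ses == pytest.approx(0.0)
        assert not res.significant

    def test_observed_below_all_null_values_is_significant(self):
        null = np.arange(1.0, 101.0)
        res = tstats.ses(-10.0, null)
        assert res.significant and res.ses < res.null_ci[0]

    def test_degenerate_null_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            tstats.ses(1.0, np.ones(100))


class TestAggregateSES:
    def _result(self, ses_value, rng):
        null = rng.normal(0, 1, 199)
        mu, sd = null.mean(), null.std(ddof=1)
        return tstats.ses(mu + ses_value * sd, null, plot_id="p", statistic="t_ip_ic")

    def test_all_zero_ses(self):
        rng = np.random.default_rng(0)
        results = [self._result(0.0, rng) for _ in range(4)]
        agg = tstats.aggregate_ses(results)
        assert agg.mean_ses == pytest.approx(0.0, abs=1e-12)
        assert agg.sd_ses == pytest.approx(0.0, abs=1e-12)
        assert not agg.significant

    def test_symmetric_pair(self):
        rng = np.random.default_rng(1)
        results = [self._result(-1.0, rng), self._result(1.0, rng)]
        agg = tstats.aggregate_ses(results)
        assert agg.mean_ses == pytest.approx(0.0, abs=1e-12)
        assert agg.sd_ses == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_mixed_statistics_rejected(self):
        rng = np.random.default_rng(2)
        a, b = self._result(0.0, rng), self._result(0.0, rng)
        b.statistic = "t_ic_ir"
        with pytest.raises(ValueError, match="mix"):
            tstats.aggregate_ses([a, b])


def test_compute_tstats_end_to_end(default_traits):
    sun = default_traits[default_traits["layer"] == "sun"]
    results, aggregates = tstats.compute_tstats(sun, nperm=99, seed=3)
    frame = tstats.results_frame(results)
    assert set(frame["statistic"]) == set(tstats.STATISTICS)
    assert frame.groupby("statistic")["plot_id"].nunique().eq(sun["plot_id"].nunique()).all()
    # strong species structure in the default scenario: internal-filter
    # statistic sits far below its null in every plot
    tip = frame[frame["statistic"] == "t_ip_ic"]
    assert (tip["ses"] < 0).all()
    assert aggregates["t_ip_ic"].mean_ses < aggregates["t_ic_ir"].mean_ses
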