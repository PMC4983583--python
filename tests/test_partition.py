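"""Nested variance components (REML vs closed form) and the
turnover/intraspecific decomposition of CWM variance."""

import numpy as np
import pandas as pd
import pytest

import traitassembly as ta
from traitassembly import partition
from traitassembly.config import ScenarioConfig

from conftest import make_trait_table, traits_from_leaf


def balanced_two_level(sigma_b=2.0, sigma_w=1.0, n_groups=10, n_obs=10, seed=42):
    rng = np.random.default_rng(seed)
    g = np.repeat([f"g{i}" for i in range(n_groups)], n_obs)
    y = np.repeat(rng.normal(0, sigma_b, n_groups), n_obs) + rng.normal(0, sigma_w, g.size)
    return pd.DataFrame({"group": g, "log_lma": y})


class TestMomentsOracle:
    def test_two_level_matches_explicit_ems(self):
        df = balanced_two_level()
        comp = partition.moments_oracle(df, hierarchy=("group",))
        gm = df.groupby("group")["log_lma"].mean()
        ms_b = 10 * gm.var(ddof=1)
        ms_w = (
            (df["log_lma"] - df.groupby("group")["log_lma"].transform("mean")) ** 2
        ).sum() / (100 - 10)
        assert comp.variances[1] == pytest.approx(ms_w, rel=1e-12)
        assert comp.variances[0] == pytest.approx((ms_b - ms_w) / 10, rel=1e-12)

    def test_groups_of_one_reduce_to_sample_variance(self):
        df = pd.DataFrame({"group": list("abcd"), "log_lma": [1.0, 2.0, 4.0, 9.0]})
        comp = partition.moments_oracle(df, hierarchy=("group",))
        assert comp.variances[0] == pytest.approx(np.var(df["log_lma"], ddof=1))
        assert comp.variances[1] == pytest.approx(0.0)

    def test_constant_data_gives_zero_components(self):
        df = balanced_two_level()
        df["log_lma"] = 3.0
        comp = partition.moments_oracle(df, hierarchy=("group",))
        assert np.allclose(comp.variances, 0.0)

    def test_unbalanced_design_rejected(self):
        df = balanced_two_level().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            partition.moments_oracle(df, hierarchy=("group",))


class TestNestedREML:
    def test_matches_moments_on_balanced_two_level(self):
        df = balanced_two_level()
        mo = partition.moments_oracle(df, hierarchy=("group",))
        re = partition.nested_variance_components(df, hierarchy=("group",))
        np.testing.assert_allclose(re.variances, mo.variances, rtol=1e-6)
        assert re.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_between_group_spread_vanishes(self):
        df = balanced_two_level(sigma_b=0.0, sigma_w=1.0, seed=7)
        comp = partition.nested_variance_components(df, hierarchy=("group",))
        assert comp.variances[0] == pytest.approx(0.0, abs=5e-2)

    def test_non_nested_labels_listed(self):
        t = make_trait_table(["P1"] * 4, ["A", "A", "B", "B"], [1, 2, 3, 4])
        t["genus"] = ["g1", "g1", "g1", "g1"]
        t["family"] = ["f1", "f2", "f1", "f1"]  # g1 sits under two families
        with pytest.raises(ValueError, match="g1"):
            partition.nested_variance_components(
                t, hierarchy=("plot_id", "family", "genus", "species")
            )

    def test_recovers_generator_variance_structure(self):
        # fully nested scenario: narrow niches make species unique to plots,
        # so the species level carries sigma_species^2 + sigma_pop^2
        cfg = ScenarioConfig(
            n_plots=20,
            env=tuple(np.linspace(200, 3600, 20)),
            pool_size=400,
            niche_width=30.0,
            beta_env=0.0,
            trees_per_species=(5, 5),
            leaves_per_tree=(5, 5),
            include_shade=False,
            seed=21,
        )
        leaf, *_ = ta.simulate_region(cfg)
        leaf = leaf.assign(lma=(leaf["lamina_dry_mass"] + leaf["petiole_dry_mass"])
                           / (leaf["lamina_fresh_area"] + leaf["petiole_fresh_area"]))
        leaf["log_lma"] = np.log(leaf["lma"])
        comp = partition.nested_variance_components(
            leaf, hierarchy=("plot_id", "species", "tree_id")
        )
        est = dict(zip(comp.levels, comp.variances))
        truth = {
            "plot_id": cfg.sigma_site**2,
            "species": cfg.sigma_species**2 + cfg.sigma_pop**2,
            "tree_id": cfg.sigma_tree**2,
            "leaf": cfg.sigma_leaf**2,
        }
        counts = {
            "plot_id": 20,
            "species": leaf.groupby(["plot_id", "species"]).ngroups,
            "tree_id": leaf["tree_id"].nunique(),
            "leaf": len(leaf),
        }
        # sampling noise of a variance component estimated from G units,
        # inflated by the mean-squared contribution of the levels below it
        below = {
            "plot_id": (truth["species"]) / 10 + truth["tree_id"] / 50,
            "species": truth["tree_id"] / 5 + truth["leaf"] / 25,
            "tree_id": truth["leaf"] / 5,
            "leaf": 0.0,
        }
        for level, true_var in truth.items():
            se = np.sqrt(2.0 / (counts[level] - 1)) * (true_var + below[level])
            assert est[level] == pytest.approx(true_var, abs=3 * se), level


class TestLepsDecomposition:
    def test_identical_species_means_give_pure_turnover(self):
        t = pd.concat(
            [
                make_trait_table(["P1"] * 2, ["A", "B"], np.log([100.0, 200.0])),
                make_trait_table(["P2"] * 2, ["A", "B"], np.log([100.0, 200.0])),
            ],
            ignore_index=True,
        )
        census = pd.DataFrame(
            {
                "plot_id": ["P1", "P1", "P2", "P2"],
                "species": ["A", "B", "A", "B"],
                "basal_area": [3.0, 1.0, 1.0, 3.0],
            }
        )
        dec = partition.leps_decomposition(t, census)
        assert dec.ss_intra == pytest.approx(0.0, abs=1e-12)
        assert dec.cov == pytest.approx(0.0, abs=1e-9)
        assert dec.turnover_share == pytest.approx(1.0)

    def test_two_by_two_hand_fixture(self):
        t = pd.concat(
            [
                make_trait_table(["P1"] * 2, ["A", "B"], np.log([100.0, 200.0])),
                make_trait_table(["P2"] * 2, ["A", "B"], np.log([120.0, 260.0])),
            ],
            ignore_index=True,
        )
        census = pd.DataFrame(
            {
                "plot_id": ["P1", "P1", "P2", "P2"],
                "species": ["A", "B", "A", "B"],
                "basal_area": [0.5, 0.5, 0.25, 0.75],
            }
        )
        dec = partition.leps_decomposition(t, census)
        # specific CWMs: 150, 225; fixed means A=110, B=230 -> fixed CWMs 170, 200
        assert dec.ss_specific == pytest.approx(2812.5)
        assert dec.ss_fixed == pytest.approx(450.0)
        assert dec.ss_intra == pytest.approx(1012.5)
        assert dec.cov == pytest.approx(1350.0)

    def test_single_plot_rejected(self):
        t = make_trait_table(["P1"] * 2, ["A", "B"], [1.0, 2.0])
        census = pd.DataFrame(
            {"plot_id": ["P1", "P1"], "species": ["A", "B"], "basal_area": [1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="2 plots"):
            partition.leps_decomposition(t, census)

    def test_identity_holds_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_plots, n_sp = rng.integers(2, 6), rng.integers(2, 7)
            frames, census_rows = [], []
            for p in range(n_plots):
                vals = rng.normal(np.log(120), 0.4, n_sp)
                frames.append(
                    make_trait_table([f"P{p}"] * n_sp, [f"s{i}" for i in range(n_sp)], vals)
                )
                for i in range(n_sp):
                    census_rows.append((f"P{p}", f"s{i}", rng.lognormal(0, 1)))
            t = pd.concat(frames, ignore_index=True)
            census = pd.DataFrame(census_rows, columns=["plot_id", "species", "basal_area"])
            dec = partition.leps_decomposition(t, census)
            assert dec.ss_fixed + dec.ss_intra + dec.cov == pytest.approx(
                dec.ss_specific, rel=1e-12, abs=1e-12
            )
            assert dec.turnover_share + dec.intraspecific_share + dec.cov_share == pytest.approx(1.0)
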