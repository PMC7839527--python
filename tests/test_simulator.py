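"""Inventory initialization, daily physics, demography and bookkeeping."""

import copy

import numpy as np
import pandas as pd
import pytest

from lianacomp import physiology as ph
from lianacomp import simulator as sim

from conftest import make_inventory


@pytest.fixture()
def mixed_inventory():
    return make_inventory(
        [
            ("p1", "t1", "tree", 30.0, 0.45),
            ("p1", "t2", "tree", 15.0, 0.62),
            ("p1", "t3", "tree", 45.0, 0.80),
            ("p1", "l1", "liana", 10.0, np.nan),
            ("p1", "l2", "liana", 2.0, np.nan),
        ]
    )


class TestInitialization:
    def test_canopy_liana_raised_to_tallest_tree_plus_offset(self, mixed_inventory):
        forest = sim.initialize_from_inventory(mixed_inventory, patch_area_m2=400.0)
        patch = forest.patches[0]
        tallest = patch.tallest_tree_height()
        liana = [c for c in patch.cohorts if c.pft == "liana" and c.dbh >= 3.0][0]
        assert liana.height == pytest.approx(tallest + forest.config.h_offset)
        assert liana.delta_dbh > 0.0

    def test_small_liana_follows_its_own_allometry(self, mixed_inventory):
        forest = sim.initialize_from_inventory(mixed_inventory, patch_area_m2=400.0)
        patch = forest.patches[0]
        liana = [c for c in patch.cohorts if c.pft == "liana" and c.dbh < 3.0][0]
        pars = forest.param("liana")
        assert liana.height == pytest.approx(float(ph.height_from_dbh(liana.dbh, pars)))
        assert liana.delta_dbh == 0.0

    def test_trees_classified_by_wood_density(self, mixed_inventory):
        forest = sim.initialize_from_inventory(mixed_inventory, patch_area_m2=400.0)
        pfts = {c.pft for c in forest.patches[0].cohorts}
        assert {"early", "mid", "late", "liana"} <= pfts

    def test_liana_without_trees_keeps_own_allometry_with_warning(self, caplog):
        inv = make_inventory([("p1", "l1", "liana", 10.0, np.nan)])
        with caplog.at_level("WARNING"):
            forest = sim.initialize_from_inventory(inv, patch_area_m2=400.0)
        c = forest.patches[0].cohorts[0]
        assert c.height == pytest.approx(
            float(ph.height_from_dbh(10.0, forest.param("liana")))
        )
        assert "climbing cap inactive" in caplog.text

    def test_nonpositive_dbh_rejected(self):
        inv = make_inventory([("p1", "t1", "tree", -3.0, 0.5)])
        with pytest.raises(ValueError, match="dbh"):
            sim.initialize_from_inventory(inv)

    def test_tree_only_inventory_equals_liana_removal_of_mixed(self, mixed_inventory):
        trees_only = mixed_inventory[mixed_inventory["growth_form"] == "tree"]
        f1 = sim.initialize_from_inventory(trees_only, patch_area_m2=400.0)
        f2 = sim.remove_lianas(
            sim.initialize_from_inventory(mixed_inventory, patch_area_m2=400.0)
        )
        s1 = [(c.pft, c.dbh, c.density) for p in f1.patches for c in p.cohorts]
        s2 = [(c.pft, c.dbh, c.density) for p in f2.patches for c in p.cohorts]
        assert s1 == s2


class TestRemoveLianas:
    def test_idempotent_and_tree_preserving(self, bci_forest):
        once = sim.remove_lianas(bci_forest)
        twice = sim.remove_lianas(once)
        n_tree = lambda f: sum(
            1 for p in f.patches for c in p.cohorts if c.pft != "liana"
        )
        n_liana = lambda f: sum(
            1 for p in f.patches for c in p.cohorts if c.pft == "liana"
        )
        assert n_liana(once) == 0
        assert n_tree(once) == n_tree(bci_forest)
        assert [len(p.cohorts) for p in twice.patches] == [
            len(p.cohorts) for p in once.patches
        ]

    def test_forest_without_lianas_unchanged(self, bci_forest):
        nl = sim.remove_lianas(bci_forest)
        again = sim.remove_lianas(nl)
        assert [len(p.cohorts) for p in again.patches] == [
            len(p.cohorts) for p in nl.patches
        ]


def _one_day_met(par, precip=0.0, tair=26.0, rh=0.8):
    return pd.DataFrame(
        [{"date": "2004-01-01", "precip_mm": precip, "par_umol_m2_s": par,
          "tair_C": tair, "rh_frac": rh}]
    )


class TestDailyPhysics:
    def test_zero_par_day_has_zero_gpp_positive_respiration(self, small_forest):
        met = _one_day_met(par=0.0)
        cache = sim._MonthCache(small_forest)
        out, _ = sim._daily_step(small_forest, cache, met.iloc[0], [], "000")
        assert all(v["gpp"] == 0.0 for v in out.values())
        assert all(v["r_leaf"] > 0.0 for v in out.values())

    def test_identical_patches_produce_identical_fluxes(self):
        rows = [("a", "t1", "tree", 30.0, 0.45), ("a", "l1", "liana", 8.0, np.nan)]
        rows += [("b",) + r[1:] for r in rows]
        forest = sim.initialize_from_inventory(make_inventory(rows), patch_area_m2=400.0)
        cache = sim._MonthCache(forest)
        wr = []
        sim._daily_step(forest, cache, _one_day_met(600.0, 5.0).iloc[0], wr, "000")
        w = pd.DataFrame(wr)
        a = w[w["patch"] == "a"].drop(columns=["patch"]).reset_index(drop=True)
        b = w[w["patch"] == "b"].drop(columns=["patch"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_water_budget_closes_each_patch_day(self, small_forest, small_met):
        res = sim.ForestSimulation(small_forest, small_met).run(years=1)
        assert res.water_closure_error() < 1e-6

    def test_carbon_budget_closes_each_cohort_month(self, small_forest, small_met):
        res = sim.ForestSimulation(small_forest, small_met).run(years=1)
        assert res.carbon_closure_error() < 1e-6

    def test_runs_are_bit_reproducible(self, small_forest, small_met):
        r1 = sim.ForestSimulation(small_forest, small_met).run(years=1, seed=3)
        r2 = sim.ForestSimulation(small_forest, small_met).run(years=1, seed=3)
        pd.testing.assert_frame_equal(r1.fluxes, r2.fluxes)


class TestDemography:
    def test_logistic_mortality_arithmetic(self):
        pars = ph.PFTParameterSet.liana_posterior().replace(mort2=15.0, mort3=0.05)
        # healthy cohort: density-dependent term ~ mort1 * 3e-7, total ~ mort3
        healthy = pars.mort3 + pars.mort1 / (1.0 + np.exp(pars.mort2 * 1.0))
        assert healthy == pytest.approx(pars.mort3, abs=1e-6)
        # fully stressed: logistic midpoint -> mort1 / 2
        starved = pars.mort1 / (1.0 + np.exp(pars.mort2 * 0.0))
        assert starved == pytest.approx(pars.mort1 / 2.0)

    def test_stressed_cohorts_die_faster_in_simulation(self, small_forest, small_met):
        res = sim.ForestSimulation(small_forest, small_met).run(years=1)
        led = res.carbon_ledger
        assert (led["gpp"] >= 0).all()
        # densities and pools never negative in the final state
        for p in res.forest.patches:
            for c in p.cohorts:
                assert c.density >= 0 and min(c.bl, c.bs, c.br) >= 0

    def test_liana_height_restriction_updates_delta_dbh(self):
        rows = [("a", "t1", "tree", 25.0, 0.45), ("a", "l1", "liana", 8.0, np.nan)]
        forest = sim.initialize_from_inventory(make_inventory(rows), patch_area_m2=400.0)
        patch = forest.patches[0]
        liana = [c for c in patch.cohorts if c.pft == "liana"][0]
        tallest = patch.tallest_tree_height()
        # pretend the liana assimilated a lot: force growth then re-restrict
        for c in patch.cohorts:
            c.acc["gpp"] = 5.0 if c.pft == "liana" else 0.1
            c.acc["pot_gpp"] = 5.0
        sim._monthly_demography(forest, 30, [], "000")
        tallest_new = patch.tallest_tree_height()
        liana = [c for c in patch.cohorts if c.pft == "liana" and c.dbh > 3][0]
        assert liana.height <= tallest_new + forest.config.h_offset + 1e-9


class TestLianaShare:
    def _fluxes(self, liana, eco):
        rows = []
        for i, (l, e) in enumerate(zip(liana, eco)):
            rows.append({"month_index": i, "pft": "liana", "gpp": l})
            rows.append({"month_index": i, "pft": "ecosystem", "gpp": e})
        return pd.DataFrame(rows)

    def test_all_liana_forest(self):
        share = sim.liana_share(self._fluxes([2.0], [2.0]))
        assert share.iloc[0] == 1.0

    def test_no_lianas(self):
        f = pd.DataFrame(
            [{"month_index": 0, "pft": "ecosystem", "gpp": 3.0}]
        )
        assert sim.liana_share(f).iloc[0] == 0.0

    def test_two_equal_pfts(self):
        share = sim.liana_share(self._fluxes([1.5], [3.0]))
        assert share.iloc[0] == 0.5

    def test_zero_total_flagged_undefined(self):
        share = sim.liana_share(self._fluxes([0.0], [0.0]))
        assert np.isnan(share.iloc[0])
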