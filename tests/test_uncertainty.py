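"""Sensitivity design, splines, elasticity, decomposition, ensembles, masks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lianacomp import simulator as sim
from lianacomp import synth, uncertainty as unc
from lianacomp.traits import TraitDistribution, TraitPosterior

from conftest import make_inventory


class TestSensitivityDesign:
    def test_standard_normal_design_is_the_z_grid(self):
        d = TraitDistribution("x", "normal", 0.0, 1.0)
        values = np.array([v for _, v in unc.sensitivity_design(d)])
        assert values == pytest.approx([-3, -2, -1, 0, 1, 2, 3], abs=1e-9)

    def test_uniform_design_equals_the_probabilities(self):
        d = TraitDistribution("x", "uniform", 0.0, 1.0)
        pairs = unc.sensitivity_design(d)
        for p, v in pairs:
            assert v == pytest.approx(p, abs=1e-12)

    def test_lognormal_median_matches_printed_value(self):
        d = TraitDistribution("K_max", "lognormal", -3.0, 0.75)
        pairs = unc.sensitivity_design(d)
        assert pairs[3][1] == pytest.approx(0.0498, abs=1e-3)

    def test_empirical_design_from_posterior_draws(self):
        post = TraitPosterior("x", np.random.default_rng(0).normal(5, 1, 20000),
                              "meta-analysis")
        values = np.array([v for _, v in unc.sensitivity_design(post)])
        assert values[3] == pytest.approx(5.0, abs=0.05)
        assert np.all(np.diff(values) > 0)


class TestEvaluateDesign:
    def test_constant_linear_and_monotone_models(self):
        d = TraitDistribution("x", "normal", 2.0, 0.5)
        design = unc.sensitivity_design(d)
        const = unc.evaluate_design(lambda p: 7.0, {"x": 2.0}, "x", design)
        assert np.allclose(const, 7.0)
        lin = unc.evaluate_design(lambda p: 2.0 * p["x"], {"x": 2.0}, "x", design)
        assert lin == pytest.approx([2.0 * v for _, v in design])
        assert np.all(np.diff(lin) > 0)

    def test_failed_runs_recorded_as_missing(self):
        d = TraitDistribution("x", "normal", 0.0, 1.0)
        design = unc.sensitivity_design(d)

        def flaky(p):
            if p["x"] < -2.5:
                raise RuntimeError("boom")
            return p["x"]

        resp = unc.evaluate_design(flaky, {}, "x", design)
        assert np.isnan(resp[0]) and np.isfinite(resp[1:]).all()
        g = unc.fit_response_spline([v for _, v in design], resp)
        assert g(0.0) == pytest.approx(0.0, abs=1e-9)


class TestResponseSpline:
    def test_linear_data_reproduced_everywhere(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        g = unc.fit_response_spline(x, 2.0 * x + 1.0)
        grid = np.linspace(-6, 6, 500)  # includes the linear tails
        assert np.max(np.abs(g(grid) - (2 * grid + 1))) < 1e-12

    def test_quadratic_within_5pct_on_node_span(self):
        """Dense-grid comparison against the quadratic: deviation stays
        within 5% of the response range (the monotone slope limiter flattens
        the interpolant slightly around the minimum)."""
        x = np.linspace(-3, 3, 7)
        g = unc.fit_response_spline(x, x**2)
        grid = np.linspace(-3, 3, 400)
        ref = grid**2
        assert np.max(np.abs(g(grid) - ref)) < 0.05 * ref.max()
        mask = ref >= 2.0
        assert np.max(np.abs(g(grid)[mask] - ref[mask]) / ref[mask]) < 0.05

    def test_nodes_interpolated_exactly(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(-5, 5, 7))
        y = rng.normal(size=7)
        g = unc.fit_response_spline(x, y)
        assert g(x) == pytest.approx(y, abs=1e-12)

    def test_duplicate_design_values_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            unc.fit_response_spline([0, 1, 1, 2, 3], [1, 2, 3, 4, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            unc.fit_response_spline([0, 1, 2], [1, 2, 3])


class _AnalyticG:
    """Closed-form response used as an elasticity oracle."""

    def __init__(self, f, df):
        self.f, self.df = f, df

    def __call__(self, v):
        return self.f(np.asarray(v, dtype=float))

    def derivative(self, v):
        return self.df(np.asarray(v, dtype=float))


class TestElasticity:
    def test_constant_response_has_zero_elasticity(self):
        g = unc.fit_response_spline([-3, -1, 0, 1, 3], [4.0] * 5)
        assert unc.elasticity(g, 1.0) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_power_law_elasticity_is_the_exponent(self, k):
        g = _AnalyticG(lambda b: b**k, lambda b: k * b ** (k - 1))
        assert unc.elasticity(g, 1.7) == pytest.approx(k, abs=1e-6)

    def test_linear_response_closed_form(self):
        # g = a*b + c at bbar=1, a=2, c=2 -> 0.5
        g = unc.fit_response_spline([-3, -1, 0, 1, 3], [2 * v + 2 for v in [-3, -1, 0, 1, 3]])
        assert unc.elasticity(g, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_zero_response_reported_undefined(self):
        g = unc.fit_response_spline([-3, -1, 0, 1, 3], [-3, -1, 0, 1, 3])
        assert math.isnan(unc.elasticity(g, 0.0))


class TestVarianceDecomposition:
    def test_single_trait_gets_all_the_variance(self):
        g = unc.fit_response_spline([-3, -1, 0, 1, 3], [-6, -2, 0, 2, 6])
        draws = np.random.default_rng(0).normal(0, 1, 10000)
        table = unc.variance_decomposition({"q": g}, {"q": draws})
        assert table.table["rel_var"].iloc[0] == 1.0

    def test_equal_variances_split_equally(self):
        x = [-3, -1, 0, 1, 3]
        rng = np.random.default_rng(1)
        splines, posts = {}, {}
        for name in ["K_max", "P50", "SLA", "q"]:
            splines[name] = unc.fit_response_spline(x, [2 * v for v in x])
            posts[name] = rng.normal(0, 1, 50000)
        table = unc.variance_decomposition(splines, posts)
        assert table.table["rel_var"].to_numpy() == pytest.approx([0.25] * 4, abs=0.02)

    def test_linear_response_matches_closed_form_variance(self):
        a, v = 3.0, 0.49
        x = [-3, -1, 0, 1, 3]
        g = unc.fit_response_spline(x, [a * u for u in x])
        draws = np.random.default_rng(2).normal(0, math.sqrt(v), 10**5)
        table = unc.variance_decomposition({"q": g}, {"q": draws})
        assert table.tot_var == pytest.approx(a**2 * v, rel=0.02)

    def test_rel_var_sums_to_one_and_aggregates_partition(self):
        rng = np.random.default_rng(3)
        x = np.linspace(-2, 2, 7)
        splines = {
            n: unc.fit_response_spline(x, rng.normal(size=7).cumsum())
            for n in ["K_max", "SLA", "b1Bs", "quantum_efficiency", "stoma_psi_b"]
        }
        posts = {n: rng.normal(0, 0.5, 20000) for n in splines}
        table = unc.variance_decomposition(splines, posts)
        assert table.table["rel_var"].sum() == pytest.approx(1.0, abs=1e-12)
        for by in ("competition", "organ", "process"):
            assert table.aggregate(by).sum() == pytest.approx(1.0, abs=1e-12)
        assert table.water_share + table.light_share <= 1.0 + 1e-12

    def test_empty_draws_rejected(self):
        g = unc.fit_response_spline([-3, -1, 0, 1, 3], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="empty"):
            unc.variance_decomposition({"q": g}, {"q": np.array([])})


class TestEnsemble:
    def test_point_mass_parameters_give_zero_ci_width(self):
        post = TraitPosterior("x", np.full(100, 2.0), "meta-analysis")
        res = unc.ensemble(lambda p: [p["x"], p["x"] ** 2], {"x": post}, n=20, seed=0)
        assert np.all(res.ci_width() == 0.0)

    def test_same_seed_reproduces_results(self):
        d = {"x": TraitDistribution("x", "normal", 0.0, 1.0)}
        r1 = unc.ensemble(lambda p: [p["x"]], d, n=30, seed=5)
        r2 = unc.ensemble(lambda p: [p["x"]], d, n=30, seed=5)
        assert np.array_equal(r1.outputs, r2.outputs)

    def test_posterior_contraction_narrows_the_envelope(self):
        """For a monotone model, a posterior that is a contraction of the
        prior yields a narrower ensemble CI."""
        prior = TraitDistribution("x", "normal", 10.0, 2.0)
        post = TraitPosterior(
            "x", np.random.default_rng(0).normal(10.0, 0.5, 5000), "meta-analysis"
        )
        runner = lambda p: [math.exp(0.3 * p["x"])]
        r_prior = unc.ensemble(runner, {"x": prior}, n=200, seed=1)
        r_post = unc.ensemble(runner, {"x": post}, n=200, seed=1)
        assert r_post.ci_spread_ratio(r_prior) < 1.0

    def test_failed_runs_logged_and_excluded(self):
        d = {"x": TraitDistribution("x", "uniform", 0.0, 1.0)}

        def flaky(p):
            if p["x"] > 0.8:
                raise RuntimeError("boom")
            return [p["x"]]

        res = unc.ensemble(flaky, d, n=50, seed=2)
        assert res.n_failed > 0
        assert res.n_effective == 50 - res.n_failed

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            unc.ensemble(lambda p: [0.0], {}, n=1, seed=0)


class TestScenarioMasks:
    def test_dry_classification_thresholds(self):
        df = unc.dry_season_mask(pd.Series({1: 59.0, 2: 99.0, 3: 150.0}))
        assert df.loc[1, "dry"] and df.loc[1, "strong_dry"]
        assert df.loc[2, "dry"] and not df.loc[2, "strong_dry"]
        assert not df.loc[3, "dry"] and not df.loc[3, "strong_dry"]

    def test_min_count_equal_to_patch_count_selects_all(self, bci_forest):
        n = len(bci_forest.patches)
        assert len(unc.select_young_patches(bci_forest, min_count=n)) == n

    def test_min_count_exceeding_patches_rejected(self, bci_forest):
        with pytest.raises(ValueError, match="min_count"):
            unc.select_young_patches(bci_forest, len(bci_forest.patches) + 1)

    def test_selected_patches_are_liana_rich(self, bci_forest):
        chosen = unc.select_young_patches(bci_forest, min_count=2)
        m = unc._patch_metrics(bci_forest).set_index("patch")
        assert len(chosen) >= 2
        # the most liana-dense patch among low-canopy patches is selected
        assert m.loc[chosen, "liana_density"].mean() >= m["liana_density"].mean()

    def test_scenario_masks_bundle(self, bci_forest, bci_met):
        masks = unc.scenario_masks(bci_met, bci_forest, min_count=1)
        dry = masks["dry_season"]
        # BCI-like template: Jan-Mar strong dry, Apr dry, rest wet
        by_month = dry.groupby(dry.index.month)[["dry", "strong_dry"]].all()
        assert by_month.loc[[1, 2, 3], "strong_dry"].all()
        assert by_month.loc[4, "dry"] and not by_month.loc[4, "strong_dry"]
        assert not by_month.loc[[6, 7, 8], "dry"].any()
        assert len(masks["young_patches"]) >= 1


@pytest.fixture(scope="module")
def shares():
    rows = [
        ("a", "t1", "tree", 30.0, 0.45),
        ("a", "t2", "tree", 18.0, 0.62),
        ("a", "l1", "liana", 8.0, np.nan),
        ("a", "l2", "liana", 5.0, np.nan),
    ]
    forest = sim.initialize_from_inventory(make_inventory(rows), patch_area_m2=400.0)
    met = synth.generate_met(synth.BCI_TEMPLATE, years=1, seed=9)
    monthly = unc.dry_season_mask(
        met.assign(d=pd.to_datetime(met["date"]))
        .groupby(lambda i: pd.to_datetime(met["date"][i]).month)["precip_mm"]
        .sum()
    )
    dry_months = set(monthly.index[monthly["dry"]])

    def run(params, season):
        pfts = dict(forest.pfts)
        pfts["liana"] = pfts["liana"].replace(**{k: abs(v) for k, v in params.items()})
        f = forest.copy()
        f.pfts = pfts
        res = sim.run_simulation(f, met, years=1)
        li = res.fluxes[res.fluxes["pft"] == "liana"].set_index("month_index")["gpp"]
        if season == "dry":
            li = li[[m - 1 in {d - 1 for d in dry_months} for m in li.index + 1]]
        return float(li.mean()) if len(li) else 0.0

    from lianacomp.traits import load_priors

    dists = {t: load_priors()[t] for t in ["stoma_psi_b", "SLA"]}
    out = {}
    for season in ("all", "dry"):
        sa = unc.SensitivityAnalysis(lambda p, s=season: run(p, s), dists)
        results = sa.fit()
        table = unc.variance_decomposition(
            {t: r.spline for t, r in results.items()},
            {t: dists[t].rvs(4000, np.random.default_rng(1)) for t in dists},
        )
        out[season] = table.water_share
    return out


class TestDrySeasonWaterShare:
    """Directional analogue of the seasonal competition shift: on a strongly
    seasonal site, the water-related share of output variance is at least as
    large in the dry season as over the full year."""

    def test_dry_season_water_share_not_smaller(self, shares):
        assert shares["dry"] >= shares["all"] - 1e-9
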