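"""Final-model tests: fits, prediction curves, percent change, sign switch."""

import numpy as np
import pandas as pd
import pytest

from conftest import degenerate_fit, identity_design
from skyglow.abundance import (MissingTermError, alan_cap, drop_stations_refit,
                               dual_scale_marginal, fit_final,
                               nearest_rank_percentile, percent_change,
                               posterior_coef_correlation, predict_curve,
                               sign_switch)
from skyglow.covariates import MultiScaleDesign
from skyglow.mcmc import ChainConfig
from skyglow.synthdata import TrueParameters, make_multiscale_design, simulate_counts


def _fitted(seed=0, n=400, cfg=None, interaction=True):
    d = make_multiscale_design(n, covs=("alan", "urban"), cross_corr=0.4, seed=seed)
    truth = TrueParameters(intercept=np.log(1.6),
                           coefficients={"alan": (0.3, 1600), "urban": (0.2, 1600)},
                           interaction=(-0.5, 1600, 1600) if interaction else None,
                           dispersion=2.0)
    tab = simulate_counts(d, truth, seed=seed + 1)
    d.df["count"] = tab["true_count"].to_numpy()
    cfg = cfg or ChainConfig(chains=3, iterations=1200, burn_in=300, seed=seed)
    fit = fit_final(d, {"alan": 1600, "urban": 1600}, cfg,
                    interaction=("alan", "urban") if interaction else None,
                    interaction_scales=(1600, 1600) if interaction else None)
    return fit, truth


class TestFitFinal:
    def test_true_coefficients_inside_95_ci(self):
        fit, truth = _fitted(seed=3)
        checks = {"intercept": truth.intercept, "alan": 0.3, "urban": 0.2,
                  "alan:urban": -0.5}
        for name, val in checks.items():
            lo, hi = fit.samples.interval(name)
            assert lo <= val <= hi, name

    def test_dropping_interaction_removes_exactly_one_term(self):
        with_int, _ = _fitted(seed=4, n=150,
                              cfg=ChainConfig(chains=1, iterations=150, burn_in=50))
        without, _ = _fitted(seed=4, n=150, interaction=False,
                             cfg=ChainConfig(chains=1, iterations=150, burn_in=50))
        assert len(with_int.samples.names) == len(without.samples.names) + 1

    def test_refit_same_seed_same_dic(self):
        cfg = ChainConfig(chains=2, iterations=300, burn_in=100, seed=9)
        a, _ = _fitted(seed=5, n=150, cfg=cfg)
        b, _ = _fitted(seed=5, n=150, cfg=cfg)
        assert a.dic.dic == b.dic.dic

    def test_duplicate_scale_rejected(self):
        d = make_multiscale_design(50, covs=("alan",), seed=0)
        d.df["count"] = 1
        with pytest.raises(ValueError, match="duplicate"):
            fit_final(d, {"alan": [1600, 1600]},
                      ChainConfig(chains=1, iterations=20, burn_in=5),
                      interaction=None)


class TestAlanCap:
    def _design(self, alan, urban):
        df = pd.DataFrame({"station_id": "S", "count": 0,
                           "alan_1600": alan, "urban_1600": urban})
        for r in (400, 6400):
            df[f"alan_{r}"] = 0.0
            df[f"urban_{r}"] = 0.0
        scaling = {c: (0.0, 1.0) for c in df.columns if c.startswith(("alan", "urban"))}
        return MultiScaleDesign(df=df, radii=(400, 1600, 6400),
                                landscape_covs=("alan", "urban"), fixed_covs=(),
                                quad_pairs=(), scaling=scaling, standardized=True)

    def test_dark_surveys_cap_zero(self):
        d = self._design(np.zeros(20), np.full(20, 0.1))
        assert alan_cap(d, 0.5, 1600) == 0.0

    def test_nearest_rank_99th(self):
        d = self._design(np.arange(1.0, 101.0), np.zeros(100))
        assert alan_cap(d, 0.5, 1600) == 99.0
        assert nearest_rank_percentile(np.arange(1.0, 101.0), 0.95) == 95.0

    def test_cap_nondecreasing_in_urban_level(self):
        rng = np.random.default_rng(0)
        urban = rng.uniform(0, 1, 200)
        alan = urban * 10 + rng.uniform(0, 1, 200)
        d = self._design(alan, urban)
        caps = [alan_cap(d, u, 1600) for u in (0.2, 0.5, 0.9)]
        assert caps == sorted(caps)

    def test_too_few_qualifying_surveys_rejected(self):
        d = self._design(np.arange(20.0), np.linspace(0, 1, 20))
        with pytest.raises(ValueError, match="urban"):
            alan_cap(d, 0.01, 1600)


class TestPredictCurve:
    def test_zero_slopes_flat_curve(self):
        fit = degenerate_fit(beta_alan=0.0, intercept=np.log(2.0))
        ps = predict_curve(fit, [0.0, 1.0, 5.0], urban_level=0.0)
        np.testing.assert_allclose(ps.curve["mean"], 2.0, rtol=1e-12)

    def test_single_draw_zero_width_interval(self):
        fit = degenerate_fit(beta_alan=-0.2, intercept=0.5)
        ps = predict_curve(fit, [0.0, 1.0], urban_level=0.0)
        np.testing.assert_allclose(ps.curve["lo95"], ps.curve["mean"])
        np.testing.assert_allclose(ps.curve["hi95"], ps.curve["mean"])

    def test_negative_coefficient_strictly_decreasing(self):
        fit = degenerate_fit(beta_alan=-0.4, intercept=1.0, n_draws=50)
        ps = predict_curve(fit, np.linspace(0, 5, 20), urban_level=0.0)
        assert np.all(np.diff(ps.curve["mean"]) < 0)

    def test_grid_beyond_cap_rejected_unless_forced(self):
        fit = degenerate_fit(beta_alan=-0.1)
        with pytest.raises(ValueError, match="cap"):
            predict_curve(fit, [0.0, 4.0], urban_level=0.0, cap=2.0)
        ps = predict_curve(fit, [0.0, 4.0], urban_level=0.0, cap=2.0, force=True)
        assert len(ps.curve) == 2


class TestPercentChange:
    def test_no_change_for_equal_endpoints(self):
        fit = degenerate_fit(beta_alan=-0.3, n_draws=20)
        pc = percent_change(fit, 1.5, 1.5, urban_level=0.2)
        assert pc.mean == 0.0 and pc.lo95 == 0.0 and pc.hi95 == 0.0

    def test_poorwill_coefficient_closed_form(self):
        """The interaction-free ALAN coefficient -0.32 over a 0 -> 1.23
        radiance rise gives a ~32% decline by the log-link formula."""
        fit = degenerate_fit(beta_alan=-0.32)
        pc = percent_change(fit, 0.0, 1.23, urban_level=0.0)
        assert pc.mean == pytest.approx(100 * (np.exp(-0.32 * 1.23) - 1), abs=1e-9)
        assert pc.mean == pytest.approx(-32.5, abs=0.1)

    def test_two_draw_hand_computation(self):
        fit = degenerate_fit(beta_alan=-0.2, n_draws=2)
        fit.samples.draws[1, fit.samples.names.index("alan")] = -0.4
        pc = percent_change(fit, 0.0, 1.0, urban_level=0.0)
        expect = 100 * ((np.exp(-0.2) + np.exp(-0.4)) / 2 - 1)
        assert pc.mean == pytest.approx(expect, abs=1e-9)

    def test_invariant_to_standardization_constants(self):
        fit = degenerate_fit(beta_alan=-0.32)
        # rescale the design: natural-unit result must not move
        fit2 = degenerate_fit(beta_alan=-0.32 * 2.0)
        fit2.design.scaling["alan_1600"] = (1.0, 2.0)
        a = percent_change(fit, 0.0, 1.23, urban_level=0.0).mean
        b = percent_change(fit2, 0.0, 1.23, urban_level=0.0).mean
        assert a == pytest.approx(b, abs=1e-9)


class TestSignSwitch:
    def test_ratio_closed_form(self):
        fit = degenerate_fit(beta_alan=0.2, beta_int=-1.0)
        ss = sign_switch(fit)
        assert ss.mean == pytest.approx(0.2)
        assert ss.lo95 == ss.hi95 == pytest.approx(0.2)

    def test_zero_alan_coefficient_gives_zero_threshold(self):
        fit = degenerate_fit(beta_alan=0.0, beta_int=-0.7)
        assert sign_switch(fit).mean == 0.0

    def test_interaction_free_fit_is_typed_error(self):
        fit = degenerate_fit(beta_alan=-0.3)
        with pytest.raises(MissingTermError):
            sign_switch(fit)

    def test_recovers_simulated_switch_point(self):
        """Truth switches sign at urban = 0.18; the posterior CI should cover
        it in most replicates."""
        hits = 0
        for seed in range(10):
            d = make_multiscale_design(800, covs=("alan", "urban"),
                                       cross_corr=0.3, seed=seed)
            truth = TrueParameters(intercept=np.log(1.6),
                                   coefficients={"alan": (0.18, 1600),
                                                 "urban": (0.2, 1600)},
                                   interaction=(-1.0, 1600, 1600), dispersion=2.0)
            tab = simulate_counts(d, truth, seed=200 + seed)
            d.df["count"] = tab["true_count"].to_numpy()
            cfg = ChainConfig(chains=2, iterations=1000, burn_in=300, seed=seed)
            fit = fit_final(d, {"alan": 1600, "urban": 1600}, cfg,
                            interaction=("alan", "urban"),
                            interaction_scales=(1600, 1600))
            ss = sign_switch(fit)
            hits += ss.lo95 <= 0.18 <= ss.hi95
        assert hits >= 8


class TestPosteriorCorrelation:
    def test_self_correlation_is_one(self):
        fit = degenerate_fit(beta_alan=0.1, beta_int=-0.5, n_draws=100)
        rng = np.random.default_rng(0)
        fit.samples.draws[:, 1] = rng.normal(size=100)
        assert posterior_coef_correlation(fit, [("alan", "alan")])[("alan", "alan")] \
            == pytest.approx(1.0)

    def test_mirror_draws_give_minus_one(self):
        fit = degenerate_fit(beta_alan=0.0, beta_int=0.0, n_draws=100)
        x = np.random.default_rng(1).normal(size=100)
        fit.samples.draws[:, fit.samples.names.index("alan")] = x
        fit.samples.draws[:, fit.samples.names.index("alan:urban")] = -x
        r = posterior_coef_correlation(fit, [("alan", "alan:urban")])
        assert r[("alan", "alan:urban")] == pytest.approx(-1.0)

    def test_independent_streams_near_zero(self):
        fit = degenerate_fit(beta_alan=0.0, beta_int=0.0, n_draws=27_000)
        rng = np.random.default_rng(2)
        fit.samples.draws[:, 1] = rng.normal(size=27_000)
        fit.samples.draws[:, 2] = rng.normal(size=27_000)
        r = posterior_coef_correlation(fit, [("alan", "alan:urban")])
        assert abs(r[("alan", "alan:urban")]) < 0.05

    def test_high_correlation_logs_advisory(self, caplog):
        fit = degenerate_fit(beta_alan=0.0, beta_int=0.0, n_draws=200)
        x = np.random.default_rng(3).normal(size=200)
        fit.samples.draws[:, 1] = x
        fit.samples.draws[:, 2] = x + 0.01 * np.random.default_rng(4).normal(size=200)
        with caplog.at_level("WARNING", logger="skyglow"):
            posterior_coef_correlation(fit, [("alan", "alan:urban")])
        assert "multicollinearity" in caplog.text

    def test_unknown_parameter_rejected(self):
        fit = degenerate_fit(beta_alan=0.0)
        with pytest.raises(KeyError):
            posterior_coef_correlation(fit, [("alan", "nope")])


class TestPostHocRefits:
    def test_removing_no_stations_changes_nothing(self):
        cfg = ChainConfig(chains=2, iterations=400, burn_in=100, seed=7)
        fit, _ = _fitted(seed=8, n=200, cfg=cfg)
        res = drop_stations_refit(fit, ["no-such-station"], cfg)
        np.testing.assert_allclose(res.deltas["delta"], 0.0, atol=1e-12)

    def test_survey_accounting_after_drop(self):
        cfg = ChainConfig(chains=1, iterations=200, burn_in=50, seed=0)
        fit, _ = _fitted(seed=9, n=300, cfg=cfg)
        # give four stations 14 surveys each
        ids = fit.design.df["station_id"].to_numpy().copy()
        for i, st in enumerate(("V0", "V1", "V2", "V3")):
            ids[i * 14:(i + 1) * 14] = st
        fit.design.df["station_id"] = ids
        res = drop_stations_refit(fit, ["V0", "V1", "V2", "V3"], cfg)
        assert len(res.fit.design.df) == 300 - 56

    def test_removing_informative_stations_widens_ci(self):
        """Stations carrying all the covariate contrast are removed: the
        coefficient's posterior sd must grow."""
        rng = np.random.default_rng(10)
        n = 300
        d = make_multiscale_design(n, covs=("alan",), seed=10)
        x = np.zeros(n)
        x[:60] = rng.normal(3.0, 1.0, size=60)      # contrast lives here
        d.df["alan_1600"] = (x - x.mean()) / x.std()
        d.df.loc[:59, "station_id"] = "HOT"
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + np.exp(0.3 + 0.4 * d.df["alan_1600"])))
        d.df["count"] = y
        cfg = ChainConfig(chains=2, iterations=600, burn_in=200, seed=1)
        fit = fit_final(d, {"alan": 1600}, cfg, interaction=None)
        res = drop_stations_refit(fit, ["HOT"], cfg)
        assert res.deltas.loc["alan", "sd_after"] > res.deltas.loc["alan", "sd_before"]

    def test_emptying_refit_rejected(self):
        cfg = ChainConfig(chains=1, iterations=100, burn_in=20, seed=0)
        fit, _ = _fitted(seed=11, n=100, cfg=cfg)
        all_stations = fit.design.df["station_id"].unique().tolist()
        with pytest.raises(ValueError):
            drop_stations_refit(fit, all_stations, cfg)


class TestDualScaleMarginal:
    def test_identical_columns_split_the_single_scale_coefficient(self):
        """With the two scale columns exactly equal, only the coefficient sum
        is identified and must match the single-column fit."""
        rng = np.random.default_rng(12)
        n = 400
        d = make_multiscale_design(n, covs=("alan",), seed=12)
        d.df["alan_6400"] = d.df["alan_1600"]
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + np.exp(0.4 - 0.5 * d.df["alan_1600"])))
        d.df["count"] = y
        cfg = ChainConfig(chains=2, iterations=1500, burn_in=500, seed=2)
        single = fit_final(d, {"alan": 1600}, cfg, interaction=None)
        dual = dual_scale_marginal(d, "alan", (1600, 6400), cfg, interaction=None)
        s = single.samples.get("alan").mean()
        pair = dual.samples.get("alan@1600").mean() + dual.samples.get("alan@6400").mean()
        assert pair == pytest.approx(s, abs=0.1)

    def test_filter_predicate_contract(self):
        d = make_multiscale_design(200, covs=("alan",), seed=13)
        d.df["count"] = 1
        cfg = ChainConfig(chains=1, iterations=100, burn_in=20, seed=0)
        fit = dual_scale_marginal(d, "alan", (400, 6400), cfg, interaction=None,
                                  filter_predicate=lambda df: df["alan_1600"] < 0)
        assert (fit.design.df["alan_1600"] < 0).all()

    def test_empty_filter_rejected(self):
        d = make_multiscale_design(50, covs=("alan",), seed=14)
        d.df["count"] = 1
        with pytest.raises(ValueError, match="every survey"):
            dual_scale_marginal(d, "alan", (400, 6400),
                                ChainConfig(chains=1, iterations=20, burn_in=5),
                                interaction=None,
                                filter_predicate=lambda df: df["alan_1600"] > 99)

    def test_negative_truth_at_both_scales_recovered(self):
        wins = 0
        for seed in range(10):
            d = make_multiscale_design(400, covs=("alan",), inter_scale_corr=0.4,
                                       seed=seed + 30)
            truth = TrueParameters(intercept=np.log(1.6),
                                   coefficients={"alan": [(-0.4, 1600), (-0.3, 6400)]},
                                   dispersion=2.0)
            tab = simulate_counts(d, truth, seed=seed + 60)
            d.df["count"] = tab["true_count"].to_numpy()
            cfg = ChainConfig(chains=2, iterations=600, burn_in=200, seed=seed)
            fit = dual_scale_marginal(d, "alan", (1600, 6400), cfg, interaction=None)
            wins += (fit.samples.get("alan@1600").mean() < 0
                     and fit.samples.get("alan@6400").mean() < 0)
        assert wins >= 8
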