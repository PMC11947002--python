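"""Conditional quasi-Poisson fitter: oracle equivalence and contracts."""

import numpy as np
import pandas as pd
import pytest

from casets import (
    CaseTimeSeriesDLNM,
    CrossBasisSpec,
    DLNMResults,
    InestimableColumnError,
    PercentileAnchors,
    SimulationConfig,
    SplineSpec,
    build_design,
    fit_conditional_quasipoisson,
    prepare_panel,
    qaic,
    simulate_panel,
)

from conftest import single_region_config


def dummy_glm_oracle(design):
    """Independent reference: statsmodels Poisson GLM with one explicit
    dummy column per stratum."""
    import statsmodels.api as sm

    mask = design.complete
    y = design.y[mask]
    X = design.X[mask]
    strata = pd.factorize(design.strata[mask])[0]
    D = pd.get_dummies(strata).to_numpy(float)
    fit = sm.GLM(y, np.hstack([X, D]), family=sm.families.Poisson()).fit()
    p = X.shape[1]
    return fit.params[:p], fit.cov_params()[:p, :p]


@pytest.fixture(scope="module")
def fitted(small_panel_module):
    model = CaseTimeSeriesDLNM.from_panel(small_panel_module)
    return model, model.fit()


@pytest.fixture(scope="module")
def small_panel_module():
    cfg = SimulationConfig(
        n_zones=10, date_start="2016-01-01", date_end="2017-12-31", seed=42
    )
    return simulate_panel(cfg)


class TestDesign:
    def test_block_shapes(self, small_panel_module):
        model = CaseTimeSeriesDLNM.from_panel(small_panel_module)
        d = model.design
        sl = d.blocks
        assert sl["cb"].stop - sl["cb"].start == model.cbspec.vx * model.cbspec.vl
        assert sl["rh"].stop - sl["rh"].start == 2
        # df=3 per year x 2 years
        assert sl["doy_year"].stop - sl["doy_year"].start == 6
        assert sl["dow"].stop - sl["dow"].start == 6

    def test_dow_reference_rows_all_zero(self, small_panel_module):
        model = CaseTimeSeriesDLNM.from_panel(small_panel_module)
        d = model.design
        dow_block = d.X[:, d.blocks["dow"]]
        sundays = model.panel["dow"].to_numpy() == 6
        assert np.all(dow_block[sundays] == 0)
        assert np.all(dow_block[~sundays].sum(axis=1) == 1)

    def test_single_year_panel_rejected(self):
        cfg = SimulationConfig(
            n_zones=3, date_start="2016-01-01", date_end="2017-12-31", seed=0
        )
        panel = simulate_panel(cfg)
        one_year = panel[pd.to_datetime(panel["date"]).dt.year == 2016]
        with pytest.raises(ValueError, match="2 distinct years"):
            CaseTimeSeriesDLNM.from_panel(one_year).design  # noqa: B018

    def test_incomplete_lag_rows_masked(self, small_panel_module):
        model = CaseTimeSeriesDLNM.from_panel(small_panel_module)
        d = model.design
        assert (~d.complete).sum() == 7 * small_panel_module["zone_id"].nunique()


class TestFitOracle:
    def test_matches_explicit_dummy_glm(self, fitted):
        """Central contract: stratum-absorbed conditional fit equals the
        explicit stratum-dummy Poisson MLE, coefficients and unscaled
        covariance alike."""
        model, res = fitted
        beta_o, cov_o = dummy_glm_oracle(model.design)
        assert np.abs(res.params - beta_o).max() < 1e-6
        rel = np.abs(res.vcov_unscaled - cov_o).max() / np.abs(cov_o).max()
        assert rel < 1e-6

    def test_dispersion_near_one_for_poisson_data(self):
        cfg = single_region_config(seed=21, n_zones=10, years=2, overdispersion=1.0)
        res = CaseTimeSeriesDLNM.from_panel(simulate_panel(cfg)).fit()
        assert 0.9 <= res.dispersion <= 1.1

    def test_zone_level_covariate_is_inestimable(self, small_panel_module):
        model = CaseTimeSeriesDLNM.from_panel(small_panel_module)
        d = model.design
        # a zone-level value is constant within every zone-month stratum
        zone_val = pd.factorize(small_panel_module["zone_id"])[0].astype(float)
        d.X = np.column_stack([d.X, zone_val])
        d.colnames = d.colnames + ["zone_ice"]
        d.blocks = {**d.blocks, "extra": slice(d.X.shape[1] - 1, d.X.shape[1])}
        with pytest.raises(InestimableColumnError, match="zone_ice"):
            fit_conditional_quasipoisson(d)

    def test_all_zero_stratum_dropped_without_changing_beta(self):
        cfg = single_region_config(
            seed=22, n_zones=6, years=2, baseline_rate=4.0
        )
        panel = simulate_panel(cfg)
        res_a = CaseTimeSeriesDLNM.from_panel(panel).fit()
        # zero out one zone-month entirely: that stratum leaves the
        # conditional likelihood, the rest must be untouched
        panel2 = panel.copy()
        sel = (panel2["zone_id"] == "Z0000") & (
            pd.to_datetime(panel2["date"]).dt.strftime("%Y-%m") == "2016-03"
        )
        panel2.loc[sel, "count"] = 0
        model_b = CaseTimeSeriesDLNM.from_panel(panel2, cbspec=None)
        res_b = model_b.fit(tol=1e-12)
        assert res_b.n_strata_dropped == 1
        # direct comparison: mask that stratum's rows out of the design
        model_c = CaseTimeSeriesDLNM.from_panel(panel2, cbspec=model_b.cbspec)
        d = model_c.design
        sel_rows = (model_c.panel["zone_id"] == "Z0000") & (
            model_c.panel["date"].dt.strftime("%Y-%m") == "2016-03"
        )
        d.complete = d.complete & ~sel_rows.to_numpy()
        res_c = fit_conditional_quasipoisson(d, tol=1e-12)
        assert np.abs(res_b.params - res_c.params).max() < 1e-8

    def test_quasi_scaling_of_vcov(self, fitted):
        _, res = fitted
        assert np.allclose(res.vcov, res.vcov_unscaled * res.dispersion)
        # Wald z changes exactly by sqrt(phi)
        z_quasi = res.params / res.bse
        z_plain = res.params / np.sqrt(np.diag(res.vcov_unscaled))
        assert np.allclose(z_plain, z_quasi * np.sqrt(res.dispersion))

    def test_temperature_shift_invariance(self):
        """Adding a constant to all temperatures while shifting the basis
        knots identically leaves the cumulative RR curve unchanged."""
        cfg = single_region_config(seed=23, n_zones=6, years=2)
        panel = prepare_panel(simulate_panel(cfg))  # freezes rh_pct
        t = panel["tavg_c"].to_numpy()
        spec = CaseTimeSeriesDLNM.default_crossbasis(t)
        res1 = CaseTimeSeriesDLNM.from_panel(panel, cbspec=spec).fit(tol=1e-13)

        shift = 7.0
        panel2 = panel.assign(tavg_c=t + shift)
        e = spec.exposure
        spec2 = CrossBasisSpec(
            exposure=SplineSpec(
                knots=tuple(k + shift for k in e.knots),
                boundary=(e.boundary[0] + shift, e.boundary[1] + shift),
            ),
            max_lag=spec.max_lag,
        )
        res2 = CaseTimeSeriesDLNM.from_panel(panel2, cbspec=spec2).fit(tol=1e-13)
        a1 = PercentileAnchors.from_series(t)
        a2 = PercentileAnchors.from_series(t + shift)
        c1 = res1.cumulative_curve(anchors=a1)
        c2 = res2.cumulative_curve(anchors=a2)
        assert np.abs(c1.log_rr - c2.log_rr).max() < 1e-8
        assert np.abs(c1.se - c2.se).max() < 1e-6


class TestQAIC:
    def test_reduces_to_aic_plus_dispersion_penalty(self, fitted):
        _, res = fitted
        assert qaic(res, 1.0) == pytest.approx(
            -2 * res.loglik + 2 * (len(res.params) + 1)
        )

    def test_penalty_monotone_in_parameters(self, fitted):
        _, res = fitted
        import copy

        smaller = copy.copy(res)
        smaller.params = res.params[:-2]
        assert qaic(smaller, res.dispersion) < qaic(res, res.dispersion)

    def test_selects_true_lag_flexibility(self):
        """With a two-knot true lag structure, QAIC should prefer the
        matching lag spline over clear under/over-fits in most replicates."""
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            surf_weights = np.array([0.05, 0.30, 0.30, 0.15, 0.08, 0.05, 0.04, 0.03])
            from casets import TrueEffectSurface

            surf = TrueEffectSurface.linear(
                slope=0.012, reference=16.3, lag_weights=tuple(surf_weights)
            )
            cfg = single_region_config(
                seed=seed, n_zones=25, years=2, surface=surf, baseline_rate=10.0
            )
            panel = simulate_panel(cfg)
            temps = panel["tavg_c"].to_numpy()
            exposure = CaseTimeSeriesDLNM.default_crossbasis(temps).exposure
            candidates = {
                "under": SplineSpec(df=1, intercept=True),  # constant in lag
                "true": SplineSpec(knots=(1.0, 3.0), boundary=(0.0, 7.0),
                                   intercept=True),
                "over": SplineSpec(knots=(1.0, 2.0, 3.0, 4.0, 5.0),
                                   boundary=(0.0, 7.0), intercept=True),
            }
            fits = {}
            for name, lag in candidates.items():
                spec = CrossBasisSpec(exposure=exposure, lag=lag)
                fits[name] = CaseTimeSeriesDLNM.from_panel(panel, cbspec=spec).fit()
            phi_ref = fits["over"].dispersion
            scores = {k: qaic(f, phi_ref) for k, f in fits.items()}
            wins += min(scores, key=scores.get) == "true"
        assert wins >= 0.6 * n_rep

    def test_phi_ref_must_be_positive(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError):
            qaic(res, 0.0)


class TestSerialization:
    def test_results_json_roundtrip(self, fitted):
        _, res = fitted
        back = DLNMResults.from_json(res.to_json())
        assert np.allclose(back.params, res.params)
        assert np.allclose(back.vcov, res.vcov)
        assert back.basis_spec == res.basis_spec
        a = PercentileAnchors(0.0, 15.0, 28.0)
        assert back.rr_at(97.5, anchors=a) == pytest.approx(
            res.rr_at(97.5, anchors=a)
        )

    def test_summary_renders(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "dispersion" in text and "cb_x0_l0" in text


class TestPanelValidation:
    def test_duplicate_zone_day_rejected(self, small_panel_module):
        dup = pd.concat([small_panel_module, small_panel_module.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            prepare_panel(dup)

    def test_date_gap_rejected(self, small_panel_module):
        gappy = small_panel_module.drop(index=5)
        with pytest.raises(ValueError, match="gap"):
            prepare_panel(gappy)

    def test_rh_derived_when_missing(self, small_panel_module):
        p = prepare_panel(small_panel_module)
        assert ((p["rh_pct"] > 0) & (p["rh_pct"] <= 100)).all()
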