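"""Logistic and predator-prey fits: recovery, diagnostics, robustness."""

import numpy as np
import pandas as pd
import pytest

from carrgo.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedR2Error,
)
from carrgo.estimators import CarrgoRegressor, LogisticGrowthRegressor
from carrgo.fitting import (
    FitResult,
    carrgo_problem,
    downsampling_robustness,
    fit_carrgo,
    fit_logistic,
    goodness_of_fit,
    multistart_fit,
    parameter_trend_summary,
)
from carrgo.model import CarrgoParams
from carrgo.rtca import select_fit_window
from conftest import line_ci_max, line_growth


def _well(wells, wid):
    return next(w for w in wells if w.meta.well_id == wid)


def _treated_window(wells, ws):
    return select_fit_window(
        ws, ci_max=max(line_ci_max(wells)[ws.meta.cell_line], float(ws.ci.max()))
    )


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        assert goodness_of_fit([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_zero_covariance(self):
        assert goodness_of_fit([1.0, 3.0, 1.0], [1.0, 2.0, 3.0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_hand_rolled_formula(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 1.9, 3.2])
        cov = np.mean((obs - obs.mean()) * (pred - pred.mean()))
        expected = cov**2 / (obs.var() * pred.var())
        assert goodness_of_fit(pred, obs) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedR2Error):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            goodness_of_fit([1.0, 2.0], [1.0, 2.0])


class TestLogisticFit:
    def test_zero_noise_recovery_within_1pct(self, zero_noise_plate):
        _, wells, truth = zero_noise_plate
        ws = _well(wells, "PBT138H_untr_r1")
        fr = fit_logistic(ws, select_fit_window(ws))
        assert fr.params.rho == pytest.approx(0.72, rel=0.01)
        assert fr.params.K == pytest.approx(10.0, rel=0.01)
        assert fr.r2 > 0.999
        assert fr.converged

    def test_constant_series_degenerate(self):
        t = np.linspace(25, 50, 20)
        est = LogisticGrowthRegressor()
        with pytest.raises(DegenerateDataError):
            est.fit(t / 24, np.full(20, 2.0))

    def test_treated_well_rejected(self, zero_noise_plate):
        _, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT138H_BBz_1-5_r1")
        with pytest.raises(InvalidInputError):
            fit_logistic(ws, _treated_window(wells, ws))

    def test_sklearn_contract(self):
        est = LogisticGrowthRegressor(rho_init=0.5)
        assert est.get_params()["rho_init"] == 0.5
        est.set_params(rho_init=1.0)
        t = np.linspace(0, 3, 30)
        from carrgo.model import logistic_solution

        est.fit(t, logistic_solution(0.9, 8.0, 1.0, t))
        assert est.rho_ == pytest.approx(0.9, rel=1e-4)
        assert np.allclose(est.predict(t), logistic_solution(0.9, 8.0, 1.0, t),
                           rtol=1e-4)


class TestCarrgoFit:
    def test_zero_noise_recovery_within_5pct(self, zero_noise_plate):
        cfg, wells, truth = zero_noise_plate
        ws = _well(wells, "PBT138H_BBz_1-10_r1")
        g = line_growth(wells)["PBT138H"]
        fr = fit_carrgo(ws, _treated_window(wells, ws), *g,
                        calibration_slope=cfg.calibration_slope)
        row = truth[truth.well_id == ws.meta.well_id].iloc[0]
        assert fr.params.kappa1 == pytest.approx(row.kappa1, rel=0.05)
        assert fr.params.kappa2 == pytest.approx(row.kappa2, rel=0.05)
        assert fr.params.theta == pytest.approx(row.theta, rel=0.05)
        assert fr.r2 > 0.999

    def test_exhaustion_sign_recovered(self, zero_noise_plate):
        """A kappa2 < 0 (treatment-failure) well fits to negative kappa2."""
        cfg, wells, truth = zero_noise_plate
        ws = _well(wells, "HT1080H_BBz_1-10_r1")
        g = line_growth(wells)["HT1080H"]
        fr = fit_carrgo(ws, _treated_window(wells, ws), *g,
                        calibration_slope=cfg.calibration_slope)
        assert fr.params.kappa2 < 0

    def test_rmse_matches_independent_computation(self, zero_noise_plate):
        cfg, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT030_BBz_1-20_r1")
        win = _treated_window(wells, ws)
        g = line_growth(wells)["PBT030"]
        fr = fit_carrgo(ws, win, *g, calibration_slope=cfg.calibration_slope)
        est = CarrgoRegressor(
            rho=g[0], K=g[1],
            y0_dose=cfg.calibration_slope * ws.meta.seeding_count * ws.meta.et_ratio,
            t_dose=ws.meta.treat_time_h / 24.0,
        )
        est.kappa1_, est.kappa2_, est.theta_ = (
            fr.params.kappa1, fr.params.kappa2, fr.params.theta,
        )
        from carrgo.fitting import bridge_mean_ci

        t = ws.t[win.start : win.end] / 24.0
        y = ws.ci[win.start : win.end]
        est.x_bridge = bridge_mean_ci(ws, float(ws.t[win.start]))
        est.t_ = t
        est.x0_ = y[0]
        resid = est.predict(t) - y
        assert fr.rmse == pytest.approx(float(np.sqrt(np.mean(resid**2))), abs=1e-12)

    def test_untreated_well_rejected(self, zero_noise_plate):
        _, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT030_untr_r1")
        with pytest.raises(InvalidInputError):
            fit_carrgo(ws, select_fit_window(ws), 1.0, 10.0, Y0=0.1)


def _toy_problem(ridge):
    """Least-squares toy: y = a*t (convex) or y = a*b*t (ridge)."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, 20)
    y = 2.0 * t if not ridge else 2.0 * t  # truth a=2 (or a*b=2)

    def run(start):
        from scipy.optimize import least_squares

        if ridge:
            res = least_squares(
                lambda p: p[0] * p[1] * t - y,
                x0=[start["kappa1"], start["kappa2"]],
                bounds=([1e-6, 1e-6], [1e3, 1e3]),
            )
            a, b = res.x
        else:
            res = least_squares(
                lambda p: p[0] * t - y, x0=[start["kappa1"]], bounds=(1e-6, 1e3)
            )
            a, b = res.x[0], 1.0
        params = CarrgoParams(rho=1.0, K=1.0, kappa1=a, kappa2=b, theta=0.0)
        return FitResult(
            params=params, fitted=("kappa1", "kappa2"), rmse=float(np.sqrt(
                2 * res.cost / len(t))), r2=1.0, n_points=len(t), converged=True,
        )

    ranges = {"kappa1": (1e-2, 1e2), "kappa2": (1e-2, 1e2)}
    return run, ranges


class TestMultistart:
    def test_convex_toy_unique(self):
        rep = multistart_fit(_toy_problem(ridge=False), n_starts=20, seed=1)
        assert rep.n_converged == 20
        assert rep.dispersion["kappa1"] < 1e-6
        assert rep.unique == "unique"

    def test_product_ridge_detected_as_non_unique(self):
        """Two parameters entering only as a product sit on a ridge."""
        rep = multistart_fit(_toy_problem(ridge=True), n_starts=20, seed=1)
        assert rep.dispersion["kappa1"] > 0.5
        assert rep.unique == "non-unique"

    def test_well_conditioned_well_is_unique(self, zero_noise_plate):
        cfg, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT138H_BBz_1-20_r1")
        win = _treated_window(wells, ws)
        g = line_growth(wells)["PBT138H"]
        problem = carrgo_problem(ws, win, *g,
                                 calibration_slope=cfg.calibration_slope)
        rep = multistart_fit(problem, n_starts=12, seed=5)
        assert rep.unique == "unique"
        assert rep.n_converged > 0
        single = problem[0]({})  # default single start
        for name in ("kappa1", "kappa2"):
            assert getattr(rep.best.params, name) == pytest.approx(
                getattr(single.params, name), rel=1e-3
            )


class TestDownsamplingRobustness:
    def test_noiseless_deviations_negligible(self, zero_noise_plate):
        cfg, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT030_BBz_1-10_r1")
        g = line_growth(wells)["PBT030"]
        tab = downsampling_robustness(
            ws, *g, calibration_slope=cfg.calibration_slope,
            ci_max=line_ci_max(wells)["PBT030"],
        )
        assert max(tab.attrs["max_rel_dev"].values()) < 1e-3

    def test_native_interval_deviation_zero(self, zero_noise_plate):
        cfg, wells, _ = zero_noise_plate
        ws = _well(wells, "PBT030_BBz_1-10_r1")
        g = line_growth(wells)["PBT030"]
        tab = downsampling_robustness(
            ws, *g, intervals=(0.25,), calibration_slope=cfg.calibration_slope,
            ci_max=line_ci_max(wells)["PBT030"],
        )
        assert max(tab.attrs["max_rel_dev"].values()) < 1e-6

    def test_noisy_deviations_within_bootstrap_sd(self, noisy_plate):
        """Coarse-grid refit deviations are sampling noise, not systematic
        error: each parameter's 10-h deviation lies within 3 bootstrap sd
        of the coarse-grid estimator (replicate noise realisations)."""
        from carrgo.rtca import downsample
        from carrgo.synthetic import default_plate_config, generate_plate

        cfg, wells, _ = noisy_plate
        wid = "PBT138H_BBz_1-20_r1"
        ws = _well(wells, wid)
        g = line_growth(wells)
        rho, K = g["PBT138H"]
        ci_max = line_ci_max(wells)["PBT138H"]
        tab = downsampling_robustness(
            ws, rho, K, intervals=(10.0,),
            calibration_slope=cfg.calibration_slope, ci_max=ci_max,
        )
        nat, coarse = tab.iloc[0], tab.iloc[1]
        boot = []
        for seed in range(20, 30):
            bcfg = default_plate_config(seed=seed)
            bwells, _ = generate_plate(bcfg)
            bws = downsample(_well(bwells, wid), 10.0)
            win = select_fit_window(bws, ci_max=ci_max)
            fr = fit_carrgo(bws, win, rho, K,
                            calibration_slope=cfg.calibration_slope,
                            start={"kappa1": nat.kappa1, "kappa2": nat.kappa2,
                                   "theta": nat.theta})
            boot.append([fr.params.kappa1, fr.params.kappa2, fr.params.theta])
        sd = np.std(np.array(boot), axis=0, ddof=1)
        for j, name in enumerate(("kappa1", "kappa2", "theta")):
            dev = abs(coarse[name] - nat[name])
            assert dev <= 3 * sd[j] + 1e-9, (name, dev, sd[j])

    def test_monotone_identifiability(self, zero_noise_plate):
        """Multi-start dispersion does not grow when points are added."""
        cfg, wells, _ = zero_noise_plate
        g = line_growth(wells)
        checked = 0
        for wid in [
            "PBT138H_BBz_1-5_r1", "PBT138H_BBz_1-20_r1", "PBT030_BBz_1-5_r1",
            "PBT030_BBz_1-10_r1", "HT1080H_BBz_1-10_r1",
        ]:
            ws = _well(wells, wid)
            win = _treated_window(wells, ws)
            half = type(win)(win.start, win.start + (win.end - win.start) // 2)
            rho, K = g[ws.meta.cell_line]
            disp = {}
            for tag, w in (("half", half), ("full", win)):
                rep = multistart_fit(
                    carrgo_problem(ws, w, rho, K,
                                   calibration_slope=cfg.calibration_slope),
                    n_starts=6, seed=2,
                )
                disp[tag] = max(rep.dispersion.values()) if rep.dispersion else np.inf
            assert disp["full"] <= disp["half"] + 1e-6
            checked += 1
        assert checked == 5


class TestTrendSummary:
    def _fits_frame(self, zero_noise_plate):
        cfg, wells, truth = zero_noise_plate
        g = line_growth(wells)
        rows = []
        for w in wells:
            if not w.meta.treated or w.meta.replicate_id != 1:
                continue
            if w.meta.cell_line != "PBT138H":
                continue
            fr = fit_carrgo(w, _treated_window(wells, w), *g["PBT138H"],
                            calibration_slope=cfg.calibration_slope)
            row = fr.as_row()
            row["et_ratio"] = w.meta.et_ratio
            rows.append(row)
        return pd.DataFrame(rows)

    def test_dose_trends_recovered(self, zero_noise_plate):
        fits = self._fits_frame(zero_noise_plate)
        summary, corrs = parameter_trend_summary(
            fits, "et_ratio", corr_pairs=(("et_ratio", "kappa1"),
                                          ("et_ratio", "kappa2")),
        )
        # killing rate falls, proliferation/exhaustion rate rises with dose
        assert corrs[("et_ratio", "kappa1")][0] < -0.9
        assert corrs[("et_ratio", "kappa2")][0] > 0.9
        k1_means = summary[("kappa1", "mean")]
        assert k1_means.loc[0.2] < k1_means.loc[0.1] < k1_means.loc[0.05]

    def test_too_few_groups(self):
        df = pd.DataFrame({"g": [1, 2], "kappa1": [1.0, 2.0], "kappa2": [0, 1],
                           "theta": [0, 0], "rho": [1, 1]})
        with pytest.raises(InsufficientDataError):
            parameter_trend_summary(df, "g")

    def test_constant_values_undefined_correlation(self):
        df = pd.DataFrame({"g": [1, 2, 3], "kappa1": [1.0, 1.0, 1.0],
                           "kappa2": [0.1, 0.2, 0.3], "theta": [0, 0, 0],
                           "rho": [1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateDataError):
            parameter_trend_summary(df, "g", corr_pairs=(("rho", "kappa2"),))
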