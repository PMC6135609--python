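"""Exponential fits, replots, global fitting, profiles, bootstrap."""

import numpy as np
import pytest

import parpflow as pf
from parpflow.fitting import default_free_params, global_fit, profile_bound


class TestSingleExponential:
    def test_exact_exponential_recovered_to_4_sig_figs(self):
        t = np.geomspace(1e-3, 0.2, 200)
        trace = pf.Trace(times=t, values=0.1 + 0.15 * np.exp(-50.0 * t))
        fit = pf.fit_single_exponential(trace)
        assert fit.converged
        assert fit.kobs == pytest.approx(50.0, rel=1e-4)
        assert fit.amplitude == pytest.approx(0.15, rel=1e-4)
        assert fit.offset == pytest.approx(0.1, rel=1e-4)

    def test_flat_noisy_trace_reports_no_kinetics(self):
        rng = np.random.default_rng(0)
        t = np.geomspace(1e-3, 1.0, 300)
        trace = pf.Trace(times=t, values=0.05 + rng.normal(0, 0.004, t.size))
        fit = pf.fit_single_exponential(trace)
        assert not fit.converged and fit.kobs == 0.0
        assert "flat" in fit.message

    def test_constant_trace_reports_no_kinetics(self):
        t = np.geomspace(1e-3, 1.0, 50)
        fit = pf.fit_single_exponential(pf.Trace(times=t, values=np.full(50, 0.2)))
        assert not fit.converged and fit.kobs == 0.0

    def test_too_few_points_rejected(self):
        t = np.linspace(0.1, 1.0, 5)
        with pytest.raises(ValueError, match="10 points"):
            pf.fit_single_exponential(pf.Trace(times=t, values=np.sin(t)))

    def test_pseudo_first_order_kobs(self, wt):
        # noiseless binding at large protein excess: kobs = k1*P + k_m1
        inst = pf.association_instrument(seed=0, noise_sd=0.0, n_points=300)
        series = pf.generate_association_series(wt, [83.0], 0.8, inst)
        fit = pf.fit_single_exponential(series.traces[0])
        assert fit.kobs == pytest.approx(wt.k1 * 83.0 + wt.k_m1, rel=0.02)

    def test_ternary_decay_is_single_exponential_at_high_competitor(self, wt):
        inst = pf.dissociation_instrument(seed=0, noise_sd=0.0, n_points=300)
        series = pf.generate_dissociation_series(wt, 37.0, 25.0, [4000.0],
                                                 "ternary", inst)
        fit = pf.fit_single_exponential(series.traces[0])
        assert fit.converged
        assert fit.rmse < 0.01 * abs(fit.amplitude)


class TestReplot:
    def test_collinear_points_recovered_exactly(self):
        pairs = [(c, 3.1 * c + 5.0) for c in (60.0, 100.0, 180.0, 250.0)]
        rep = pf.replot_kobs(pairs)
        assert rep.slope == pytest.approx(3.1)
        assert rep.intercept == pytest.approx(5.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_association_series_slope_recovers_on_rate(self, wt):
        # pseudo-first-order probe concentration: the replot slope is only an
        # unbiased on-rate estimate when protein depletion is negligible
        inst = pf.association_instrument(seed=0, noise_sd=0.0, n_points=250)
        series = pf.generate_association_series(
            wt, [60.0, 110.0, 150.0, 200.0, 250.0], 3.0, inst
        )
        fits = [(tr.varied, pf.fit_single_exponential(tr)) for tr in series]
        rep = pf.replot_kobs(fits)
        assert rep.slope == pytest.approx(3.1, rel=0.03)

    def test_flat_kobs_series_has_slope_indistinguishable_from_zero(self, dwgr):
        inst = pf.dissociation_instrument(seed=9, t_end=1.0, n_points=300)
        series = pf.generate_dissociation_series(
            dwgr, 37.0, 25.0, [500.0, 1000.0, 2000.0, 4000.0],
            "simple_competition", inst,
        )
        fits = [(tr.varied, pf.fit_single_exponential(tr)) for tr in series]
        rep = pf.replot_kobs(fits)
        # kobs stays flat at the scale of the mechanism: the slope moves it by
        # < 10% over the whole competitor range (vs ~20x under the ternary
        # mechanism); the residual few-percent rise is probe-rebinding
        # retardation fading with competitor excess.
        kobs = [f.kobs for _, f in fits]
        assert abs(rep.slope) * (4000.0 - 500.0) < 0.1 * np.median(kobs)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pf.replot_kobs([(1.0, 2.0), (2.0, 3.0)])


class TestGlobalFit:
    def test_noiseless_self_recovery_association(self, wt):
        inst = pf.association_instrument(seed=0, noise_sd=0.0, n_points=100)
        series = pf.generate_association_series(wt, [60.0, 133.0, 250.0], 30.0, inst)
        fit = global_fit(series, "association", n_starts=2, seed=0)
        assert fit.params.k1 == pytest.approx(wt.k1, rel=1e-4)
        assert fit.params.k_m1 == pytest.approx(wt.k_m1, rel=1e-4)

    def test_noiseless_self_recovery_simple_competition(self, dwgr):
        inst = pf.dissociation_instrument(seed=0, noise_sd=0.0, t_end=1.0, n_points=120)
        series = pf.generate_dissociation_series(
            dwgr, 37.0, 25.0, [400.0, 1300.0, 4000.0], "simple_competition", inst
        )
        fit = global_fit(series, "simple_competition", fixed_params=dwgr,
                         n_starts=2, seed=0)
        assert fit.params.k_m1 == pytest.approx(dwgr.k_m1, rel=1e-4)

    def test_noiseless_self_recovery_ternary(self, wt):
        inst = pf.dissociation_instrument(seed=0, noise_sd=0.0, n_points=150)
        series = pf.generate_dissociation_series(
            wt, 37.0, 25.0, [76.0, 398.0, 1000.0, 4000.0], "ternary", inst
        )
        fit = global_fit(series, "ternary", fixed_params=wt, n_starts=3, seed=0)
        for name in ("k2", "k_m2", "k3", "k_m3"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(wt, name), rel=1e-4
            )

    def test_best_optimum_beats_every_logged_start(self, wt):
        inst = pf.dissociation_instrument(seed=1, n_points=120)
        series = pf.generate_dissociation_series(
            wt, 37.0, 25.0, [149.0, 1000.0, 4000.0], "ternary", inst
        )
        fit = global_fit(series, "ternary", fixed_params=wt, n_starts=5, seed=1)
        assert fit.converged
        assert all(fit.chi2 <= e["chi2"] + 1e-10 for e in fit.multistart_log)

    def test_deterministic_under_fixed_seed(self, wt):
        inst = pf.association_instrument(seed=2, n_points=80)
        series = pf.generate_association_series(wt, [60.0, 133.0, 250.0], 30.0, inst)
        a = global_fit(series, "association", n_starts=4, seed=7)
        b = global_fit(series, "association", n_starts=4, seed=7)
        assert a.params == b.params and a.chi2 == b.chi2

    def test_default_free_parameters_per_scheme(self):
        assert default_free_params("association") == ("k1", "k_m1")
        assert default_free_params("simple_competition") == ("k_m1",)
        assert default_free_params("ternary") == ("k2", "k_m2", "k3", "k_m3")

    def test_missing_fixed_binding_constants_rejected(self, wt):
        inst = pf.dissociation_instrument(seed=3, n_points=80)
        series = pf.generate_dissociation_series(
            wt, 37.0, 25.0, [1000.0, 4000.0], "ternary", inst
        )
        with pytest.raises(ValueError, match="k1"):
            global_fit(series, "ternary", seed=0)


@pytest.fixture(scope="module")
def assoc_series(wt):
    inst = pf.association_instrument(seed=13, n_points=120)
    return pf.generate_association_series(
        wt, [60.0, 110.0, 150.0, 200.0, 250.0], 30.0, inst
    )


class TestProfileBound:
    def test_zero_threshold_returns_point_estimate(self, wt, assoc_series):
        fit = global_fit(assoc_series, "association", n_starts=2, seed=0)
        pb = profile_bound(assoc_series, "association", "k_m1",
                           delta_chi2=0.0, fit=fit, seed=0)
        assert pb.value == pytest.approx(fit.params.k_m1)

    def test_uninformative_parameter_is_unbounded(self, wt, assoc_series):
        # the ternary release rate k3 has no influence on an association trace
        pb = profile_bound(
            assoc_series, "association", "k3",
            free_params=("k1", "k_m1", "k3"),
            fixed_params=pf.RateParameters(k2=0.043, k_m2=102.0, k_m3=0.013),
            bound_type="upper", seed=0,
        )
        assert pb.unbounded and pb.value == np.inf

    def test_unknown_parameter_rejected(self, assoc_series):
        with pytest.raises(ValueError, match="free"):
            profile_bound(assoc_series, "association", "k2", seed=0)


class TestBootstrap:
    def test_small_n_boot_rejected(self, wt, fast_assoc_instrument):
        series = pf.generate_association_series(
            wt, [60.0, 133.0, 250.0], 30.0, fast_assoc_instrument
        )
        with pytest.raises(ValueError, match="n_boot"):
            pf.bootstrap_uncertainty(series, "association", n_boot=5, seed=0)

    def test_noiseless_data_give_degenerate_intervals(self, wt):
        inst = pf.association_instrument(seed=0, noise_sd=0.0, n_points=60)
        series = pf.generate_association_series(wt, [60.0, 133.0, 250.0], 30.0, inst)
        fit = global_fit(series, "association", n_starts=1, seed=0)
        boot = pf.bootstrap_uncertainty(series, "association", n_boot=10,
                                        seed=0, fit=fit)
        lo, hi = boot.intervals["k1"]
        assert hi - lo < 1e-4 * wt.k1
        assert lo <= fit.params.k1 <= hi

    def test_deterministic_and_covering(self, wt):
        inst = pf.association_instrument(seed=5, n_points=80)
        series = pf.generate_association_series(wt, [60.0, 133.0, 250.0], 30.0, inst)
        fit = global_fit(series, "association", n_starts=2, seed=5)
        a = pf.bootstrap_uncertainty(series, "association", n_boot=12, seed=3, fit=fit)
        b = pf.bootstrap_uncertainty(series, "association", n_boot=12, seed=3, fit=fit)
        assert a.intervals == b.intervals
        lo, hi = a.intervals["k1"]
        assert lo <= fit.params.k1 <= hi

    def test_interval_coverage_of_truth(self, wt):
        # scaled-down calibration check: 95% intervals from 6 independent
        # noisy series should nearly always cover the generating k1
        covered = 0
        for i in range(6):
            inst = pf.association_instrument(seed=40 + i, n_points=80)
            series = pf.generate_association_series(
                wt, [60.0, 133.0, 250.0], 30.0, inst
            )
            fit = global_fit(series, "association", n_starts=1, seed=i)
            boot = pf.bootstrap_uncertainty(series, "association", n_boot=24,
                                            seed=i, fit=fit)
            lo, hi = boot.intervals["k1"]
            covered += lo <= wt.k1 <= hi
        assert covered >= 4
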