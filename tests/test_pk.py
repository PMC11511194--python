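"""Disposition simulation, PK metrics, fitting, population Monte-Carlo."""

import dataclasses

import numpy as np
import pytest

from pbbmkit.pk import (
    CTProfile,
    DispositionParameters,
    PopulationSpec,
    first_order_input,
    fit_disposition,
    pk_metrics,
    population_simulate,
    simulate_pk,
)

T = np.arange(0.05, 48.0, 0.05)


def _one_compartment(cl=5.0, vc=50.0, q_h=1e6):
    # enormous hepatic flow -> negligible first-pass, ke = cl/vc
    return DispositionParameters(n_compartments=1, vc=vc, cl=cl, q_h=q_h)


class TestSimulatePK:
    def test_bateman_tmax_closed_form(self):
        ka, ke = 1.0, 0.1
        disp = _one_compartment(cl=ke * 50.0, vc=50.0)
        prof = simulate_pk(first_order_input(10.0, ka), disp, T)
        tmax_expected = np.log(ka / ke) / (ka - ke)
        assert prof.metrics["tmax"] == pytest.approx(tmax_expected, abs=0.06)
        # full Bateman curve, not only the peak position
        c_expected = (10.0 * ka / (50.0 * (ka - ke))
                      * (np.exp(-ke * T) - np.exp(-ka * T)) * 1000.0)
        assert np.allclose(prof.concentration, c_expected, rtol=1e-4, atol=1e-4)

    def test_zero_absorption_flat_zero(self):
        prof = simulate_pk(lambda t: 0.0 * np.asarray(t), _one_compartment(), T)
        assert np.all(prof.concentration == 0.0)

    def test_doubling_clearance_halves_auc_inf(self):
        p1 = simulate_pk(first_order_input(10.0, 1.0), _one_compartment(cl=4.0), T)
        p2 = simulate_pk(first_order_input(10.0, 1.0), _one_compartment(cl=8.0), T)
        assert p1.metrics["auc_inf"] / p2.metrics["auc_inf"] == pytest.approx(2.0, rel=5e-3)

    def test_dose_proportionality(self):
        disp = _one_compartment()
        p1 = simulate_pk(first_order_input(10.0, 1.0), disp, T)
        p2 = simulate_pk(first_order_input(30.0, 1.0), disp, T)
        mask = p1.concentration > 1e-6
        assert np.allclose(p2.concentration[mask] / p1.concentration[mask], 3.0,
                           rtol=1e-6)

    def test_hepatic_first_pass_scales_exposure(self):
        base = simulate_pk(first_order_input(10.0, 1.0),
                           _one_compartment(cl=5.0, q_h=1e6), T)
        fp = simulate_pk(first_order_input(10.0, 1.0),
                         DispositionParameters(vc=50.0, cl=5.0, q_h=10.0), T)
        # F_h = 1 - 5/10 = 0.5
        assert fp.metrics["auc_inf"] / base.metrics["auc_inf"] == pytest.approx(0.5, rel=5e-3)

    def test_sampling_beyond_window_rejected(self, riva_absorption, riva):
        with pytest.raises(ValueError, match="covers"):
            simulate_pk(riva_absorption, riva.disp, np.array([1.0, 100.0]))

    def test_invalid_disposition_rejected(self):
        with pytest.raises(ValueError):
            DispositionParameters(n_compartments=2, vc=50.0, cl=5.0)
        with pytest.raises(ValueError):
            DispositionParameters(vc=50.0, cl=100.0, q_h=90.0)  # cl >= q_h


class TestPKMetrics:
    def test_rectangle_profile(self):
        prof = CTProfile(times=np.array([0.0, 1.0, 2.0, 4.0]),
                         concentration=np.array([5.0, 5.0, 5.0, 5.0]), dose=1.0)
        assert pk_metrics(prof)["auc_0_t"] == pytest.approx(20.0)

    def test_monoexponential_auc_inf(self):
        t = np.arange(0.0, 12.0, 0.25)
        ke, c0 = 0.3, 100.0
        prof = CTProfile(times=t, concentration=c0 * np.exp(-ke * t), dose=1.0)
        m = pk_metrics(prof)
        assert m["auc_inf"] == pytest.approx(c0 / ke, rel=5e-3)
        assert m["lambda_z"] == pytest.approx(ke, rel=1e-6)

    def test_tmax_at_argmax(self):
        t = np.arange(0.0, 10.0, 0.5)
        c = np.exp(-((t - 3.0) ** 2))
        m = pk_metrics(CTProfile(times=t, concentration=c, dose=1.0))
        assert m["tmax"] == 3.0
        assert m["cmax"] == pytest.approx(1.0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            CTProfile(times=np.array([0.0, 2.0, 1.0]),
                      concentration=np.zeros(3), dose=1.0)


class TestFitDisposition:
    def test_two_compartment_round_trip(self):
        truth = DispositionParameters(n_compartments=2, vc=30.0, vp=60.0,
                                      q=8.0, cl=12.0, q_h=1e6)
        flux = first_order_input(100.0, 1.2)
        t_obs = np.array([0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 36, 48.0])
        observed = simulate_pk(flux, truth, t_obs)
        base = dataclasses.replace(truth, cl=5.0, vc=50.0, vp=40.0, q=4.0)
        res = fit_disposition(observed, flux, base, free=("cl", "vc", "vp", "q"),
                              n_starts=4, seed=1)
        assert res.params.cl == pytest.approx(12.0, rel=0.02)
        assert res.params.vc == pytest.approx(30.0, rel=0.02)
        assert res.params.vp == pytest.approx(60.0, rel=0.02)
        assert res.params.q == pytest.approx(8.0, rel=0.02)

    def test_scale_confounded_free_set_rejected(self):
        obs = CTProfile(times=np.arange(1.0, 10.0),
                        concentration=np.exp(-0.2 * np.arange(1.0, 10.0)),
                        dose=1.0)
        with pytest.raises(ValueError, match="scale-confounded"):
            fit_disposition(obs, first_order_input(1.0, 1.0),
                            _one_compartment(), free=("vc", "kp_scalar"))

    def test_noisy_clearance_recovery_median(self):
        """Median CL from 10%-noise seeded replicates within 15% of truth."""
        truth = _one_compartment(cl=6.0, vc=40.0)
        flux = first_order_input(50.0, 1.0)
        t_obs = np.array([0.5, 1, 2, 4, 6, 8, 12, 16, 24, 32, 48.0])
        clean = simulate_pk(flux, truth, t_obs).concentration
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = clean * np.exp(np.sqrt(np.log(1 + 0.1**2))
                                   * rng.standard_normal(len(clean)))
            obs = CTProfile(times=t_obs, concentration=noisy, dose=50.0)
            res = fit_disposition(obs, flux, _one_compartment(cl=3.0, vc=60.0),
                                  free=("cl", "vc"), n_starts=2, seed=seed)
            estimates.append(res.params.cl)
        assert np.median(estimates) == pytest.approx(6.0, rel=0.15)


def _analytic_profile(params, t=np.arange(0.5, 24.0, 0.5)):
    ka, ke, v, dose = 1.0, params["cl"] / params["vc"], params["vc"], 10.0
    return (dose * ka / (v * (ka - ke))
            * (np.exp(-ke * t) - np.exp(-ka * t)) * 1000.0)


class TestPopulationSimulate:
    BASE = {"cl": 5.0, "vc": 50.0}

    def test_zero_cv_band_collapses(self):
        pop = PopulationSpec(n_trials=4, n_subjects=3,
                             variability={"cl": 0.0}, seed=1)
        with pytest.warns(UserWarning, match="degenerate"):
            res = population_simulate(_analytic_profile, self.BASE, pop,
                                      np.arange(0.5, 24.0, 0.5))
        assert res.degenerate_band
        assert np.allclose(res.lower, res.upper)

    def test_default_design_runs_100_subjects(self):
        calls = []

        def counting(params):
            calls.append(1)
            return _analytic_profile(params)

        pop = PopulationSpec(seed=3)
        res = population_simulate(counting, self.BASE, pop,
                                  np.arange(0.5, 24.0, 0.5))
        assert len(calls) == 100
        assert res.trial_means.shape[0] == 10

    def test_same_seed_identical_bands(self):
        pop = PopulationSpec(n_trials=5, n_subjects=5,
                             variability={"cl": 30.0}, seed=11)
        t = np.arange(0.5, 24.0, 0.5)
        a = population_simulate(_analytic_profile, self.BASE, pop, t)
        b = population_simulate(_analytic_profile, self.BASE, pop, t)
        assert np.array_equal(a.lower, b.lower)
        assert np.array_equal(a.upper, b.upper)

    def test_band_width_nondecreasing_in_cv(self):
        t = np.arange(0.5, 24.0, 0.5)
        widths = []
        for cv in (10.0, 30.0, 60.0):
            pop = PopulationSpec(n_trials=10, n_subjects=10,
                                 variability={"cl": cv}, seed=5)
            res = population_simulate(_analytic_profile, self.BASE, pop, t)
            widths.append(np.trapezoid(res.upper - res.lower, t))
        assert widths[0] < widths[1] < widths[2]

    def test_unknown_variability_key_rejected(self):
        pop = PopulationSpec(variability={"nope": 10.0}, seed=1)
        with pytest.raises(KeyError):
            population_simulate(_analytic_profile, self.BASE, pop,
                                np.arange(0.5, 5.0, 0.5))
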