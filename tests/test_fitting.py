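import numpy as np
import pytest

import dispkin as dk
from dispkin.fitting import model_config, standard_errors


class TestModelConfig:
    def test_named_configs(self):
        assert set(model_config("5p").floating) == {
            "K1_disp", "K1_post", "VT", "fND", "K1D"}
        assert set(model_config("7p").floating) == {
            "K1_disp", "K1_post", "VT", "fND", "K1D", "koff", "koffD"}
        assert "fNDD" in model_config("6p:fNDD").floating

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            model_config("4p")
        with pytest.raises(ValueError):
            model_config("6p:VT")


class TestJointFit:
    def test_noiseless_self_consistency(self, noiseless_lev_dataset, lev_5p_fit):
        truth = noiseless_lev_dataset.truth["putamen"]
        for name, est in lev_5p_fit.estimates.items():
            assert est == pytest.approx(truth[name], rel=0.01), name

    def test_noiseless_optimum_has_negligible_residual(
        self, noiseless_lev_dataset, lev_5p_fit
    ):
        data = np.concatenate([
            noiseless_lev_dataset.displacement.tacs["putamen"],
            noiseless_lev_dataset.postdose.tacs["putamen"],
        ])
        scale = float(np.sum(data**2))
        assert lev_5p_fit.ss / scale < 1e-9
        assert lev_5p_fit.n == 66

    def test_nesting_ss_decreases_with_freedom(self, noisy_lev_dataset):
        f5 = dk.fit_joint(noisy_lev_dataset, "putamen", config="5p")
        f6 = dk.fit_joint(noisy_lev_dataset, "putamen", config="6p:koffD",
                          x0=dict(f5.estimates))
        f7 = dk.fit_joint(noisy_lev_dataset, "putamen", config="7p",
                          x0=dict(f5.estimates))
        tol = 1e-6 * f5.ss
        assert f6.ss <= f5.ss + tol
        assert f7.ss <= f6.ss + tol

    def test_k1_step_variant_recovers_constant_k1(self, noiseless_lev_dataset):
        """Letting tracer K1 change at the displacement time (off by default)
        returns matching pre/post values when the truth has no step."""
        from dispkin.fitting import model_config
        cfg = model_config("5p", allow_k1_step=True)
        fit = dk.fit_joint(noiseless_lev_dataset, "putamen", config=cfg)
        truth = noiseless_lev_dataset.truth["putamen"]
        assert fit.estimates["K1_disp"] == pytest.approx(truth["K1_disp"],
                                                         rel=0.02)
        assert fit.estimates["K1_disp2"] == pytest.approx(truth["K1_disp"],
                                                          rel=0.05)
        assert fit.estimates["K1D"] == pytest.approx(truth["K1D"], rel=0.05)

    def test_explicit_and_model_based_weights(self, noiseless_lev_dataset,
                                              lev_5p_fit):
        from dispkin.fitting import model_based_weights
        w = model_based_weights(noiseless_lev_dataset, "putamen",
                                lev_5p_fit.estimates)
        assert w.shape == (66,)
        assert np.all(w > 0)
        refit = dk.fit_joint(noiseless_lev_dataset, "putamen", config="5p",
                             x0=dict(lev_5p_fit.estimates), weights=w)
        truth = noiseless_lev_dataset.truth["putamen"]
        for name, est in refit.estimates.items():
            assert est == pytest.approx(truth[name], rel=0.01), name

    def test_unit_convention_is_microliters_in_reports(self, lev_5p_fit):
        p = dk.KineticParameters(K1_disp=0.5, K1_post=0.5, VT=20.0, fND=0.1,
                                 K1D=lev_5p_fit.estimates["K1D"])
        assert p.K1D_uL == pytest.approx(1000.0 * p.K1D)


class TestOneTissueComparator:
    @staticmethod
    def _pure_1tc_scan(K1=0.45, VT=20.0, seed=0):
        """Synthesize a drug-free scan whose tissue follows an exact 1TC."""
        from dispkin.fitting import _solve_1tc
        from dispkin.model import scan_grid

        design = dk.StudyDesign(noise_scale=0.0, dose_mg=1500.0)
        frames = design.frames
        plasma = dk.bolus_infusion_input(amplitude=4000.0)
        wb = dk.SampledCurve(times=plasma.times, values=plasma.values * 1.1,
                             kind="whole-blood", units="Bq/mL")
        grid = scan_grid(0.0, 120.0, frames)
        c = _solve_1tc(K1, K1 / VT, plasma, grid)
        tac = dk.predict_pet(grid, c, wb, frames, vB=0.05)
        return dk.ScanData(role="displacement", injection_time=0.0,
                           frames=frames, tacs={"putamen": tac},
                           plasma=plasma, whole_blood=wb, fP=0.30)

    def test_exact_recovery_on_1tc_data(self):
        scan = self._pure_1tc_scan(K1=0.45, VT=20.0)
        fit = dk.fit_1tc(scan, "putamen", t_minutes=60.0)
        assert fit.estimates["K1"] == pytest.approx(0.45, rel=1e-4)
        assert fit.estimates["VT"] == pytest.approx(20.0, rel=1e-3)

    def test_against_extended_model_without_drug(self):
        """Drug-free extended-model data: the 1TC comparator recovers VT to a
        few percent and K1 within 10%."""
        design = dk.StudyDesign(noise_scale=0.0, dose_mg=0.0)
        ds = dk.generate_subject(design)
        truth = ds.truth["putamen"]
        fit = dk.fit_1tc(ds.displacement, "putamen", t_minutes=60.0)
        assert fit.estimates["VT"] == pytest.approx(truth["VT"], rel=0.08)
        assert fit.estimates["K1"] == pytest.approx(truth["K1_disp"], rel=0.10)

    def test_requires_enough_frames(self, noiseless_lev_dataset):
        with pytest.raises(ValueError):
            dk.fit_1tc(noiseless_lev_dataset.displacement, "putamen",
                       t_minutes=2.0)


class TestStandardErrors:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(5)
        x = np.linspace(1, 10, 40)
        sigma = 0.3
        a = 2.0
        y = a * x + rng.normal(0, sigma, x.size)
        a_hat = np.sum(x * y) / np.sum(x**2)
        jac = x[:, None]
        res = y - a_hat * x
        se, rse, ok = standard_errors(jac, res, np.array([a_hat]))
        s2 = np.sum(res**2) / (x.size - 1)
        assert ok
        assert se[0] == pytest.approx(np.sqrt(s2 / np.sum(x**2)), rel=1e-10)

    def test_duplicating_data_shrinks_se_by_sqrt2(self):
        rng = np.random.default_rng(6)
        x = np.linspace(1, 10, 50)
        y = 2.0 * x + rng.normal(0, 0.5, x.size)
        a_hat = np.sum(x * y) / np.sum(x**2)
        se1, _, _ = standard_errors(x[:, None], y - a_hat * x, np.array([a_hat]))
        x2, y2 = np.tile(x, 2), np.tile(y, 2)
        se2, _, _ = standard_errors(x2[:, None], y2 - a_hat * x2, np.array([a_hat]))
        # duplicated data: same s2 (up to dof), doubled information
        assert se2[0] / se1[0] == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_monte_carlo_sd_matches_reported_se(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.5, 8, 30)
        sigma, a = 0.4, 1.7
        ses, a_hats = [], []
        for _ in range(200):
            y = a * x + rng.normal(0, sigma, x.size)
            a_hat = np.sum(x * y) / np.sum(x**2)
            se, _, _ = standard_errors(x[:, None], y - a_hat * x,
                                       np.array([a_hat]))
            a_hats.append(a_hat)
            ses.append(se[0])
        assert np.mean(ses) == pytest.approx(np.std(a_hats, ddof=1), rel=0.2)

    def test_singular_normal_matrix_flagged(self):
        jac = np.zeros((10, 2))
        jac[:, 0] = np.arange(10)
        jac[:, 1] = 2 * np.arange(10)  # collinear
        se, rse, ok = standard_errors(jac, np.ones(10), np.array([1.0, 1.0]))
        assert not ok
        assert np.all(np.isnan(se))

    def test_reported_rse_is_percent_of_estimate(self, lev_5p_fit):
        for k in lev_5p_fit.estimates:
            expected = 100.0 * lev_5p_fit.se[k] / abs(lev_5p_fit.estimates[k])
            assert lev_5p_fit.rse[k] == pytest.approx(expected)
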