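import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dispkin as dk
from dispkin.model import (
    Timeline,
    derive_secondary,
    mechanistic_rhs,
    occupancy_metrics,
    predict_pet,
    reduced_rhs,
    scan_grid,
)


def make_params(K1_disp=0.47, K1_post=0.49, VT=21.6, fND=0.076, K1D=0.0052,
                fP=0.30, drug="LEV"):
    return dk.KineticParameters(
        K1_disp=K1_disp, K1_post=K1_post, VT=VT, fND=fND, K1D=K1D,
        fP_disp=fP, fP_post=fP, constants=dk.FixedConstants.for_drug(drug),
    )


class TestDeriveSecondary:
    def test_k2_equals_k1_when_fnd_equals_fp(self):
        p = make_params(fND=0.30, fP=0.30, VT=21.6)
        d = derive_secondary(p)
        assert d.k2 == pytest.approx(p.K1_disp)

    def test_bmax_direct_arithmetic(self):
        # VT=20, fND=0.1, fP=0.4 -> Bmax = 3.4*(20*0.25 - 1)/0.1 = 136 nmol/L
        p = make_params(VT=20.0, fND=0.1, fP=0.4)
        assert derive_secondary(p).Bmax == pytest.approx(136.0)

    def test_negative_bmax_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="fND"):
            make_params(VT=2.0, fND=0.1, fP=0.4)

    @given(
        st.floats(0.2, 0.6), st.floats(8.0, 25.0), st.floats(0.05, 0.2),
        st.floats(0.2, 0.4), st.floats(0.001, 0.2),
    )
    @settings(deadline=None, max_examples=30)
    def test_reduced_form_equals_mechanistic_form(self, k1, vt, fnd, fp, k1d):
        """The occupancy/VT parameterization and the mass-action form give the
        same derivatives at arbitrary states (exact reparameterization)."""
        p = make_params(K1_disp=k1, VT=vt, fND=fnd, K1D=k1d, fP=fp)
        d = derive_secondary(p)
        cp = lambda t: 1000.0
        dp = lambda t: 800.0
        rng = np.random.default_rng(0)
        for _ in range(5):
            cnd, cs, dnd = rng.uniform(0, 5e4, 3)
            occ = rng.uniform(0, 0.95)
            y_red = np.array([cnd, cs, dnd, occ])
            y_mech = np.array([cnd, cs, dnd, occ * d.Bmax])
            f_red = reduced_rhs(0.0, y_red, p, "displacement", cp, dp)
            f_mech = mechanistic_rhs(0.0, y_mech, p, "displacement", cp, dp)
            np.testing.assert_allclose(f_red[:3], f_mech[:3], rtol=1e-10)
            # dD_S = Bmax * dO
            np.testing.assert_allclose(f_mech[3], d.Bmax * f_red[3], rtol=1e-10)


def constant_curve(value, t_end=600.0, kind="tracer-plasma", units="Bq/mL"):
    return dk.SampledCurve(times=[0.0, t_end], values=[value, value],
                           kind=kind, units=units)


class TestSimulateSystem:
    def test_zero_drug_input_keeps_occupancy_zero(self):
        p = make_params()
        tl = Timeline(injections=(0.0,), scan_ends=(120.0,), infusion_start=60.0)
        traj = dk.simulate_system(p, constant_curve(1000.0),
                                  constant_curve(0.0, kind="drug-plasma",
                                                 units="nmol/L"), tl)
        assert np.all(traj.O == 0.0)
        assert np.all(traj.D_ND == 0.0)

    def test_constant_drug_reaches_closed_form_equilibrium(self, lev_constants):
        # D_P = KDD/fPD gives 50% occupancy at steady state
        p = make_params()
        dp_level = lev_constants.KDD / lev_constants.fPD
        tl = Timeline(injections=(0.0,), scan_ends=(3000.0,), infusion_start=0.0)
        traj = dk.simulate_system(
            p, constant_curve(0.0),
            constant_curve(dp_level, kind="drug-plasma", units="nmol/L"),
            tl, grids=[np.linspace(0, 3000.0, 2000)],
        )
        assert traj.O[-1] == pytest.approx(0.5, abs=1e-4)
        assert dk.equilibrium_occupancy(lev_constants, dp_level) == pytest.approx(0.5)

    def test_tracer_only_ratio_converges_to_vt(self):
        p = make_params()
        tl = Timeline(injections=(0.0,), scan_ends=(2000.0,), infusion_start=0.0)
        traj = dk.simulate_system(p, constant_curve(1000.0), None, tl,
                                  grids=[np.linspace(0, 2000.0, 3000)])
        ratio = traj.tissue[-1] / 1000.0
        assert ratio == pytest.approx(p.VT, rel=0.01)

    def test_occupancy_bounds_and_nonnegative_states(self, noisy_lev_dataset):
        p = make_params(K1D=0.05)
        traj = dk.simulate_system(
            p, [noisy_lev_dataset.displacement.plasma,
                noisy_lev_dataset.postdose.plasma],
            noisy_lev_dataset.drug_plasma, noisy_lev_dataset.timeline(),
        )
        assert np.all((traj.O >= 0) & (traj.O <= 1))
        assert np.all(traj.C_ND >= 0) and np.all(traj.C_S >= 0)
        assert np.all(traj.D_ND >= -1e-9)

    def test_negative_input_rejected(self):
        p = make_params()
        tl = Timeline(injections=(0.0,), scan_ends=(120.0,), infusion_start=60.0)
        bad = dk.SampledCurve.__new__(dk.SampledCurve)
        object.__setattr__(bad, "times", np.array([0.0, 120.0]))
        object.__setattr__(bad, "values", np.array([-1.0, 1.0]))
        object.__setattr__(bad, "kind", "tracer-plasma")
        object.__setattr__(bad, "units", "Bq/mL")
        with pytest.raises(ValueError):
            dk.simulate_system(p, bad, None, tl)


class TestExpmFastPath:
    def test_matches_lsoda_within_tenth_percent(self, noiseless_lev_dataset):
        rng = np.random.default_rng(7)
        ds = noiseless_lev_dataset
        grid1 = scan_grid(0.0, 120.0, dk.FrameSchedule.default())
        grid2 = scan_grid(330.0, 450.0, dk.FrameSchedule.default())
        for i in range(5):
            p = make_params(
                K1_disp=rng.uniform(0.2, 0.6), VT=rng.uniform(10, 25),
                fND=rng.uniform(0.06, 0.12), K1D=rng.uniform(0.002, 0.1),
                drug="BRV" if i % 2 else "LEV",
            )
            dt_, _, occ_ = dk.simulate_drug(p, ds.drug_plasma, 60.0, 450.0)
            for role, inp, grid in (
                ("displacement", ds.displacement.plasma, grid1),
                ("post-dose", ds.postdose.plasma, grid2),
            ):
                y_ref = dk.simulate_tracer(p, role, inp, dt_, occ_, grid,
                                           method="lsoda")
                y_fast = dk.simulate_tracer(p, role, inp, dt_, occ_, grid,
                                            method="expm")
                dev = np.max(np.abs(y_ref - y_fast)) / np.max(np.abs(y_ref))
                assert dev < 1e-3


class TestPredictPet:
    def _traj(self, f):
        t = np.linspace(0.0, 120.0, 2401)
        return t, f(t)

    def test_vb_zero_is_pure_tissue(self):
        t, v = self._traj(lambda t: np.full_like(t, 7.0))
        frames = dk.FrameSchedule.default()
        wb = constant_curve(123.0, kind="whole-blood")
        out = predict_pet(t, v, wb, frames, vB=0.0)
        np.testing.assert_allclose(out, 7.0)

    def test_constant_mixture(self):
        t, v = self._traj(lambda t: np.full_like(t, 100.0))
        frames = dk.FrameSchedule.default()
        wb = constant_curve(50.0, kind="whole-blood")
        out = predict_pet(t, v, wb, frames, vB=0.05)
        np.testing.assert_allclose(out, 0.95 * 100.0 + 0.05 * 50.0)

    def test_linear_trajectory_equals_midpoint_value(self):
        t, v = self._traj(lambda t: 3.0 * t + 5.0)
        frames = dk.FrameSchedule.default()
        wb = constant_curve(0.0, kind="whole-blood")
        out = predict_pet(t, v, wb, frames, vB=0.0)
        np.testing.assert_allclose(out, 3.0 * frames.midpoint + 5.0, rtol=1e-12)

    def test_frames_outside_span_rejected(self):
        t, v = self._traj(lambda t: t)
        frames = dk.FrameSchedule.default().shifted(60.0)
        wb = constant_curve(0.0, kind="whole-blood")
        with pytest.raises(ValueError):
            predict_pet(t, v, wb, frames, vB=0.0, injection=60.0)


class TestOccupancyMetrics:
    @staticmethod
    def _exp_traj(omax=0.8, lam=np.log(2) / 3.0, dose=60.0):
        t = np.linspace(0, 600, 24001)
        o = np.where(t >= dose, omax * (1 - np.exp(-lam * (t - dose))), 0.0)
        z = np.zeros_like(t)
        return dk.StateTrajectory(t=t, C_ND=z, C_S=z, D_ND=z, O=o)

    def test_half_time_closed_form(self):
        m = occupancy_metrics(self._exp_traj(), dose_time=60.0)
        assert m.t_half == pytest.approx(3.0, rel=1e-2)
        assert m.t_half < m.t_max

    def test_all_zero_flagged_undefined(self):
        t = np.linspace(0, 100, 101)
        z = np.zeros_like(t)
        m = occupancy_metrics(
            dk.StateTrajectory(t=t, C_ND=z, C_S=z, D_ND=z, O=z), dose_time=10.0
        )
        assert not m.defined
        assert np.isnan(m.O_max)

    def test_faster_entry_gives_shorter_half_time(self, noiseless_lev_dataset):
        """Same plateau, higher K1D -> earlier half occupancy."""
        ds = noiseless_lev_dataset
        halves = []
        for k1d in (0.005, 0.08):
            p = make_params(K1D=k1d)
            traj = dk.simulate_system(
                p, [ds.displacement.plasma, ds.postdose.plasma],
                ds.drug_plasma, ds.timeline(),
            )
            halves.append(occupancy_metrics(traj, 60.0).t_half)
        assert halves[1] < halves[0]


def test_trajectory_tidy_export(tmp_path, noiseless_lev_dataset):
    p = make_params()
    ds = noiseless_lev_dataset
    traj = dk.simulate_system(
        p, [ds.displacement.plasma, ds.postdose.plasma], ds.drug_plasma,
        ds.timeline(),
    )
    traj.to_csv(tmp_path / "traj.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "traj.csv")
    assert list(df.columns) == ["t", "C_ND", "C_S", "D_ND", "O"]
    assert len(df) == len(traj.t)
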