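import numpy as np
import pytest

import dispkin as dk
from dispkin.synthgen import (
    LAMBDA_C11,
    StudyDesign,
    add_noise,
    generate_drug_pk,
    noise_sd,
)


class TestStudyDesign:
    def test_defaults_match_protocol(self):
        d = StudyDesign()
        assert len(d.frames) == 33
        assert d.frames.span == pytest.approx(120.0)
        assert d.infusion_start == 60.0
        assert d.infusion_duration == 5.0
        assert d.injection2 == pytest.approx(330.0)  # 4.5 h after dosing
        times = d.drug_sample_times()
        # 1-60 min post-infusion plus pre/mid/end of the post-dose scan
        np.testing.assert_allclose(times[1:12] - 60.0,
                                   [1, 3, 5, 6, 8, 10, 15, 20, 30, 45, 60])
        np.testing.assert_allclose(times[-3:], [330.0, 390.0, 450.0])

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(infusion_start=130.0)
        with pytest.raises(ValueError):
            StudyDesign(post_dose_delay=30.0)
        with pytest.raises(ValueError):
            StudyDesign(noise_scale=-1.0)
        with pytest.raises(ValueError):
            StudyDesign(target_occupancy=0.2)  # outside the allowed range


class TestDrugPK:
    def test_zero_dose_gives_zero_curve_and_occupancy(self):
        d = StudyDesign(dose_mg=0.0)
        cont, obs = generate_drug_pk(d)
        assert np.all(cont.values == 0.0)
        ds = dk.generate_subject(d)
        p = dk.default_truth("LEV")["putamen"]
        traj = dk.simulate_system(
            p, [ds.displacement.plasma, ds.postdose.plasma], ds.drug_plasma,
            ds.timeline(),
        )
        assert np.all(traj.O == 0.0)

    def test_linear_in_dose(self):
        lo = generate_drug_pk(StudyDesign(dose_mg=750.0))[0]
        hi = generate_drug_pk(StudyDesign(dose_mg=1500.0))[0]
        np.testing.assert_allclose(hi.values, 2.0 * lo.values, rtol=1e-10)

    def test_calibrated_to_target_equilibrium_occupancy(self):
        for drug, dose in (("LEV", 1500.0), ("BRV", 100.0)):
            d = StudyDesign(drug=drug, dose_mg=dose, target_occupancy=0.8)
            cont, _ = generate_drug_pk(d)
            c = dk.FixedConstants.for_drug(drug)
            occ = dk.equilibrium_occupancy(c, float(cont(d.scan1_end)))
            assert occ == pytest.approx(0.8, rel=0.01)

    def test_biphasic_decline(self):
        cont, _ = generate_drug_pk(StudyDesign())
        peak = np.max(cont.values)
        assert cont(450.0) < cont(120.0) < peak


class TestNoise:
    frames = dk.FrameSchedule.default()

    def test_scale_zero_is_identity(self):
        tac = np.linspace(1e4, 5e4, 33)
        rng = np.random.default_rng(0)
        noisy, clipped = add_noise(tac, self.frames, 0.0, rng)
        np.testing.assert_array_equal(noisy, tac)
        assert clipped == 0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(33), self.frames, -1.0, np.random.default_rng(0))

    def test_decay_term_raises_late_frame_sd(self):
        # equal value and equal duration -> later frame has larger SD
        tac = np.full(33, 2e4)
        sd = noise_sd(tac, self.frames, 1.0)
        late = self.frames.duration == 5.0
        assert np.all(np.diff(sd[late]) > 0)

    def test_inverse_duration_variance_scaling(self):
        tac = np.full(33, 2e4)
        sd = noise_sd(tac, self.frames, 1.0)
        # frames 6 (1 min) and 0 (0.5 min) are early; compare via the model
        expect = np.sqrt(
            tac * np.exp(LAMBDA_C11 * self.frames.midpoint) / self.frames.duration
        )
        np.testing.assert_allclose(sd, expect)

    def test_empirical_sd_matches_model(self):
        tac = np.full(33, 3e4)
        rng = np.random.default_rng(42)
        reps = np.array([add_noise(tac, self.frames, 10.0, rng)[0]
                         for _ in range(500)])
        emp = reps.std(axis=0, ddof=1)
        model = noise_sd(tac, self.frames, 10.0)
        # no clipping at this amplitude, so the SD should match closely
        np.testing.assert_allclose(emp, model, rtol=0.10)


class TestGenerateSubject:
    def test_noiseless_tacs_equal_model_prediction(self, noiseless_lev_dataset):
        """Noise-free TACs are the frame-averaged model prediction: exactly
        equal on the generator's solver path, and within solver fidelity
        (<0.2%) of the adaptive reference path."""
        ds = noiseless_lev_dataset
        p = dk.KineticParameters(**ds.truth["putamen"])
        grid = dk.model.scan_grid(0.0, 120.0, ds.displacement.frames)
        dt_, _, occ_ = dk.simulate_drug(p, ds.drug_plasma, 60.0, 450.0,
                                        method="rk4")
        y = dk.simulate_tracer(p, "displacement", ds.displacement.plasma,
                               dt_, occ_, grid, method="expm")
        pred = dk.predict_pet(grid, y[0] + y[1], ds.displacement.whole_blood,
                              ds.displacement.frames, vB=0.05)
        np.testing.assert_allclose(ds.displacement.tacs["putamen"], pred,
                                   rtol=1e-9)
        traj = dk.simulate_system(
            p, [ds.displacement.plasma, ds.postdose.plasma], ds.drug_plasma,
            ds.timeline(),
            grids=[grid, dk.model.scan_grid(330.0, 450.0, ds.postdose.frames)],
        )
        ref = dk.predict_pet_trajectory(
            traj, ds.displacement.whole_blood, ds.displacement.frames,
            vB=0.05, injection=0.0,
        )
        np.testing.assert_allclose(ds.displacement.tacs["putamen"], ref,
                                   rtol=2e-3)

    def test_same_seed_is_byte_identical(self):
        d = StudyDesign(seed=9)
        a = dk.generate_subject(d)
        b = dk.generate_subject(d)
        for scan_a, scan_b in zip(a.scans, b.scans):
            for region in scan_a.tacs:
                np.testing.assert_array_equal(scan_a.tacs[region],
                                              scan_b.tacs[region])
        np.testing.assert_array_equal(a.drug_plasma.values, b.drug_plasma.values)

    def test_truth_sidecar_records_generation_parameters(self):
        d = StudyDesign(seed=3)
        ds = dk.generate_subject(d)
        assert set(ds.truth) == {"putamen", "frontal", "cerebellum"}
        assert ds.truth["putamen"]["VT"] == pytest.approx(21.6)
        assert ds.truth["putamen"]["K1D"] == pytest.approx(0.0052)

    def test_parameter_recovery_across_noisy_subjects(self):
        """Median recovery error across noisy subjects: tracer parameters are
        tight, the drug entry rate is the least identifiable."""
        errs = {"VT": [], "K1_disp": [], "fND": [], "K1D": []}
        for seed in range(10):
            design = StudyDesign(seed=100 + seed)
            truth = {"putamen": dk.default_truth("LEV")["putamen"]}
            ds = dk.generate_subject(design, truth=truth, subject=f"r{seed}")
            fit = dk.fit_joint(ds, "putamen", config="5p")
            for k in errs:
                errs[k].append(abs(fit.estimates[k] / truth["putamen"].__getattribute__(k) - 1))
        assert np.median(errs["VT"]) < 0.05
        assert np.median(errs["K1_disp"]) < 0.05
        assert np.median(errs["fND"]) < 0.15
        assert np.median(errs["K1D"]) < 0.25


class TestRatioStudy:
    def test_entry_rate_ratio_is_exact_and_displacement_faster(self):
        study = dk.generate_ratio_study(n_subjects=2, ratio=15.0, seed=5,
                                        noise_scale=0.0)
        for lev, brv in zip(study["LEV"], study["BRV"]):
            k_lev = lev.truth["putamen"]["K1D"]
            k_brv = brv.truth["putamen"]["K1D"]
            assert k_brv / k_lev == pytest.approx(15.0, rel=1e-12)
            halves = {}
            for tag, ds in (("LEV", lev), ("BRV", brv)):
                p = dk.KineticParameters(
                    **ds.truth["putamen"],
                    constants=dk.FixedConstants.for_drug(tag),
                )
                traj = dk.simulate_system(
                    p, [ds.displacement.plasma, ds.postdose.plasma],
                    ds.drug_plasma, ds.timeline(),
                )
                halves[tag] = dk.occupancy_metrics(traj, 60.0).t_half
            assert halves["BRV"] < halves["LEV"]
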