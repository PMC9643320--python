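"""End-to-end validation experiments.

Self-contained study-level checks of the pipeline: recovery of published
population-median parameters from noiseless synthetic scan pairs, numerical
agreement of the stiff solver with a fixed-step Runge-Kutta oracle,
closed-form equilibrium checks, type-I-error calibration of the nested-model
F test, conservativeness of the entry-rate ratio bound, and the sign pattern
of the drug-affinity sensitivity scan.
"""

from __future__ import annotations

import numpy as np

from . import synthgen
from .fitting import fit_joint
from .inference import f_test, k1d_bound_search, ratio_bound, sensitivity_fixed_params
from .model import (
    FixedConstants,
    KineticParameters,
    Timeline,
    equilibrium_occupancy,
    simulate_system,
)
from .curves import SampledCurve

__all__ = [
    "recover_printed_medians",
    "solver_oracle_deviation",
    "equilibrium_occupancy_error",
    "tracer_only_vt_error",
    "ftest_type1_rate",
    "ratio_bound_study",
    "kdd_sensitivity_signs",
]


def recover_printed_medians(drug: str, regions=("putamen",),
                            noise_scale: float = 0.0, seed: int = 0) -> dict:
    """Fit noiseless scan pairs generated from the published 5p medians.

    Returns {region: {param: (truth, estimate)}} for the five floating
    parameters; with ``noise_scale=0`` the estimates should recover the
    generating medians to optimizer tolerance.
    """
    design = synthgen.StudyDesign(
        drug=drug, dose_mg=synthgen.REFERENCE_DOSE[drug.upper()],
        noise_scale=noise_scale, seed=seed,
    )
    truth_all = synthgen.default_truth(drug)
    truth = {r: truth_all[r] for r in regions}
    ds = synthgen.generate_subject(design, truth=truth, subject=f"median-{drug}")
    out = {}
    for region in regions:
        fit = fit_joint(ds, region, config="5p")
        out[region] = {
            name: (getattr(truth[region], name), est)
            for name, est in fit.estimates.items()
        }
    return out


# --- fixed-step oracle -------------------------------------------------------


def _rk4_displacement(params: KineticParameters, tracer_plasma, drug_plasma,
                      t_end: float, infusion_start: float, dt: float = 0.001):
    """Fixed-step classical Runge-Kutta integration of the four coupled
    states over one displacement scan; the brute-force numerical oracle."""
    from numba import njit

    c = params.constants
    K1, fP = params.K1_disp, params.fP_disp
    k2 = K1 * params.fND / fP
    cap = params.VT * params.fND / fP - 1.0
    n = int(round(t_end / dt))
    th = np.linspace(0.0, t_end, 2 * n + 1)
    cp = np.interp(th, tracer_plasma.times, tracer_plasma.values)
    dp = np.interp(th, drug_plasma.times, drug_plasma.values)
    dp[th < infusion_start] = 0.0

    @njit(cache=True)
    def run(cp, dp, n, dt, K1, k2, koff, cap, K1D, k2D, koffD, ratio, coefD):
        out = np.zeros((4, n + 1))
        y = np.zeros(4)
        k = np.zeros((4, 4))
        for i in range(n):
            for stage in range(4):
                if stage == 0:
                    w, j = 0.0, 2 * i
                elif stage < 3:
                    w, j = 0.5, 2 * i + 1
                else:
                    w, j = 1.0, 2 * i + 2
                y0 = y[0] + w * dt * k[stage - 1, 0] if stage else y[0]
                y1 = y[1] + w * dt * k[stage - 1, 1] if stage else y[1]
                y2 = y[2] + w * dt * k[stage - 1, 2] if stage else y[2]
                y3 = y[3] + w * dt * k[stage - 1, 3] if stage else y[3]
                bt = koff * (cap * (1.0 - y3) * y0 - y1)
                bd = koffD * (ratio * (1.0 - y3) * y2 - y3)
                k[stage, 0] = K1 * cp[j] - k2 * y0 - bt
                k[stage, 1] = bt
                k[stage, 2] = K1D * dp[j] - k2D * y2 - coefD * bd
                k[stage, 3] = bd
            for m in range(4):
                y[m] += dt / 6.0 * (k[0, m] + 2 * k[1, m] + 2 * k[2, m] + k[3, m])
            out[:, i + 1] = y
        return out

    Y = run(cp, dp, n, dt, K1, k2, c.koff, cap, params.K1D,
            params.K1D * c.fNDD / c.fPD, c.koffD, c.fNDD / c.KDD,
            (c.KD / params.fND) * cap)
    step = int(round(1.0 / dt))
    return np.linspace(0.0, t_end, n + 1)[::step], Y[:, ::step]


def solver_oracle_deviation(n_cases: int = 10, seed: int = 0,
                            dt: float = 0.001) -> float:
    """Worst sup-norm relative deviation between the adaptive stiff solver and
    the fixed-step RK4 oracle over random parameter draws (one displacement
    scan each, all four states)."""
    rng = np.random.default_rng(seed)
    design = synthgen.StudyDesign(noise_scale=0.0, seed=seed)
    ds = synthgen.generate_subject(
        design, truth={"putamen": synthgen.default_truth("LEV")["putamen"]}
    )
    tl = Timeline(injections=(0.0,), scan_ends=(120.0,), infusion_start=60.0)
    worst = 0.0
    for i in range(n_cases):
        params = KineticParameters(
            K1_disp=rng.uniform(0.2, 0.6), K1_post=rng.uniform(0.2, 0.6),
            VT=rng.uniform(10.0, 25.0), fND=rng.uniform(0.06, 0.12),
            K1D=rng.uniform(0.002, 0.1),
            constants=FixedConstants.for_drug("BRV" if i % 2 else "LEV"),
        )
        t_ref, y_ref = _rk4_displacement(
            params, ds.displacement.plasma, ds.drug_plasma, 120.0, 60.0, dt=dt
        )
        traj = simulate_system(params, ds.displacement.plasma, ds.drug_plasma,
                               tl, grids=[t_ref], method="lsoda")
        states = np.vstack([traj.C_ND, traj.C_S, traj.D_ND, traj.O])
        for s in range(4):
            ref_max = np.max(np.abs(y_ref[s]))
            if ref_max > 0:
                worst = max(
                    worst, float(np.max(np.abs(states[s] - y_ref[s])) / ref_max)
                )
    return worst


# --- closed-form equilibria --------------------------------------------------


def equilibrium_occupancy_error(drug: str = "LEV",
                                occupancy: float = 0.5) -> float:
    """|terminal simulated occupancy - closed form| under a constant drug
    plasma level, after many equilibration half-times."""
    c = FixedConstants.for_drug(drug)
    dp_level = c.KDD * occupancy / (c.fPD * (1.0 - occupancy))
    p = synthgen.default_truth(drug)["putamen"]
    t_end = 3000.0
    tl = Timeline(injections=(0.0,), scan_ends=(t_end,), infusion_start=0.0)
    const = SampledCurve(times=[0.0, t_end], values=[dp_level, dp_level],
                         kind="drug-plasma", units="nmol/L")
    zero = SampledCurve(times=[0.0, t_end], values=[0.0, 0.0])
    traj = simulate_system(p, zero, const, tl,
                           grids=[np.linspace(0, t_end, 2000)])
    return float(abs(traj.O[-1] - equilibrium_occupancy(c, dp_level)))


def tracer_only_vt_error(drug: str = "LEV") -> float:
    """Relative error of the late tissue/plasma ratio against VT with a
    constant tracer input and no drug."""
    p = synthgen.default_truth(drug)["putamen"]
    t_end = 2000.0
    tl = Timeline(injections=(0.0,), scan_ends=(t_end,), infusion_start=0.0)
    const = SampledCurve(times=[0.0, t_end], values=[1000.0, 1000.0])
    traj = simulate_system(p, const, None, tl,
                           grids=[np.linspace(0, t_end, 3000)])
    return float(abs(traj.tissue[-1] / 1000.0 / p.VT - 1.0))


# --- F-test calibration ------------------------------------------------------


def ftest_type1_rate(n_reps: int = 1000, seed: int = 0, n: int = 66,
                     alpha: float = 0.05) -> float:
    """Empirical type-I error of the nested-model F test under the null.

    The reduced model (quadratic polynomial, 5 coefficients after padding) is
    true; the full model adds two spurious terms, mirroring the 5p-vs-7p
    comparison's degrees of freedom on n = 66 frames.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n)
    X_red = np.vander(x, 5, increasing=True)   # p_reduced = 5
    X_full = np.vander(x, 7, increasing=True)  # p_full = 7
    beta = np.array([1.0, -2.0, 0.5, 0.3, -0.1])
    rejections = 0
    for _ in range(n_reps):
        y = X_red @ beta + rng.normal(0.0, 0.2, n)
        ss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
        ss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
        r = f_test(ss_red, min(ss_full, ss_red), 5, 7, n)
        rejections += r.p_value < alpha
    return rejections / n_reps


# --- ratio-bound conservativeness -------------------------------------------


def ratio_bound_study(ratio: float, seed: int, n_subjects: int = 4,
                      region: str = "putamen", grid_points: int = 4,
                      alpha: float = 0.05) -> dict:
    """One synthetic two-drug study: unconstrained fits, then the
    constrained-K1D searches, returning the conservative ratio bound.

    Grids are placed geometrically below (BRV) / above (LEV) the pooled median
    unconstrained estimate, and the boundary interval is bisected.
    """
    study = synthgen.generate_ratio_study(
        n_subjects=n_subjects, ratio=ratio, lev_k1d_uL=5.0, seed=seed
    )
    # 5 and 50 uL/cm^3/min starts bracket both drugs; SS differences relevant
    # to the F test are O(1%), so 1e-8 optimizer tolerances are ample here.
    # Weights follow the noise-free part of the count-statistics variance so
    # the pooled F test stays close to its nominal size.
    fit_kw = {"k1d_starts": (0.005, 0.05), "tol": 1e-8, "weighting": "decay"}
    fits = {drug: [fit_joint(ds, region, config="5p", **fit_kw)
                   for ds in study[drug]]
            for drug in ("LEV", "BRV")}

    def anchor(fs):
        # precision-weighted common estimate (falls back to the median)
        est = np.array([f.estimates["K1D"] for f in fs]) * 1000.0
        se = np.array([f.se["K1D"] for f in fs]) * 1000.0
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / se**2
            return float(np.sum(w * est) / np.sum(w))
        return float(np.median(est))

    v0 = {drug: anchor(fs) for drug, fs in fits.items()}
    brv = k1d_bound_search(
        study["BRV"], region, "BRV", "lower",
        grid=np.geomspace(0.25 * v0["BRV"], 2.0 * v0["BRV"], grid_points + 1),
        alpha=alpha, refine=True, refine_tol_uL=max(0.1, 0.04 * v0["BRV"]),
        full_fits=fits["BRV"], **fit_kw,
    )
    lev = k1d_bound_search(
        study["LEV"], region, "LEV", "upper",
        grid=np.geomspace(0.5 * v0["LEV"], 4.0 * v0["LEV"], grid_points + 1),
        alpha=alpha, refine=True, refine_tol_uL=max(0.1, 0.04 * v0["LEV"]),
        full_fits=fits["LEV"], **fit_kw,
    )
    return {
        "true_ratio": ratio,
        "ratio_bound": ratio_bound(brv, lev),
        "brv_lower_uL": brv.bound,
        "lev_upper_uL": lev.bound,
        "brv_unconstrained_uL": brv.k1d_unconstrained.tolist(),
        "lev_unconstrained_uL": lev.k1d_unconstrained.tolist(),
    }


# --- sensitivity sign pattern ------------------------------------------------


def kdd_sensitivity_signs(seed: int = 0) -> dict:
    """Percent change of the fitted entry rate when the drug dissociation
    constant is halved/doubled on a noiseless levetiracetam-like subject."""
    design = synthgen.StudyDesign(noise_scale=0.0, seed=seed)
    truth = {"putamen": synthgen.default_truth("LEV")["putamen"]}
    ds = synthgen.generate_subject(design, truth=truth, subject="sens")
    table = sensitivity_fixed_params(ds, "putamen", params=("KDD",),
                                     factors=(0.5, 2.0))
    k1d = table[table["quantity"] == "K1D"].set_index("factor")["percent_change"]
    return {"kdd_half_pct": float(k1d[0.5]), "kdd_double_pct": float(k1d[2.0])}
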