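"""Weighted nonlinear least-squares estimation of the competition model.

The extended model is fitted jointly to the displacement and post-dose TACs of
one region: the drug states are one continuous trajectory on the study clock,
tracer states restart at zero at each injection, and the weighted residuals of
both scans' frames are stacked into a single least-squares problem
(``scipy.optimize.least_squares``, bound-constrained trust region, forward
finite-difference Jacobian).

Model configurations follow the fixed/floating scheme of the analysis:

* ``5p``  — K1_disp, K1_post, VT, fND, K1D float; everything else fixed
            (koff/koffD at study-average values).
* ``7p``  — 5p plus koff and koffD.
* ``6p:X`` — 5p plus exactly one of fPD, fNDD, KD, KDD, koff, koffD.
* ``1tc`` — the conventional one-tissue comparator on the first 60 min of the
            displacement scan (see :func:`fit_1tc`).

Per-frame weights are proportional to frame duration by default (uniform
variance per unit scan time); ``weighting="uniform"`` is the alternative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import SampledCurve
from .data import ScanData, SubjectDataset
from .model import (
    FixedConstants,
    KineticParameters,
    predict_pet,
    refine_grid,
    scan_grid,
    simulate_drug,
    simulate_tracer,
)

PRIMARY_PARAMS = ("K1_disp", "K1_post", "VT", "fND", "K1D")
EXTRA_PARAMS = ("koff", "koffD", "fPD", "fNDD", "KD", "KDD")

#: (lower, upper, typical scale) per parameter; rates in mL/cm^3/min,
#: K1D in mL/cm^3/min (reported x1000), dissociation constants in nmol/L.
PARAM_BOUNDS = {
    "K1_disp": (1e-3, 5.0, 0.5),
    "K1_post": (1e-3, 5.0, 0.5),
    "K1_disp2": (1e-3, 5.0, 0.5),
    "VT": (0.5, 200.0, 20.0),
    "fND": (1e-3, 1.0, 0.1),
    "K1D": (1e-6, 1.0, 0.01),
    "koff": (1e-3, 100.0, 5.0),
    "koffD": (1e-3, 100.0, 5.0),
    "fPD": (1e-3, 1.0, 0.9),
    "fNDD": (1e-3, 1.0, 0.9),
    "KD": (1e-2, 1e3, 3.0),
    "KDD": (1.0, 1e7, 1e4),
}

#: multi-start values for K1D, mL/cm^3/min (1, 10, 100 uL/cm^3/min)
K1D_STARTS = (0.001, 0.01, 0.1)


@dataclass(frozen=True)
class ModelConfig:
    """Which parameters float, and overrides for the fixed remainder."""

    id: str
    floating: tuple
    fixed_overrides: dict = field(default_factory=dict)
    allow_k1_step: bool = False

    def __post_init__(self):
        bad = [p for p in self.floating
               if p not in PRIMARY_PARAMS + EXTRA_PARAMS + ("K1_disp2",)]
        if bad:
            raise ValueError(f"unknown floating parameters {bad}")


def model_config(config_id: str, fixed_overrides: dict | None = None,
                 allow_k1_step: bool = False) -> ModelConfig:
    """Build a named configuration: '5p', '7p', '6p:<param>'."""
    fixed_overrides = dict(fixed_overrides or {})
    floating: tuple
    if config_id == "5p":
        floating = PRIMARY_PARAMS
    elif config_id == "7p":
        floating = PRIMARY_PARAMS + ("koff", "koffD")
    elif config_id.startswith("6p:"):
        extra = config_id.split(":", 1)[1]
        if extra not in EXTRA_PARAMS:
            raise ValueError(
                f"6p extra parameter must be one of {EXTRA_PARAMS}, got {extra!r}"
            )
        floating = PRIMARY_PARAMS + (extra,)
    else:
        raise ValueError(f"unknown model configuration {config_id!r}")
    if allow_k1_step:
        floating = floating + ("K1_disp2",)
    return ModelConfig(id=config_id, floating=floating,
                       fixed_overrides=fixed_overrides,
                       allow_k1_step=allow_k1_step)


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one fit."""

    config_id: str
    region: str
    estimates: dict
    se: dict
    rse: dict               # percent: 100*SE/|estimate|
    ss: float
    n: int
    n_params: int
    converged: bool
    message: str = ""
    nfev: int = 0
    at_bound: dict = field(default_factory=dict)
    se_available: bool = True
    residuals: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return self.n - self.n_params


def standard_errors(jacobian: np.ndarray, residuals: np.ndarray,
                    estimates: np.ndarray | None = None,
                    cond_max: float = 1e12):
    """SE (and rSE) from the weighted normal matrix at the optimum.

    cov = s^2 (J'J)^{-1} with s^2 = SS/(n-p); the Jacobian is expected to be
    that of the *weighted* residuals.  Returns (se, rse, available); a normal
    matrix with condition number above ``cond_max`` is flagged unavailable and
    yields NaNs.
    """
    jacobian = np.asarray(jacobian, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    n, p = jacobian.shape
    if n <= p:
        return np.full(p, np.nan), np.full(p, np.nan), False
    ss = float(residuals @ residuals)
    s2 = ss / (n - p)
    _, sv, vt = np.linalg.svd(jacobian, full_matrices=False)
    if sv[0] <= 0 or sv[-1] <= 0 or sv[0] / sv[-1] > cond_max:
        return np.full(p, np.nan), np.full(p, np.nan), False
    cov = (vt.T / sv**2) @ vt * s2
    se = np.sqrt(np.diag(cov))
    if estimates is None:
        return se, np.full(p, np.nan), True
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = 100.0 * se / np.abs(estimates)
    return se, rse, True


class _FrameAverager:
    """Frame averages by trapezoid quadrature on a structured fine grid."""

    def __init__(self, scan: ScanData, points_per_frame: int = 11):
        self.ppf = points_per_frame
        self.grid = scan_grid(scan.injection_time, scan.end_time, scan.frames,
                              points_per_frame)
        nseg = points_per_frame - 1
        nfr = len(scan.frames)
        idx = np.arange(nfr)[:, None] * nseg + np.arange(points_per_frame)[None, :]
        self.idx = idx
        w = np.full(points_per_frame, 1.0 / nseg)
        w[0] = w[-1] = 0.5 / nseg
        self.w = w  # mean = sum(w * v) over each frame's points

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return (values[self.idx] * self.w).sum(axis=1)


class JointModel:
    """Residual machinery for one (dataset, region, config) triple.

    Precomputes fine grids, frame-quadrature weights, the blood contribution
    (parameter independent) and the weighted data vector; caches the drug
    trajectory keyed by the drug-relevant parameter values so that
    finite-difference steps in tracer-only parameters do not re-solve it.
    """

    def __init__(self, dataset: SubjectDataset, region: str, config: ModelConfig,
                 weighting: str = "duration", tracer_solver: str = "expm",
                 drug_dt: float = 0.1, weights: np.ndarray | None = None):
        if region not in dataset.regions:
            raise KeyError(f"region {region!r} not in dataset {dataset.regions}")
        self.dataset = dataset
        self.region = region
        self.config = config
        self.tracer_solver = tracer_solver
        self.drug_dt = drug_dt
        base = FixedConstants.for_drug(dataset.drug)
        self.constants = base.with_updates(**{
            k: v for k, v in config.fixed_overrides.items()
            if k in ("KD", "KDD", "fPD", "fNDD", "koff", "koffD", "vB")
        })
        self.fixed_params = {
            k: v for k, v in config.fixed_overrides.items()
            if k in PRIMARY_PARAMS
        }

        self.scans = dataset.scans
        self.avg = [_FrameAverager(s) for s in self.scans]
        self.refined = [refine_grid(a.grid) for a in self.avg]
        if weighting == "duration":
            wts = [s.frames.duration for s in self.scans]
        elif weighting == "uniform":
            wts = [np.ones(len(s.frames)) for s in self.scans]
        elif weighting == "decay":
            # inverse of the noise-free part of the count-statistics variance
            # for decay-corrected frames: var ~ value * exp(lambda*t_mid)/dur;
            # the noisy value factor is deliberately left out so weights stay
            # uncorrelated with the residuals
            lam = np.log(2.0) / 20.4
            wts = [
                s.frames.duration / np.exp(lam * s.frames.midpoint)
                for s in self.scans
            ]
        elif weighting == "ivar":
            # full inverse-variance using the measured values (beware: noisy
            # values correlate weights with residuals at low counts)
            lam = np.log(2.0) / 20.4
            wts = []
            for s in self.scans:
                v = np.asarray(s.tacs[region], dtype=float)
                floor = max(1e-12, 0.01 * float(np.max(v)))
                wts.append(
                    s.frames.duration
                    / (np.maximum(v, floor) * np.exp(lam * s.frames.midpoint))
                )
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        self.data = np.concatenate(
            [np.asarray(s.tacs[region], float) for s in self.scans]
        )
        self.n = self.data.size
        if weights is not None:
            wts = [np.asarray(weights, dtype=float)]
            if wts[0].shape != (self.n,):
                raise ValueError(
                    f"explicit weights must have length {self.n}"
                )
        self.sqrtw = np.sqrt(np.concatenate(wts))
        vB = self.constants.vB
        self.blood = [
            vB * a(s.whole_blood(a.grid)) for s, a in zip(self.scans, self.avg)
        ]
        self._drug_cache: dict = {}

    # -- parameter plumbing --

    def build_params(self, x: np.ndarray) -> KineticParameters:
        values = dict(zip(self.config.floating, x))
        const_updates = {k: values.pop(k) for k in list(values)
                         if k in ("koff", "koffD", "fPD", "fNDD", "KD", "KDD")}
        values.pop("K1_disp2", None)
        merged = {**self.fixed_params, **values}
        # keep the binding capacity non-negative while the optimizer explores:
        # clip fND to the zero-capacity boundary VT*fND/fP = 1
        min_fnd = max(self.scans[0].fP, self.scans[1].fP) / merged["VT"] \
            * (1.0 + 1e-9)
        if merged["fND"] < min_fnd:
            merged["fND"] = min_fnd
        return KineticParameters(
            K1_disp=merged["K1_disp"],
            K1_post=merged["K1_post"],
            VT=merged["VT"],
            fND=merged["fND"],
            K1D=merged["K1D"],
            fP_disp=self.scans[0].fP,
            fP_post=self.scans[1].fP,
            constants=self.constants.with_updates(**const_updates),
        )

    def _drug_trajectory(self, p: KineticParameters):
        c = p.constants
        key = (p.K1D, p.VT, p.fND, p.fP_disp, c.koffD, c.fNDD, c.fPD, c.KDD, c.KD)
        hit = self._drug_cache.get(key)
        if hit is None:
            hit = simulate_drug(
                p, self.dataset.drug_plasma, self.dataset.infusion_start,
                self.scans[1].end_time, dt=self.drug_dt, method="rk4",
            )
            if len(self._drug_cache) > 64:
                self._drug_cache.clear()
            self._drug_cache[key] = hit
        return hit

    # -- prediction and residuals --

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.build_params(x)
        dt_, dnd_, occ_ = self._drug_trajectory(p)
        vB = p.constants.vB
        out = []
        k1_step = dict(zip(self.config.floating, x)).get("K1_disp2")
        for scan, avg, refined, blood in zip(self.scans, self.avg, self.refined,
                                             self.blood):
            if scan.role == "displacement" and k1_step is not None:
                y = self._tracer_with_step(p, scan, avg.grid, k1_step, dt_, occ_)
            else:
                y = simulate_tracer(p, scan.role, scan.plasma, dt_, occ_,
                                    avg.grid, method=self.tracer_solver,
                                    refined=refined)
            tissue = y[0] + y[1]
            out.append((1.0 - vB) * avg(tissue) + blood)
        return np.concatenate(out)

    def _tracer_with_step(self, p, scan, grid, k1_after, dt_, occ_):
        """Displacement-scan variant where K1 changes at the infusion time."""
        from .model import _expm_tracer

        t_sw = self.dataset.infusion_start
        pre = grid[grid <= t_sw]
        post = grid[grid >= t_sw]
        c = p.constants
        y_pre = _expm_tracer(p.K1_disp, p.fP_disp, p.fND, p.VT, c.koff,
                             scan.plasma, dt_, occ_, pre)
        y_post = _expm_tracer(k1_after, p.fP_disp, p.fND, p.VT, c.koff,
                              scan.plasma, dt_, occ_, post,
                              y0=(y_pre[0, -1], y_pre[1, -1]))
        out = np.empty((2, len(grid)))
        out[:, : len(pre)] = y_pre
        out[:, len(grid) - len(post):] = y_post
        return out

    def residuals(self, x: np.ndarray) -> np.ndarray:
        return self.sqrtw * (self.predict(x) - self.data)

    def ss(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)


def _initial_values(dataset: SubjectDataset, region: str, config: ModelConfig,
                    weighting: str) -> dict:
    """Starting values: K1/VT from a preliminary 1TC fit, fND = 0.1."""
    try:
        pre = fit_1tc(dataset.displacement, region,
                      t_minutes=dataset.infusion_start
                      - dataset.displacement.injection_time,
                      vB=FixedConstants.for_drug(dataset.drug).vB,
                      weighting=weighting)
        k1_0 = pre.estimates["K1"]
        vt_0 = pre.estimates["VT"]
    except Exception:
        k1_0, vt_0 = 0.4, 15.0
    return {"K1_disp": k1_0, "K1_post": k1_0, "K1_disp2": k1_0,
            "VT": vt_0, "fND": 0.1, "K1D": 0.01,
            "koff": 1.0, "koffD": 1.0}


def fit_joint(
    dataset: SubjectDataset,
    region: str,
    config: ModelConfig | str = "5p",
    weighting: str = "duration",
    k1d_starts=K1D_STARTS,
    x0: dict | None = None,
    tracer_solver: str = "expm",
    max_nfev: int = 400,
    tol: float = 1e-10,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Jointly fit the displacement + post-dose TAC pair of one region.

    Multi-starts over ``k1d_starts`` (lowest SS wins; ties broken by smallest
    parameter-vector norm).  ``x0`` overrides individual starting values and,
    when it pins ``K1D``, disables the multi-start.
    """
    if isinstance(config, str):
        config = model_config(config)
    jm = JointModel(dataset, region, config, weighting=weighting,
                    tracer_solver=tracer_solver, weights=weights)
    init = _initial_values(dataset, region, config, weighting)
    for name in ("koff", "koffD", "fPD", "fNDD", "KD", "KDD"):
        if name in config.floating and name not in ("koff", "koffD"):
            init[name] = getattr(jm.constants, name)
    x0 = dict(x0 or {})
    init.update({k: v for k, v in x0.items() if k in config.floating})

    lb = np.array([PARAM_BOUNDS[p][0] for p in config.floating])
    ub = np.array([PARAM_BOUNDS[p][1] for p in config.floating])
    scale = np.array([PARAM_BOUNDS[p][2] for p in config.floating])

    starts = list(k1d_starts) if ("K1D" in config.floating and "K1D" not in x0) \
        else [init["K1D"]]
    # floating dissociation rates: try both the generic start (1/min) and the
    # study-average fixed values, so nested fits never end above the 5p optimum
    rate_names = [p for p in ("koff", "koffD")
                  if p in config.floating and p not in x0]
    rate_variants = [{}]
    if rate_names:
        rate_variants.append(
            {p: getattr(jm.constants, p) for p in rate_names}
        )
    best = None
    total_nfev = 0
    for k1d0, variant in itertools.product(starts, rate_variants):
        trial = dict(init)
        trial.update(variant)
        trial["K1D"] = k1d0
        xx0 = np.clip(np.array([trial[p] for p in config.floating]), lb, ub)
        res = least_squares(
            jm.residuals, xx0, bounds=(lb, ub), method="trf", x_scale=scale,
            ftol=tol, xtol=tol, gtol=tol, max_nfev=max_nfev,
        )
        total_nfev += res.nfev
        cand_ss = float(res.fun @ res.fun)
        if best is None or cand_ss < best[0] - 1e-12 or (
            abs(cand_ss - best[0]) <= 1e-12
            and np.linalg.norm(res.x / scale) < np.linalg.norm(best[1].x / scale)
        ):
            best = (cand_ss, res)
    ss, res = best
    se, rse, ok = standard_errors(res.jac, res.fun, res.x)
    est = dict(zip(config.floating, res.x))
    at_bound = {
        p: bool(np.isclose(v, PARAM_BOUNDS[p][0]) or np.isclose(v, PARAM_BOUNDS[p][1]))
        for p, v in est.items()
    }
    return FitResult(
        config_id=config.id,
        region=region,
        estimates=est,
        se=dict(zip(config.floating, se)),
        rse=dict(zip(config.floating, rse)),
        ss=ss,
        n=jm.n,
        n_params=len(config.floating),
        converged=bool(res.status > 0),
        message=res.message,
        nfev=total_nfev,
        at_bound=at_bound,
        se_available=ok,
        residuals=res.fun,
    )


def model_based_weights(dataset: SubjectDataset, region: str,
                        estimates: dict, config: ModelConfig | str = "5p",
                        tracer_solver: str = "expm") -> np.ndarray:
    """Inverse-variance frame weights from model-predicted TAC values.

    Evaluates the count-statistics variance model var ~ value*e^{lambda*t}/dur
    at the *predicted* (noise-free) frame values of a reference fit, so the
    weights are smooth and uncorrelated with the measurement noise.  Use the
    same weight vector for every model being compared by an F test.
    """
    if isinstance(config, str):
        config = model_config(config)
    jm = JointModel(dataset, region, config, weighting="uniform",
                    tracer_solver=tracer_solver)
    x = np.array([estimates[p] for p in config.floating])
    pred = jm.predict(x)
    lam = np.log(2.0) / 20.4
    decay = np.concatenate([np.exp(lam * s.frames.midpoint)
                            for s in dataset.scans])
    dur = np.concatenate([s.frames.duration for s in dataset.scans])
    floor = max(1e-12, 0.01 * float(np.max(pred)))
    return dur / (np.maximum(pred, floor) * decay)


# --- one-tissue comparator ---------------------------------------------------


def _solve_1tc(K1: float, k2: float, plasma: SampledCurve,
               grid: np.ndarray) -> np.ndarray:
    """Exact piecewise-linear-input solution of dC/dt = K1*Cp - k2*C."""
    cp = K1 * np.interp(grid, plasma.times, plasma.values)
    h = np.diff(grid)
    e = np.exp(-k2 * h)
    b0 = cp[:-1]
    slope = (cp[1:] - cp[:-1]) / h
    # int_0^h e^{-k2 (h-s)} (b0 + slope*s) ds
    i0 = (1.0 - e) / k2
    i1 = (h - i0) / k2
    forced = b0 * i0 + slope * i1
    c = np.empty(len(grid))
    c[0] = 0.0
    for i in range(len(h)):
        c[i + 1] = c[i] * e[i] + forced[i]
    return c


def fit_1tc(
    scan: ScanData,
    region: str,
    t_minutes: float = 60.0,
    vB: float = 0.05,
    weighting: str = "duration",
) -> FitResult:
    """One-tissue compartment fit to the first ``t_minutes`` of a scan.

    Estimates K1 and VT (k2 = K1/VT) with the same weighting and blood-volume
    treatment as the extended model; standard errors from the fit covariance.
    """
    frames = scan.frames
    keep = frames.end <= t_minutes + 1e-9
    if keep.sum() < 10:
        raise ValueError(
            f"need >= 10 frames before {t_minutes} min, found {int(keep.sum())}"
        )
    from .curves import FrameSchedule
    sub = FrameSchedule(start=frames.start[keep], duration=frames.duration[keep])
    sub_scan_end = scan.injection_time + float(sub.end[-1])
    grid = scan_grid(scan.injection_time, sub_scan_end, sub)
    avg = _FrameAverager(
        ScanData(role=scan.role, injection_time=scan.injection_time, frames=sub,
                 tacs={region: np.asarray(scan.tacs[region])[keep]},
                 plasma=scan.plasma, whole_blood=scan.whole_blood, fP=scan.fP)
    )
    data = np.asarray(scan.tacs[region], float)[keep]
    w = np.sqrt(sub.duration if weighting == "duration" else np.ones(len(sub)))
    blood = vB * avg(scan.whole_blood(avg.grid))

    def residual(x):
        K1, VT = x
        c = _solve_1tc(K1, K1 / VT, scan.plasma, avg.grid)
        return w * ((1.0 - vB) * avg(c) + blood - data)

    vt0 = max(1.0, data[-1] / max(scan.plasma(sub.end[-1]), 1e-9))
    res = least_squares(
        residual, np.array([0.3, min(vt0, 50.0)]),
        bounds=([1e-4, 0.5], [5.0, 200.0]), method="trf",
        x_scale=[0.3, 10.0], ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    se, rse, ok = standard_errors(res.jac, res.fun, res.x)
    ss = float(res.fun @ res.fun)
    return FitResult(
        config_id="1tc", region=region,
        estimates={"K1": res.x[0], "VT": res.x[1]},
        se=dict(zip(("K1", "VT"), se)), rse=dict(zip(("K1", "VT"), rse)),
        ss=ss, n=int(keep.sum()), n_params=2,
        converged=bool(res.status > 0), message=res.message, nfev=res.nfev,
        se_available=ok, residuals=res.fun,
    )
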