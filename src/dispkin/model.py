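"""Tracer-drug competition compartment model.

A PET tracer and a competing drug both enter brain tissue from plasma and bind
reversibly to a shared target (here SV2A).  The tracer contributes two tissue
states, non-displaceable C_ND(t) and specifically bound C_S(t) (Bq/cm^3); the
drug contributes the non-displaceable tissue concentration D_ND(t) (nmol/L) and
the target occupancy O(t) = D_S(t)/Bmax.  In the estimation form the system is

    dC_ND/dt = K1*C_P - (K1*fND/fP)*C_ND
               - koff*[(VT*fND/fP - 1)*(1-O)*C_ND - C_S]
    dC_S/dt  = koff*[(VT*fND/fP - 1)*(1-O)*C_ND - C_S]
    dD_ND/dt = K1D*D_P - (K1D*fNDD/fPD)*D_ND
               - koffD*(KD/fND)*(VT*fND/fP - 1)*[(fNDD/KDD)*(1-O)*D_ND - O]
    dO/dt    = koffD*[(fNDD/KDD)*(1-O)*D_ND - O]

which is an exact reparameterization of the mechanistic mass-action form (in
k2, kon, Bmax, ...) under the assumption that the tracer occupies a negligible
fraction of the target (the C_S/M term is dropped; molar activity M is carried
as metadata only).

The drug pair (D_ND, O) does not depend on the tracer states, so it is solved
once per parameter set on the full study clock and the tracer pair — a linear
time-varying 2-state ODE given O(t) — is solved per scan.  Two tracer solvers
are provided: LSODA (reference) and a piecewise matrix-exponential propagator
(fast path used by fitting), which agree to well below 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .curves import FrameSchedule, SampledCurve

__all__ = [
    "FixedConstants",
    "KineticParameters",
    "DerivedParameters",
    "StateTrajectory",
    "Timeline",
    "derive_secondary",
    "simulate_drug",
    "simulate_tracer",
    "simulate_system",
    "predict_pet",
    "occupancy_metrics",
    "OccupancyMetrics",
    "equilibrium_occupancy",
]

#: default solver tolerances (stiff-capable LSODA)
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class FixedConstants:
    """Constants fixed from literature/measured values.

    KD, KDD in nmol/L; koff, koffD in 1/min; fPD, fNDD dimensionless in (0,1];
    vB is the blood volume fraction.
    """

    KD: float = 3.4
    KDD: float = 21000.0
    fPD: float = 0.90
    fNDD: float = 1.0
    koff: float = 4.9
    koffD: float = 4.9
    vB: float = 0.05

    def __post_init__(self):
        for name in ("KD", "KDD", "fPD", "fNDD", "koff", "koffD"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fPD > 1 or self.fNDD > 1:
            raise ValueError("fPD and fNDD must be <= 1")
        if not (0 <= self.vB <= 0.2):
            raise ValueError("vB must lie in [0, 0.2]")

    @classmethod
    def for_drug(cls, drug: str) -> "FixedConstants":
        """Literature defaults for levetiracetam (LEV) or brivaracetam (BRV).

        koff / koffD are the cross-subject averages used when they are fixed
        in the 5-parameter model.
        """
        drug = drug.upper()
        if drug == "LEV":
            return cls(KDD=21000.0, fPD=0.90, fNDD=1.0, koffD=4.9)
        if drug == "BRV":
            return cls(KDD=2000.0, fPD=0.83, fNDD=0.88, koffD=5.9)
        raise ValueError(f"unknown drug {drug!r}; expected 'LEV' or 'BRV'")

    def with_updates(self, **kw) -> "FixedConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class KineticParameters:
    """Floating (or potentially floating) parameters plus the fixed constants.

    K1_disp / K1_post : tracer plasma->tissue rate per scan, mL/min/cm^3.
    fP_disp / fP_post : tracer plasma free fraction per scan.
    VT : tracer distribution volume, mL/cm^3.
    fND : tracer tissue free fraction.
    K1D : drug plasma->tissue rate, mL/min/cm^3 (reported x1000 as uL/cm^3/min).
    """

    K1_disp: float
    K1_post: float
    VT: float
    fND: float
    K1D: float
    fP_disp: float = 0.30
    fP_post: float = 0.30
    constants: FixedConstants = field(default_factory=FixedConstants)
    molar_activity: float | None = None  # MBq/umol, metadata only

    def __post_init__(self):
        for name in ("K1_disp", "K1_post", "VT", "fND", "K1D", "fP_disp", "fP_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fND > 1:
            raise ValueError("fND must be <= 1")
        for scan, fp in (("displacement", self.fP_disp), ("post-dose", self.fP_post)):
            if self.VT * self.fND / fp < 1.0:
                raise ValueError(
                    f"VT*fND/fP < 1 for the {scan} scan "
                    f"(VT={self.VT}, fND={self.fND}, fP={fp}): "
                    "the specific-binding capacity would be negative"
                )

    def k1_fp(self, role: str) -> tuple[float, float]:
        if role == "displacement":
            return self.K1_disp, self.fP_disp
        if role == "post-dose":
            return self.K1_post, self.fP_post
        raise ValueError(f"unknown scan role {role!r}")

    @property
    def K1D_uL(self) -> float:
        """K1D in the reporting unit, uL/cm^3/min."""
        return 1000.0 * self.K1D

    def with_updates(self, **kw) -> "KineticParameters":
        const_keys = {k: v for k, v in kw.items() if hasattr(self.constants, k)}
        own = {k: v for k, v in kw.items() if k not in const_keys}
        constants = self.constants.with_updates(**const_keys) if const_keys else self.constants
        return replace(self, constants=constants, **own)


@dataclass(frozen=True)
class DerivedParameters:
    """Mechanistic (mass-action) parameters implied by the estimation form."""

    k2: float        # 1/min, tracer tissue->plasma (displacement scan)
    k2_post: float   # 1/min, tracer tissue->plasma (post-dose scan)
    k2D: float       # 1/min, drug tissue->plasma
    Bmax: float      # nmol/L, total target concentration
    kon: float       # 1/(nmol/L)/min, tracer association
    konD: float      # 1/(nmol/L)/min, drug association


def derive_secondary(params: KineticParameters) -> DerivedParameters:
    """Mechanistic parameters from the estimation parameterization.

    k2 = K1*fND/fP, kon = koff/KD, konD = koffD/KDD and
    Bmax = KD*(VT*fND/fP - 1)/fND (displacement-scan fP).
    """
    c = params.constants
    cap = params.VT * params.fND / params.fP_disp - 1.0
    if cap < 0:
        raise ValueError(
            f"VT*fND/fP - 1 = {cap:.4g} < 0 "
            f"(VT={params.VT}, fND={params.fND}, fP={params.fP_disp}): "
            "Bmax would be negative"
        )
    return DerivedParameters(
        k2=params.K1_disp * params.fND / params.fP_disp,
        k2_post=params.K1_post * params.fND / params.fP_post,
        k2D=params.K1D * c.fNDD / c.fPD,
        Bmax=c.KD * cap / params.fND,
        kon=c.koff / c.KD,
        konD=c.koffD / c.KDD,
    )


def equilibrium_occupancy(constants: FixedConstants, d_plasma: float) -> float:
    """Steady-state occupancy under a constant drug plasma level (nmol/L)."""
    x = constants.fPD * d_plasma
    return x / (constants.KDD + x)


# --- right-hand sides --------------------------------------------------------


def reduced_rhs(t, y, params: KineticParameters, role: str, cp, dp):
    """Estimation-form RHS; y = [C_ND, C_S, D_ND, O]; cp, dp callables."""
    c = params.constants
    K1, fP = params.k1_fp(role)
    cap = params.VT * params.fND / fP - 1.0
    cnd, cs, dnd, occ = y
    bind_t = c.koff * (cap * (1.0 - occ) * cnd - cs)
    bind_d = c.koffD * ((c.fNDD / c.KDD) * (1.0 - occ) * dnd - occ)
    return np.array([
        K1 * cp(t) - (K1 * params.fND / fP) * cnd - bind_t,
        bind_t,
        params.K1D * dp(t) - (params.K1D * c.fNDD / c.fPD) * dnd
        - (c.KD / params.fND) * cap * bind_d,
        bind_d,
    ])


def mechanistic_rhs(t, y, params: KineticParameters, role: str, cp, dp):
    """Mass-action RHS; y = [C_ND, C_S, D_ND, D_S] (C_S/M term dropped)."""
    d = derive_secondary(params)
    c = params.constants
    K1, _ = params.k1_fp(role)
    k2 = d.k2 if role == "displacement" else d.k2_post
    cnd, cs, dnd, ds = y
    free = d.Bmax - ds
    bind_t = params.fND * d.kon * free * cnd - c.koff * cs
    bind_d = c.fNDD * d.konD * free * dnd - c.koffD * ds
    return np.array([
        K1 * cp(t) - k2 * cnd - bind_t,
        bind_t,
        params.K1D * dp(t) - d.k2D * dnd - bind_d,
        bind_d,
    ])


# --- drug subsystem ----------------------------------------------------------


def simulate_drug(
    params: KineticParameters,
    drug_input: SampledCurve,
    t_start: float,
    t_end: float,
    dt: float = 0.1,
    method: str = "lsoda",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate (D_ND, O) from ``t_start`` (states zero) to ``t_end``.

    Returns (t, D_ND, O) on a grid of step <= dt (dense just after the
    infusion start).  The drug states are continuous across the inter-scan
    gap; the capacity term uses the displacement-scan fP.  ``method`` is
    "lsoda" (adaptive, reference) or "rk4" (fixed-step compiled fast path
    used by fitting; step chosen from the fastest local rate).
    """
    c = params.constants
    cap = params.VT * params.fND / params.fP_disp - 1.0
    k2D = params.K1D * c.fNDD / c.fPD
    coef = (c.KD / params.fND) * cap
    K1D, koffD, ratio = params.K1D, c.koffD, c.fNDD / c.KDD
    td, vd = drug_input.times, drug_input.values
    if np.any(vd < 0):
        raise ValueError("drug input has negative values")

    t = _drug_grid(t_start, t_end, dt)
    if method == "rk4" and _drug_rk4 is not None:
        # stability/accuracy bound on the step from the fastest rate:
        # binding turnover koffD*(ratio*D_ND + 1) with D_ND <~ fPD*Dp_max/fNDD
        dnd_max = max(c.fPD * float(np.max(vd)) / c.fNDD, 1.0)
        rate = koffD * (ratio * dnd_max + 1.0) + k2D
        h = min(0.02, 1.0 / rate)
        y = _drug_rk4(td.astype(float), vd.astype(float), t, float(h),
                      K1D, k2D, koffD, ratio, coef)
        return t, y[0], y[1]

    def rhs(y, t):
        dnd, occ = y
        b = koffD * (ratio * (1.0 - occ) * dnd - occ)
        return (K1D * np.interp(t, td, vd) - k2D * dnd - coef * b, b)

    y = _odeint_checked(rhs, [0.0, 0.0], t,
                        context=f"drug states (K1D={params.K1D:.4g}, "
                                f"koffD={c.koffD:.4g}, KDD={c.KDD:.4g})")
    return t, y[:, 0], y[:, 1]


def _odeint_checked(rhs, y0, t, context: str):
    y, info = odeint(rhs, y0, t, rtol=RTOL, atol=ATOL, mxstep=50000,
                     full_output=True)
    if info["message"] != "Integration successful.":
        raise RuntimeError(
            f"ODE solver failed for {context}: {info['message']}"
        )
    return y


try:
    from numba import njit as _njit_rk4

    @_njit_rk4(cache=True)
    def _drug_rk4(td, vd, out_t, h, K1D, k2D, koffD, ratio, coef):  # pragma: no cover
        n_out = out_t.size
        out = np.zeros((2, n_out))
        dnd = 0.0
        occ = 0.0
        for i in range(n_out - 1):
            t0 = out_t[i]
            t1 = out_t[i + 1]
            nsub = max(1, int(np.ceil((t1 - t0) / h)))
            dt_ = (t1 - t0) / nsub
            for j in range(nsub):
                t = t0 + j * dt_
                kd = np.empty((4, 2))
                for stage in range(4):
                    if stage == 0:
                        w, ts = 0.0, t
                    elif stage < 3:
                        w, ts = 0.5, t + 0.5 * dt_
                    else:
                        w, ts = 1.0, t + dt_
                    y0 = dnd + w * dt_ * kd[stage - 1, 0] if stage else dnd
                    y1 = occ + w * dt_ * kd[stage - 1, 1] if stage else occ
                    dp = np.interp(ts, td, vd)
                    b = koffD * (ratio * (1.0 - y1) * y0 - y1)
                    kd[stage, 0] = K1D * dp - k2D * y0 - coef * b
                    kd[stage, 1] = b
                dnd += dt_ / 6.0 * (kd[0, 0] + 2 * kd[1, 0] + 2 * kd[2, 0]
                                    + kd[3, 0])
                occ += dt_ / 6.0 * (kd[0, 1] + 2 * kd[1, 1] + 2 * kd[2, 1]
                                    + kd[3, 1])
            out[0, i + 1] = dnd
            out[1, i + 1] = occ
        return out
except ImportError:  # pragma: no cover
    _drug_rk4 = None


def _drug_grid(t_start: float, t_end: float, dt: float) -> np.ndarray:
    """Output grid for the drug states: dense immediately after the infusion
    start (fast occupancy rise), progressively coarser later."""
    edges = [t_start, min(t_start + 10.0, t_end), min(t_start + 60.0, t_end), t_end]
    steps = [dt / 5.0, dt, 10.0 * dt]
    pieces = [np.array([t_start])]
    for lo, hi, step in zip(edges[:-1], edges[1:], steps):
        if hi > lo:
            n = max(1, int(np.ceil((hi - lo) / step)))
            pieces.append(np.linspace(lo, hi, n + 1)[1:])
    return np.concatenate(pieces)


# --- tracer subsystem --------------------------------------------------------


def _tracer_rhs_factory(K1, fP, fND, VT, koff, cp_t, cp_v, occ_t, occ_v):
    k2 = K1 * fND / fP
    cap = VT * fND / fP - 1.0

    def rhs(y, t):
        o = np.interp(t, occ_t, occ_v)
        b = koff * (cap * (1.0 - o) * y[0] - y[1])
        return (K1 * np.interp(t, cp_t, cp_v) - k2 * y[0] - b, b)

    return rhs


def simulate_tracer(
    params: KineticParameters,
    role: str,
    tracer_input: SampledCurve,
    occ_t: np.ndarray,
    occ_v: np.ndarray,
    grid: np.ndarray,
    method: str = "lsoda",
    refined=None,
) -> np.ndarray:
    """Solve (C_ND, C_S) on ``grid`` (absolute minutes; grid[0] = injection).

    Tracer states start at zero at the injection (first grid point).  ``occ_t``
    / ``occ_v`` sample the occupancy trajectory (empty arrays mean no drug).
    ``refined`` optionally passes a precomputed :func:`refine_grid` result to
    the expm path.
    """
    K1, fP = params.k1_fp(role)
    c = params.constants
    if np.any(tracer_input.values < 0):
        raise ValueError("tracer input has negative values")
    if occ_t is None or len(occ_t) == 0:
        occ_t, occ_v = np.array([grid[0]]), np.array([0.0])
    if method == "lsoda":
        rhs = _tracer_rhs_factory(
            K1, fP, params.fND, params.VT, c.koff,
            tracer_input.times, tracer_input.values, occ_t, occ_v,
        )
        y = _odeint_checked(
            rhs, [0.0, 0.0], grid,
            context=f"tracer states ({role}, K1={K1:.4g}, VT={params.VT:.4g}, "
                    f"fND={params.fND:.4g}, koff={c.koff:.4g})",
        )
        return y.T
    if method == "expm":
        return _expm_tracer(
            K1, fP, params.fND, params.VT, c.koff,
            tracer_input, occ_t, occ_v, grid, refined=refined,
        )
    raise ValueError(f"unknown tracer solver {method!r}")


def refine_grid(grid: np.ndarray, max_step: float = 0.05):
    """Subdivide every interval of ``grid`` to steps <= ``max_step``.

    Returns (fine grid, indices of the original points in it); precompute this
    once per scan when calling :func:`_expm_tracer` repeatedly.
    """
    pieces = [np.array([grid[0]])]
    idx = [0]
    for i in range(len(grid) - 1):
        n = max(1, int(np.ceil((grid[i + 1] - grid[i]) / max_step)))
        pieces.append(np.linspace(grid[i], grid[i + 1], n + 1)[1:])
        idx.append(idx[-1] + n)
    return np.concatenate(pieces), np.asarray(idx)


def _expm_core_py(h, a, k2, koff, cp, x0=0.0, x1=0.0):
    """Vectorized-assembly fallback for the exponential propagator."""
    p, q, r, s = -k2 - a, np.full_like(a, koff), a, np.full_like(a, -koff)
    m = (p + s) / 2.0
    det = p * s - q * r
    mu2 = m * m - det
    mu = np.sqrt(np.abs(mu2))
    arg = mu * h
    pos = mu2 >= 0
    ch = np.where(pos, np.cosh(arg), np.cos(arg))
    with np.errstate(invalid="ignore", divide="ignore"):
        sh = np.where(pos, np.sinh(arg), np.sin(arg))
        snc = np.where(arg > 1e-12, sh / np.where(arg > 1e-12, mu, 1.0), h)
    e = np.exp(m * h)
    P00 = e * (ch + snc * (p - m))
    P01 = e * (snc * q)
    P10 = e * (snc * r)
    P11 = e * (ch + snc * (s - m))
    inv = 1.0 / det
    i00, i01, i10, i11 = inv * s, -inv * q, -inv * r, inv * p
    F00, F01, F10, F11 = P00 - 1.0, P01, P10, P11 - 1.0
    Q100 = i00 * F00 + i01 * F10
    Q110 = i10 * F00 + i11 * F10
    Q101 = i00 * F01 + i01 * F11
    Q111 = i10 * F01 + i11 * F11
    G00, G01, G10, G11 = Q100 - h, Q101, Q110, Q111 - h
    Q200 = i00 * G00 + i01 * G10
    Q210 = i10 * G00 + i11 * G10
    b0 = cp[:-1]
    slope = (cp[1:] - cp[:-1]) / h
    c0 = Q100 * b0 + Q200 * slope
    c1 = Q110 * b0 + Q210 * slope
    cnd = np.empty(len(h) + 1)
    cs = np.empty(len(h) + 1)
    cnd[0], cs[0] = x0, x1
    for i in range(len(h)):
        x0, x1 = (
            P00[i] * x0 + P01[i] * x1 + c0[i],
            P10[i] * x0 + P11[i] * x1 + c1[i],
        )
        cnd[i + 1], cs[i + 1] = x0, x1
    return cnd, cs


try:  # scalar-loop version compiles to a tight machine loop
    from numba import njit as _njit

    @_njit(cache=True)
    def _expm_core_nb(h, a, k2, koff, cp, x0=0.0, x1=0.0):  # pragma: no cover
        n = h.size
        cnd = np.empty(n + 1)
        cs = np.empty(n + 1)
        cnd[0] = x0
        cs[0] = x1
        for i in range(n):
            hi = h[i]
            ai = a[i]
            p = -k2 - ai
            s = -koff
            q = koff
            r = ai
            m = 0.5 * (p + s)
            det = p * s - q * r
            mu2 = m * m - det
            mu = np.sqrt(abs(mu2))
            arg = mu * hi
            if mu2 >= 0.0:
                ch = np.cosh(arg)
                sh = np.sinh(arg)
            else:
                ch = np.cos(arg)
                sh = np.sin(arg)
            snc = sh / mu if arg > 1e-12 else hi
            e = np.exp(m * hi)
            P00 = e * (ch + snc * (p - m))
            P01 = e * snc * q
            P10 = e * snc * r
            P11 = e * (ch + snc * (s - m))
            inv = 1.0 / det
            i00 = inv * s
            i01 = -inv * q
            i10 = -inv * r
            i11 = inv * p
            F00 = P00 - 1.0
            F01 = P01
            F10 = P10
            F11 = P11 - 1.0
            Q100 = i00 * F00 + i01 * F10
            Q110 = i10 * F00 + i11 * F10
            Q101 = i00 * F01 + i01 * F11
            Q111 = i10 * F01 + i11 * F11
            G00 = Q100 - hi
            G10 = Q110
            Q200 = i00 * G00 + i01 * G10
            Q210 = i10 * G00 + i11 * G10
            b0 = cp[i]
            slope = (cp[i + 1] - cp[i]) / hi
            c0 = Q100 * b0 + Q200 * slope
            c1 = Q110 * b0 + Q210 * slope
            nx0 = P00 * x0 + P01 * x1 + c0
            x1 = P10 * x0 + P11 * x1 + c1
            x0 = nx0
            cnd[i + 1] = x0
            cs[i + 1] = x1
        return cnd, cs

    _expm_core = _expm_core_nb
except ImportError:  # pragma: no cover
    _expm_core = _expm_core_py


def _expm_tracer(K1, fP, fND, VT, koff, tracer_input, occ_t, occ_v, grid,
                 max_step=0.05, refined=None, y0=(0.0, 0.0)):
    """Piecewise matrix-exponential propagator for the linear tracer pair.

    Within each substep the coupling coefficient a(t) = koff*cap*(1-O(t)) is
    frozen at the midpoint and the forcing K1*C_P(t) is taken linear; both are
    second-order accurate, and substeps are capped at ``max_step`` minutes.
    """
    k2 = K1 * fND / fP
    cap = VT * fND / fP - 1.0
    tt, out_idx = refined if refined is not None else refine_grid(grid, max_step)
    h = np.diff(tt)
    tm = tt[:-1] + h / 2
    a = koff * cap * (1.0 - np.interp(tm, occ_t, occ_v))
    cp = K1 * np.interp(tt, tracer_input.times, tracer_input.values)
    cnd, cs = _expm_core(h, a, float(k2), float(koff), cp,
                         float(y0[0]), float(y0[1]))
    return np.vstack([cnd[out_idx], cs[out_idx]])


# --- full-system simulation --------------------------------------------------


@dataclass(frozen=True)
class Timeline:
    """Event times (absolute minutes; first tracer injection at 0).

    ``injections`` are the tracer injection times of the scans in order
    (displacement, post-dose); ``scan_ends`` the corresponding scan end times;
    ``infusion_start`` the start of the drug infusion.
    """

    injections: tuple
    scan_ends: tuple
    infusion_start: float

    def __post_init__(self):
        if len(self.injections) != len(self.scan_ends):
            raise ValueError("injections and scan_ends must pair up")
        for inj, end in zip(self.injections, self.scan_ends):
            if end <= inj:
                raise ValueError("scan end must follow its injection")
        if len(self.injections) > 1:
            if self.scan_ends[0] > self.injections[1]:
                raise ValueError("scans must not overlap")
        if not (self.injections[0] <= self.infusion_start <= self.scan_ends[0]):
            raise ValueError("drug infusion must start inside the first scan")

    @classmethod
    def default(cls) -> "Timeline":
        """Displacement scan 0-120 min, infusion at 60 min, post-dose scan
        injected 4.5 h after dosing (330-450 min)."""
        return cls(injections=(0.0, 330.0), scan_ends=(120.0, 450.0),
                   infusion_start=60.0)


@dataclass(frozen=True)
class StateTrajectory:
    """Model states on an absolute study clock.

    O(t) in [0, 1]; C_* in Bq/cm^3; D_ND in nmol/L.  Tracer states are zero
    outside the scans (each injection restarts them from zero).
    """

    t: np.ndarray
    C_ND: np.ndarray
    C_S: np.ndarray
    D_ND: np.ndarray
    O: np.ndarray

    @property
    def tissue(self) -> np.ndarray:
        return self.C_ND + self.C_S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "C_ND": self.C_ND, "C_S": self.C_S,
             "D_ND": self.D_ND, "O": self.O}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


def scan_grid(injection: float, scan_end: float, frames: FrameSchedule | None,
              points_per_frame: int = 11) -> np.ndarray:
    """Fine quadrature grid for one scan: >= ``points_per_frame`` per frame."""
    if frames is None:
        return np.linspace(injection, scan_end, 1201)
    pieces = [np.array([injection + frames.start[0]])]
    for s, d in zip(frames.start, frames.duration):
        pieces.append(
            np.linspace(injection + s, injection + s + d, points_per_frame)[1:]
        )
    return np.concatenate(pieces)


def simulate_system(
    params: KineticParameters,
    tracer_inputs,
    drug_input: SampledCurve | None,
    timeline: Timeline,
    grids=None,
    method: str = "lsoda",
    drug_dt: float = 0.1,
) -> StateTrajectory:
    """Forward-simulate the full system over the study.

    ``tracer_inputs`` is one SampledCurve per scan (absolute clock); ``grids``
    one output grid per scan (defaults to a fine uniform grid).  The drug pair
    is integrated continuously from the infusion start through the last scan
    end; tracer states restart at zero at each injection.
    """
    if isinstance(tracer_inputs, SampledCurve):
        tracer_inputs = [tracer_inputs] * len(timeline.injections)
    if grids is None:
        grids = [
            scan_grid(inj, end, None)
            for inj, end in zip(timeline.injections, timeline.scan_ends)
        ]
    t_end = timeline.scan_ends[-1]
    if drug_input is not None:
        dt_, dnd_, occ_ = simulate_drug(
            params, drug_input, timeline.infusion_start, t_end, dt=drug_dt
        )
    else:
        dt_ = np.array([timeline.infusion_start])
        dnd_ = occ_ = np.array([0.0])

    roles = ["displacement", "post-dose"][: len(timeline.injections)]
    ts, cnds, css = [], [], []
    for role, inp, grid in zip(roles, tracer_inputs, grids):
        y = simulate_tracer(params, role, inp, dt_, occ_, grid, method=method)
        ts.append(grid)
        cnds.append(y[0])
        css.append(y[1])
    t = np.concatenate(ts)
    order = np.argsort(t, kind="stable")
    t = t[order]
    cnd = np.concatenate(cnds)[order]
    cs = np.concatenate(css)[order]
    occ = np.interp(t, dt_, occ_, left=0.0)
    dnd = np.interp(t, dt_, dnd_, left=0.0)
    return StateTrajectory(t=t, C_ND=cnd, C_S=cs, D_ND=dnd, O=occ)


# --- PET signal prediction ---------------------------------------------------


def predict_pet(
    tissue_t: np.ndarray,
    tissue_v: np.ndarray,
    whole_blood: SampledCurve,
    frames: FrameSchedule,
    vB: float = 0.05,
    injection: float = 0.0,
    points_per_frame: int = 11,
) -> np.ndarray:
    """Frame-averaged PET signal: (1-vB)*(C_ND+C_S) + vB*C_WB.

    Per-frame values are time averages over [start, start+duration] computed by
    trapezoid quadrature on ``points_per_frame`` points per frame.  ``tissue_t``
    must cover all frames (absolute clock; frame starts relative to
    ``injection``).
    """
    starts = injection + frames.start
    ends = injection + frames.end
    if starts[0] < tissue_t[0] - 1e-9 or ends[-1] > tissue_t[-1] + 1e-9:
        raise ValueError(
            f"frames [{starts[0]}, {ends[-1]}] outside trajectory span "
            f"[{tissue_t[0]}, {tissue_t[-1]}]"
        )
    out = np.empty(len(frames))
    for i, (s, e) in enumerate(zip(starts, ends)):
        sub = np.linspace(s, e, points_per_frame)
        tis = np.interp(sub, tissue_t, tissue_v)
        wb = whole_blood(sub)
        out[i] = np.trapezoid((1.0 - vB) * tis + vB * wb, sub) / (e - s)
    return out


def predict_pet_trajectory(
    traj: StateTrajectory,
    whole_blood: SampledCurve,
    frames: FrameSchedule,
    vB: float = 0.05,
    injection: float = 0.0,
    points_per_frame: int = 11,
) -> np.ndarray:
    return predict_pet(
        traj.t, traj.tissue, whole_blood, frames, vB, injection, points_per_frame
    )


# --- occupancy metrics -------------------------------------------------------


@dataclass(frozen=True)
class OccupancyMetrics:
    """Peak occupancy and timing, minutes after the dose."""

    O_max: float          # peak occupancy, fraction
    t_max: float          # first attainment of the peak, min after dose
    t_half: float         # first crossing of O_max/2, min after dose
    defined: bool = True  # False when the trajectory never shows occupancy


def occupancy_metrics(
    traj: StateTrajectory, dose_time: float, rel_tol: float = 1e-9
) -> OccupancyMetrics:
    """Peak occupancy after ``dose_time`` with first-attainment timing.

    t_half is the first upward crossing of O_max/2, linearly interpolated
    between grid points.  An all-zero occupancy trajectory is flagged as
    undefined rather than returned as zeros.
    """
    mask = traj.t >= dose_time
    if not np.any(mask):
        raise ValueError("trajectory does not extend past the dose time")
    t = traj.t[mask]
    o = traj.O[mask]
    omax = float(np.max(o))
    if omax <= 0.0:
        return OccupancyMetrics(np.nan, np.nan, np.nan, defined=False)
    i_max = int(np.argmax(o >= omax * (1.0 - rel_tol)))
    t_max = float(t[i_max] - dose_time)
    half = omax / 2.0
    above = np.nonzero(o >= half)[0]
    i = int(above[0])
    if i == 0:
        t_half = float(t[0] - dose_time)
    else:
        frac = (half - o[i - 1]) / (o[i] - o[i - 1])
        t_half = float(t[i - 1] + frac * (t[i] - t[i - 1]) - dose_time)
    return OccupancyMetrics(O_max=omax, t_max=t_max, t_half=t_half)
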