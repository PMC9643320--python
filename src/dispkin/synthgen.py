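"""Synthetic subject and study generation.

Emulates the displacement + post-dose study design: a bolus-plus-infusion
tracer administration (Kbol = 150 min) over a 120-min, 33-frame scan; a 5-min
intravenous drug infusion starting 60 min after tracer injection; a second
tracer injection 4.5 h after dosing; drug plasma sampling at 1-60 min after
the infusion start plus three samples bracketing the post-dose scan; and
count-statistics TAC noise.

Drug plasma kinetics are a stand-in (the study measures but never models
them): a two-compartment disposition model with a zero-order 5-min infusion,
whose amplitude is calibrated so that the equilibrium occupancy implied by the
plasma level at the end of the displacement scan hits a target value.  The
*forward simulation uses the linearly interpolated sparse samples* as the drug
input — exactly the input function the fitting stage sees — so noiseless
datasets are recoverable without input-model mismatch.

Ground-truth kinetic parameters default to the 5-parameter population medians
for putamen, frontal cortex and cerebellum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from .curves import BolusShape, FrameSchedule, SampledCurve, bolus_infusion_input
from .data import ScanData, SubjectDataset
from .model import (
    FixedConstants,
    KineticParameters,
    Timeline,
    equilibrium_occupancy,
    predict_pet,
    scan_grid,
    simulate_drug,
    simulate_tracer,
)

#: physical decay constant of 11C, 1/min (half-life 20.4 min); the TACs are
#: decay corrected, so noise variance grows with exp(+lambda t).
LAMBDA_C11 = np.log(2.0) / 20.4

#: drug plasma sampling offsets after infusion start, minutes
DRUG_SAMPLE_OFFSETS = (1.0, 3.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0)

#: 5-parameter population medians per region used as default ground truth:
#: (VT mL/cm^3, fND, K1_disp, K1_post mL/cm^3/min, K1D uL/cm^3/min)
POPULATION_MEDIANS = {
    "LEV": {
        "putamen": (21.6, 0.076, 0.47, 0.49, 5.2),
        "frontal": (18.7, 0.088, 0.43, 0.43, 5.1),
        "cerebellum": (13.7, 0.099, 0.37, 0.36, 4.0),
    },
    "BRV": {
        "putamen": (21.5, 0.089, 0.46, 0.46, 88.3),
        "frontal": (18.3, 0.105, 0.44, 0.42, 72.9),
        "cerebellum": (13.5, 0.094, 0.37, 0.35, 43.9),
    },
}

REGIONS = ("putamen", "frontal", "cerebellum")

#: reference doses (mg) at which the PK amplitude calibration applies
REFERENCE_DOSE = {"LEV": 1500.0, "BRV": 100.0}


@dataclass(frozen=True)
class DrugPK:
    """Two-compartment disposition rates (1/min) and central volume scale.

    Defaults give a biphasic decline with a distribution half-time of minutes
    and a terminal half-time of several hours, typical of both drugs.
    """

    k10: float = 0.0018
    k12: float = 0.04
    k21: float = 0.06

    def __post_init__(self):
        if min(self.k10, self.k12, self.k21) <= 0:
            raise ValueError("PK rate constants must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Study conditions for one synthetic subject."""

    drug: str = "LEV"
    dose_mg: float = 1500.0
    infusion_start: float = 60.0       # min after first tracer injection
    infusion_duration: float = 5.0
    post_dose_delay: float = 270.0     # infusion start -> 2nd injection (4.5 h)
    frames: FrameSchedule = field(default_factory=FrameSchedule.default)
    kbol: float = 150.0
    tracer_amplitude: float = 4000.0   # Bq/mL scale of the bolus response
    bolus_shape: BolusShape = field(default_factory=BolusShape)
    plasma_to_blood: float = 1.0 / 1.1
    parent_fraction_floor: float = 0.30
    parent_fraction_tau: float = 50.0  # min
    pk: DrugPK = field(default_factory=DrugPK)
    target_occupancy: float = 0.85     # equilibrium occupancy at scan-1 end
    occupancy_range: tuple = (0.6, 0.95)
    fP: float = 0.30
    noise_scale: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if self.drug.upper() not in ("LEV", "BRV"):
            raise ValueError(f"unknown drug {self.drug!r}")
        scan1_end = float(self.frames.end[-1])
        if not (0.0 < self.infusion_start < scan1_end):
            raise ValueError("drug infusion must start inside the first scan")
        if self.post_dose_delay <= scan1_end - self.infusion_start:
            raise ValueError("post-dose scan must start after the first scan ends")
        lo, hi = self.occupancy_range
        if not (lo <= self.target_occupancy <= hi):
            raise ValueError(
                f"target occupancy {self.target_occupancy} outside [{lo}, {hi}]"
            )
        if self.noise_scale < 0:
            raise ValueError("noise scale must be >= 0")

    @property
    def scan1_end(self) -> float:
        return float(self.frames.end[-1])

    @property
    def injection2(self) -> float:
        return self.infusion_start + self.post_dose_delay

    @property
    def scan2_end(self) -> float:
        return self.injection2 + float(self.frames.end[-1])

    def timeline(self) -> Timeline:
        return Timeline(
            injections=(0.0, self.injection2),
            scan_ends=(self.scan1_end, self.scan2_end),
            infusion_start=self.infusion_start,
        )

    def drug_sample_times(self) -> np.ndarray:
        post = (self.injection2, self.injection2 + self.scan1_end / 2,
                self.scan2_end)
        return np.array(
            [self.infusion_start]
            + [self.infusion_start + o for o in DRUG_SAMPLE_OFFSETS]
            + list(post)
        )


def default_truth(drug: str, constants: FixedConstants | None = None,
                  fP: float = 0.30) -> dict:
    """Ground-truth KineticParameters per region from the population medians."""
    drug = drug.upper()
    constants = constants or FixedConstants.for_drug(drug)
    out = {}
    for region, (vt, fnd, k1d_, k1p, k1d_uL) in POPULATION_MEDIANS[drug].items():
        out[region] = KineticParameters(
            K1_disp=k1d_, K1_post=k1p, VT=vt, fND=fnd, K1D=k1d_uL / 1000.0,
            fP_disp=fP, fP_post=fP, constants=constants,
        )
    return out


# --- drug plasma PK ----------------------------------------------------------


def _two_compartment_curve(design: StudyDesign, rate: float,
                           dt: float = 0.25) -> SampledCurve:
    """Central-compartment concentration for a zero-order infusion at ``rate``
    (nmol/L per min of central concentration equivalent)."""
    pk = design.pk
    t0, t1 = design.infusion_start, design.infusion_start + design.infusion_duration

    def rhs_factory(inp):
        def rhs(y, t):
            c1, c2 = y
            return (inp - (pk.k10 + pk.k12) * c1 + pk.k21 * c2,
                    pk.k12 * c1 - pk.k21 * c2)
        return rhs

    # integrate the infusion and washout phases separately: the zero-order
    # input is discontinuous at the infusion end
    t_inf = np.arange(t0, t1 + dt / 4, dt / 4)
    if t_inf[-1] < t1:
        t_inf = np.append(t_inf, t1)
    y_inf = odeint(rhs_factory(rate), [0.0, 0.0], t_inf, rtol=1e-10, atol=1e-12)
    t_post = np.arange(t1, design.scan2_end + dt, dt)
    y_post = odeint(rhs_factory(0.0), y_inf[-1], t_post, rtol=1e-10, atol=1e-12)
    t = np.concatenate([t_inf[:-1], t_post])
    c1 = np.concatenate([y_inf[:-1, 0], y_post[:, 0]])
    return SampledCurve(times=t, values=np.clip(c1, 0.0, None),
                        kind="drug-plasma", units="nmol/L")


def generate_drug_pk(
    design: StudyDesign, constants: FixedConstants | None = None
) -> tuple[SampledCurve, SampledCurve]:
    """Continuous drug plasma curve and the sparse sampled observations.

    The infusion rate is calibrated (linear PK) so that the plasma level at
    the end of the displacement scan implies the design's target equilibrium
    occupancy at the *reference dose* of the drug; ``dose_mg`` then scales the
    curve linearly.  Returns (continuous curve, observed samples).
    """
    constants = constants or FixedConstants.for_drug(design.drug)
    if design.dose_mg == 0:
        t = design.drug_sample_times()
        zero = SampledCurve(times=t, values=np.zeros_like(t),
                            kind="drug-plasma", units="nmol/L")
        return zero, zero
    unit = _two_compartment_curve(design, rate=1.0)
    ref = float(unit(design.scan1_end))
    if ref <= 0:
        raise ValueError("unit-rate PK curve vanished at the calibration time")
    occ = design.target_occupancy
    if occ >= 1.0:
        raise ValueError("target occupancy must be < 1")
    dp_target = constants.KDD * occ / (constants.fPD * (1.0 - occ))
    scale = (dp_target / ref) * (design.dose_mg / REFERENCE_DOSE[design.drug.upper()])
    cont = unit.scaled(scale)
    t_obs = design.drug_sample_times()
    obs = SampledCurve(times=t_obs, values=cont(t_obs),
                       kind="drug-plasma", units="nmol/L")
    return cont, obs


# --- TAC noise ---------------------------------------------------------------


def add_noise(
    tac: np.ndarray,
    frames: FrameSchedule,
    scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Count-statistics noise surrogate for decay-corrected PET frames.

    Per-frame independent Gaussian noise with
    SD = scale * sqrt(value * exp(lambda * t_mid) / duration), lambda the 11C
    decay constant and t_mid the frame midpoint relative to injection.
    Negative results are clipped at zero; returns (noisy tac, clip count).
    """
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    tac = np.asarray(tac, dtype=float)
    if scale == 0:
        return tac.copy(), 0
    sd = noise_sd(tac, frames, scale)
    noisy = tac + rng.normal(0.0, 1.0, size=tac.shape) * sd
    clipped = int(np.sum(noisy < 0))
    return np.clip(noisy, 0.0, None), clipped


def noise_sd(tac: np.ndarray, frames: FrameSchedule, scale: float) -> np.ndarray:
    """The noise model's per-frame standard deviation."""
    tac = np.asarray(tac, dtype=float)
    return scale * np.sqrt(
        np.clip(tac, 0.0, None) * np.exp(LAMBDA_C11 * frames.midpoint)
        / frames.duration
    )


# --- subject generation ------------------------------------------------------


def _parent_fraction(design: StudyDesign, grid: np.ndarray,
                     injection: float) -> SampledCurve:
    frac = design.parent_fraction_floor + (1.0 - design.parent_fraction_floor) \
        * np.exp(-(grid - injection) / design.parent_fraction_tau)
    return SampledCurve(times=grid, values=frac, kind="parent-fraction",
                        units="fraction")


def generate_subject(
    design: StudyDesign,
    truth: dict | None = None,
    subject: str = "sim01",
    rng: np.random.Generator | None = None,
) -> SubjectDataset:
    """Generate one complete synthetic subject dataset.

    ``truth`` maps region -> KineticParameters (defaults to the population
    medians with the design's fP).  TACs are frame-averaged model predictions
    plus count-statistics noise; the ground truth is recorded in the dataset's
    ``truth`` sidecar.
    """
    rng = rng or np.random.default_rng(design.seed)
    constants = None
    if truth is None:
        truth = default_truth(design.drug, fP=design.fP)
    constants = next(iter(truth.values())).constants

    timeline = design.timeline()
    _, drug_obs = generate_drug_pk(design, constants)

    scans = []
    for role, injection, scan_end in zip(
        ("displacement", "post-dose"), timeline.injections, timeline.scan_ends
    ):
        total = bolus_infusion_input(
            shape=design.bolus_shape, kbol=design.kbol,
            scan_duration=design.scan1_end, amplitude=design.tracer_amplitude,
        ).shifted(injection)
        pf = _parent_fraction(design, total.times, injection)
        plasma = SampledCurve(times=total.times, values=total.values * pf.values,
                              kind="tracer-plasma", units="Bq/mL")
        wb = SampledCurve(times=total.times,
                          values=total.values / design.plasma_to_blood,
                          kind="whole-blood", units="Bq/mL")
        grid = scan_grid(injection, scan_end, design.frames)
        tacs = {}
        for region, p in truth.items():
            # same validated integrators as the fitting stage, so noiseless
            # datasets are exactly recoverable (no solver-mismatch residue)
            if design.dose_mg > 0:
                dt_, dnd_, occ_ = simulate_drug(p, drug_obs,
                                                design.infusion_start, scan_end,
                                                method="rk4")
            else:
                dt_ = np.array([design.infusion_start])
                occ_ = np.array([0.0])
            y = simulate_tracer(p, role, plasma, dt_, occ_, grid, method="expm")
            clean = predict_pet(grid, y[0] + y[1], wb, design.frames,
                                vB=constants.vB, injection=injection)
            noisy, _ = add_noise(clean, design.frames, design.noise_scale, rng)
            tacs[region] = noisy
        scans.append(ScanData(
            role=role, injection_time=injection, frames=design.frames,
            tacs=tacs, plasma=plasma, whole_blood=wb, fP=design.fP,
            parent_fraction=pf,
        ))

    truth_sidecar = {
        region: {
            "K1_disp": p.K1_disp, "K1_post": p.K1_post, "VT": p.VT,
            "fND": p.fND, "K1D": p.K1D, "fP_disp": p.fP_disp,
            "fP_post": p.fP_post,
        }
        for region, p in truth.items()
    }
    return SubjectDataset(
        subject=subject, drug=design.drug.upper(), dose_mg=design.dose_mg,
        displacement=scans[0], postdose=scans[1], drug_plasma=drug_obs,
        infusion_start=design.infusion_start,
        infusion_duration=design.infusion_duration,
        truth=truth_sidecar,
    )


def jittered_truth(drug: str, rng: np.random.Generator, sigma: float = 0.10,
                   fP: float = 0.30, k1d_scale: float = 1.0) -> dict:
    """Population medians with per-subject log-normal jitter on the tracer
    parameters.

    K1D is left at the population value times ``k1d_scale``: the ratio-bound
    procedure searches a single entry rate common to all subjects, so the
    generator treats K1D as a population constant (inter-subject variability
    enters through the tracer parameters and the frame noise).
    """
    base = default_truth(drug, fP=fP)
    out = {}
    for region, p in base.items():
        jit = np.exp(rng.normal(0.0, sigma, size=4))
        out[region] = replace(
            p,
            K1_disp=p.K1_disp * jit[0], K1_post=p.K1_post * jit[1],
            VT=p.VT * jit[2], fND=min(p.fND * jit[3], 1.0),
            K1D=p.K1D * k1d_scale,
        )
    return out


def generate_ratio_study(
    n_subjects: int = 4,
    ratio: float = 15.0,
    lev_k1d_uL: float = 5.0,
    seed: int = 0,
    noise_scale: float | None = None,
    regions=("putamen",),
) -> dict:
    """A 4-subject two-drug study with a known BRV/LEV entry-rate ratio.

    Each subject gets a LEV and a BRV dataset; tracer parameters are jittered
    per subject, while the entry rates are population constants: LEV K1D is
    ``lev_k1d_uL`` and BRV K1D exactly ``ratio`` times that.  Returns
    {"LEV": [SubjectDataset...], "BRV": [...], "ratio": ratio}.
    """
    rng = np.random.default_rng(seed)
    out = {"LEV": [], "BRV": [], "ratio": ratio}
    for i in range(n_subjects):
        lev_truth = jittered_truth(
            "LEV", rng, k1d_scale=lev_k1d_uL / POPULATION_MEDIANS["LEV"]["putamen"][4]
        )
        brv_base = default_truth("BRV")
        brv_truth = {}
        for region in lev_truth:
            lp = lev_truth[region]
            if region not in brv_base:
                continue
            brv_truth[region] = replace(
                lp, K1D=lp.K1D * ratio, constants=brv_base[region].constants
            )
        for drug, truth in (("LEV", lev_truth), ("BRV", brv_truth)):
            truth = {r: truth[r] for r in regions}
            design = StudyDesign(
                drug=drug,
                dose_mg=REFERENCE_DOSE[drug],
                seed=int(rng.integers(2**31 - 1)),
                noise_scale=noise_scale if noise_scale is not None
                else StudyDesign.noise_scale,
            )
            out[drug].append(
                generate_subject(design, truth=truth,
                                 subject=f"sub{i + 1:02d}", rng=rng)
            )
    return out
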