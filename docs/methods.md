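# Methods

## The model

`dispkin` models a PET displacement experiment in which a radiotracer and an
unlabeled drug compete for the same binding target (here the SV2A tracer
^11^C-UCB-J and the antiepileptic drugs levetiracetam, LEV, and brivaracetam,
BRV).  Both compounds enter brain tissue from plasma and bind reversibly to a
shared pool of sites of total concentration B_max.  The tracer contributes two
tissue states — non-displaceable C_ND(t) and specifically bound C_S(t), in
Bq/cm^3 — and the drug contributes the non-displaceable tissue concentration
D_ND(t) (nmol/L) and the target occupancy O(t) = D_S(t)/B_max.  In the
estimation form actually fitted:

    dC_ND/dt = K1·C_P(t) − (K1·f_ND/f_P)·C_ND
               − k_off·[(V_T·f_ND/f_P − 1)·(1 − O)·C_ND − C_S]
    dC_S/dt  =   k_off·[(V_T·f_ND/f_P − 1)·(1 − O)·C_ND − C_S]
    dD_ND/dt = K1^D·D_P(t) − (K1^D·f_ND^D/f_P^D)·D_ND
               − k_off^D·(K_D/f_ND)·(V_T·f_ND/f_P − 1)·[(f_ND^D/K_D^D)·(1 − O)·D_ND − O]
    dO/dt    =   k_off^D·[(f_ND^D/K_D^D)·(1 − O)·D_ND − O]

This is an exact reparameterization of the underlying mass-action system (in
k2 = K1·f_ND/f_P, k_on = k_off/K_D, B_max = K_D·(V_T·f_ND/f_P − 1)/f_ND, and
the drug analogues), under one approximation: the tracer occupies a negligible
fraction of the target, so the tracer-mass term C_S/M (M = molar activity) is
dropped.  `derive_secondary` converts between the two forms and the test suite
verifies that their right-hand sides agree to machine precision at arbitrary
states.

The measured PET signal is the frame-time-average of
(1 − v_B)·(C_ND + C_S) + v_B·C_WB with the blood volume fraction v_B fixed at
0.05.

Key identities used throughout:

* equilibrium occupancy under constant drug plasma level D_P:
  O_eq = f_P^D·D_P / (K_D^D + f_P^D·D_P);
* distribution volume: with constant tracer input and no drug, the tissue to
  plasma ratio converges to V_T.

## Parameters and defaults

Floating parameters of the 5p configuration (the primary analysis): K1 of the
tracer per scan (displacement and post-dose, mL plasma/min/cm^3 tissue), V_T
(mL/cm^3), f_ND (tracer tissue free fraction), and the drug entry rate K1^D
(stored in mL/cm^3/min, reported ×1000 as µL/cm^3/min).  The 7p configuration
additionally floats k_off and k_off^D; a 6p configuration adds exactly one of
the fixed constants.

Fixed constants (`FixedConstants.for_drug`): tracer K_D = 3.4 nmol/L;
k_off = 4.9 /min; drug plasma free fraction f_P^D = 0.90 (LEV) / 0.83 (BRV);
drug dissociation constant K_D^D = 21 µM (LEV) / 2 µM (BRV), stored in nmol/L;
drug tissue free fraction f_ND^D = 1.0 (LEV) / 0.88 (BRV); k_off^D = 4.9 (LEV)
/ 5.9 (BRV) /min; v_B = 0.05.  The tracer plasma free fraction f_P is a
per-scan measured quantity; synthetic studies use a nominal 0.30 for both
scans (the source study measured but did not publish per-scan values).

All concentrations are internally nmol/L (drug) and Bq/cm^3 (tracer); K_D^D
is converted from µM at the boundary.  Keeping a single internal unit system
avoids µM/nM mixing errors; reports convert K1^D to µL/cm^3/min.

## Numerics

The drug pair (D_ND, O) is independent of the tracer states, so it is solved
once per parameter vector with LSODA (rtol 1e-8, atol 1e-10) on a grid that is
dense (0.02 min) for the first 10 min after the infusion start, 0.1 min for
the next 50 min, and 1 min across the inter-scan gap.  Given O(t), the tracer
pair is a *linear* time-varying ODE; two solvers are provided:

* `lsoda` — the reference adaptive stiff path;
* `expm` — a piecewise matrix-exponential propagator (midpoint-frozen
  coefficient, linear forcing, substeps ≤ 0.05 min) used in the fitting hot
  loop; it agrees with the reference to < 0.1% sup-norm (tested), and with a
  fixed-step RK4 oracle at dt = 0.001 min to the same tolerance.

The fitting loop likewise solves the drug pair with a compiled fixed-step RK4
(`simulate_drug(method="rk4")`, step bounded by the reciprocal of the fastest
local rate, capped at 0.02 min), which matches the LSODA reference to ~1e-6
relative; everywhere else the adaptive solver is the default.

Tracer states restart at zero at each injection (the second scan starts
≥ 10 radionuclide half-lives after the first); drug states are continuous
across the gap on the absolute study clock.  The capacity term of the drug
equation is evaluated with the displacement-scan f_P so the drug trajectory
is single-valued across scans.  Frame averages use trapezoid quadrature on
11 points per frame.

Degenerate inputs: an all-zero drug input yields O ≡ 0 exactly; an all-zero
occupancy trajectory makes the occupancy metrics undefined (flagged, not
zero); parameter vectors with V_T·f_ND/f_P < 1 (negative binding capacity)
are rejected at the type level and clipped to the zero-capacity boundary
inside the optimizer so the fit can traverse that region smoothly.

## Fitting

`fit_joint` minimizes the weighted residual sum of squares over both scans'
frames simultaneously (66 frames for two full scans) with bound-constrained
trust-region least squares (`scipy.optimize.least_squares`, finite-difference
Jacobian).  Per-frame weights default to frame duration (uniform variance per
unit scan time); alternatives are `uniform`, `decay`
(w = Δt·e^{−λt_mid}, the noise-free part of the count-statistics variance
model) and `ivar` (full inverse variance using the measured frame values;
`model_based_weights` builds the same weights from a reference fit's
predicted values instead, which keeps them uncorrelated with the noise).
The weighting of the original analysis is not documented; duration weighting
is the general-purpose default.  The packaged bound studies use `decay`:
an F test on weighted residuals is only close to its nominal size when the
weights track the noise variance (the decay factor alone spans ~59x across a
scan), and weights built from noisy measured values at low-count frames
correlate with the residuals and inflate the test statistic.

Initialization: K1 and V_T from a preliminary one-tissue (1TC) fit to the
pre-drug 60 min; f_ND = 0.1; multi-start over K1^D ∈ {1, 10, 100}
µL/cm^3/min; floating dissociation rates start from both 1 /min and their
study-average fixed values (so nested fits never terminate above the 5p
optimum).  Lowest SS wins; ties go to the smallest scaled parameter norm.
Standard errors come from the Jacobian-based covariance at the optimum,
s²(JᵀJ)⁻¹ with s² = SS/(n − p), reported as percent rSE = 100·SE/|estimate|; a
singular normal matrix is flagged and yields rSE "unavailable" rather than a
number.

The rejected variant that lets tracer K1 change at the displacement time is
available behind `allow_k1_step=True` (off by default).

## Inference

* Nested models are compared with the F test
  F = ((SS_r − SS_f)/(p_f − p_r))/(SS_f/(n − p_f)).
* The conservative bound on the BRV/LEV entry-rate ratio fixes K1^D on a
  grid, refits the remaining parameters per subject, pools SS across the 4
  subjects, and compares against the pooled unconstrained fits with pooled
  degrees of freedom (one constrained parameter per subject; pooled n = sum of
  frames, pooled p_full = 5 per subject).  The bound is the last non-rejected
  grid value moving away from the optimum, bisected to 0.1 µL/cm^3/min on the
  boundary interval; p-monotonicity along the grid is checked and warned on.
  The ratio bound is lower-bound(BRV)/upper-bound(LEV), computed per region
  (per-region search is assumed; the source reports per-region bounds).
* Sensitivity: Test-1 style 6p refits with an F test against 5p; Test-2 style
  50%/200% perturbations of each fixed constant with percent-change tables
  (positive = perturbed fit higher than the 5p reference).
* Test–retest: 2·(test − retest)/(test + retest).

## Synthetic data

The generator reproduces the study conditions: bolus-plus-infusion tracer
administration with K_bol = 150 min (bolus = K_bol minutes' worth of
infusion; tri-exponential impulse response, a standard arterial shape chosen
here because the source gives none); a 33-frame, 120-min schedule (6×0.5,
3×1, 2×2, 22×5 min); a 5-min intravenous drug infusion starting 60 min after
tracer injection; a post-dose scan injected 4.5 h after dosing; drug plasma
samples at 1–60 min post-infusion-start plus pre/mid/end of the post-dose
scan; whole blood as plasma × 1.1; a parent-fraction curve decaying to 0.30
with a 50-min time constant.

Drug plasma kinetics are a *stand-in* (the study measured, never modelled,
drug plasma): a two-compartment disposition model (k10 = 0.0018, k12 = 0.04,
k21 = 0.06 /min — minutes-scale distribution, hours-scale elimination) whose
infusion rate is calibrated so the plasma level at the end of the displacement
scan implies a target equilibrium occupancy (default 0.85, configurable within
0.6–0.95, bracketing the reported maxima); dose in mg scales the curve
linearly from the drug's reference dose (1500 mg LEV / 100 mg BRV).
Critically, the forward simulation uses the *linearly interpolated sparse
samples* as the drug input — the same input function the fitting stage uses —
so noiseless datasets are exactly recoverable; the continuous PK curve only
generates the samples.

TAC noise is a count-statistics surrogate for decay-corrected PET: per-frame
independent Gaussian with SD = scale·sqrt(value·e^{λt_mid}/Δt), λ = ln2/20.4
min⁻¹ for ¹¹C; negatives are clipped at zero (clip count recorded).  The
default scale (18.0) was calibrated so that 5p fits of default synthetic
subjects show the qualitative uncertainty pattern of the human data — V_T rSE
a few percent, f_ND ~10%, K1^D by far the least precise (~20–30%) — while
keeping K1^D median recovery error under 25%.  The scale is larger than raw
scanner ROI counting noise because synthetic data are otherwise perfectly
model-consistent (ideal inputs, no lack of fit), so all parameter uncertainty
must come from frame noise.

What passing tests on synthetic data do *not* show: robustness to the
early-time lack of fit seen in real TACs, to sparse/imprecise drug sampling in
the first minutes of infusion, to metabolite- or dispersion-correction errors,
or to fixed constants that differ from their literature values in humans.

Ground truth defaults to the published 5-parameter population medians per
region (putamen, frontal cortex, cerebellum).  Multi-subject studies add
per-subject log-normal jitter (σ = 0.10) to the tracer parameters only; the
drug entry rate K1^D is treated as a population constant, because the
ratio-bound procedure searches a single fixed K1^D common to all subjects —
its estimand is the population entry rate, and per-subject entry-rate
variability would make every common value statistically inconsistent with a
pooled 4-subject fit.  Conservativeness experiments impose an exact BRV/LEV
entry-rate ratio on these population values.

## Problem sizes in the validation suite

The packaged validation experiments use: noiseless recovery over 2 drugs × 3
regions; 20 four-subject two-drug studies (true ratios 5/10/20, putamen,
5-point geometric grids spanning 0.25–2× (BRV) or 0.5–4× (LEV) the
precision-weighted pooled estimate, plus bisection refinement) for bound
conservativeness; 1000 replicates for the F-test size (nested polynomial
regression — the test statistic is generic in (SS, dof), and a linear null
makes a 1000-replicate calibration practical); 10 random parameter draws for
the RK4 solver oracle.  These sizes are the package's chosen defaults and are
what `scripts/acceptance.py` reports.

## Known limitations

* One competing drug; no voxelwise modelling; no radioactive-decay term (TACs
  are assumed decay-corrected); no arterial dispersion/delay correction.
* K1^D is weakly identified whenever drug entry is fast relative to the frame
  rate (the BRV regime) — the motivation for the ratio-bound procedure.
* The drug PK stand-in is not a fitted model of either drug; occupancy-timing
  numbers for LEV in particular depend on its shape.
* Whether the original analysis frame-averaged or midpoint-sampled model
  predictions is unknown; this package frame-averages (the midpoint value of
  a linear signal is the exact frame average, so the difference is second
  order).
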