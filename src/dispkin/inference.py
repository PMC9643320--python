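"""Model comparison and sensitivity analysis.

Implements the nested-model F test, the conservative grid search for the
statistically feasible extreme of the drug brain-entry rate K1D (used to put a
lower bound on the BRV/LEV entry-rate ratio), sensitivity scans over the fixed
constants, and the paired test-retest statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectDataset
from .fitting import FitResult, ModelConfig, fit_joint, model_config

__all__ = [
    "FTestResult",
    "BoundSearchResult",
    "f_test",
    "k1d_bound_search",
    "ratio_bound",
    "sensitivity_fixed_params",
    "sensitivity_one_extra",
    "test_retest",
]


@dataclass(frozen=True)
class FTestResult:
    F: float
    p_value: float
    df1: int
    df2: int


def f_test(ss_reduced: float, ss_full: float, p_reduced: int, p_full: int,
           n: int) -> FTestResult:
    """Nested-model F test on residual sums of squares.

    F = ((SS_r - SS_f)/(p_f - p_r)) / (SS_f/(n - p_f)), with p from the F
    distribution on (p_f - p_r, n - p_f) degrees of freedom.
    """
    if p_full <= p_reduced:
        raise ValueError("the full model must have more parameters than the reduced")
    if n <= p_full:
        raise ValueError(f"n = {n} must exceed the full parameter count {p_full}")
    if ss_full < 0 or ss_reduced < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_reduced < ss_full - 1e-9 * max(ss_full, 1.0):
        raise ValueError(
            f"invalid nesting: SS_reduced = {ss_reduced:.6g} < SS_full = {ss_full:.6g}"
        )
    df1 = p_full - p_reduced
    df2 = n - p_full
    num = max(ss_reduced - ss_full, 0.0) / df1
    den = ss_full / df2
    F = num / den if den > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2))
    return FTestResult(F=float(F), p_value=p, df1=df1, df2=df2)


# --- K1D bound search --------------------------------------------------------


@dataclass
class BoundSearchResult:
    """Trace and outcome of the constrained-K1D grid search."""

    drug: str
    region: str
    direction: str                 # "lower" | "upper"
    grid: np.ndarray               # fixed K1D values tried, uL/cm^3/min
    pooled_ss: np.ndarray          # constrained pooled SS per grid value; NaN
    F: np.ndarray                  # where the search stopped early (values
    p: np.ndarray                  # beyond the first rejection)
    ss_unconstrained: float
    k1d_unconstrained: np.ndarray  # per-subject estimates, uL/cm^3/min
    bound: float                   # uL/cm^3/min; NaN if outside the grid
    bound_in_grid: bool
    alpha: float
    monotone: bool                 # p monotone along the search direction
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k1d_fixed_uL": self.grid,
            "pooled_ss": self.pooled_ss,
            "F": self.F,
            "p": self.p,
        })


def k1d_bound_search(
    datasets: list,
    region: str,
    drug: str,
    direction: str,
    grid,
    alpha: float = 0.05,
    config: ModelConfig | str = "5p",
    refine_tol_uL: float = 0.1,
    refine: bool = True,
    full_fits: list | None = None,
    **fit_kw,
) -> BoundSearchResult:
    """Extreme K1D statistically consistent with a multi-subject dataset.

    For every grid value (uL/cm^3/min), K1D is fixed and the remaining model
    parameters are refitted per subject; the pooled constrained SS is compared
    with the pooled unconstrained SS by an F test whose degrees of freedom pool
    across subjects (one constrained parameter per subject).  The bound is the
    last grid value, moving away from the optimum in ``direction``, that is
    not rejected at ``alpha``; with ``refine=True`` the boundary interval is
    bisected down to ``refine_tol_uL``.
    """
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    grid = np.sort(np.asarray(grid, dtype=float))
    if isinstance(config, str):
        config = model_config(config)
    if "K1D" not in config.floating:
        raise ValueError("the bound search requires a config with floating K1D")

    if full_fits is None:
        full_fits = [fit_joint(ds, region, config=config, **fit_kw)
                     for ds in datasets]
    elif len(full_fits) != len(datasets):
        raise ValueError("full_fits must align with datasets")
    ss_full = float(sum(f.ss for f in full_fits))
    n = sum(f.n for f in full_fits)
    p_full = sum(f.n_params for f in full_fits)
    p_red = p_full - len(datasets)
    k1d_hat = np.array([f.estimates["K1D"] * 1000.0 for f in full_fits])
    # warm starts and constrained config: K1D becomes fixed
    starts = [dict(f.estimates) for f in full_fits]
    cfg_constr = ModelConfig(
        id=f"{config.id}-fixedK1D",
        floating=tuple(p for p in config.floating if p != "K1D"),
        fixed_overrides=dict(config.fixed_overrides),
    )

    # per-subject warm starts: chain from the nearest evaluated grid value
    solutions: dict = {}  # k1d_uL -> list of per-subject estimate dicts

    def constrained_ss(k1d_uL: float) -> float:
        if solutions:
            nearest = min(solutions, key=lambda v: abs(v - k1d_uL))
            warm = solutions[nearest]
        else:
            warm = [{k: v for k, v in s.items() if k != "K1D"} for s in starts]
        total = 0.0
        sols = []
        for ds, x0 in zip(datasets, warm):
            cfg = ModelConfig(
                id=cfg_constr.id, floating=cfg_constr.floating,
                fixed_overrides={**cfg_constr.fixed_overrides,
                                 "K1D": k1d_uL / 1000.0},
            )
            res = fit_joint(ds, region, config=cfg, x0=dict(x0), **fit_kw)
            total += res.ss
            sols.append(dict(res.estimates))
        solutions[k1d_uL] = sols
        return total

    # evaluate the grid moving in the search direction; the grid may extend
    # past the pooled optimum, so p can first rise then fall.  Stop once a
    # rejection follows an acceptance (the far edge of the accepted region).
    order = np.argsort(grid)[::-1] if direction == "lower" else np.argsort(grid)
    ss_c = np.full(len(grid), np.nan)
    F = np.full(len(grid), np.nan)
    p = np.full(len(grid), np.nan)
    seen_accept = False
    for j in order:
        ss_c[j] = constrained_ss(float(grid[j]))
        t = f_test(max(ss_c[j], ss_full), ss_full, p_red, p_full, n)
        F[j], p[j] = t.F, t.p_value
        if t.p_value >= alpha:
            seen_accept = True
        elif seen_accept:
            break

    warnings_ = []
    if np.any(ss_c < ss_full - 1e-6 * max(ss_full, 1.0)):
        warnings_.append(
            "constrained pooled SS fell below the unconstrained optimum; "
            "unconstrained fits may not be at the global minimum"
        )

    p_ord = p[order]
    evaluated = ~np.isnan(p_ord)
    accepted = evaluated & (p_ord >= alpha)
    # p should fall moving away from the accepted region toward the bound
    acc_idx = np.nonzero(accepted)[0]
    if acc_idx.size:
        tail = p_ord[acc_idx[-1]:][evaluated[acc_idx[-1]:]]
        mono = bool(np.all(np.diff(tail) <= 1e-3))
    else:
        mono = True
    if not mono:
        warnings_.append("p-values are not monotone beyond the accepted region")
    if acc_idx.size and np.any(~accepted[acc_idx[0]:acc_idx[-1] + 1]
                               & evaluated[acc_idx[0]:acc_idx[-1] + 1]):
        warnings_.append("accepted grid values are not contiguous")

    if not acc_idx.size:
        bound, in_grid = float("nan"), False
        warnings_.append("all grid values rejected; bound lies outside the grid")
    else:
        # furthest accepted value in the search direction
        last = acc_idx[-1]
        bound = float(grid[order][last])
        in_grid = True
        if refine and last + 1 < len(order) and evaluated[last + 1]:
            a, b = grid[order][last], grid[order][last + 1]
            while abs(b - a) > refine_tol_uL:
                mid = 0.5 * (a + b)
                ssc = max(constrained_ss(mid), ss_full)
                if f_test(ssc, ss_full, p_red, p_full, n).p_value >= alpha:
                    a = mid
                else:
                    b = mid
            bound = float(a)

    return BoundSearchResult(
        drug=drug, region=region, direction=direction, grid=grid,
        pooled_ss=ss_c, F=F, p=p, ss_unconstrained=ss_full,
        k1d_unconstrained=k1d_hat, bound=bound, bound_in_grid=in_grid,
        alpha=alpha, monotone=mono, warnings=warnings_,
    )


def ratio_bound(brv_lower: BoundSearchResult,
                lev_upper: BoundSearchResult) -> float:
    """Conservative lower bound on the BRV/LEV entry-rate ratio."""
    if not (brv_lower.bound_in_grid and lev_upper.bound_in_grid):
        return float("nan")
    return brv_lower.bound / lev_upper.bound


# --- sensitivity analyses ----------------------------------------------------

SENSITIVITY_PARAMS = ("koff", "koffD", "KD", "KDD", "fPD", "fNDD")
SENSITIVITY_QUANTITIES = ("VT", "fND", "K1_disp", "K1_post", "K1D", "SS")


def sensitivity_fixed_params(
    dataset: SubjectDataset,
    region: str,
    params=SENSITIVITY_PARAMS,
    factors=(0.5, 2.0),
    reference: FitResult | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Percent change of the 5p estimates when one fixed constant is scaled.

    Positive values mean the perturbed-constant fit is higher than the
    reference 5p fit.  Returns a tidy table (parameter, factor, quantity,
    percent_change).
    """
    if isinstance(params, str):
        params = (params,)
    ref = reference or fit_joint(dataset, region, config="5p", **fit_kw)
    if not ref.converged:
        raise RuntimeError("reference 5p fit did not converge")
    rows = []
    for param in params:
        if param not in SENSITIVITY_PARAMS:
            raise ValueError(f"{param!r} is not a fixed constant of the 5p model")
        for factor in factors:
            from .model import FixedConstants
            base = FixedConstants.for_drug(dataset.drug)
            cfg = model_config(
                "5p", fixed_overrides={param: getattr(base, param) * factor}
            )
            alt = fit_joint(dataset, region, config=cfg,
                            x0=dict(ref.estimates), **fit_kw)
            for q in SENSITIVITY_QUANTITIES:
                ref_v = ref.ss if q == "SS" else ref.estimates[q]
                alt_v = alt.ss if q == "SS" else alt.estimates[q]
                rows.append({
                    "parameter": param,
                    "factor": factor,
                    "quantity": q,
                    "percent_change": 100.0 * (alt_v - ref_v) / ref_v,
                })
    return pd.DataFrame(rows)


def sensitivity_one_extra(
    dataset: SubjectDataset,
    region: str,
    extra_param: str,
    reference: FitResult | None = None,
    **fit_kw,
) -> tuple[FitResult, FTestResult]:
    """6p fit (5p + one previously fixed parameter) and its F test vs 5p."""
    ref = reference or fit_joint(dataset, region, config="5p", **fit_kw)
    fit6 = fit_joint(dataset, region, config=f"6p:{extra_param}",
                     x0=dict(ref.estimates), **fit_kw)
    ss6 = min(fit6.ss, ref.ss)  # guard tiny optimizer noise in the nesting
    test = f_test(ref.ss, ss6, ref.n_params, fit6.n_params, ref.n)
    return fit6, test


def test_retest(test_value: float, retest_value: float) -> float:
    """Signed paired difference: 2*(test - retest)/(test + retest)."""
    s = test_value + retest_value
    if s <= 0:
        raise ValueError("test + retest must be positive")
    return 2.0 * (test_value - retest_value) / s
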