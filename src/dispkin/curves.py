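"""Input curves: sampled time series and the bolus-plus-infusion tracer input.

All curves live on an absolute study clock in minutes (tracer injection of the
first scan at t = 0).  Interpolation between samples is linear; outside the
sampled support a curve is held at its first/last value.  Curves that are zero
before an event (drug infusion, tracer injection) carry an explicit leading
zero sample at the event time so the hold-at-edge policy returns 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CURVE_KINDS = ("tracer-plasma", "whole-blood", "parent-fraction", "drug-plasma")


@dataclass(frozen=True)
class SampledCurve:
    """A non-negative concentration (or fraction) time series.

    Parameters
    ----------
    times : array of minutes, strictly increasing.
    values : array of concentrations; Bq/mL for radioactivity, nmol/L for drug,
        dimensionless in [0, 1] for parent fraction.
    kind : one of ``CURVE_KINDS``.
    units : unit tag carried through I/O.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "tracer-plasma"
    units: str = "Bq/mL"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("curve must have at least one sample")
        if v.shape != t.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError(f"{self.kind} curve has negative values")
        if self.kind == "parent-fraction" and np.any(v > 1.0):
            raise ValueError("parent-fraction values must lie in [0, 1]")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def __call__(self, t):
        """Linear interpolation; held at the first/last sample outside."""
        return np.interp(t, self.times, self.values)

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def shifted(self, dt: float) -> "SampledCurve":
        return replace(self, times=self.times + dt)

    def scaled(self, factor: float) -> "SampledCurve":
        return replace(self, values=self.values * factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "value": self.values,
                "units": self.units,
                "kind": self.kind,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path) -> "SampledCurve":
        df = pd.read_csv(path)
        for col in ("time_min", "value", "units", "kind"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(
            times=df["time_min"].to_numpy(float),
            values=df["value"].to_numpy(float),
            kind=str(df["kind"].iloc[0]),
            units=str(df["units"].iloc[0]),
        )


def interpolate(curve: SampledCurve, t) -> np.ndarray:
    """Evaluate ``curve`` at time(s) ``t`` (linear, held at the edges)."""
    return curve(t)


def metabolite_correct(
    total_plasma: SampledCurve, parent_fraction: SampledCurve
) -> SampledCurve:
    """Metabolite-corrected plasma input: pointwise product on the union grid.

    The product of the two piecewise-linear interpolants is evaluated at every
    node of either input, so the result is exact at all original sample times.
    """
    if parent_fraction.kind != "parent-fraction":
        raise ValueError("second argument must be a parent-fraction curve")
    lo = max(total_plasma.start, parent_fraction.start)
    hi = min(total_plasma.end, parent_fraction.end)
    if hi <= lo:
        raise ValueError("curves have no overlapping time support")
    grid = np.union1d(total_plasma.times, parent_fraction.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    return SampledCurve(
        times=grid,
        values=total_plasma(grid) * parent_fraction(grid),
        kind=total_plasma.kind,
        units=total_plasma.units,
    )


# --- bolus + infusion tracer administration ---------------------------------

#: Tri-exponential bolus impulse response used for synthesis:
#: amplitudes (arbitrary activity units) and decay rates (1/min) of a fast
#: distribution phase, an intermediate phase and a slow terminal phase.
DEFAULT_BOLUS_AMPLITUDES = (60.0, 8.0, 2.5)
DEFAULT_BOLUS_RATES = (3.0, 0.25, 0.012)


@dataclass(frozen=True)
class BolusShape:
    """Tri-exponential impulse response h(t) = sum_i A_i exp(-lambda_i t)."""

    amplitudes: tuple = DEFAULT_BOLUS_AMPLITUDES
    rates: tuple = DEFAULT_BOLUS_RATES

    def __post_init__(self):
        if len(self.amplitudes) != len(self.rates):
            raise ValueError("amplitudes and rates must have equal length")
        if any(a < 0 for a in self.amplitudes) or any(r <= 0 for r in self.rates):
            raise ValueError("amplitudes must be >= 0 and rates > 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in zip(self.amplitudes, self.rates):
            out += a * np.exp(-lam * t)
        return out

    def integral(self, t):
        """Running integral of h from 0 to t (closed form)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, lam in zip(self.amplitudes, self.rates):
            out += a / lam * (1.0 - np.exp(-lam * t))
        return out

    @property
    def total_integral(self) -> float:
        return float(sum(a / lam for a, lam in zip(self.amplitudes, self.rates)))


def bolus_fraction(kbol: float, scan_duration: float) -> float:
    """Fraction of the administered dose given as bolus.

    A bolus-plus-infusion protocol splits the dose so that the bolus equals
    ``kbol`` minutes' worth of the constant infusion; over a scan of length T
    the bolus fraction is Kbol / (Kbol + T).
    """
    if kbol <= 0:
        raise ValueError("Kbol must be positive")
    return kbol / (kbol + scan_duration)


def bolus_infusion_input(
    shape: BolusShape | None = None,
    kbol: float = 150.0,
    scan_duration: float = 120.0,
    amplitude: float = 1.0,
    dt: float = 0.1,
    kind: str = "tracer-plasma",
    units: str = "Bq/mL",
) -> SampledCurve:
    """Plasma shape of a bolus + constant-infusion administration.

    The bolus response is ``amplitude * h(t)``; the infusion contributes the
    running integral of the same impulse response scaled by 1/Kbol, so the
    late-time curve approaches the plateau ``amplitude / Kbol * int_0^inf h``.
    """
    if kbol <= 0:
        raise ValueError("Kbol must be positive")
    shape = shape or BolusShape()
    t = np.arange(0.0, scan_duration + dt / 2, dt)
    v = amplitude * (shape(t) + shape.integral(t) / kbol)
    return SampledCurve(times=t, values=v, kind=kind, units=units)


# --- frame schedule ----------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frames (minutes relative to injection)."""

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start, dtype=float)
        d = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", s)
        object.__setattr__(self, "duration", d)
        if s.shape != d.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("start and duration must be equal-length 1-d arrays")
        if np.any(d <= 0):
            raise ValueError("frame durations must be positive")
        gaps = s[1:] - (s[:-1] + d[:-1])
        if np.any(np.abs(gaps) > 1e-9):
            bad = np.nonzero(np.abs(gaps) > 1e-9)[0]
            raise ValueError(
                f"frames must be contiguous and non-overlapping; "
                f"violations after frame indices {bad.tolist()}"
            )

    @classmethod
    def default(cls) -> "FrameSchedule":
        """33-frame 120-min schedule: 6x0.5, 3x1, 2x2, 22x5 min."""
        d = np.concatenate([
            np.full(6, 0.5), np.full(3, 1.0), np.full(2, 2.0), np.full(22, 5.0),
        ])
        s = np.concatenate([[0.0], np.cumsum(d)[:-1]])
        return cls(start=s, duration=d)

    def __len__(self) -> int:
        return self.start.size

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def midpoint(self) -> np.ndarray:
        return self.start + self.duration / 2

    @property
    def span(self) -> float:
        return float(self.end[-1] - self.start[0])

    def shifted(self, dt: float) -> "FrameSchedule":
        return FrameSchedule(start=self.start + dt, duration=self.duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_min": self.start, "duration_min": self.duration})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path)
        for col in ("start_min", "duration_min"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(
            start=df["start_min"].to_numpy(float),
            duration=df["duration_min"].to_numpy(float),
        )
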