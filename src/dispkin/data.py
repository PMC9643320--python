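"""Study data containers: per-scan measurements and the subject-level bundle."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import FrameSchedule, SampledCurve

SCAN_ROLES = ("displacement", "post-dose")


@dataclass(frozen=True)
class ScanData:
    """One PET scan: frame schedule, regional TACs and its input curves.

    Frames are relative to ``injection_time``; all curves are on the absolute
    study clock.  TAC values are decay-corrected Bq/cm^3.
    """

    role: str
    injection_time: float
    frames: FrameSchedule
    tacs: dict  # region -> np.ndarray, one value per frame
    plasma: SampledCurve          # metabolite-corrected tracer plasma
    whole_blood: SampledCurve
    fP: float
    parent_fraction: SampledCurve | None = None

    def __post_init__(self):
        if self.role not in SCAN_ROLES:
            raise ValueError(f"unknown scan role {self.role!r}")
        if not (0.0 < self.fP <= 1.0):
            raise ValueError("fP must lie in (0, 1]")
        for region, v in self.tacs.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.frames),):
                raise ValueError(
                    f"TAC for {region!r} has {v.size} values "
                    f"but the schedule has {len(self.frames)} frames"
                )

    @property
    def regions(self) -> list:
        return list(self.tacs)

    @property
    def end_time(self) -> float:
        return self.injection_time + float(self.frames.end[-1])


@dataclass(frozen=True)
class SubjectDataset:
    """Displacement + post-dose scan pair with the drug input on one clock."""

    subject: str
    drug: str                      # "LEV" | "BRV"
    dose_mg: float
    displacement: ScanData
    postdose: ScanData
    drug_plasma: SampledCurve      # sparse samples, linearly interpolated
    infusion_start: float
    infusion_duration: float = 5.0
    truth: dict | None = None      # generation sidecar (synthetic data only)

    def __post_init__(self):
        if self.drug.upper() not in ("LEV", "BRV"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.displacement.role != "displacement":
            raise ValueError("first scan must have role 'displacement'")
        if self.postdose.role != "post-dose":
            raise ValueError("second scan must have role 'post-dose'")
        if not (
            self.displacement.injection_time
            <= self.infusion_start
            <= self.displacement.end_time
        ):
            raise ValueError("drug infusion must start inside the displacement scan")
        if self.postdose.injection_time < self.displacement.end_time:
            raise ValueError("post-dose scan must start after the displacement scan")

    @property
    def scans(self) -> tuple:
        return (self.displacement, self.postdose)

    @property
    def regions(self) -> list:
        return self.displacement.regions

    def timeline(self):
        from .model import Timeline

        return Timeline(
            injections=(self.displacement.injection_time, self.postdose.injection_time),
            scan_ends=(self.displacement.end_time, self.postdose.end_time),
            infusion_start=self.infusion_start,
        )
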