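"""Dataset directory I/O.

A subject dataset is a directory of plain CSV/JSON files::

    meta.json                     subject, drug, dose_mg, fP per scan,
                                  injection times, infusion start/duration
    frames_displacement.csv       start_min, duration_min
    frames_postdose.csv
    tac_displacement.csv          region, start_min, duration_min, value, units
    tac_postdose.csv
    plasma_displacement.csv       time_min, value, units, kind
    plasma_postdose.csv
    wholeblood_displacement.csv
    wholeblood_postdose.csv
    parentfraction_displacement.csv   (optional)
    parentfraction_postdose.csv       (optional)
    drug_plasma.csv
    truth.json                    (optional ground-truth sidecar)

All times are minutes on the absolute study clock (first injection at 0).
Numeric round trips are exact to >= 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FrameSchedule, SampledCurve
from .data import ScanData, SubjectDataset

_ROLE_TAG = {"displacement": "displacement", "post-dose": "postdose"}
_FLOAT_FMT = "%.15g"


def write_dataset(dataset: SubjectDataset, out_dir) -> Path:
    """Write a SubjectDataset to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject": dataset.subject,
        "drug": dataset.drug,
        "dose_mg": dataset.dose_mg,
        "infusion_start": dataset.infusion_start,
        "infusion_duration": dataset.infusion_duration,
        "scans": {},
    }
    for scan in dataset.scans:
        tag = _ROLE_TAG[scan.role]
        meta["scans"][tag] = {
            "role": scan.role,
            "injection_time": scan.injection_time,
            "fP": scan.fP,
        }
        scan.frames.to_csv(out / f"frames_{tag}.csv")
        rows = []
        for region, values in scan.tacs.items():
            for s, d, v in zip(scan.frames.start, scan.frames.duration, values):
                rows.append((region, s, d, v, "Bq/cm^3"))
        pd.DataFrame(
            rows, columns=["region", "start_min", "duration_min", "value", "units"]
        ).to_csv(out / f"tac_{tag}.csv", index=False, float_format=_FLOAT_FMT)
        scan.plasma.to_csv(out / f"plasma_{tag}.csv")
        scan.whole_blood.to_csv(out / f"wholeblood_{tag}.csv")
        if scan.parent_fraction is not None:
            scan.parent_fraction.to_csv(out / f"parentfraction_{tag}.csv")
    dataset.drug_plasma.to_csv(out / "drug_plasma.csv")
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if dataset.truth is not None:
        (out / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"dataset is missing required file: {path}")
    return path


def _read_tacs(path: Path, frames: FrameSchedule) -> dict:
    df = pd.read_csv(path)
    for col in ("region", "start_min", "duration_min", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    tacs = {}
    for region, grp in df.groupby("region", sort=False):
        if len(grp) != len(frames):
            raise ValueError(
                f"{path}: region {region!r} has {len(grp)} frames, "
                f"schedule has {len(frames)}"
            )
        if not np.allclose(grp["start_min"].to_numpy(float), frames.start):
            raise ValueError(f"{path}: frame starts for {region!r} do not match "
                             "the frame schedule")
        tacs[str(region)] = grp["value"].to_numpy(float)
    return tacs


def read_dataset(in_dir) -> SubjectDataset:
    """Read a SubjectDataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    meta = json.loads(_require(d / "meta.json").read_text())
    scans = {}
    for tag, sm in meta["scans"].items():
        frames = FrameSchedule.from_csv(_require(d / f"frames_{tag}.csv"))
        # frames are stored relative to injection
        tacs = _read_tacs(_require(d / f"tac_{tag}.csv"), frames)
        plasma = SampledCurve.from_csv(_require(d / f"plasma_{tag}.csv"))
        wb = SampledCurve.from_csv(_require(d / f"wholeblood_{tag}.csv"))
        pf_path = d / f"parentfraction_{tag}.csv"
        pf = SampledCurve.from_csv(pf_path) if pf_path.exists() else None
        scans[tag] = ScanData(
            role=sm["role"], injection_time=float(sm["injection_time"]),
            frames=frames, tacs=tacs, plasma=plasma, whole_blood=wb,
            fP=float(sm["fP"]), parent_fraction=pf,
        )
    truth_path = d / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return SubjectDataset(
        subject=str(meta["subject"]), drug=str(meta["drug"]),
        dose_mg=float(meta["dose_mg"]),
        displacement=scans["displacement"], postdose=scans["postdose"],
        drug_plasma=SampledCurve.from_csv(_require(d / "drug_plasma.csv")),
        infusion_start=float(meta["infusion_start"]),
        infusion_duration=float(meta["infusion_duration"]),
        truth=truth,
    )


def write_fit_results(results: list, path) -> pd.DataFrame:
    """Fit results as one CSV row per (region x config), with a JSON sidecar
    of diagnostics next to it."""
    rows, diag = [], {}
    for r in results:
        row = {"config": r.config_id, "region": r.region, "ss": r.ss, "n": r.n,
               "converged": r.converged}
        for name, v in r.estimates.items():
            out_name = f"{name}_uL" if name == "K1D" else name
            row[out_name] = v * 1000.0 if name == "K1D" else v
            row[f"rse_{name}_pct"] = r.rse.get(name, float("nan"))
        rows.append(row)
        diag[f"{r.region}:{r.config_id}"] = {
            "message": r.message, "nfev": r.nfev, "at_bound": r.at_bound,
            "se_available": r.se_available,
        }
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    path.with_suffix(".diagnostics.json").write_text(json.dumps(diag, indent=2))
    return df
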