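"""CSV interchange formats and configuration loading.

All stages exchange plain UTF-8 comma-separated files with a header row and
'.' decimals. Schemas (units):

- participants: ``participant_id,age,sex,mass,height,dominant_side``
  (years, kg, m)
- recordings:   ``participant_id,location,t,x,y,z`` (s, g, g, g)
- breaths:      ``participant_id,t,vo2,vco2`` (s, L/min, L/min)
- bouts:        ``participant_id,activity_label,start,end,cadence,is_fms``
- epochs:       ``participant_id,location,epoch_start,epoch_length,svm_gs``
- mets:         ``participant_id,epoch_start,epoch_length,ee_rate,met,intensity``
  (missing calorimetry epochs have empty met/intensity)
- labeled:      the join of epochs and mets (see alignment.LABELED_COLUMNS)
- cutpoints:    ``location,intensity,auc,ci_low,ci_high,sensitivity,specificity,cut_low,cut_high``
  mirroring the published cut-point table layout: sedentary/moderate rows
  carry a single cut-point (cut_low == cut_high), light rows the band, and
  FMS rows use intensity ``fms``.

Recordings round-trip to 6 decimal places.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import LABELED_COLUMNS, BoutAnnotation
from .crossval import ValidationReport
from .energy import BreathSeries, MetSeries
from .roc import CalibrationReport
from .signal import EpochSeries, TriaxialRecording
from .synthetic import ActivitySpec, ParticipantProfile, SimulationConfig, StudyBundle


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, path, cols: list[str]) -> pd.DataFrame:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed value in column {c!r} at line {line}")
        df[c] = vals
    return df


# -- participants -----------------------------------------------------------

def write_participants_csv(participants: list[ParticipantProfile], path) -> None:
    pd.DataFrame([asdict(p) for p in participants]).rename(
        columns={"id": "participant_id"}
    ).to_csv(path, index=False)


def read_participants_csv(path) -> list[ParticipantProfile]:
    df = _read_csv(path, ["participant_id", "age", "sex", "mass", "height", "dominant_side"])
    df = _numeric(df, path, ["age", "mass", "height"])
    return [
        ParticipantProfile(
            id=str(r.participant_id),
            age=float(r.age),
            sex=str(r.sex),
            mass=float(r.mass),
            height=float(r.height),
            dominant_side=str(r.dominant_side),
        )
        for r in df.itertuples()
    ]


# -- recordings -------------------------------------------------------------

def write_recordings_csv(recordings: list[TriaxialRecording], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": r.participant_id,
                "location": r.location,
                "t": r.t,
                "x": r.x,
                "y": r.y,
                "z": r.z,
            }
        )
        for r in recordings
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_recordings_csv(path) -> list[TriaxialRecording]:
    """Read a recordings CSV, one TriaxialRecording per (participant,
    location) in first-appearance order; sampling rate inferred from the
    smallest time step."""
    df = _read_csv(path, ["participant_id", "location", "t", "x", "y", "z"])
    df = _numeric(df, path, ["t", "x", "y", "z"])
    out = []
    for (pid, loc), sub in df.groupby(["participant_id", "location"], sort=False):
        t = sub["t"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                line = int(sub.index[np.argmax(dt <= 0) + 1]) + 2
                raise ValueError(f"{path}: non-monotone timestamp at line {line}")
            rate = 1.0 / float(np.min(dt))
        else:
            rate = 1.0
        out.append(
            TriaxialRecording(
                participant_id=str(pid),
                location=str(loc),
                sampling_rate=float(np.round(rate, 6)),
                t=t,
                x=sub["x"].to_numpy(dtype=float),
                y=sub["y"].to_numpy(dtype=float),
                z=sub["z"].to_numpy(dtype=float),
            )
        )
    return out


# -- breaths ----------------------------------------------------------------

def write_breaths_csv(breaths: list[BreathSeries], path) -> None:
    frames = [
        pd.DataFrame({"participant_id": b.participant_id, "t": b.t, "vo2": b.vo2, "vco2": b.vco2})
        for b in breaths
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_breaths_csv(path) -> list[BreathSeries]:
    df = _read_csv(path, ["participant_id", "t", "vo2", "vco2"])
    df = _numeric(df, path, ["t", "vo2", "vco2"])
    return [
        BreathSeries(
            participant_id=str(pid),
            t=sub["t"].to_numpy(dtype=float),
            vo2=sub["vo2"].to_numpy(dtype=float),
            vco2=sub["vco2"].to_numpy(dtype=float),
        )
        for pid, sub in df.groupby("participant_id", sort=False)
    ]


# -- bouts ------------------------------------------------------------------

def write_bouts_csv(bouts: list[BoutAnnotation], path) -> None:
    pd.DataFrame([asdict(b) for b in bouts]).to_csv(path, index=False)


def read_bouts_csv(path) -> list[BoutAnnotation]:
    df = _read_csv(path, ["participant_id", "activity_label", "start", "end", "cadence", "is_fms"])
    df = _numeric(df, path, ["start", "end", "cadence"])
    return [
        BoutAnnotation(
            participant_id=str(r.participant_id),
            activity_label=str(r.activity_label),
            start=float(r.start),
            end=float(r.end),
            cadence=float(r.cadence),
            is_fms=bool(r.is_fms),
        )
        for r in df.itertuples()
    ]


# -- epochs and mets --------------------------------------------------------

def write_epochs_csv(epochs: list[EpochSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": e.participant_id,
                "location": e.location,
                "epoch_start": e.epoch_start,
                "epoch_length": e.epoch_length,
                "svm_gs": e.svm_gs,
            }
        )
        for e in epochs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epochs_csv(path) -> list[EpochSeries]:
    df = _read_csv(path, ["participant_id", "location", "epoch_start", "epoch_length", "svm_gs"])
    df = _numeric(df, path, ["epoch_start", "epoch_length", "svm_gs"])
    return [
        EpochSeries(
            participant_id=str(pid),
            location=str(loc),
            epoch_length=float(sub["epoch_length"].iloc[0]),
            epoch_start=sub["epoch_start"].to_numpy(dtype=float),
            svm_gs=sub["svm_gs"].to_numpy(dtype=float),
        )
        for (pid, loc), sub in df.groupby(["participant_id", "location"], sort=False)
    ]


def write_mets_csv(mets: list[MetSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": m.participant_id,
                "epoch_start": m.epoch_start,
                "epoch_length": m.epoch_length,
                "ee_rate": m.ee_rate,
                "met": m.met,
                "intensity": [i if i is not None else "" for i in m.intensity],
            }
        )
        for m in mets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_mets_csv(path) -> list[MetSeries]:
    df = _read_csv(
        path, ["participant_id", "epoch_start", "epoch_length", "ee_rate", "met", "intensity"]
    )
    df = _numeric(df, path, ["epoch_start", "epoch_length", "ee_rate", "met"])
    out = []
    for pid, sub in df.groupby("participant_id", sort=False):
        intensity = [
            None if (isinstance(i, float) and np.isnan(i)) or i == "" else str(i)
            for i in sub["intensity"]
        ]
        out.append(
            MetSeries(
                participant_id=str(pid),
                epoch_length=float(sub["epoch_length"].iloc[0]),
                epoch_start=sub["epoch_start"].to_numpy(dtype=float),
                ee_rate=sub["ee_rate"].to_numpy(dtype=float),
                met=sub["met"].to_numpy(dtype=float),
                intensity=intensity,
            )
        )
    return out


# -- labelled table ---------------------------------------------------------

def write_labeled_csv(table: pd.DataFrame, path) -> None:
    table[LABELED_COLUMNS].to_csv(path, index=False)


def read_labeled_csv(path) -> pd.DataFrame:
    df = _read_csv(path, LABELED_COLUMNS)
    df = _numeric(df, path, ["epoch_start", "svm_gs", "met"])
    df["is_fms"] = df["is_fms"].astype(bool)
    return df[LABELED_COLUMNS]


# -- calibration / validation reports ---------------------------------------

def calibration_to_frame(report: CalibrationReport) -> pd.DataFrame:
    """Cut-point table in the published layout (sedentary, light band,
    moderate, FMS rows per location)."""
    rows = []
    for loc, cps in report.cutpoints.items():
        for r in (cps.sedentary, cps.moderate):
            rows.append(
                {
                    "location": loc,
                    "intensity": r.positive_class,
                    "auc": r.auc,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "cut_low": r.cutpoint,
                    "cut_high": r.cutpoint,
                    "grade": r.grade,
                }
            )
        rows.append(
            {
                "location": loc,
                "intensity": "light",
                "auc": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "sensitivity": np.nan,
                "specificity": np.nan,
                "cut_low": cps.light_band[0],
                "cut_high": cps.light_band[1],
                "grade": "",
            }
        )
    for loc, r in report.fms.items():
        rows.append(
            {
                "location": loc,
                "intensity": "fms",
                "auc": r.auc,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "cut_low": r.cutpoint,
                "cut_high": r.cutpoint,
                "grade": r.grade,
            }
        )
    order = {"sedentary": 0, "light": 1, "moderate": 2, "fms": 3}
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["intensity", "location"], key=lambda s: s.map(order).fillna(s), kind="stable"
    ).reset_index(drop=True)


def write_cutpoints_csv(report: CalibrationReport, path) -> None:
    calibration_to_frame(report).to_csv(path, index=False)


def read_cutpoints_csv(path) -> dict[str, tuple[float, float]]:
    """Fixed (sedentary, moderate) cut-points per location from a cut-point CSV."""
    df = _read_csv(path, ["location", "intensity", "cut_low", "cut_high"])
    df = _numeric(df, path, ["cut_low", "cut_high"])
    cuts: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        if r.intensity in ("sedentary", "moderate"):
            cuts.setdefault(str(r.location), {})[str(r.intensity)] = float(r.cut_low)
    out = {}
    for loc, d in cuts.items():
        if "sedentary" not in d or "moderate" not in d:
            raise ValueError(f"{path}: location {loc!r} lacks sedentary or moderate cut-point")
        out[loc] = (d["sedentary"], d["moderate"])
    if not out:
        raise ValueError(f"{path}: no usable cut-point rows")
    return out


def write_validation_csv(report: ValidationReport, path) -> None:
    report.to_frame().to_csv(path, index=False)


def calibration_summary(report: CalibrationReport) -> str:
    """Human-readable calibration summary (normality gate, criterion
    validity, graded discrimination, cut-points)."""
    lines = []
    for loc in report.locations:
        cps = report.cutpoints[loc]
        rho, p = report.spearman[loc]
        norm = report.normality[loc]
        lines.append(f"[{loc}]")
        lines.append(
            f"  counts normality: W={norm.statistic:.3f} p={norm.p_value:.2g} "
            f"-> {'normal' if norm.normal else 'non-normal'} (rank statistics used)"
        )
        lines.append(f"  Spearman rho vs METs: {rho:.3f} (p={p:.2g})")
        for r in (cps.sedentary, cps.moderate):
            lines.append(
                f"  {r.positive_class}: AUC {r.auc:.3f} "
                f"({r.ci95[0]:.3f}-{r.ci95[1]:.3f}, {r.grade}), "
                f"Se {r.sensitivity:.1f}% Sp {r.specificity:.1f}%, "
                f"cut-point {r.cutpoint:.1f} g*s"
            )
        lines.append(f"  light band: {cps.light_band[0]:.1f}-{cps.light_band[1]:.1f} g*s")
        if loc in report.fms:
            r = report.fms[loc]
            lines.append(
                f"  fms: AUC {r.auc:.3f} ({r.ci95[0]:.3f}-{r.ci95[1]:.3f}, {r.grade}), "
                f"Se {r.sensitivity:.1f}% Sp {r.specificity:.1f}%, "
                f"cut-point {r.cutpoint:.1f} g*s"
            )
    return "\n".join(lines) + "\n"


# -- study bundle and configuration -----------------------------------------

BUNDLE_FILES = {
    "participants": "participants.csv",
    "recordings": "recordings.csv",
    "breaths": "breaths.csv",
    "bouts": "bouts.csv",
}


def write_bundle(bundle: StudyBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_participants_csv(bundle.participants, d / BUNDLE_FILES["participants"])
    write_recordings_csv(bundle.recordings, d / BUNDLE_FILES["recordings"])
    write_breaths_csv(bundle.breaths, d / BUNDLE_FILES["breaths"])
    write_bouts_csv(bundle.bouts, d / BUNDLE_FILES["bouts"])


def load_config(path, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file (top-level keys mirror the
    dataclass fields; ``activities`` is a list of activity mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "activities" in raw:
        raw["activities"] = tuple(ActivitySpec(**a) for a in raw["activities"])
    if "wear_locations" in raw:
        raw["wear_locations"] = tuple(raw["wear_locations"])
    for key in ("age_range", "rer_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = seed
    return SimulationConfig(**raw)
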