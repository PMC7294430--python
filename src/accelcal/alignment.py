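"""Bout trimming, steady-state screening, and the count↔MET join.

Each 5 min activity bout is trimmed to its steady-state analysis window
(discard the first 2 min and the last 1 min, keep minutes 2–4). Every 1 s
accelerometer epoch inside a trimmed window inherits the MET value and
intensity category of the 10 s calorimetry epoch containing its start time,
yielding the pooled labelled table the ROC statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import MetSeries
from .signal import EpochSeries

TRIM_LEAD = 120.0  # s discarded at bout start
WINDOW_LENGTH = 120.0  # s analysed per bout

LABELED_COLUMNS = [
    "participant_id",
    "location",
    "epoch_start",
    "svm_gs",
    "met",
    "intensity",
    "activity_label",
    "is_fms",
]


@dataclass(frozen=True)
class BoutAnnotation:
    participant_id: str
    activity_label: str
    start: float
    end: float
    cadence: float  # events/min; 0 for continuous activities
    is_fms: bool


@dataclass(frozen=True)
class SteadyStateResult:
    cv: float
    passed: bool
    n_epochs: int


@dataclass(frozen=True)
class JoinReport:
    """Bookkeeping for build_labeled_table: rows kept and rows dropped
    because their 10 s calorimetry epoch was missing."""

    n_rows: int
    n_missing_met: int


def trim_bout(bout: BoutAnnotation) -> tuple[float, float]:
    """Analysis window [start+120, start+240) of a bout; error below 240 s."""
    if bout.end - bout.start < TRIM_LEAD + WINDOW_LENGTH:
        raise ValueError(
            f"bout of {bout.end - bout.start:.0f} s cannot yield the "
            f"{WINDOW_LENGTH:.0f} s analysis window (needs >= {TRIM_LEAD + WINDOW_LENGTH:.0f} s)"
        )
    return (bout.start + TRIM_LEAD, bout.start + TRIM_LEAD + WINDOW_LENGTH)


def steady_state_check(
    mets: MetSeries, window: tuple[float, float], threshold: float = 0.10
) -> SteadyStateResult:
    """Coefficient of variation of in-window METs; advisory pass/fail.

    An automated stand-in for by-eye steady-state verification: pass iff
    sd/mean <= threshold. Requires >= 3 non-missing MET epochs starting in
    the window. Advisory only — callers must not silently drop bouts on fail.
    """
    lo, hi = window
    mask = (mets.epoch_start >= lo) & (mets.epoch_start < hi) & ~mets.missing
    vals = mets.met[mask]
    if len(vals) < 3:
        raise ValueError("steady-state check needs at least 3 MET epochs in the window")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    cv = sd / mean
    return SteadyStateResult(cv=cv, passed=cv <= threshold, n_epochs=int(len(vals)))


def build_labeled_table(
    epochs: Iterable[EpochSeries],
    mets: Iterable[MetSeries],
    bouts: Sequence[BoutAnnotation],
) -> tuple[pd.DataFrame, JoinReport]:
    """Join 1 s count epochs to 10 s MET epochs inside trimmed bout windows.

    Returns the pooled labelled table (one row per participant x location x
    1 s epoch) plus a join report counting rows excluded because their
    calorimetry epoch was missing. Raises if the join yields zero rows or if
    duplicate (participant, location, epoch_start) rows appear.
    """
    met_by_pid: dict[str, MetSeries] = {}
    for m in mets:
        if m.participant_id in met_by_pid:
            raise ValueError(f"duplicate MetSeries for participant {m.participant_id!r}")
        met_by_pid[m.participant_id] = m

    windows_by_pid: dict[str, list[tuple[float, float, BoutAnnotation]]] = {}
    for bout in bouts:
        lo, hi = trim_bout(bout)
        windows_by_pid.setdefault(bout.participant_id, []).append((lo, hi, bout))
    for wins in windows_by_pid.values():
        wins.sort()
        for (lo1, hi1, _), (lo2, _, _) in zip(wins, wins[1:]):
            if lo2 < hi1:
                raise ValueError("overlapping trimmed bout windows")

    frames = []
    n_missing = 0
    for es in epochs:
        wins = windows_by_pid.get(es.participant_id)
        m = met_by_pid.get(es.participant_id)
        if not wins or m is None:
            continue
        los = np.array([w[0] for w in wins])
        his = np.array([w[1] for w in wins])
        pos = np.searchsorted(los, es.epoch_start, side="right") - 1
        inside = (pos >= 0) & (es.epoch_start < his[np.clip(pos, 0, None)])
        if not np.any(inside):
            continue
        starts = es.epoch_start[inside]
        counts = es.svm_gs[inside]
        bouts_in = [wins[p][2] for p in pos[inside]]
        # containing 10 s calorimetry epoch
        k = np.floor(starts / m.epoch_length).astype(np.int64)
        k0 = int(np.floor(m.epoch_start[0] / m.epoch_length))
        rel = k - k0
        valid = (rel >= 0) & (rel < len(m))
        met_vals = np.full(len(starts), np.nan)
        met_vals[valid] = m.met[rel[valid]]
        have = ~np.isnan(met_vals)
        n_missing += int((~have).sum())
        if not np.any(have):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": es.participant_id,
                    "location": es.location,
                    "epoch_start": starts[have],
                    "svm_gs": counts[have],
                    "met": met_vals[have],
                    "intensity": [m.intensity[r] for r in rel[have]],
                    "activity_label": [b.activity_label for b, h in zip(bouts_in, have) if h],
                    "is_fms": [b.is_fms for b, h in zip(bouts_in, have) if h],
                }
            )
        )
    if not frames:
        raise ValueError("join produced zero labelled rows")
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(
        ["participant_id", "location", "epoch_start"], kind="stable"
    ).reset_index(drop=True)
    if table.duplicated(["participant_id", "location", "epoch_start"]).any():
        raise ValueError("duplicate (participant, location, epoch_start) rows in join")
    return table[LABELED_COLUMNS], JoinReport(n_rows=len(table), n_missing_met=n_missing)
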