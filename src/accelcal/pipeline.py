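"""In-memory pipeline glue: simulated study -> labelled table -> reports.

Raw recordings are converted to 1 s epochs one bout at a time, so a full
study (20 children x 5 locations x 7 bouts at 80 Hz) never holds all raw
samples simultaneously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import (
    BoutAnnotation,
    JoinReport,
    build_labeled_table,
    steady_state_check,
    trim_bout,
)
from .crossval import ValidationReport, evaluate
from .energy import (
    HARRELL_SCHEME,
    BreathSeries,
    IntensityScheme,
    met_epochs,
    schofield_rmr,
)
from .roc import CalibrationReport, calibrate
from .signal import svm_gs_epochs
from .synthetic import (
    SimulationConfig,
    bout_schedule,
    simulate_breaths,
    simulate_participants,
    simulate_recording,
)


def run_study(
    config: SimulationConfig, scheme: IntensityScheme = HARRELL_SCHEME
) -> tuple[pd.DataFrame, JoinReport, pd.DataFrame]:
    """Simulate a study and build its labelled epoch table.

    Returns (labelled table, join report, steady-state screen) where the
    screen holds the advisory per-bout MET coefficient of variation.
    """
    participants = simulate_participants(config)
    starts = bout_schedule(config)
    epochs, mets, bouts = [], [], []
    steady_rows = []
    for p in participants:
        rmr = schofield_rmr(p.age, p.sex, p.mass)
        participant_bouts = []
        bt, bo2, bco2 = [], [], []
        for act, s0 in zip(config.activities, starts):
            bout = BoutAnnotation(p.id, act.label, s0, s0 + act.duration, act.cadence, act.is_fms)
            participant_bouts.append(bout)
            b = simulate_breaths(p, act, config, start_time=s0)
            bt.append(b.t)
            bo2.append(b.vo2)
            bco2.append(b.vco2)
            for loc in config.wear_locations:
                rec = simulate_recording(p, act, loc, config, start_time=s0)
                epochs.append(svm_gs_epochs(rec))
        series = BreathSeries(p.id, np.concatenate(bt), np.concatenate(bo2), np.concatenate(bco2))
        m = met_epochs(series, rmr, scheme=scheme)
        mets.append(m)
        bouts.extend(participant_bouts)
        for bout in participant_bouts:
            res = steady_state_check(m, trim_bout(bout))
            steady_rows.append(
                {
                    "participant_id": p.id,
                    "activity_label": bout.activity_label,
                    "cv": res.cv,
                    "passed": res.passed,
                    "n_epochs": res.n_epochs,
                }
            )
    table, report = build_labeled_table(epochs, mets, bouts)
    return table, report, pd.DataFrame(steady_rows)


def run_calibration(
    config: SimulationConfig, scheme: IntensityScheme = HARRELL_SCHEME
) -> tuple[pd.DataFrame, CalibrationReport]:
    """Simulate a calibration study and derive its cut-points."""
    table, _, _ = run_study(config, scheme)
    return table, calibrate(table, scheme)


def run_cross_validation(
    config: SimulationConfig,
    cuts,
    scheme: IntensityScheme = HARRELL_SCHEME,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Simulate an independent study and validate fixed cut-points on it."""
    table, _, _ = run_study(config, scheme)
    return table, evaluate(table, cuts)
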