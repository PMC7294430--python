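"""Breath-by-breath gas exchange to 10 s MET epochs and intensity categories.

Energy expenditure is computed with the Weir equation from V̇O₂ and V̇CO₂,
METs as measured energy-expenditure rate divided by the resting metabolic
rate predicted from age, sex and body mass (Schofield weight-only
equations). METs are coded into the conventional paediatric bands:
sedentary < 1.5, light 1.5–3, moderate 3–6, vigorous ≥ 6 (half-open
intervals close the printed 2.99→3 / 5.99→6 gaps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MJ_PER_DAY_TO_KCAL_PER_MIN = 239.006 / 1440.0
#: Schofield weight-only RMR coefficients (MJ/day): (sex, age band) -> (slope, intercept),
#: age bands [3, 10) and [10, 18] years. Editable so an audited transcription
#: can be swapped in.
SCHOFIELD_WEIGHT_ONLY = {
    ("male", "3-10"): (0.095, 2.110),
    ("male", "10-18"): (0.074, 2.754),
    ("female", "3-10"): (0.085, 2.033),
    ("female", "10-18"): (0.056, 2.898),
}


@dataclass(frozen=True)
class IntensityScheme:
    """MET bands plus an AUC grading scale.

    ``bands``: ordered (name, lower-inclusive, upper-exclusive) tiling
    [0, inf). ``auc_grades``: ordered (name, lower-inclusive,
    upper-exclusive) tiling [0, 1]; the top grade's upper bound is treated as
    inclusive so AUC = 1 grades.
    """

    bands: tuple[tuple[str, float, float], ...]
    auc_grades: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        lo = 0.0
        for _, a, b in self.bands:
            if a != lo or b <= a:
                raise ValueError("MET bands must tile [0, inf) without gaps or overlap")
            lo = b
        if not math.isinf(lo):
            raise ValueError("last MET band must extend to infinity")
        lo = 0.0
        for _, a, b in self.auc_grades:
            if a != lo or b <= a:
                raise ValueError("AUC grades must tile [0, 1]")
            lo = b
        if lo != 1.0:
            raise ValueError("AUC grades must end at 1")

    def band_name(self, met: float) -> str:
        if met < 0 or not math.isfinite(met):
            raise ValueError("MET value must be finite and nonnegative")
        for name, a, b in self.bands:
            if a <= met < b:
                return name
        raise AssertionError("unreachable: bands tile [0, inf)")

    def grade(self, auc: float) -> str:
        if not 0.0 <= auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        for name, a, b in self.auc_grades:
            if a <= auc < b:
                return name
        return self.auc_grades[-1][0]  # auc == 1.0


HARRELL_SCHEME = IntensityScheme(
    bands=(
        ("sedentary", 0.0, 1.5),
        ("light", 1.5, 3.0),
        ("moderate", 3.0, 6.0),
        ("vigorous", 6.0, math.inf),
    ),
    auc_grades=(
        ("poor", 0.0, 0.7),
        ("fair", 0.7, 0.8),
        ("good", 0.8, 0.9),
        ("excellent", 0.9, 1.0),
    ),
)


@dataclass
class BreathSeries:
    """Breath-by-breath V̇O₂/V̇CO₂ (L/min) for one participant."""

    participant_id: str
    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (len(self.t) == len(self.vo2) == len(self.vco2)):
            raise ValueError("t, vo2, vco2 must have equal length")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("gas exchange rates must be nonnegative")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("breath timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MetSeries:
    """10 s calorimetry epochs: EE rate (kcal/min), METs and intensity.

    Covers the contiguous 10 s grid from the epoch containing the first
    breath to the one containing the last; epochs with no breaths are marked
    missing (NaN met, None intensity), never zero.
    """

    participant_id: str
    epoch_length: float
    epoch_start: np.ndarray
    ee_rate: np.ndarray
    met: np.ndarray
    intensity: list

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.ee_rate = np.asarray(self.ee_rate, dtype=float)
        self.met = np.asarray(self.met, dtype=float)

    def __len__(self) -> int:
        return len(self.epoch_start)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.met)


def schofield_rmr(age: float, sex: str, mass: float) -> float:
    """Predicted resting metabolic rate in MJ/day (Schofield, weight only).

    ``age`` in years (supported range 3–18, bands 3–10 and 10–18),
    ``sex`` in {male, female}, ``mass`` in kg.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not 3.0 <= age <= 18.0:
        raise ValueError("age outside supported Schofield bands 3-10 and 10-18 years")
    band = "3-10" if age < 10.0 else "10-18"
    slope, intercept = SCHOFIELD_WEIGHT_ONLY[(sex, band)]
    return slope * mass + intercept


def ee_rate(vo2, vco2):
    """Weir equation: energy expenditure in kcal/min from V̇O₂/V̇CO₂ in L/min."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas exchange rates must be nonnegative")
    out = 3.941 * vo2 + 1.106 * vco2
    if out.ndim == 0:
        return float(out)
    return out


def rmr_kcal_per_min(rmr_mj_day: float) -> float:
    """Convert an RMR from MJ/day to kcal/min (1 MJ = 239.006 kcal, 1440 min/day)."""
    if rmr_mj_day <= 0:
        raise ValueError("RMR must be positive")
    return rmr_mj_day * MJ_PER_DAY_TO_KCAL_PER_MIN


def met_epochs(
    breaths: BreathSeries,
    rmr_mj_day: float,
    epoch_length: float = 10.0,
    scheme: IntensityScheme = HARRELL_SCHEME,
) -> MetSeries:
    """Average breath-wise EE into fixed epochs and express as METs.

    Per epoch, the mean Weir EE rate (kcal/min) of the breaths whose
    timestamps fall inside it, divided by the predicted RMR expressed in
    kcal/min. Breaths are assigned to the epoch containing their timestamp;
    no interpolation. Epochs without breaths are marked missing.
    """
    rmr_min = rmr_kcal_per_min(rmr_mj_day)
    if len(breaths) == 0:
        raise ValueError("empty breath series")
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    ee = ee_rate(breaths.vo2, breaths.vco2)
    k = np.floor(breaths.t / epoch_length).astype(np.int64)
    k0, k1 = int(k[0]), int(k[-1])
    n = k1 - k0 + 1
    sums = np.bincount(k - k0, weights=ee, minlength=n)
    counts = np.bincount(k - k0, minlength=n)
    mean_ee = np.full(n, np.nan)
    np.divide(sums, counts, out=mean_ee, where=counts > 0)
    met = mean_ee / rmr_min
    intensity = [scheme.band_name(m) if not np.isnan(m) else None for m in met]
    return MetSeries(
        participant_id=breaths.participant_id,
        epoch_length=float(epoch_length),
        epoch_start=(np.arange(k0, k1 + 1)) * float(epoch_length),
        ee_rate=mean_ee,
        met=met,
        intensity=intensity,
    )


def code_intensity(met: float, scheme: IntensityScheme = HARRELL_SCHEME) -> str:
    """Map a MET value to its intensity category (half-open bands)."""
    return scheme.band_name(met)
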