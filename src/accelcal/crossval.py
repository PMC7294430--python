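"""Cross-validation: apply fixed cut-points to an independent labelled table.

A fixed cut-point set induces a three-way classification of counts
(≤ sedentary cut → sedentary, ≥ moderate cut → moderate, otherwise light).
Validation reports, per location and intensity, (a) the threshold-free
one-vs-rest ROC AUC of the counts on the new data and (b) Se/Sp of the
fixed rule. A fixed threshold has no AUC of its own, so the AUC column
measures how discriminable each intensity remains in the new sample; for
the middle (light) band the counts are used as-is, which is ill-posed for a
band-shaped class and is reported for comparability with standard software,
not as a recommended statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import roc as _roc

INTENSITIES = ("sedentary", "light", "moderate")


@dataclass(frozen=True)
class ValidationCell:
    location: str
    intensity: str
    auc: float
    ci95: tuple[float, float]
    sensitivity: float  # percent, at the fixed cut-points
    specificity: float  # percent
    n_positive: int
    n_negative: int


@dataclass
class ValidationReport:
    cells: list[ValidationCell] = field(default_factory=list)
    absent: list[tuple[str, str]] = field(default_factory=list)  # zero-positive cells

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "location": c.location,
                    "intensity": c.intensity,
                    "auc": c.auc,
                    "ci_low": c.ci95[0],
                    "ci_high": c.ci95[1],
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "n_positive": c.n_positive,
                    "n_negative": c.n_negative,
                }
                for c in self.cells
            ]
        )

    def cell(self, location: str, intensity: str) -> ValidationCell:
        for c in self.cells:
            if (c.location, c.intensity) == (location, intensity):
                return c
        raise KeyError((location, intensity))


def classify_epochs(table: pd.DataFrame, cuts: Mapping[str, tuple[float, float]]) -> pd.Series:
    """Assign each epoch an intensity from fixed cut-points.

    ``cuts`` maps location -> (sedentary cut, moderate cut); counts at or
    below the sedentary cut are sedentary, at or above the moderate cut
    moderate, strictly between the two light.
    """
    if len(table) == 0:
        raise ValueError("empty epoch table")
    missing = set(table["location"]) - set(cuts)
    if missing:
        raise ValueError(f"no cut-points for location(s): {sorted(missing)}")
    out = pd.Series(index=table.index, dtype=object)
    for loc, sub in table.groupby("location"):
        sed_cut, mod_cut = cuts[loc]
        s = sub["svm_gs"].to_numpy(dtype=float)
        lab = np.where(s <= sed_cut, "sedentary", np.where(s >= mod_cut, "moderate", "light"))
        out.loc[sub.index] = lab
    return out


def _fixed_rule(counts: np.ndarray, intensity: str, sed_cut: float, mod_cut: float) -> np.ndarray:
    if intensity == "sedentary":
        return counts <= sed_cut
    if intensity == "moderate":
        return counts >= mod_cut
    return (counts > sed_cut) & (counts < mod_cut)


def evaluate(
    table: pd.DataFrame,
    cuts: Mapping[str, tuple[float, float]],
    scheme=None,
) -> ValidationReport:
    """Validate fixed cut-points on an independent labelled table.

    Per location and intensity (one-vs-rest): DeLong-CI AUC of the raw
    counts (low counts positive for sedentary, high otherwise) and Se/Sp of
    the fixed classification rule. Intensities absent from a location are
    flagged rather than reported.
    """
    if len(table) == 0:
        raise ValueError("empty epoch table")
    report = ValidationReport()
    for loc, sub in table.groupby("location", sort=True):
        loc = str(loc)
        if loc not in cuts:
            raise ValueError(f"no cut-points for location {loc!r}")
        sed_cut, mod_cut = cuts[loc]
        counts = sub["svm_gs"].to_numpy(dtype=float)
        truth = sub["intensity"].to_numpy()
        for intensity in INTENSITIES:
            y = truth == intensity
            if not y.any() or y.all():
                report.absent.append((loc, intensity))
                continue
            direction = _roc.LOW if intensity == "sedentary" else _roc.HIGH
            auc, ci = _roc.auc_with_ci(counts, y, direction)
            pred = _fixed_rule(counts, intensity, sed_cut, mod_cut)
            se = 100.0 * float(np.mean(pred[y]))
            sp = 100.0 * float(np.mean(~pred[~y]))
            report.cells.append(
                ValidationCell(
                    location=loc,
                    intensity=intensity,
                    auc=auc,
                    ci95=ci,
                    sensitivity=se,
                    specificity=sp,
                    n_positive=int(y.sum()),
                    n_negative=int((~y).sum()),
                )
            )
    if not report.cells:
        raise ValueError("no (location, intensity) cell had both classes present")
    return report
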