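"""ROC cut-point calibration: AUC with DeLong CIs, Youden thresholds,
Spearman criterion validity, AUC grading and light-band construction.

The calibration answers, per wear location: which count threshold best
separates sedentary from non-sedentary epochs (low counts predict
sedentary), and which best separates moderate from lighter epochs (high
counts predict moderate)? Counts between the two cut-points are classified
light, so light intensity needs no ROC of its own. A parallel ROC
distinguishes fundamental-movement-skill (FMS) bouts from continuous
locomotion/rest.

Cut-points maximise Youden's J = Se + Sp − 1 over the observed count values;
ties are broken by larger sensitivity, then by the smaller
direction-normalised threshold. The selected threshold is rounded to a
reporting grid (0.1 g·s, the precision cut-points are published at) and the
reported Se/Sp are recomputed at that rounded cut-point under the final
boundary conventions (count ≤ cut → sedentary; count ≥ cut → moderate), so
applying a published cut-point set back to its calibration data reproduces
the reported Se/Sp exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .energy import HARRELL_SCHEME, IntensityScheme

HIGH = "high_scores_positive"
LOW = "low_scores_positive"
DEFAULT_GRID = 0.1


@dataclass(frozen=True)
class RocResult:
    positive_class: str
    direction: str
    auc: float
    ci95: tuple[float, float]
    cutpoint: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden_j: float
    grade: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class CutPointSet:
    """Per-location sedentary and moderate cut-points plus the light band."""

    location: str
    sedentary: RocResult
    moderate: RocResult
    light_band: tuple[float, float]

    @property
    def fixed(self) -> tuple[float, float]:
        """(sedentary cut, moderate cut) on the count scale."""
        return (self.sedentary.cutpoint, self.moderate.cutpoint)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool


@dataclass
class CalibrationReport:
    cutpoints: dict[str, CutPointSet] = field(default_factory=dict)
    fms: dict[str, RocResult] = field(default_factory=dict)
    spearman: dict[str, tuple[float, float]] = field(default_factory=dict)
    normality: dict[str, NormalityResult] = field(default_factory=dict)

    @property
    def locations(self) -> list[str]:
        return list(self.cutpoints)

    def fixed_cuts(self) -> dict[str, tuple[float, float]]:
        return {loc: cps.fixed for loc, cps in self.cutpoints.items()}


def _as_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def _normalise(scores, labels, direction):
    s, y = _as_scores_labels(scores, labels)
    if direction == HIGH:
        return s, y
    if direction == LOW:
        return -s, y
    raise ValueError(f"unknown direction {direction!r}")


def roc_points(scores, labels, direction=HIGH) -> np.ndarray:
    """ROC curve as an array of (fpr, tpr, threshold) rows.

    Thresholds are the distinct observed scores (after direction
    normalisation: score >= threshold is called positive), descending, with
    a leading (0, 0, inf) anchor; the final row is (1, 1, min score).
    """
    s, y = _normalise(scores, labels, direction)
    thresholds = np.unique(s)[::-1]
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    tpr = (len(pos) - np.searchsorted(pos, thresholds, side="left")) / len(pos)
    fpr = (len(neg) - np.searchsorted(neg, thresholds, side="left")) / len(neg)
    out = np.column_stack(
        [np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr]), np.concatenate([[np.inf], thresholds])]
    )
    return out


def _delong(pos: np.ndarray, neg: np.ndarray):
    """AUC as the Mann–Whitney pair statistic (ties ½) and DeLong variance."""
    m, n = len(pos), len(neg)
    sneg = np.sort(neg)
    below = np.searchsorted(sneg, pos, side="left")
    eq = np.searchsorted(sneg, pos, side="right") - below
    auc = (below.sum() + 0.5 * eq.sum()) / (m * n)
    v10 = (below + 0.5 * eq) / n
    spos = np.sort(pos)
    above = m - np.searchsorted(spos, neg, side="right")
    eqn = np.searchsorted(spos, neg, side="right") - np.searchsorted(spos, neg, side="left")
    v01 = (above + 0.5 * eqn) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var)


def auc_with_ci(scores, labels, direction=HIGH) -> tuple[float, tuple[float, float]]:
    """Mann–Whitney AUC with a 95% DeLong confidence interval.

    The AUC is the fraction of (positive, negative) pairs ranked concordantly
    with ties counted one half; the CI is auc ± 1.96·sqrt(DeLong variance),
    truncated to [0, 1] (degenerate separation yields a zero-width interval).
    """
    s, y = _normalise(scores, labels, direction)
    auc, var = _delong(s[y], s[~y])
    half = 1.959963984540054 * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def youden_cutpoint(
    scores, labels, direction=HIGH, grid: float | None = DEFAULT_GRID
) -> tuple[float, float, float]:
    """Cut-point maximising Youden's J, with Se/Sp in percent at that cut.

    Candidate thresholds are the unique observed scores (direction
    normalised; score >= t positive). J ties are broken by larger Se, then
    smaller normalised t. With ``grid`` set, the winning threshold is
    rounded to the nearest grid multiple on the *original* count scale and
    Se/Sp are recomputed there under the reporting convention
    (score ≤ cut positive for low_scores_positive, score ≥ cut otherwise);
    ``grid=None`` reports the raw optimal candidate.
    """
    s, y = _normalise(scores, labels, direction)
    cand = np.unique(s)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    m, n = len(pos), len(neg)
    # count ratios formed directly so equal Se/Sp from equal counts are
    # bit-identical (ties must compare exactly)
    se = (m - np.searchsorted(pos, cand, side="left")) / m
    sp = np.searchsorted(neg, cand, side="left") / n
    j = se + sp - 1.0
    best = np.lexsort((-cand, se, j))[-1]  # max J, then max Se, then min t
    t = cand[best]
    cut = -t if direction == LOW else t
    if grid is None:
        return float(cut), float(100.0 * se[best]), float(100.0 * sp[best])
    cut = round(round(cut / grid) * grid, 10)
    se_r, sp_r = se_sp_at_cut(scores, labels, cut, direction)
    return float(cut), se_r, sp_r


def se_sp_at_cut(scores, labels, cut: float, direction=HIGH) -> tuple[float, float]:
    """Se/Sp (percent) of the fixed rule score ≥ cut (or ≤ cut when low
    scores indicate the positive class)."""
    s, y = _as_scores_labels(scores, labels)
    pred = s <= cut if direction == LOW else s >= cut
    se = 100.0 * float(np.mean(pred[y]))
    sp = 100.0 * float(np.mean(~pred[~y]))
    return se, sp


def grade_auc(auc: float, scheme: IntensityScheme = HARRELL_SCHEME) -> str:
    """Grade an AUC on the conventional scale (≥0.90 excellent, 0.80–0.89
    good, 0.70–0.79 fair, <0.70 poor)."""
    return scheme.grade(auc)


def light_band(
    sedentary_cut: float, moderate_cut: float, grid: float = DEFAULT_GRID
) -> tuple[float, float]:
    """Light-intensity count band: one grid step above the sedentary
    cut-point up to one grid step below the moderate cut-point."""
    if moderate_cut - sedentary_cut < 2 * grid - 1e-12:
        raise ValueError("cut-points too close: light band would be empty")
    lo = round(round((sedentary_cut + grid) / grid) * grid, 10)
    hi = round(round((moderate_cut - grid) / grid) * grid, 10)
    return (lo, hi)


def normality_gate(values, alpha: float = 0.05, max_n: int = 5000, seed: int = 0) -> NormalityResult:
    """Shapiro–Wilk normality screen; subsamples above ``max_n``.

    The pipeline reports Spearman correlations regardless (count data are
    right-skewed), but the gate records the evidence.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(v) > max_n:
        rng = np.random.default_rng(seed)
        v = rng.choice(v, size=max_n, replace=False)
    stat, p = stats.shapiro(v)
    return NormalityResult(statistic=float(stat), p_value=float(p), normal=bool(p >= alpha))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("spearman_rho needs equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _roc_result(scores, labels, positive_class, direction, scheme, grid) -> RocResult:
    auc, ci = auc_with_ci(scores, labels, direction)
    cut, se, sp = youden_cutpoint(scores, labels, direction, grid)
    y = np.asarray(labels, dtype=bool)
    return RocResult(
        positive_class=positive_class,
        direction=direction,
        auc=auc,
        ci95=ci,
        cutpoint=cut,
        sensitivity=se,
        specificity=sp,
        youden_j=se / 100.0 + sp / 100.0 - 1.0,
        grade=grade_auc(auc, scheme),
        n_positive=int(y.sum()),
        n_negative=int((~y).sum()),
    )


def calibrate(
    table,
    scheme: IntensityScheme = HARRELL_SCHEME,
    grid: float = DEFAULT_GRID,
    include_fms: bool = True,
) -> CalibrationReport:
    """Full per-location calibration of a labelled epoch table.

    Per wear location: sedentary ROC (positive = sedentary epochs, low
    counts positive), moderate ROC (positive = moderate, negatives =
    sedentary + light), the light band between the two cut-points, an FMS
    ROC (positive = FMS bouts, high counts positive), the Spearman rho of
    counts vs METs, and a Shapiro–Wilk normality screen of the counts.
    """
    report = CalibrationReport()
    required = ("sedentary", "light", "moderate")
    for loc, sub in table.groupby("location", sort=True):
        counts = sub["svm_gs"].to_numpy(dtype=float)
        intensity = sub["intensity"].to_numpy()
        for cls in required:
            if not np.any(intensity == cls):
                raise ValueError(f"location {loc!r}: no epochs of intensity {cls!r}")
        sed = _roc_result(counts, intensity == "sedentary", "sedentary", LOW, scheme, grid)
        mod = _roc_result(counts, intensity == "moderate", "moderate", HIGH, scheme, grid)
        report.cutpoints[str(loc)] = CutPointSet(
            location=str(loc),
            sedentary=sed,
            moderate=mod,
            light_band=light_band(sed.cutpoint, mod.cutpoint, grid),
        )
        if include_fms:
            fms = sub["is_fms"].to_numpy(dtype=bool)
            if not fms.any() or fms.all():
                raise ValueError(f"location {loc!r}: both FMS classes required")
            report.fms[str(loc)] = _roc_result(counts, fms, "fms", HIGH, scheme, grid)
        report.spearman[str(loc)] = spearman_rho(counts, sub["met"].to_numpy(dtype=float))
        report.normality[str(loc)] = normality_gate(counts)
    return report
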