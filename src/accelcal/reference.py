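"""Published GENEActiv SVM-gs cut-points for children aged 8-12.

Cut-points (g*s per 1 s epoch) from a published wrist/waist/ankle
calibration of raw-acceleration monitors against indirect calorimetry in
8-12-year-old children performing rest, locomotion and football-skill
bouts. Shipped so independently collected epoch tables can be classified or
cross-validated against the published thresholds without re-deriving them.
"""

from __future__ import annotations

#: location -> (sedentary cut-point, moderate cut-point); counts at or below
#: the first are sedentary, at or above the second moderate.
PUBLISHED_CHILD_CUTPOINTS: dict[str, tuple[float, float]] = {
    "dominant_wrist": (4.5, 16.5),
    "nondominant_wrist": (4.4, 12.5),
    "waist": (4.0, 8.9),
    "dominant_ankle": (3.5, 39.3),
    "nondominant_ankle": (4.0, 81.7),
}

#: location -> cut-point separating fundamental-movement-skill bouts (counts
#: at or above) from continuous locomotion and rest, same calibration.
PUBLISHED_CHILD_FMS_CUTPOINTS: dict[str, float] = {
    "dominant_wrist": 6.1,
    "nondominant_wrist": 7.7,
    "waist": 7.6,
    "dominant_ankle": 35.1,
    "nondominant_ankle": 31.8,
}
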