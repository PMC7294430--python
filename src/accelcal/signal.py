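"""Raw triaxial acceleration to gravity-subtracted signal-vector-magnitude epochs.

The accelerometer "count" used throughout this package is the SVM-gs: per
sample the Euclidean magnitude of the three axes minus 1 g (static gravity),
taken in absolute value, summed within fixed-length epochs (1 s by default).
Absolute value rather than truncation at zero makes 0.9 g and 1.1 g
contribute symmetrically, matching the post-processing convention of
raw-acceleration wrist/waist/ankle monitors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

WEAR_LOCATIONS = (
    "dominant_wrist",
    "nondominant_wrist",
    "waist",
    "dominant_ankle",
    "nondominant_ankle",
)


@dataclass
class TriaxialRecording:
    """Raw x/y/z acceleration stream for one participant x wear location.

    Units: ``t`` in seconds, axes in g. Timestamps must be strictly
    increasing and all values finite.
    """

    participant_id: str
    location: str
    sampling_rate: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.location not in WEAR_LOCATIONS:
            raise ValueError(
                f"unknown wear location {self.location!r}; expected one of {WEAR_LOCATIONS}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("t, x, y, z must have equal length")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class EpochSeries:
    """SVM-gs counts per fixed-length epoch for one participant x location.

    ``epoch_start`` values are absolute seconds (the raw recording's clock);
    epochs with no samples (e.g. gaps between activity bouts) are omitted
    rather than reported as zero.
    """

    participant_id: str
    location: str
    epoch_length: float
    epoch_start: np.ndarray = field(default_factory=lambda: np.empty(0))
    svm_gs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.svm_gs = np.asarray(self.svm_gs, dtype=float)
        if np.any(self.svm_gs < 0):
            raise ValueError("svm_gs must be nonnegative")
        if len(self.epoch_start) > 1 and not np.all(np.diff(self.epoch_start) > 0):
            raise ValueError("epoch starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.epoch_start)


def vector_magnitude(x, y, z):
    """Euclidean magnitude sqrt(x^2 + y^2 + z^2) of a triaxial sample, in g.

    Accepts scalars or arrays; rejects non-finite input. Rotation invariant,
    hence also invariant to axis permutation and sign flips.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("vector_magnitude requires finite inputs")
    vm = np.sqrt(x * x + y * y + z * z)
    if vm.ndim == 0:
        return float(vm)
    return vm


def svm_gs_epochs(recording: TriaxialRecording, epoch_length: float = 1.0) -> EpochSeries:
    """Summarise a raw recording into per-epoch SVM-gs counts.

    Per epoch the count is ``sum(|vm_i - 1|)`` over samples whose timestamp
    falls in the half-open window ``[t0 + k*L, t0 + (k+1)*L)`` aligned to the
    first sample. A trailing epoch not fully covered by the recording span is
    dropped rather than scaled up. Epochs containing no samples are omitted.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n = len(recording)
    if n == 0:
        raise ValueError("empty recording")
    t0 = recording.t[0]
    span = (recording.t[-1] - t0) + 1.0 / recording.sampling_rate
    n_full = math.floor(span / epoch_length + 1e-9)
    if n_full < 1:
        raise ValueError("recording spans less than one epoch")
    idx = np.floor((recording.t - t0) / epoch_length).astype(np.int64)
    keep = idx < n_full
    idx = idx[keep]
    vm = vector_magnitude(recording.x[keep], recording.y[keep], recording.z[keep])
    dev = np.abs(vm - 1.0)
    sums = np.bincount(idx, weights=dev, minlength=n_full)
    counts = np.bincount(idx, minlength=n_full)
    occupied = counts > 0
    return EpochSeries(
        participant_id=recording.participant_id,
        location=recording.location,
        epoch_length=float(epoch_length),
        epoch_start=t0 + np.nonzero(occupied)[0] * float(epoch_length),
        svm_gs=sums[occupied],
    )


def concat_epochs(series: list[EpochSeries]) -> EpochSeries:
    """Concatenate epoch series for the same participant x location.

    Inputs may arrive per activity bout; starts must not overlap.
    """
    if not series:
        raise ValueError("no epoch series to concatenate")
    pid = series[0].participant_id
    loc = series[0].location
    length = series[0].epoch_length
    for s in series:
        if (s.participant_id, s.location, s.epoch_length) != (pid, loc, length):
            raise ValueError("cannot concatenate epoch series with differing identity")
    starts = np.concatenate([s.epoch_start for s in series])
    values = np.concatenate([s.svm_gs for s in series])
    order = np.argsort(starts, kind="stable")
    return EpochSeries(pid, loc, length, starts[order], values[order])
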