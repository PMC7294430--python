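"""Synthetic calibration / cross-validation study generator.

No raw data from the original laboratory studies were deposited, so this
module generates complete synthetic studies with the statistical structure
the downstream analysis assumes: a cohort of children, a protocol of
five-minute activity bouts (rest, locomotion, and object-control
fundamental movement skills at slow and fast cadence), raw 80 Hz triaxial
acceleration per wear location, and breath-by-breath gas exchange.

Signal model
------------
Per 1 s epoch the expected SVM-gs count is
``base_gain(location) * activity_gain(location) * subject_gain * (MET - 1)``,
so counts are zero for truly resting activity and increase monotonically
with intensity, with location-specific scale (ankles accumulate far larger
counts than the waist). The per-epoch count noise is lognormal
(multiplicative, right-skewed — the shape of real count data) plus an
additive Gaussian floor, clipped at zero; a pure-Gaussian option exists so
tests can compare empirical AUCs against the binormal closed form
Phi(delta / (sigma * sqrt(2))). Raw samples are reconstructed from each
epoch's count: every sample's dynamic deviation is count/samples-per-epoch
in a random 3-d direction on top of the 1 g static component, so epoching
the raw signal recovers the drawn counts.

Breath model
------------
Breath times follow a gamma renewal process (~2-4 s apart). V̇O₂ rises from
rest along a mono-exponential (tau = 30 s) rescaled to reach the target
steady state exactly at 120 s — only the final two minutes of each bout are
analysed, and the steady-state V̇O₂ is chosen so that energy expenditure
equals ``target_met`` times the participant's Schofield-predicted RMR.
V̇CO₂ is RER times V̇O₂ with RER drawn per bout from [0.80, 0.95].

All randomness derives from a single master seed; sub-streams are keyed by
(participant id, wear location, activity label) so removing one bout or
location never shifts another's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import BoutAnnotation
from .energy import BreathSeries, rmr_kcal_per_min, schofield_rmr
from .signal import WEAR_LOCATIONS, TriaxialRecording

#: Location-specific scale of expected counts per (MET - 1), g*s per 1 s epoch.
LOCATION_BASE_GAIN = {
    "dominant_wrist": 6.0,
    "nondominant_wrist": 5.0,
    "waist": 4.0,
    "dominant_ankle": 16.0,
    "nondominant_ankle": 30.0,
}

_WRISTS = ("dominant_wrist", "nondominant_wrist")
_ANKLES = ("dominant_ankle", "nondominant_ankle")


def cadence_from_interval(interval_s: float) -> float:
    """Skill cadence in events/min from the between-event interval in s."""
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    return 60.0 / interval_s


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    age: float  # years
    sex: str  # {male, female}
    mass: float  # kg
    height: float  # m
    dominant_side: str  # {left, right}

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0:
            raise ValueError("mass and height must be positive")


@dataclass(frozen=True)
class ActivitySpec:
    label: str
    duration: float  # s
    target_met: float
    cadence: float = 0.0  # events/min; 0 for continuous activities
    is_fms: bool = False
    #: wear-location -> multiplier on the dynamic-acceleration gain
    location_gain: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.target_met < 1.0:
            raise ValueError("target_met must be >= 1.0")
        if any(g <= 0 for g in self.location_gain.values()):
            raise ValueError("location gains must be positive")


def default_calibration_activities() -> tuple[ActivitySpec, ...]:
    """The seven-bout calibration protocol: lying, standing, medium-paced
    run, and football instep passing / dribbling each at slow and fast
    cadence (10 and 20 passes/min; 6 and 12 dribble circuits/min).

    Target METs sit at the intensity-band midpoints the bouts are meant to
    occupy (supine/standing sedentary; slow-cadence skills light; running
    and fast-cadence skills moderate); passing and dribbling load the
    ankles more, and the wrists less, than continuous locomotion does.
    """
    pass_gain = {**{w: 0.7 for w in _WRISTS}, **{a: 1.4 for a in _ANKLES}}
    dribble_gain = {**{w: 0.8 for w in _WRISTS}, **{a: 1.5 for a in _ANKLES}}
    return (
        ActivitySpec("lying_supine", 300.0, 1.0),
        ActivitySpec("standing", 300.0, 1.25),
        ActivitySpec("run_medium", 300.0, 4.5),
        ActivitySpec("pass_slow", 300.0, 2.0, cadence_from_interval(6.0), True, pass_gain),
        ActivitySpec("pass_fast", 300.0, 3.5, cadence_from_interval(3.0), True, pass_gain),
        ActivitySpec("dribble_slow", 300.0, 2.5, cadence_from_interval(10.0), True, dribble_gain),
        ActivitySpec("dribble_fast", 300.0, 4.0, cadence_from_interval(5.0), True, dribble_gain),
    )


def default_validation_activities() -> tuple[ActivitySpec, ...]:
    """The independent cross-validation protocol: seated play, slow walk,
    medium and fast runs, overarm throw-and-catch and fast instep passing
    (both at 20 events/min). Throwing loads the wrists rather than the
    ankles."""
    throw_gain = {
        **{w: 1.5 for w in _WRISTS},
        **{a: 0.5 for a in _ANKLES},
        "waist": 0.8,
    }
    pass_gain = {**{w: 0.7 for w in _WRISTS}, **{a: 1.4 for a in _ANKLES}}
    return (
        ActivitySpec("lying_lego", 300.0, 1.2),
        ActivitySpec("walk_slow", 300.0, 2.2),
        ActivitySpec("run_medium", 300.0, 4.5),
        ActivitySpec("run_fast", 300.0, 5.5),
        ActivitySpec("throw_catch", 300.0, 3.2, 20.0, True, throw_gain),
        ActivitySpec("pass_fast", 300.0, 3.5, 20.0, True, pass_gain),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 20
    activities: tuple[ActivitySpec, ...] = field(default_factory=default_calibration_activities)
    wear_locations: tuple[str, ...] = WEAR_LOCATIONS
    sampling_rate: float = 80.0  # Hz
    breath_interval_mean: float = 3.0  # s
    count_noise_sd: float = 0.6  # lognormal sigma (or absolute sd in gaussian mode)
    vo2_noise_sd: float = 0.05  # multiplicative, fraction of instantaneous V̇O₂
    seed: int = 0
    count_model: str = "lognormal"  # {"lognormal", "gaussian"}
    floor_noise_sd: float = 0.8  # additive g*s noise floor on epoch counts
    subject_sd: float = 0.35  # lognormal sigma of the per-child count gain
    rest_interval: float = 300.0  # s between bouts
    female_fraction: float = 0.0
    age_mean: float = 10.1
    age_sd: float = 1.5
    age_range: tuple[float, float] = (8.0, 12.0)
    mass_mean: float = 36.5
    mass_sd: float = 7.5
    height_mean: float = 1.4
    height_sd: float = 0.2
    rer_range: tuple[float, float] = (0.80, 0.95)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.breath_interval_mean <= 0:
            raise ValueError("breath_interval_mean must be positive")
        if self.count_model not in ("lognormal", "gaussian"):
            raise ValueError("count_model must be 'lognormal' or 'gaussian'")
        for loc in self.wear_locations:
            if loc not in WEAR_LOCATIONS:
                raise ValueError(f"unknown wear location {loc!r}")


def default_calibration_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions of the calibration cohort: 20 boys aged 8-12
    (10.1 ± 1.5 y, 36.5 ± 7.5 kg, 1.4 ± 0.2 m), five wear locations,
    seven 5 min bouts, 80 Hz."""
    return replace(SimulationConfig(seed=seed), **overrides)


def default_validation_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Study conditions of the independent cross-validation cohort: 30
    children (16 boys, 14 girls) aged 8-11 (9.4 ± 1.4 y), four wear
    locations (no non-dominant ankle), six 5 min bouts."""
    cfg = SimulationConfig(
        n_participants=30,
        activities=default_validation_activities(),
        wear_locations=("dominant_wrist", "nondominant_wrist", "waist", "dominant_ankle"),
        seed=seed,
        female_fraction=14 / 30,
        age_mean=9.4,
        age_sd=1.4,
        age_range=(8.0, 11.0),
        mass_mean=33.0,
        mass_sd=7.0,
        height_mean=1.36,
        height_sd=0.15,
    )
    return replace(cfg, **overrides)


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    participants: list[ParticipantProfile]
    recordings: list[TriaxialRecording]
    breaths: list[BreathSeries]
    bouts: list[BoutAnnotation]


def _key(*parts) -> np.random.Generator:
    """Deterministic sub-stream from structured integer/string keys."""
    ints = [zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def simulate_participants(config: SimulationConfig) -> list[ParticipantProfile]:
    """Draw the cohort: ages, masses and heights from truncated normals at
    the configured means/SDs; sex composition from ``female_fraction``."""
    n = config.n_participants
    rng = _key(config.seed, 0)
    ages = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range, n)
    masses = _truncated_normal(
        rng, config.mass_mean, config.mass_sd,
        config.mass_mean - 3 * config.mass_sd, config.mass_mean + 3 * config.mass_sd, n,
    )
    heights = _truncated_normal(
        rng, config.height_mean, config.height_sd,
        config.height_mean - 3 * config.height_sd, config.height_mean + 3 * config.height_sd, n,
    )
    n_female = int(round(n * config.female_fraction))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sexes)
    sides = np.where(rng.random(n) < 0.85, "right", "left")
    width = max(2, len(str(n)))
    return [
        ParticipantProfile(
            id=f"P{i + 1:0{width}d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            mass=float(masses[i]),
            height=float(heights[i]),
            dominant_side=str(sides[i]),
        )
        for i in range(n)
    ]


def _subject_gain(participant: ParticipantProfile, config: SimulationConfig) -> float:
    if config.subject_sd == 0:
        return 1.0
    rng = _key(config.seed, 3, participant.id)
    return float(rng.lognormal(-0.5 * config.subject_sd**2, config.subject_sd))


def expected_epoch_count(
    participant: ParticipantProfile,
    activity: ActivitySpec,
    location: str,
    config: SimulationConfig,
) -> float:
    """Expected SVM-gs per 1 s epoch under the generative model (the child's
    own gain included)."""
    if location not in WEAR_LOCATIONS:
        raise ValueError(f"unknown wear location {location!r}")
    gain = LOCATION_BASE_GAIN[location] * activity.location_gain.get(location, 1.0)
    return gain * _subject_gain(participant, config) * max(0.0, activity.target_met - 1.0)


def _epoch_counts(mu: float, n_epochs: int, rng, config: SimulationConfig) -> np.ndarray:
    if config.count_model == "gaussian":
        c = rng.normal(mu, config.count_noise_sd, size=n_epochs)
    else:
        s = config.count_noise_sd
        body = rng.lognormal(-0.5 * s * s, s, size=n_epochs) if s > 0 else np.ones(n_epochs)
        c = mu * body + rng.normal(0.0, config.floor_noise_sd, size=n_epochs)
    return np.clip(c, 0.0, None)


def simulate_recording(
    participant: ParticipantProfile,
    activity: ActivitySpec,
    location: str,
    config: SimulationConfig,
    start_time: float = 0.0,
) -> TriaxialRecording:
    """Raw triaxial signal for one bout: static 1 g plus a dynamic deviation
    whose per-epoch absolute sum realises the drawn SVM-gs count, pointing
    in a random direction per sample."""
    duration = activity.duration
    n_epochs = int(round(duration))
    if abs(duration - n_epochs) > 1e-9 or n_epochs < 1:
        raise ValueError("activity duration must be a positive whole number of seconds")
    mu = expected_epoch_count(participant, activity, location, config)
    rng = _key(config.seed, 1, participant.id, location, activity.label)
    counts = _epoch_counts(mu, n_epochs, rng, config)
    sps = int(round(config.sampling_rate))  # samples per 1 s epoch
    if abs(config.sampling_rate - sps) > 1e-9 or sps < 1:
        raise ValueError("sampling_rate must be a whole number of Hz")
    dev = np.repeat(counts / sps, sps)
    u = rng.normal(size=(n_epochs * sps, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    xyz = (1.0 + dev)[:, None] * u
    t = start_time + np.arange(n_epochs * sps) / float(sps)
    return TriaxialRecording(
        participant_id=participant.id,
        location=location,
        sampling_rate=float(sps),
        t=t,
        x=xyz[:, 0],
        y=xyz[:, 1],
        z=xyz[:, 2],
    )


def simulate_breaths(
    participant: ParticipantProfile,
    activity: ActivitySpec,
    config: SimulationConfig,
    start_time: float = 0.0,
) -> BreathSeries:
    """Breath-by-breath gas exchange for one bout (see module docstring)."""
    rng = _key(config.seed, 2, participant.id, activity.label)
    mean = config.breath_interval_mean
    n_max = int(np.ceil(activity.duration / mean * 3)) + 10
    intervals = rng.gamma(shape=4.0, scale=mean / 4.0, size=n_max)
    times = np.cumsum(intervals)
    times = times[times < activity.duration]
    rer = float(rng.uniform(*config.rer_range))
    rmr_min = rmr_kcal_per_min(schofield_rmr(participant.age, participant.sex, participant.mass))
    kcal_per_l = 3.941 + 1.106 * rer  # Weir with V̇CO₂ = RER * V̇O₂
    vo2_rest = rmr_min / kcal_per_l
    vo2_ss = activity.target_met * vo2_rest
    tau, t_ss = 30.0, 120.0
    ramp = np.minimum(1.0, (1.0 - np.exp(-times / tau)) / (1.0 - np.exp(-t_ss / tau)))
    vo2 = vo2_rest + (vo2_ss - vo2_rest) * ramp
    if config.vo2_noise_sd > 0:
        vo2 = vo2 * (1.0 + rng.normal(0.0, config.vo2_noise_sd, size=len(vo2)))
        vo2 = np.clip(vo2, 0.0, None)
    return BreathSeries(
        participant_id=participant.id,
        t=start_time + times,
        vo2=vo2,
        vco2=rer * vo2,
    )


def bout_schedule(config: SimulationConfig) -> list[float]:
    """Absolute start time of each activity bout (rest interval between)."""
    starts, t = [], 0.0
    for act in config.activities:
        starts.append(t)
        t += act.duration + config.rest_interval
    return starts


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a full study bundle: one recording per participant x
    location x activity, one concatenated breath series per participant,
    and bout annotations."""
    participants = simulate_participants(config)
    starts = bout_schedule(config)
    recordings: list[TriaxialRecording] = []
    breaths: list[BreathSeries] = []
    bouts: list[BoutAnnotation] = []
    for p in participants:
        bt, bo2, bco2 = [], [], []
        for act, s0 in zip(config.activities, starts):
            bouts.append(
                BoutAnnotation(
                    participant_id=p.id,
                    activity_label=act.label,
                    start=s0,
                    end=s0 + act.duration,
                    cadence=act.cadence,
                    is_fms=act.is_fms,
                )
            )
            b = simulate_breaths(p, act, config, start_time=s0)
            bt.append(b.t)
            bo2.append(b.vo2)
            bco2.append(b.vco2)
            for loc in config.wear_locations:
                recordings.append(simulate_recording(p, act, loc, config, start_time=s0))
        breaths.append(
            BreathSeries(
                participant_id=p.id,
                t=np.concatenate(bt),
                vo2=np.concatenate(bo2),
                vco2=np.concatenate(bco2),
            )
        )
    return StudyBundle(
        config=config,
        participants=participants,
        recordings=recordings,
        breaths=breaths,
        bouts=bouts,
    )
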