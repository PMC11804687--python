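"""Synthetic gait-protocol simulator.

Generates dual-site (thigh + low back) tri-axial accelerometer recordings,
sample-accurate ground-truth labels and an instantaneous speed trace for a
semi-structured walking/jogging protocol: five consecutive 5-min bouts
(slow, moderate and brisk walking, jogging, and a slow→brisk→slow speed
ramp), with three heel-drop synchronization impulses at each end of the
recording and 2-s transition gaps between bouts.

Signal model, per site
----------------------
``a(t) = g_proj + gait(t) + impacts(t) + noise(t)`` where

* ``g_proj`` is the static gravity projection for the site's tilt angle,
* ``gait(t)`` is the sum of the first three harmonics of the step frequency
  ``f_step = (cadence_intercept + cadence_slope * v) / 60`` Hz with per-axis
  amplitude proportional to speed (zero at standstill) and to the
  participant's ``amplitude_gain``; the thigh moves more than the back,
* ``impacts(t)`` are per-step half-sine heel-strike transients added only
  while jogging, with peak amplitude above anything walking produces,
* ``noise(t)`` is additive white Gaussian noise per axis.

The model is intentionally minimal: it reproduces the speed-dependent
cadence/amplitude structure that window features must detect, not
biomechanics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CLASSES, OTHER_LABEL, LabelTrack, Recording

# --- speed category cut-offs (km/h) ----------------------------------------
# The walking bins are ≤4 (slow), 4.1–5.4 (moderate), ≥5.5 (brisk); the gaps
# (4.0, 4.1) and (5.4, 5.5) are closed at their midpoints so that a
# continuous ramp maps every speed to a class.  Jogging is >6.4 km/h and is
# a mode, not a speed bin.
SLOW_MAX_KMH = 4.05
MODERATE_MAX_KMH = 5.45
JOG_MIN_KMH = 6.4

#: Gait harmonic amplitude per km/h of speed (g), before site/participant gains.
AMPLITUDE_PER_KMH = 0.06

_SITE_GAIN = {"thigh": 1.0, "back": 0.45}
_IMPACT_GAIN = {"thigh": 1.0, "back": 0.7}
# per-axis weights of the gait waveform (x≈anterior-posterior, z≈longitudinal)
_AXIS_WEIGHTS = {"thigh": (1.0, 0.35, 0.75), "back": (0.6, 0.4, 1.0)}
# fixed per-site, per-axis, per-harmonic phase offsets (radians)
_HARMONIC_PHASES = {
    "thigh": ((0.0, 1.1, 2.3), (0.4, 1.7, 2.9), (0.9, 2.1, 0.2)),
    "back": ((0.5, 1.9, 0.7), (1.3, 0.3, 2.5), (0.1, 1.5, 2.8)),
}

HEEL_DROP_PEAK_G = 4.0
HEEL_DROP_WIDTH_S = 0.1
HEEL_DROP_SPACING_S = 1.0


def speed_to_class(
    v: float,
    mode: str,
    slow_max: float = SLOW_MAX_KMH,
    moderate_max: float = MODERATE_MAX_KMH,
) -> str:
    """Map an instantaneous speed (km/h) and locomotion mode to a class."""
    if v < 0:
        raise ValueError("speed must be non-negative")
    if mode == "jog":
        return "jogging"
    if mode != "walk":
        raise ValueError(f"unknown mode {mode!r}")
    if v <= slow_max:
        return "slow"
    if v <= moderate_max:
        return "moderate"
    return "brisk"


def classify_speed(v: np.ndarray, mode: str) -> np.ndarray:
    """Vectorized :func:`speed_to_class`."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    if mode == "jog":
        return np.full(v.shape, "jogging", dtype=object)
    out = np.where(v <= SLOW_MAX_KMH, "slow",
                   np.where(v <= MODERATE_MAX_KMH, "moderate", "brisk"))
    return out.astype(object)


def compute_percent_hrmax(age: float, hr: float) -> float:
    """Heart rate as a percentage of the age-predicted maximum.

    Maximal heart rate is estimated as ``208 - 0.7 * age`` (Tanaka model).
    """
    if not age > 0 or not hr > 0:
        raise ValueError("age and hr must be positive")
    return 100.0 * hr / (208.0 - 0.7 * age)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class ParticipantProfile:
    """Per-participant anthropometrics and gait-signal parameters."""

    participant_id: str
    sex: str
    age: float           # years
    height: float        # cm
    mass: float          # kg
    cadence_intercept: float  # steps/min at zero speed extrapolation
    cadence_slope: float      # steps/min per km/h
    amplitude_gain: float     # dimensionless movement vigour multiplier
    noise_sd: float           # g
    thigh_tilt: float         # degrees from the site's reference axis
    back_tilt: float          # degrees
    rng_seed: int

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 70:
            raise ValueError("age must be within [18, 70] years")
        if not 150 <= self.height <= 200:
            raise ValueError("height must be within [150, 200] cm")
        if not 45 <= self.mass <= 110:
            raise ValueError("mass must be within [45, 110] kg")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.amplitude_gain > 0:
            raise ValueError("amplitude_gain must be positive")
        if not self.cadence_slope > 0:
            raise ValueError("cadence_slope must be positive")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


# mean, SD, min, max by sex (age in years, height cm, mass kg)
_ANTHROPOMETRICS = {
    "female": {"age": (35.5, 12.1, 23.0, 60.0),
               "height": (170.0, 7.5, 156.5, 188.0),
               "mass": (65.7, 8.6, 58.4, 91.0)},
    "male": {"age": (36.9, 12.2, 26.0, 62.0),
             "height": (183.9, 8.0, 173.0, 198.5),
             "mass": (78.6, 8.8, 67.4, 99.5)},
}
_FEMALE_FRACTION = 14 / 24


def sample_cohort(n: int, seed: int) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles emulating the study cohort.

    Anthropometrics are truncated normals bracketing the study sample by
    sex (14:10 female:male mix).  Cadence, movement vigour, sensor tilt and
    noise parameters are simulator-specific heterogeneity knobs.
    Deterministic given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        sex = "female" if rng.uniform() < _FEMALE_FRACTION else "male"
        a = _ANTHROPOMETRICS[sex]
        cohort.append(ParticipantProfile(
            participant_id=f"P{i:02d}",
            sex=sex,
            age=_truncnorm(rng, *a["age"]),
            height=_truncnorm(rng, *a["height"]),
            mass=_truncnorm(rng, *a["mass"]),
            cadence_intercept=_truncnorm(rng, 85.0, 4.0, 75.0, 95.0),
            cadence_slope=_truncnorm(rng, 10.0, 0.6, 8.0, 12.0),
            amplitude_gain=_truncnorm(rng, 1.0, 0.15, 0.7, 1.4),
            noise_sd=0.05,
            thigh_tilt=_truncnorm(rng, 12.0, 4.0, 2.0, 22.0),
            back_tilt=_truncnorm(rng, 6.0, 3.0, 0.0, 15.0),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return cohort


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass
class BoutSpec:
    """One protocol bout.

    ``speed_profile`` is either ``("constant", low, high)`` — a target speed
    interval in km/h within which the realized speed wanders — or
    ``("ramp", start, peak, end)`` — a piecewise-linear up-then-down ramp.
    """

    mode: str
    speed_profile: tuple
    duration: float

    def __post_init__(self) -> None:
        if self.mode not in ("walk", "jog"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        kind, *speeds = self.speed_profile
        if kind not in ("constant", "ramp"):
            raise ValueError(f"unknown speed profile {kind!r}")
        if kind == "constant" and len(speeds) != 2:
            raise ValueError("constant profile needs (low, high)")
        if kind == "ramp" and len(speeds) != 3:
            raise ValueError("ramp profile needs (start, peak, end)")
        if any(s < 0 for s in speeds):
            raise ValueError("speeds must be non-negative")
        if kind == "constant" and speeds[1] < speeds[0]:
            raise ValueError("constant profile needs low <= high")
        if self.mode == "jog" and any(s <= JOG_MIN_KMH for s in speeds):
            raise ValueError(f"jog bouts require speeds > {JOG_MIN_KMH} km/h")


@dataclass
class ProtocolSpec:
    """Ordered bouts plus heel-drop marker configuration."""

    bouts: list[BoutSpec]
    heel_drops_per_marker: int = 3
    marker_positions: tuple[str, ...] = ("start", "end")
    inter_bout_gap: float = 2.0   # seconds of standing, labelled "other"
    marker_pad: float = 5.0       # seconds of standing around each marker group

    def total_bout_duration(self) -> float:
        return sum(b.duration for b in self.bouts)


def default_protocol(bout_duration: float = 300.0) -> ProtocolSpec:
    """The study-style protocol: 5 bouts (slow, moderate, brisk walking,
    jogging, slow→brisk→slow ramp), 3 heel drops at each end.

    Constant-bout target intervals follow the observed per-condition speed
    ranges: slow 2.3–3.7, moderate 4.4–5.3, brisk 5.7–6.8, jogging
    7.1–9.7 km/h.
    """
    return ProtocolSpec(bouts=[
        BoutSpec("walk", ("constant", 2.3, 3.7), bout_duration),
        BoutSpec("walk", ("constant", 4.4, 5.3), bout_duration),
        BoutSpec("walk", ("constant", 5.7, 6.8), bout_duration),
        BoutSpec("jog", ("constant", 7.1, 9.7), bout_duration),
        BoutSpec("walk", ("ramp", 3.1, 6.1, 3.1), bout_duration),
    ])


@dataclass
class SyntheticRecordingSet:
    """One participant's simulated session: both sites, labels, speed."""

    profile: ParticipantProfile
    thigh: Recording
    back: Recording
    labels: LabelTrack
    speed_trace: np.ndarray          # km/h, one value per sample
    marker_times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def participant_id(self) -> str:
        return self.profile.participant_id


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _speed_trace(bout: BoutSpec, n: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    kind, *p = bout.speed_profile
    if kind == "constant":
        lo, hi = p
        if hi > lo:
            v0 = _truncnorm(rng, (lo + hi) / 2, (hi - lo) / 6, lo, hi)
            amp = 0.1 * (hi - lo)
            phase = rng.uniform(0, 2 * np.pi)
            v = np.clip(v0 + amp * np.sin(2 * np.pi * t / 45.0 + phase), lo, hi)
        else:
            v = np.full(n, float(lo))
    else:
        start, peak, end = p
        half = bout.duration / 2
        v = np.where(t < half,
                     start + (peak - start) * t / half,
                     peak + (end - peak) * (t - half) / half)
    return v


def _gravity_vector(tilt_deg: float) -> np.ndarray:
    r = np.deg2rad(tilt_deg)
    return np.array([np.sin(r), 0.0, np.cos(r)])


def _site_signal(profile: ParticipantProfile, site: str, mode: str,
                 speed: np.ndarray, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(speed)
    tilt = profile.thigh_tilt if site == "thigh" else profile.back_tilt
    sig = np.tile(_gravity_vector(tilt), (n, 1))
    f_step = (profile.cadence_intercept + profile.cadence_slope * speed) / 60.0
    phase = 2 * np.pi * np.cumsum(f_step) / fs
    amp = AMPLITUDE_PER_KMH * speed * profile.amplitude_gain * _SITE_GAIN[site]
    for ax in range(3):
        w = _AXIS_WEIGHTS[site][ax]
        for k in (1, 2, 3):
            sig[:, ax] += amp * w / k * np.sin(k * phase + _HARMONIC_PHASES[site][ax][k - 1])
    if mode == "jog":
        width = max(2, int(round(0.06 * fs)))
        steps = np.flatnonzero(np.diff(np.floor(phase / (2 * np.pi))) > 0)
        for i in steps:
            peak = (1.8 + 0.15 * speed[i]) * profile.amplitude_gain * _IMPACT_GAIN[site]
            j = min(i + width, n)
            sig[i:j, 2] += peak * np.sin(np.pi * np.arange(j - i) / width)
    if profile.noise_sd > 0:
        sig += rng.normal(0.0, profile.noise_sd, (n, 3))
    return sig


def simulate_bout(
    profile: ParticipantProfile, bout: BoutSpec, fs: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one bout; returns (thigh (N,3), back (N,3), speed (N,)) arrays.

    Deterministic given the profile (whose ``rng_seed`` seeds the generator
    when ``rng`` is not supplied), the bout and ``fs``.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    if rng is None:
        rng = np.random.default_rng(profile.rng_seed)
    n = int(round(bout.duration * fs))
    speed = _speed_trace(bout, n, fs, rng)
    thigh = _site_signal(profile, "thigh", bout.mode, speed, fs, rng)
    back = _site_signal(profile, "back", bout.mode, speed, fs, rng)
    return thigh, back, speed


def _standing(profile: ParticipantProfile, n: int,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    out = []
    for site in ("thigh", "back"):
        tilt = profile.thigh_tilt if site == "thigh" else profile.back_tilt
        sig = np.tile(_gravity_vector(tilt), (n, 1))
        if profile.noise_sd > 0:
            sig = sig + rng.normal(0.0, profile.noise_sd, (n, 3))
        out.append(sig)
    return out[0], out[1]


def _add_heel_drops(thigh: np.ndarray, back: np.ndarray, fs: float,
                    n_drops: int, first_center_s: float) -> list[float]:
    """Inject half-sine impulses on the z axis of both sites; returns centres."""
    width = int(round(HEEL_DROP_WIDTH_S * fs))
    pulse = HEEL_DROP_PEAK_G * np.sin(np.pi * (np.arange(width) + 0.5) / width)
    centres = []
    for d in range(n_drops):
        c = first_center_s + d * HEEL_DROP_SPACING_S
        i0 = int(round(c * fs - width / 2))
        sl = slice(max(i0, 0), min(i0 + width, len(thigh)))
        seg = pulse[: sl.stop - sl.start]
        thigh[sl, 2] += seg
        back[sl, 2] += seg
        centres.append(c)
    return centres


def simulate_protocol(
    profile: ParticipantProfile, protocol: ProtocolSpec, fs: float,
) -> SyntheticRecordingSet:
    """Simulate a full session: marker pads, bouts and transition gaps.

    Sample-level labels come from :func:`speed_to_class` applied to the
    instantaneous speed trace (mode-aware); pads and gaps are labelled
    ``"other"``.  Deterministic given (profile, protocol, fs).
    """
    if not protocol.bouts:
        raise ValueError("protocol must contain at least one bout")
    if not fs > 0:
        raise ValueError("fs must be positive")
    base = np.random.default_rng(profile.rng_seed)
    child_seeds = base.integers(0, 2**31 - 1, size=len(protocol.bouts) + 3)

    thigh_parts, back_parts, speed_parts, label_parts = [], [], [], []
    marker_times: list[float] = []
    cursor = 0.0

    def add_segment(th, bk, sp, lab):
        nonlocal cursor
        thigh_parts.append(th)
        back_parts.append(bk)
        speed_parts.append(sp)
        label_parts.append(lab)
        cursor += len(sp) / fs

    n_pad = int(round(protocol.marker_pad * fs))
    pad_rng = np.random.default_rng(child_seeds[0])

    # lead-in pad with start markers
    th, bk = _standing(profile, n_pad, pad_rng)
    if "start" in protocol.marker_positions:
        centres = _add_heel_drops(th, bk, fs, protocol.heel_drops_per_marker,
                                  first_center_s=1.0)
        marker_times += [cursor + c for c in centres]
    add_segment(th, bk, np.zeros(n_pad),
                np.full(n_pad, OTHER_LABEL, dtype=object))

    gap_rng = np.random.default_rng(child_seeds[1])
    n_gap = int(round(protocol.inter_bout_gap * fs))
    for b_idx, bout in enumerate(protocol.bouts):
        rng = np.random.default_rng(child_seeds[3 + b_idx])
        th, bk, sp = simulate_bout(profile, bout, fs, rng=rng)
        add_segment(th, bk, sp, classify_speed(sp, bout.mode))
        if b_idx < len(protocol.bouts) - 1 and n_gap > 0:
            th, bk = _standing(profile, n_gap, gap_rng)
            add_segment(th, bk, np.zeros(n_gap),
                        np.full(n_gap, OTHER_LABEL, dtype=object))

    # trailing pad with end markers
    th, bk = _standing(profile, n_pad, pad_rng)
    if "end" in protocol.marker_positions:
        centres = _add_heel_drops(th, bk, fs, protocol.heel_drops_per_marker,
                                  first_center_s=1.0)
        marker_times += [cursor + c for c in centres]
    add_segment(th, bk, np.zeros(n_pad),
                np.full(n_pad, OTHER_LABEL, dtype=object))

    thigh = np.vstack(thigh_parts)
    back = np.vstack(back_parts)
    speed = np.concatenate(speed_parts)
    labels = np.concatenate(label_parts)

    # collapse per-sample labels into half-open intervals
    intervals: list[tuple[float, float, str]] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            intervals.append((run_start / fs, i / fs, labels[run_start]))
            run_start = i

    pid = profile.participant_id
    return SyntheticRecordingSet(
        profile=profile,
        thigh=Recording(pid, "thigh", fs, thigh),
        back=Recording(pid, "back", fs, back),
        labels=LabelTrack(intervals),
        speed_trace=speed,
        marker_times=np.array(marker_times),
    )
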