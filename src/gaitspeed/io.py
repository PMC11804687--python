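"""Accelerometer recording / label-track containers, CSV I/O, resampling,
range clipping and heel-drop synchronization.

A :class:`Recording` is one tri-axial stream (units of g) from one body site
(``thigh`` or ``back``).  A :class:`LabelTrack` is a sorted list of half-open
``[start, end)`` intervals carrying the ground-truth class.  Time is in
seconds relative to the start of the recording.

The CSV dialect is deliberately simple so that any converter from vendor
binary formats (e.g. CWA exports) can emit it::

    # participant=P01
    # site=thigh
    # fs=50
    timestamp,ax,ay,az
    0.000000,0.123456,-0.023456,0.987654
    ...

Timestamps are float seconds or ISO-8601 strings; values are acceleration
in g, written to six decimal places.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

logger = logging.getLogger(__name__)

#: Canonical class order used everywhere downstream (confusion-matrix rows,
#: probability columns, arg-max tie-breaks).
CLASSES = ("slow", "moderate", "brisk", "jogging")

#: Label for transition padding / heel-drop segments; discarded before training.
OTHER_LABEL = "other"

SITES = ("thigh", "back")

#: Sensor saturation range in g.
SENSOR_RANGE_G = 8.0


class FormatError(ValueError):
    """A recording or label CSV violates the expected dialect."""


class DetectionError(RuntimeError):
    """Heel-drop markers could not be located in a recording."""


@dataclass
class Recording:
    """Uniformly (or near-uniformly) sampled tri-axial acceleration stream.

    Parameters
    ----------
    participant_id : str
    site : str
        ``"thigh"`` or ``"back"``.
    fs : float
        Nominal sampling rate in Hz.
    samples : (N, 3) ndarray
        Acceleration in g; columns are the x, y, z axes.
    t0 : float
        Time of the first sample, seconds.
    times : (N,) ndarray, optional
        Explicit per-sample timestamps.  ``None`` means an exactly uniform
        grid ``t0 + arange(N)/fs``.
    """

    participant_id: str
    site: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (N, 3) array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.samples),):
                raise ValueError("times must match samples length")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Nominal duration ``N / fs`` in seconds (uniform grid)."""
        if self.times is not None:
            return float(self.times[-1] - self.times[0]) + 1.0 / self.fs
        return self.n_samples / self.fs

    def time_axis(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return self.t0 + np.arange(self.n_samples) / self.fs

    def magnitude(self) -> np.ndarray:
        """Euclidean vector magnitude per sample, in g."""
        return np.linalg.norm(self.samples, axis=1)


@dataclass
class LabelTrack:
    """Sorted, non-overlapping, half-open labelled intervals."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        iv = [(float(s), float(e), str(c)) for s, e, c in self.intervals]
        for s, e, _ in iv:
            if not e > s:
                raise ValueError(f"interval end must exceed start: ({s}, {e})")
        for (s0, e0, _), (s1, _, _) in zip(iv, iv[1:]):
            if s1 < s0:
                raise ValueError("intervals must be sorted by start")
            if s1 < e0 - 1e-9:
                raise ValueError("intervals must not overlap")
        self.intervals = iv

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def duration_by_class(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s, e, c in self.intervals:
            out[c] = out.get(c, 0.0) + (e - s)
        return out

    def class_at_times(self, t: np.ndarray) -> np.ndarray:
        """Class label for each query time; OTHER_LABEL outside any interval."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s for s, _, _ in self.intervals])
        ends = np.array([e for _, e, _ in self.intervals])
        names = np.array([c for _, _, c in self.intervals], dtype=object)
        idx = np.searchsorted(starts, t, side="right") - 1
        out = np.full(t.shape, OTHER_LABEL, dtype=object)
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = names[idx[ok]]
        return out

    def overlap_durations(self, start: float, end: float) -> dict[str, float]:
        """Seconds of overlap of ``[start, end)`` with each class."""
        out: dict[str, float] = {}
        covered = 0.0
        for s, e, c in self.intervals:
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                out[c] = out.get(c, 0.0) + (hi - lo)
                covered += hi - lo
        gap = (end - start) - covered
        if gap > 1e-9:
            out[OTHER_LABEL] = out.get(OTHER_LABEL, 0.0) + gap
        return out

    def affine(self, a: float, b: float) -> "LabelTrack":
        """Map interval times ``t -> a*t + b`` (a must be positive)."""
        if not a > 0:
            raise ValueError("time scale must be positive")
        return LabelTrack([(a * s + b, a * e + b, c) for s, e, c in self.intervals])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.intervals, columns=["start_s", "end_s", "class"])
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelTrack":
        df = pd.read_csv(path)
        required = ["start_s", "end_s", "class"]
        if list(df.columns) != required:
            raise FormatError(
                f"{path}: expected columns {required}, found {list(df.columns)}"
            )
        return cls(list(df.itertuples(index=False, name=None)))


# ---------------------------------------------------------------------------
# Recording CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["timestamp", "ax", "ay", "az"]


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Write a recording in the package CSV dialect (6 decimal places)."""
    path = Path(path)
    t = recording.time_axis()
    with open(path, "w") as fh:
        fh.write(f"# participant={recording.participant_id}\n")
        fh.write(f"# site={recording.site}\n")
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write("timestamp,ax,ay,az\n")
        for ti, (x, y, z) in zip(t, recording.samples):
            fh.write(f"{ti:.6f},{x:.6f},{y:.6f},{z:.6f}\n")


def read_recording_csv(path: str | Path) -> Recording:
    """Read a recording CSV; see module docstring for the dialect.

    Raises
    ------
    FormatError
        On missing columns or non-monotone timestamps, naming the offending
        line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=n_meta)
    if list(df.columns) != _REQUIRED_COLUMNS:
        raise FormatError(
            f"{path}, line {n_meta + 1}: expected columns {_REQUIRED_COLUMNS}, "
            f"found {list(df.columns)}"
        )
    ts = df["timestamp"]
    if ts.dtype == object:
        try:
            times = ts.astype(float).to_numpy()
        except ValueError:
            parsed = pd.to_datetime(ts, format="ISO8601")
            times = parsed.astype("int64").to_numpy() / 1e9
            times = times - times[0]
    else:
        times = ts.to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        # +2 header line +n_meta meta lines, bad[0]+1 is the second of the pair
        lineno = n_meta + 2 + int(bad[0]) + 1
        raise FormatError(f"{path}, line {lineno}: non-monotone timestamp")
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    fs = float(meta.get("fs", 0)) or 1.0 / float(np.median(np.diff(times)))
    rec = Recording(
        participant_id=meta.get("participant", "unknown"),
        site=meta.get("site", "unknown"),
        fs=fs,
        samples=samples,
        t0=float(times[0]),
        times=times,
    )
    # collapse to an implicit uniform grid when the timestamps are exact
    grid = rec.t0 + np.arange(rec.n_samples) / fs
    if np.max(np.abs(grid - times)) < 1e-6:
        rec = replace(rec, times=None)
    return rec


# ---------------------------------------------------------------------------
# Resampling / clipping
# ---------------------------------------------------------------------------

def resample_uniform(recording: Recording, target_fs: float) -> Recording:
    """Linearly interpolate onto a uniform ``1/target_fs`` grid.

    The grid spans the original time range; the output declares
    ``fs == target_fs`` with an implicit uniform time axis.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if recording.n_samples < 2:
        raise ValueError("need at least 2 samples to resample")
    t = recording.time_axis()
    span = float(t[-1] - t[0])
    n = int(np.floor(span * target_fs + 1e-9)) + 1
    grid = t[0] + np.arange(n) / target_fs
    out = np.column_stack(
        [np.interp(grid, t, recording.samples[:, i]) for i in range(3)]
    )
    return replace(recording, fs=float(target_fs), samples=out, t0=float(t[0]),
                   times=None)


def clip_to_range(recording: Recording, limit: float = SENSOR_RANGE_G) -> Recording:
    """Saturate components outside ``±limit`` g (sensor range emulation)."""
    if not limit > 0:
        raise ValueError("limit must be positive")
    n_clipped = int(np.count_nonzero(np.abs(recording.samples) > limit))
    if n_clipped:
        logger.info("clip_to_range: saturated %d samples at ±%g g", n_clipped, limit)
    return replace(recording, samples=np.clip(recording.samples, -limit, limit))


# ---------------------------------------------------------------------------
# Heel-drop detection and synchronization
# ---------------------------------------------------------------------------

def detect_heel_drops(
    recording: Recording,
    expected_per_marker: int = 3,
    min_height: float = 1.0,
    min_separation: float = 0.4,
) -> np.ndarray:
    """Locate heel-drop impulse centres at both ends of a recording.

    Peak detection runs on the high-pass-filtered (4th-order Butterworth,
    5 Hz, zero-phase) vector magnitude.  The first and last
    ``expected_per_marker`` peaks are taken as the start / end marker groups;
    gait and jogging impacts between the markers are ignored by position.

    Returns the ``2 * expected_per_marker`` event times in seconds.

    Raises
    ------
    DetectionError
        If fewer peaks than expected are found.
    """
    if recording.duration <= 10:
        raise ValueError("recording must be longer than 10 s")
    mag = recording.magnitude()
    b, a = butter(4, 5.0, "highpass", fs=recording.fs)
    hp = filtfilt(b, a, mag)
    peaks, _ = find_peaks(
        hp, height=min_height, distance=max(1, int(min_separation * recording.fs))
    )
    k = int(expected_per_marker)
    if len(peaks) < 2 * k:
        raise DetectionError(
            f"expected at least {2 * k} heel-drop impulses, found {len(peaks)}"
        )
    t = recording.time_axis()[peaks]
    return np.concatenate([t[:k], t[-k:]])


def _estimate_alignment(
    events_a: np.ndarray, events_b: np.ndarray, expected_per_marker: int = 3
) -> tuple[float, float]:
    """Affine clock map ``t_a = alpha * t_b + beta`` from marker centroids."""
    k = expected_per_marker
    sa, ea = float(np.mean(events_a[:k])), float(np.mean(events_a[k:]))
    sb, eb = float(np.mean(events_b[:k])), float(np.mean(events_b[k:]))
    alpha = (ea - sa) / (eb - sb)
    beta = sa - alpha * sb
    return alpha, beta


def synchronize_streams(
    rec_a: Recording,
    rec_b: Recording,
    labels: LabelTrack,
    expected_per_marker: int = 3,
) -> tuple[Recording, Recording, LabelTrack]:
    """Warp ``rec_b`` (and its labels) onto ``rec_a``'s clock.

    A constant offset plus linear drift is estimated from the paired
    start/end heel-drop marker centroids; ``rec_b`` is then linearly
    interpolated onto ``rec_a``'s sample grid and the label intervals are
    mapped with the same affine transform.
    """
    events_a = detect_heel_drops(rec_a, expected_per_marker)
    events_b = detect_heel_drops(rec_b, expected_per_marker)
    alpha, beta = _estimate_alignment(events_a, events_b, expected_per_marker)
    logger.info("synchronize_streams: drift %.6f, offset %.4f s", alpha - 1.0, beta)
    tb = alpha * rec_b.time_axis() + beta
    grid = rec_a.time_axis()
    aligned = np.column_stack(
        [np.interp(grid, tb, rec_b.samples[:, i]) for i in range(3)]
    )
    rec_b_aligned = replace(
        rec_b, fs=rec_a.fs, samples=aligned, t0=float(grid[0]), times=None
    )
    return rec_a, rec_b_aligned, labels.affine(alpha, beta)
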