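"""Window segmentation, ground-truth window labelling, and the per-window
statistical feature catalogue.

Catalogue layout
----------------
Each sensor contributes a 78-feature block:

* 12 time-domain statistics x 4 channels (x, y, z axes and the vector
  magnitude): mean, std (population), median, min, max, range, iqr, rms,
  skewness, excess kurtosis, zero-crossing rate of the demeaned signal,
  energy (mean squared value) ............................................ 48
* gravity-component mean per axis (4th-order zero-phase Butterworth
  low-pass at 1 Hz) ........................................................ 3
* axis-pair Pearson correlations (xy, xz, yz) .............................. 3
* 8 frequency-domain statistics x 3 axes, computed on the body component
  (signal minus gravity) with a periodic Hann taper and a single-window
  FFT (bin width 1/length Hz, DC bin excluded): dominant frequency, power
  at the dominant frequency, spectral centroid, normalized spectral
  entropy, band powers 0-1 / 1-3 / 3-10 Hz, total body-band power ......... 24

The dual (thigh + back) set-up adds 5 cross-sensor features — magnitude
correlation, body-magnitude correlation, body-magnitude RMS ratio,
body-magnitude dominant-frequency difference, magnitude range ratio —
for 2 x 78 + 5 = 161 features per window.  Single-sensor set-ups emit the
78-feature block alone.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.signal.windows import hann

from .io import CLASSES, OTHER_LABEL, LabelTrack, Recording

logger = logging.getLogger(__name__)

TIME_STATS = ("mean", "std", "median", "min", "max", "range", "iqr", "rms",
              "skewness", "kurtosis", "zcr", "energy")
FREQ_STATS = ("dom_freq", "dom_power", "spectral_centroid", "spectral_entropy",
              "bandpower_0_1", "bandpower_1_3", "bandpower_3_10",
              "bandpower_total")
AXES = ("x", "y", "z")
CHANNELS = AXES + ("mag",)
PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))
CROSS_FEATURES = ("cross_mag_corr", "cross_body_corr", "cross_body_rms_ratio",
                  "cross_dom_freq_diff", "cross_range_ratio")

SETUPS = ("thigh", "back", "dual")

#: Metadata columns that precede the feature block in a FeatureMatrix.
METADATA_COLUMNS = ["participant_id", "setup", "window_length", "label",
                    "start_s"]


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    channel: str
    formula: str


@dataclass
class FeatureCatalogue:
    """Ordered, named feature definitions for one sensor set-up."""

    setup: str
    entries: list[FeatureEntry]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([e.__dict__ for e in self.entries], fh, indent=1)


def build_catalogue(setup: str) -> FeatureCatalogue:
    """Build the feature catalogue for ``thigh``, ``back`` or ``dual``."""
    if setup not in SETUPS:
        raise ValueError(f"setup must be one of {SETUPS}, got {setup!r}")
    sensors = ("thigh", "back") if setup == "dual" else (setup,)
    entries: list[FeatureEntry] = []
    for s in sensors:
        for ch in CHANNELS:
            for st in TIME_STATS:
                entries.append(FeatureEntry(f"{s}_{ch}_{st}", f"{s}:{ch}", st))
        for ax in AXES:
            entries.append(FeatureEntry(f"{s}_{ax}_gravity_mean", f"{s}:{ax}",
                                        "gravity_mean"))
        for a, b in PAIRS:
            entries.append(FeatureEntry(f"{s}_corr_{a}{b}", f"{s}:{a},{b}",
                                        "pearson_corr"))
        for ax in AXES:
            for st in FREQ_STATS:
                entries.append(FeatureEntry(f"{s}_{ax}_{st}", f"{s}:{ax}:body",
                                            st))
    if setup == "dual":
        for name in CROSS_FEATURES:
            entries.append(FeatureEntry(name, "thigh,back", name))
    names = [e.name for e in entries]
    assert len(names) == len(set(names))
    return FeatureCatalogue(setup=setup, entries=entries)


# ---------------------------------------------------------------------------
# Primitive computations
# ---------------------------------------------------------------------------

def split_gravity_body(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a window into gravity and body components.

    Gravity is a 4th-order zero-phase Butterworth low-pass at 1 Hz; the body
    component is the residual.  Works on (N,) or (N, 3) arrays.
    """
    b, a = butter(4, 1.0, "lowpass", fs=fs)
    gravity = filtfilt(b, a, samples, axis=0)
    return gravity, samples - gravity


def _time_stats(x: np.ndarray) -> dict[str, float]:
    n = len(x)
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d ** 2))
    sd = float(np.sqrt(m2))
    if m2 > 1e-24:
        skew = float(np.mean(d ** 3)) / m2 ** 1.5
        kurt = float(np.mean(d ** 4)) / m2 ** 2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    sb = np.signbit(d)
    zcr = float(np.count_nonzero(sb[1:] != sb[:-1])) / (n - 1)
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": m,
        "std": sd,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "iqr": float(q75 - q25),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "skewness": skew,
        "kurtosis": kurt,
        "zcr": zcr,
        "energy": float(np.mean(x ** 2)),
    }


def _freq_stats(x: np.ndarray, fs: float) -> dict[str, float]:
    """Spectral statistics of one (body-component) channel.

    Power spectrum of the Hann-tapered window; the DC bin is excluded from
    every statistic.  A numerically silent window yields all zeros.
    """
    n = len(x)
    w = hann(n, sym=False)
    P = np.abs(np.fft.rfft(x * w)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    Pb, fb = P[1:], freqs[1:]
    total = float(Pb.sum())
    zeros = {st: 0.0 for st in FREQ_STATS}
    if total <= 1e-20 or len(Pb) == 0:
        return zeros
    k = int(np.argmax(Pb))
    p = Pb / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p))) if len(p) > 1 else 0.0

    def band(lo, hi):
        sel = (fb >= lo) & (fb < hi)
        return float(Pb[sel].sum())

    return {
        "dom_freq": float(fb[k]),
        "dom_power": float(Pb[k]),
        "spectral_centroid": float((fb * Pb).sum() / total),
        "spectral_entropy": entropy,
        "bandpower_0_1": band(0.0, 1.0),
        "bandpower_1_3": band(1.0, 3.0),
        "bandpower_3_10": band(3.0, 10.0),
        "bandpower_total": total,
    }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either input has zero variance."""
    da, db = a - a.mean(), b - b.mean()
    va, vb = float(np.mean(da ** 2)), float(np.mean(db ** 2))
    if va <= 1e-24 or vb <= 1e-24:
        return 0.0
    return float(np.mean(da * db) / np.sqrt(va * vb))


def _sensor_features(arr: np.ndarray, fs: float) -> tuple[dict[str, float], dict]:
    """All 78 per-sensor features (unprefixed) plus cross-feature inputs."""
    mag = np.linalg.norm(arr, axis=1)
    gravity, body = split_gravity_body(arr, fs)
    out: dict[str, float] = {}
    chans = {"x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2], "mag": mag}
    for ch, x in chans.items():
        for st, v in _time_stats(x).items():
            out[f"{ch}_{st}"] = v
    for i, ax in enumerate(AXES):
        out[f"{ax}_gravity_mean"] = float(gravity[:, i].mean())
    for a, b in PAIRS:
        out[f"corr_{a}{b}"] = _safe_corr(chans[a], chans[b])
    for i, ax in enumerate(AXES):
        for st, v in _freq_stats(body[:, i], fs).items():
            out[f"{ax}_{st}"] = v
    body_mag = np.linalg.norm(body, axis=1)
    extras = {"mag": mag, "body_mag": body_mag}
    return out, extras


def _cross_features(extras_t: dict, extras_b: dict, fs: float) -> dict[str, float]:
    magT, magB = extras_t["mag"], extras_b["mag"]
    bmT, bmB = extras_t["body_mag"], extras_b["body_mag"]
    rms_b = float(np.sqrt(np.mean(bmB ** 2)))
    rng_b = float(magB.max() - magB.min())
    fT = _freq_stats(bmT, fs)["dom_freq"]
    fB = _freq_stats(bmB, fs)["dom_freq"]
    return {
        "cross_mag_corr": _safe_corr(magT, magB),
        "cross_body_corr": _safe_corr(bmT, bmB),
        "cross_body_rms_ratio": (float(np.sqrt(np.mean(bmT ** 2))) / rms_b
                                 if rms_b > 1e-12 else 0.0),
        "cross_dom_freq_diff": fT - fB,
        "cross_range_ratio": (float(magT.max() - magT.min()) / rng_b
                              if rng_b > 1e-12 else 0.0),
    }


def extract_window_features(
    windows: dict[str, np.ndarray], fs: float, catalogue: FeatureCatalogue,
) -> np.ndarray:
    """Feature vector (catalogue order) for one window.

    ``windows`` maps site name to its (N, 3) sample block; the dual
    catalogue requires both sites.

    Raises
    ------
    ValueError
        On non-finite input samples.
    """
    values: dict[str, float] = {}
    extras: dict[str, dict] = {}
    sensors = ("thigh", "back") if catalogue.setup == "dual" else (catalogue.setup,)
    for s in sensors:
        arr = np.asarray(windows[s], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite samples in {s} window")
        feats, ex = _sensor_features(arr, fs)
        values.update({f"{s}_{k}": v for k, v in feats.items()})
        extras[s] = ex
    if catalogue.setup == "dual":
        values.update(_cross_features(extras["thigh"], extras["back"], fs))
    return np.array([values[n] for n in catalogue.names])


# ---------------------------------------------------------------------------
# Segmentation and labelling
# ---------------------------------------------------------------------------

@dataclass
class WindowSpec:
    """Non-overlapping fixed-length windows; length in seconds."""

    length: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("window length must be positive")

    def n_samples(self, fs: float) -> int:
        n = self.length * fs
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(f"length*fs must be a positive integer, got {n}")
        return int(round(n))


@dataclass
class Window:
    start_s: float
    label: str | None            # None = discarded
    data: dict[str, np.ndarray]  # site -> (n, 3) block


def label_window(labels: LabelTrack, start: float, end: float) -> str | None:
    """Strict-majority class of ``[start, end)``; ties or an "other"
    majority yield ``None`` (discard)."""
    durations = labels.overlap_durations(start, end)
    winner = max(durations, key=lambda c: durations[c])
    if durations[winner] <= (end - start) / 2 + 1e-9:
        # require a strict majority; the +eps keeps exact 50/50 ties out
        return None
    if winner == OTHER_LABEL:
        return None
    return winner


def segment_windows(
    thigh: Recording, back: Recording, labels: LabelTrack, spec: WindowSpec,
) -> list[Window]:
    """Cut aligned, non-overlapping windows; trailing partial window dropped.

    Both recordings must share the sampling rate and length (synchronized).
    """
    if thigh.fs != back.fs:
        raise ValueError("recordings must share a sampling rate")
    if thigh.n_samples != back.n_samples:
        raise ValueError("recordings must be synchronized to equal length")
    wn = spec.n_samples(thigh.fs)
    n_win = thigh.n_samples // wn
    if n_win == 0:
        logger.warning("window of %.3g s longer than recording (%.3g s)",
                       spec.length, thigh.duration)
        return []
    out = []
    for i in range(n_win):
        a, b = i * wn, (i + 1) * wn
        t0 = thigh.t0 + a / thigh.fs
        out.append(Window(
            start_s=t0,
            label=label_window(labels, t0, t0 + spec.length),
            data={"thigh": thigh.samples[a:b], "back": back.samples[a:b]},
        ))
    return out


def build_feature_matrix(
    recording_sets, setup: str, spec: WindowSpec,
) -> pd.DataFrame:
    """Concatenate labelled window features for a cohort into a FeatureMatrix.

    Rows are ordered by (participant, window start); discarded windows are
    excluded.  The output holds :data:`METADATA_COLUMNS` first, then the
    catalogue features in order.
    """
    catalogue = build_catalogue(setup)
    rates = {rs.thigh.fs for rs in recording_sets} | {rs.back.fs for rs in recording_sets}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates in input: {sorted(rates)}")
    rows = []
    for rs in sorted(recording_sets, key=lambda r: r.thigh.participant_id):
        fs = rs.thigh.fs
        for w in segment_windows(rs.thigh, rs.back, rs.labels, spec):
            if w.label is None:
                continue
            vec = extract_window_features(w.data, fs, catalogue)
            rows.append((rs.thigh.participant_id, setup, spec.length, w.label,
                         w.start_s, *vec))
    columns = METADATA_COLUMNS + catalogue.names
    df = pd.DataFrame(rows, columns=columns)
    return df


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a FeatureMatrix."""
    return [c for c in matrix.columns if c not in METADATA_COLUMNS]
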