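"""Independent brute-force reference implementations of every catalogue
feature, kept deliberately naive (explicit loops, closed formulas) so they
share no code path with the package's vectorized extractor."""
from __future__ import annotations

import math

import numpy as np
from scipy.signal import butter, filtfilt


def naive_time_stats(x) -> dict:
    x = [float(v) for v in x]
    n = len(x)
    m = sum(x) / n
    d = [v - m for v in x]
    m2 = sum(v ** 2 for v in d) / n
    m3 = sum(v ** 3 for v in d) / n
    m4 = sum(v ** 4 for v in d) / n
    skew = m3 / m2 ** 1.5 if m2 > 1e-24 else 0.0
    kurt = m4 / m2 ** 2 - 3.0 if m2 > 1e-24 else 0.0
    # sign convention matches numpy.signbit (zero counts as non-negative)
    crossings = sum(1 for a, b in zip(d, d[1:])
                    if np.signbit(a) != np.signbit(b))
    q75 = float(np.percentile(np.array(x), 75))
    q25 = float(np.percentile(np.array(x), 25))
    sx = sorted(x)
    return {
        "mean": m,
        "std": math.sqrt(m2),
        "median": float(np.median(np.array(x))),
        "min": sx[0],
        "max": sx[-1],
        "range": sx[-1] - sx[0],
        "iqr": q75 - q25,
        "rms": math.sqrt(sum(v ** 2 for v in x) / n),
        "skewness": skew,
        "kurtosis": kurt,
        "zcr": crossings / (n - 1),
        "energy": sum(v ** 2 for v in x) / n,
    }


def naive_gravity(arr: np.ndarray, fs: float) -> np.ndarray:
    b, a = butter(4, 1.0, "lowpass", fs=fs)
    return filtfilt(b, a, np.asarray(arr, dtype=float), axis=0)


def naive_freq_stats(x, fs: float) -> dict:
    x = np.asarray(x, dtype=float)
    n = len(x)
    # periodic Hann taper written out explicitly
    w = np.array([0.5 - 0.5 * math.cos(2 * math.pi * k / n) for k in range(n)])
    X = np.fft.rfft(x * w)
    P = [abs(c) ** 2 for c in X]
    freqs = [k * fs / n for k in range(len(P))]
    Pb, fb = P[1:], freqs[1:]
    total = sum(Pb)
    if total <= 1e-20 or not Pb:
        return {k: 0.0 for k in ("dom_freq", "dom_power", "spectral_centroid",
                                 "spectral_entropy", "bandpower_0_1",
                                 "bandpower_1_3", "bandpower_3_10",
                                 "bandpower_total")}
    k_dom = max(range(len(Pb)), key=lambda k: Pb[k])
    centroid = sum(f * p for f, p in zip(fb, Pb)) / total
    probs = [p / total for p in Pb]
    ent = -sum(p * math.log(p) for p in probs if p > 0)
    ent = ent / math.log(len(probs)) if len(probs) > 1 else 0.0

    def band(lo, hi):
        return sum(p for f, p in zip(fb, Pb) if lo <= f < hi)

    return {
        "dom_freq": fb[k_dom],
        "dom_power": Pb[k_dom],
        "spectral_centroid": centroid,
        "spectral_entropy": ent,
        "bandpower_0_1": band(0.0, 1.0),
        "bandpower_1_3": band(1.0, 3.0),
        "bandpower_3_10": band(3.0, 10.0),
        "bandpower_total": total,
    }


def naive_corr(a, b) -> float:
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    va = sum((v - ma) ** 2 for v in a) / n
    vb = sum((v - mb) ** 2 for v in b) / n
    if va <= 1e-24 or vb <= 1e-24:
        return 0.0
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    return cov / math.sqrt(va * vb)


def naive_sensor_block(arr: np.ndarray, fs: float) -> dict:
    """All 78 per-sensor features, unprefixed, naive formulas."""
    arr = np.asarray(arr, dtype=float)
    mag = [math.sqrt(x * x + y * y + z * z) for x, y, z in arr]
    gravity = naive_gravity(arr, fs)
    body = arr - gravity
    out = {}
    chans = {"x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2], "mag": mag}
    for ch, x in chans.items():
        for st, v in naive_time_stats(x).items():
            out[f"{ch}_{st}"] = v
    for i, ax in enumerate(("x", "y", "z")):
        g = gravity[:, i]
        out[f"{ax}_gravity_mean"] = sum(g) / len(g)
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
        out[f"corr_{a}{b}"] = naive_corr(chans[a], chans[b])
    for i, ax in enumerate(("x", "y", "z")):
        for st, v in naive_freq_stats(body[:, i], fs).items():
            out[f"{ax}_{st}"] = v
    return out


def naive_all_features(windows: dict, fs: float, setup: str) -> dict:
    """Naive recomputation of the full catalogue for one window."""
    sensors = ("thigh", "back") if setup == "dual" else (setup,)
    out = {}
    body_mags = {}
    mags = {}
    for s in sensors:
        arr = np.asarray(windows[s], dtype=float)
        for k, v in naive_sensor_block(arr, fs).items():
            out[f"{s}_{k}"] = v
        body = arr - naive_gravity(arr, fs)
        body_mags[s] = [math.sqrt(x * x + y * y + z * z) for x, y, z in body]
        mags[s] = [math.sqrt(x * x + y * y + z * z) for x, y, z in arr]
    if setup == "dual":
        bmT, bmB = body_mags["thigh"], body_mags["back"]
        magT, magB = mags["thigh"], mags["back"]
        rmsT = math.sqrt(sum(v * v for v in bmT) / len(bmT))
        rmsB = math.sqrt(sum(v * v for v in bmB) / len(bmB))
        rngT = max(magT) - min(magT)
        rngB = max(magB) - min(magB)
        out["cross_mag_corr"] = naive_corr(magT, magB)
        out["cross_body_corr"] = naive_corr(bmT, bmB)
        out["cross_body_rms_ratio"] = rmsT / rmsB if rmsB > 1e-12 else 0.0
        out["cross_dom_freq_diff"] = (naive_freq_stats(bmT, fs)["dom_freq"]
                                      - naive_freq_stats(bmB, fs)["dom_freq"])
        out["cross_range_ratio"] = rngT / rngB if rngB > 1e-12 else 0.0
    return out
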