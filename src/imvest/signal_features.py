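"""Multimodal physiological feature extraction.

Computes, per 2.5-minute analysis block, 25 autonomic variables from ECG
(heart rate and a broad HRV panel), respiration (rate/depth/width/ratio from
robust peak detection) and electrodermal activity (trough-to-peak SCR counts,
continuous-decomposition SCR counts and tonic level), plus the
baseline-subtracted (prefix ``d``) variant of every variable.

Input signals are plain time series (``RawSignal``) or precomputed
normal-to-normal beat interval series (``NNSeries``).  All detector and
cleaning thresholds are declared defaults and configurable.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RawSignal",
    "NNSeries",
    "FeatureBlock",
    "VARIABLES",
    "BLOCKS",
    "decimate_signal",
    "detect_r_peaks",
    "clean_nn",
    "segment_blocks",
    "segment_raw_signal",
    "hrv_time_poincare",
    "hrv_geometric",
    "hrv_prsa",
    "hrv_entropy",
    "hrv_spectral",
    "rr_hrv",
    "respiration_features",
    "scr_trough_to_peak",
    "scr_cda",
    "extract_block_features",
    "build_feature_table",
    "feature_table_to_tidy",
    "read_signal_csv",
    "write_signal_csv",
]

#: the 25 physiological variables, in canonical order
VARIABLES = [
    "HR", "SD1", "SD2", "SD1SD2", "TINN", "TRI", "ac", "dc", "SampEn", "ApEn",
    "lf", "hf", "lfhf", "ttlpwr", "RMSSD", "SDNN", "pnn50", "rrHRV",
    "RespRate", "RespDepth", "RespWidth", "RespRatio",
    "nSCRcda", "nSCRttp", "Toniccda",
]

#: the 8 analysis blocks in session order
BLOCKS = ["BL1", "BL2", "training", "T1", "T2", "T3", "T4", "Tpost"]


@dataclass
class RawSignal:
    channel: str  # ecg | eda | resp
    sampling_rate: float  # Hz
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.channel}: non-finite samples after ingestion")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class NNSeries:
    """Beat times (s) and the normal-to-normal intervals (ms) between them."""

    beat_times: np.ndarray
    nn_intervals: np.ndarray
    flagged: bool = False  # True when detection/cleaning declared it unusable

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn_intervals = np.asarray(self.nn_intervals, dtype=float)

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray) -> "NNSeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(bt, np.diff(bt) * 1000.0, flagged=len(bt) < 2)

    @property
    def n(self) -> int:
        return len(self.nn_intervals)


@dataclass
class FeatureBlock:
    block: str
    values: dict = field(default_factory=dict)  # variable -> float (NaN absent)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def decimate_signal(raw: RawSignal, factor: int) -> RawSignal:
    """FIR anti-alias low-pass then keep every ``factor``-th sample.

    The filter is a zero-phase windowed-sinc low-pass with cutoff at 80% of
    the post-decimation Nyquist and a narrow transition band, so components
    near the new Nyquist are strongly attenuated before down-sampling.
    """
    if factor < 2:
        raise ValueError("decimation factor must be >= 2")
    numtaps = 30 * factor + 1
    fir = sps.firwin(numtaps, 0.8 / factor)
    filtered = sps.filtfilt(fir, [1.0], raw.samples)
    out = filtered[::factor]
    return RawSignal(raw.channel, raw.sampling_rate / factor, out, raw.start_time)


def detect_r_peaks(ecg: RawSignal, min_rr_s: float = 0.3) -> NNSeries:
    """R-peak detection: band-pass, energy, adaptive threshold, local refinement.

    A light Pan-Tompkins-style detector: the ECG is zero-phase band-passed
    (5-25 Hz), squared, and candidate peaks above an adaptive robust threshold
    and separated by a refractory period are refined to the local extremum of
    the band-passed signal.  Beat-to-beat differences give the NN series.
    """
    fs = ecg.sampling_rate
    if fs < 250:
        raise ValueError("ECG must be sampled at >= 250 Hz")
    x = ecg.samples - np.median(ecg.samples)
    if np.ptp(x) == 0:
        return NNSeries(np.array([]), np.array([]), flagged=True)
    sos = sps.butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    e = y * y
    # adaptive threshold: a fraction of the typical beat energy, estimated
    # robustly from the upper tail of the energy envelope
    tail = np.quantile(e, 0.995)
    if tail <= 0:
        return NNSeries(np.array([]), np.array([]), flagged=True)
    thr = 0.15 * tail
    idx, _ = sps.find_peaks(e, height=thr, distance=max(1, int(min_rr_s * fs)))
    if len(idx) == 0:
        return NNSeries(np.array([]), np.array([]), flagged=True)
    # refine to the extremum of |y| within +/-50 ms
    half = max(1, int(0.05 * fs))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(y[lo:hi]))))
    beats = np.unique(refined)
    times = ecg.start_time + beats / fs
    return NNSeries.from_beat_times(times)


def clean_nn(
    nn: NNSeries,
    nn_range_ms: tuple[float, float] = (300.0, 2000.0),
    max_rel_change: float = 0.20,
    max_rejection: float = 0.20,
) -> tuple[NNSeries, float]:
    """Reject implausible intervals; report the rejection fraction.

    An interval is rejected if it lies outside ``nn_range_ms`` or differs by
    more than ``max_rel_change`` from the previous accepted interval.  Above a
    ``max_rejection`` fraction the series is flagged unusable.
    """
    if nn.n == 0:
        raise ValueError("clean_nn requires a non-empty NN series")
    keep_idx: list[int] = []
    prev: float | None = None
    for i, v in enumerate(nn.nn_intervals):
        if not (nn_range_ms[0] <= v <= nn_range_ms[1]):
            continue
        if prev is not None and abs(v - prev) > max_rel_change * prev:
            continue
        keep_idx.append(i)
        prev = v
    rejection = 1.0 - len(keep_idx) / nn.n
    kept = nn.nn_intervals[keep_idx]
    # each interval is stamped with the beat time at which it ends
    end_times = nn.beat_times[1:][keep_idx] if len(nn.beat_times) == nn.n + 1 else nn.beat_times[keep_idx]
    out = NNSeries(end_times, kept, flagged=(rejection > max_rejection or len(keep_idx) == 0))
    return out, rejection


def segment_blocks(
    series: NNSeries, schedule: list[tuple[str, float, float]]
) -> dict[str, NNSeries]:
    """Slice an NN series into blocks; half-open [start, end) windows.

    The schedule must be contiguous (no gaps or overlaps).  An interval is
    assigned to the block containing the beat time that ends it.
    """
    _validate_schedule(schedule)
    out = {}
    if len(series.beat_times) == series.n + 1:
        t = series.beat_times[1:]  # interval end times
    else:
        t = series.beat_times
    for label, start, end in schedule:
        m = (t >= start) & (t < end)
        out[label] = NNSeries(t[m], series.nn_intervals[m], flagged=series.flagged)
    return out


def segment_raw_signal(
    raw: RawSignal, schedule: list[tuple[str, float, float]]
) -> dict[str, RawSignal]:
    """Slice a raw signal into blocks on half-open [start, end) windows."""
    _validate_schedule(schedule)
    out = {}
    for label, start, end in schedule:
        i0 = int(np.ceil((start - raw.start_time) * raw.sampling_rate - 1e-9))
        i1 = int(np.ceil((end - raw.start_time) * raw.sampling_rate - 1e-9))
        i0, i1 = max(i0, 0), min(i1, len(raw.samples))
        out[label] = RawSignal(raw.channel, raw.sampling_rate, raw.samples[i0:i1],
                               raw.start_time + i0 / raw.sampling_rate)
    return out


def _validate_schedule(schedule: list[tuple[str, float, float]]) -> None:
    for (_, s0, e0), (_, s1, _e1) in zip(schedule, schedule[1:]):
        if not math.isclose(e0, s1, abs_tol=1e-9):
            raise ValueError("block schedule must be contiguous (gap/overlap found)")
        if e0 <= s0:
            raise ValueError("blocks must have positive duration")


# ---------------------------------------------------------------------------
# HRV: time domain and Poincare
# ---------------------------------------------------------------------------


def hrv_time_poincare(nn: NNSeries | np.ndarray) -> dict[str, float]:
    """HR, RMSSD, SDNN, pnn50 and Poincare SD1/SD2/SD1SD2.

    SD1 is defined as RMSSD/sqrt(2) and SD2 as sqrt(2*SDNN^2 - SD1^2), so the
    identities SD1 = RMSSD/sqrt(2) and SD1^2 + SD2^2 = 2*SDNN^2 hold exactly.
    pnn50 counts successive differences strictly greater than 50 ms.
    """
    x = nn.nn_intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 2:
        return {k: float("nan") for k in ("HR", "RMSSD", "SDNN", "pnn50", "SD1", "SD2", "SD1SD2")}
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d * d)))
    sdnn = float(np.std(x))  # population std: keeps the Poincare identity exact
    sd1 = rmssd / math.sqrt(2.0)
    sd2_sq = 2.0 * sdnn * sdnn - sd1 * sd1
    sd2 = math.sqrt(sd2_sq) if sd2_sq > 0 else 0.0
    return {
        "HR": 60000.0 / float(np.mean(x)),
        "RMSSD": rmssd,
        "SDNN": sdnn,
        "pnn50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
        "SD1": sd1,
        "SD2": sd2,
        "SD1SD2": sd1 / sd2 if sd2 > 0 else float("nan"),
    }


# ---------------------------------------------------------------------------
# HRV: geometric (TINN / TRI)
# ---------------------------------------------------------------------------


def hrv_geometric(nn: NNSeries | np.ndarray, bin_width: float = 7.8125) -> dict[str, float]:
    """Triangular index TRI and TINN from the NN histogram.

    The histogram uses HRV-standard 1/128 s bins aligned to multiples of the
    bin width.  TRI = total count / modal bin count.  TINN is the base width
    of the least-squares triangle fitted to the histogram (grid search over
    base endpoints on bin centers, apex pinned at the mode).
    """
    x = nn.nn_intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 1:
        return {"TINN": float("nan"), "TRI": float("nan")}
    lo = math.floor(x.min() / bin_width)
    hi = math.floor(x.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    k = int(np.argmax(counts))
    y = counts.astype(float)
    if np.count_nonzero(counts) <= 1:
        return {"TINN": 0.0, "TRI": float(len(x)) / counts[k]}
    tri = float(len(x)) / float(counts[k])

    # least-squares triangle: apex at (centers[k], y[k]); search N <= k <= M
    best = (math.inf, 0.0)
    xk, yk = centers[k], y[k]
    for n_i in range(0, k + 1):
        for m_i in range(k, len(centers)):
            xn, xm = centers[n_i] - bin_width / 2.0, centers[m_i] + bin_width / 2.0
            if xm <= xn:
                continue
            q = np.zeros_like(y)
            left = slice(n_i, k + 1)
            right = slice(k, m_i + 1)
            if xk > xn:
                q[left] = yk * (centers[left] - xn) / (xk - xn)
            else:
                q[left] = yk
            if xm > xk:
                q[right] = yk * (xm - centers[right]) / (xm - xk)
            q[k] = yk
            err = float(np.sum((y - q) ** 2))
            if err < best[0] - 1e-12:
                best = (err, xm - xn)
    return {"TINN": best[1], "TRI": tri}


# ---------------------------------------------------------------------------
# HRV: phase-rectified signal averaging (ac / dc)
# ---------------------------------------------------------------------------


def hrv_prsa(nn: NNSeries | np.ndarray) -> dict[str, float]:
    """Acceleration and deceleration capacity by PRSA.

    Deceleration anchors are intervals strictly longer than their predecessor
    (ac: strictly shorter).  Windows of two intervals either side of each
    anchor are averaged; capacity = (X0 + X1 - X-1 - X-2) / 4.
    """
    x = nn.nn_intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    out = {"ac": float("nan"), "dc": float("nan")}
    if len(x) < 5:
        return out
    for name, cmp in (("dc", np.greater), ("ac", np.less)):
        anchors = [i for i in range(2, len(x) - 1) if cmp(x[i], x[i - 1])]
        if not anchors:
            continue
        a = np.asarray(anchors)
        out[name] = float(np.mean((x[a] + x[a + 1] - x[a - 1] - x[a - 2]) / 4.0))
    return out


# ---------------------------------------------------------------------------
# HRV: entropies
# ---------------------------------------------------------------------------


def _count_matches(x: np.ndarray, m: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """For each template of length m: count of templates within Chebyshev r.

    Returns (counts including self-match, counts excluding self-match).
    """
    n = len(x) - m + 1
    tpl = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
    within = d <= r
    incl = within.sum(axis=1)
    return incl, incl - 1


def hrv_entropy(nn: NNSeries | np.ndarray, m: int = 2, r: float | None = None) -> dict[str, float]:
    """Sample entropy and approximate entropy (template matching, Chebyshev).

    Defaults: m = 2, r = 0.2 * SDNN floored at 1 ms.  SampEn excludes
    self-matches; ApEn includes them.
    """
    x = nn.nn_intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    out = {"SampEn": float("nan"), "ApEn": float("nan")}
    if len(x) < m + 2:
        return out
    if r is None:
        r = max(0.2 * float(np.std(x)), 1.0)
    incl_m, _ = _count_matches(x, m, r)
    incl_m1, excl_m1 = _count_matches(x, m + 1, r)
    # SampEn: total matched pairs at m+1 vs m, self-matches excluded; only the
    # first N-m length-m templates are counted so the two lengths align
    _, excl_b = _count_matches(x[:-1], m, r)
    b = float(np.sum(excl_b))
    a = float(np.sum(excl_m1))
    if b > 0 and a > 0:
        out["SampEn"] = -math.log(a / b)
    # ApEn: difference of mean log match frequencies, self-matches included
    n_m, n_m1 = len(incl_m), len(incl_m1)
    phi_m = float(np.mean(np.log(incl_m / n_m)))
    phi_m1 = float(np.mean(np.log(incl_m1 / n_m1)))
    out["ApEn"] = phi_m - phi_m1
    return out


# ---------------------------------------------------------------------------
# HRV: spectral (Lomb-Scargle on the irregular beat series)
# ---------------------------------------------------------------------------

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.003, 0.40)


def hrv_spectral(nn: NNSeries) -> dict[str, float]:
    """Band powers (ms^2) of the NN series by Lomb-Scargle periodogram.

    The periodogram is evaluated on the irregular beat-time grid (no
    resampling) and scaled so that the integral over frequency approximates
    the series variance; lf = 0.04-0.15 Hz, hf = 0.15-0.40 Hz, total power =
    0.003-0.40 Hz.
    """
    out = {"lf": float("nan"), "hf": float("nan"), "lfhf": float("nan"), "ttlpwr": float("nan")}
    x = nn.nn_intervals
    # stamp each interval with the beat time ending it
    t = nn.beat_times[1:] if len(nn.beat_times) == len(x) + 1 else nn.beat_times
    if len(x) < 10:
        return out
    span = t[-1] - t[0]
    if span < 60.0:
        return out
    xc = x - np.mean(x)
    df = 1.0 / (4.0 * span)  # 4x oversampled frequency grid
    freqs = np.arange(TOTAL_BAND[0], TOTAL_BAND[1] + df, df)
    pgram = sps.lombscargle(t, xc, 2.0 * np.pi * freqs)
    # scale so the integral of the PSD recovers variance (Parseval-type)
    psd = pgram * 2.0 * span / len(x)

    def band(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[m], freqs[m])) if m.sum() > 1 else 0.0

    lf = band(*LF_BAND)
    hf = band(*HF_BAND)
    out.update(lf=lf, hf=hf, ttlpwr=band(*TOTAL_BAND))
    out["lfhf"] = lf / hf if hf > 0 else float("nan")
    return out


def rr_hrv(nn: NNSeries | np.ndarray) -> float:
    """Scale-free HRV from relative successive interval changes.

    rr_i = 2 (RR_i - RR_{i-1}) / (RR_i + RR_{i-1}); the statistic is the
    median Euclidean distance of the return-map points (rr_i, rr_{i+1}) from
    the map's center (the componentwise median).  Invariant under rescaling
    of the interval series.
    """
    x = nn.nn_intervals if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 4:
        return float("nan")
    rr = 2.0 * np.diff(x) / (x[1:] + x[:-1])
    if len(rr) < 3:
        return float("nan")
    pts = np.column_stack([rr[:-1], rr[1:]])
    center = np.median(pts, axis=0)
    return float(np.median(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])))


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------


def respiration_features(
    resp: RawSignal,
    lowpass_hz: float = 1.0,
    min_separation_s: float = 0.8,
    min_width_s: float = 0.4,
) -> dict[str, float]:
    """Respiration rate/depth/width/ratio from robust peak detection.

    The signal is zero-phase low-passed at 1 Hz; peaks must rise at least one
    robustified standard deviation (1.4826 * MAD) above their surroundings,
    be separated by >= 0.8 s and be >= 0.4 s wide.  Rate is the median of
    cycles/min implied by the inter-peak intervals; depth and width are the
    median prominence and width.
    """
    out = {"RespRate": float("nan"), "RespDepth": float("nan"),
           "RespWidth": float("nan"), "RespRatio": float("nan")}
    fs = resp.sampling_rate
    if fs < 20 or resp.duration < 30:
        return out
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, resp.samples)
    robust_sd = 1.4826 * float(np.median(np.abs(y - np.median(y))))
    if robust_sd == 0:
        return out
    peaks, props = sps.find_peaks(
        y,
        prominence=robust_sd,
        distance=max(1, int(min_separation_s * fs)),
        width=min_width_s * fs,
    )
    if len(peaks) >= 2:
        ipi = np.diff(peaks) / fs
        out["RespRate"] = float(np.median(60.0 / ipi))
    if len(peaks) >= 1:
        out["RespDepth"] = float(np.median(props["prominences"]))
        out["RespWidth"] = float(np.median(props["widths"])) / fs
        if out["RespWidth"] > 0:
            out["RespRatio"] = out["RespDepth"] / out["RespWidth"]
    return out


# ---------------------------------------------------------------------------
# Electrodermal activity
# ---------------------------------------------------------------------------


def scr_trough_to_peak(eda: RawSignal, amp_threshold: float = 0.05) -> float:
    """SCRs per minute by trough-to-peak analysis.

    The conductance is lightly smoothed; every local peak whose rise from the
    preceding trough (the minimum within a 10 s lookback, so slow tonic drift
    cannot accumulate into a spurious response) exceeds ``amp_threshold`` (uS)
    counts as one response.
    """
    fs = eda.sampling_rate
    if eda.duration < 60:
        return float("nan")
    sos = sps.butter(3, min(2.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, eda.samples)
    if np.ptp(y) == 0:
        return 0.0
    peaks, _ = sps.find_peaks(y, distance=max(1, int(0.5 * fs)))
    look = int(10.0 * fs)
    count = 0
    for p in peaks:
        base = float(np.min(y[max(0, p - look): p + 1]))
        if y[p] - base >= amp_threshold:
            count += 1
    return count * 60.0 / eda.duration


def scr_cda(
    eda: RawSignal,
    bateman_taus: tuple[float, float] = (1.0, 3.75),
    amp_threshold: float = 0.05,
    smooth_s: float = 0.75,
    tonic_window_s: float = 10.0,
) -> dict[str, float]:
    """Continuous decomposition analysis: phasic SCR rate and tonic level.

    The skin conductance y is modeled as a sudomotor driver convolved with
    the Bateman impulse response b(t) = exp(-t/tau2) - exp(-t/tau1).  Since
    b has Laplace transform (b-a) / ((s+a)(s+b)) with a = 1/tau2, b = 1/tau1,
    the exact inverse filter is the differential operator
    (y'' + (a+b) y' + a b y) / (b - a), evaluated here with smoothed
    Savitzky-Golay derivatives.  The driver is split into a slow tonic part
    (rolling median) and phasic impulses; phasic peaks whose reconstructed
    SCR amplitude exceeds ``amp_threshold`` are counted per minute, and
    Toniccda is the mean of the reconstructed tonic conductance.
    """
    out = {"nSCRcda": float("nan"), "Toniccda": float("nan")}
    fs = eda.sampling_rate
    if fs < 10 or eda.duration < 60:
        return out
    tau1, tau2 = bateman_taus
    a, b = 1.0 / tau2, 1.0 / tau1
    win = max(5, int(smooth_s * fs) | 1)
    dt = 1.0 / fs
    y0 = sps.savgol_filter(eda.samples, win, 3, deriv=0)
    y1 = sps.savgol_filter(eda.samples, win, 3, deriv=1, delta=dt)
    y2 = sps.savgol_filter(eda.samples, win, 3, deriv=2, delta=dt)
    driver = (y2 + (a + b) * y1 + a * b * y0) / (b - a)
    if not np.all(np.isfinite(driver)):
        warnings.warn("CDA deconvolution produced non-finite driver values")
        return out
    # tonic driver: slow rolling median; phasic driver: the rest
    k = max(3, int(tonic_window_s * fs) | 1)
    tonic_driver = sps.medfilt(driver, kernel_size=k)
    phasic_driver = np.clip(driver - tonic_driver, 0.0, None)

    # reconstruct conductance components by convolving with the kernel
    t_k = np.arange(0, 6.0 * tau2, dt)
    kernel = np.exp(-t_k / tau2) - np.exp(-t_k / tau1)
    phasic = np.convolve(phasic_driver, kernel, mode="full")[: len(driver)] * dt
    tonic = eda.samples - phasic
    out["Toniccda"] = float(np.mean(tonic))

    # count impulses on the (sharp) phasic driver: each peak's SCR amplitude
    # is its local driver area times the kernel maximum
    floor = max(1e-4, 0.05 * float(np.max(phasic_driver, initial=0.0)))
    peaks, _ = sps.find_peaks(phasic_driver, height=floor, distance=max(1, int(1.0 * fs)))
    kmax = float(np.max(kernel))
    w = int(1.0 * fs)
    count = 0
    for i in peaks:
        area = float(np.sum(phasic_driver[max(0, i - w): i + w])) * dt
        if area * kmax >= amp_threshold:
            count += 1
    out["nSCRcda"] = count * 60.0 / eda.duration
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def extract_block_features(
    nn: NNSeries | None = None,
    eda: RawSignal | None = None,
    resp: RawSignal | None = None,
    block: str = "",
) -> FeatureBlock:
    """Compute the 25 variables for one block from its per-modality slices."""
    values = {v: float("nan") for v in VARIABLES}
    if nn is not None and nn.n >= 2 and not nn.flagged:
        values.update(hrv_time_poincare(nn))
        values.update(hrv_geometric(nn))
        values.update(hrv_prsa(nn))
        values.update(hrv_entropy(nn))
        values.update(hrv_spectral(nn))
        values["rrHRV"] = rr_hrv(nn)
    if resp is not None:
        values.update(respiration_features(resp))
    if eda is not None:
        values["nSCRttp"] = scr_trough_to_peak(eda)
        values.update(scr_cda(eda))
    return FeatureBlock(block=block, values={v: values[v] for v in VARIABLES})


def build_feature_table(
    participants: dict[str, tuple[str, dict[str, FeatureBlock]]],
) -> pd.DataFrame:
    """Assemble the analysis table: 25 absolute + 25 baseline-subtracted columns.

    ``participants`` maps participant_id -> (group, {block -> FeatureBlock}).
    Delta columns (prefix ``d``) subtract the participant's BL1 value; a
    participant without BL1 is excluded with a warning.
    """
    rows = []
    for pid, (group, blocks) in participants.items():
        if "BL1" not in blocks:
            warnings.warn(f"participant {pid} has no BL1 block; excluded")
            continue
        bl1 = blocks["BL1"].values
        for label in BLOCKS:
            if label not in blocks:
                continue
            vals = blocks[label].values
            row = {"participant_id": pid, "group": group, "block": label}
            for v in VARIABLES:
                row[v] = vals.get(v, float("nan"))
                row[f"d{v}"] = row[v] - bl1.get(v, float("nan"))
            rows.append(row)
    df = pd.DataFrame(rows)
    return df


def feature_table_to_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Long format: participant_id, group, block, variable, value, is_delta."""
    recs = []
    for _, row in table.iterrows():
        for v in VARIABLES:
            recs.append((row["participant_id"], row["group"], row["block"], v, row[v], False))
            recs.append((row["participant_id"], row["group"], row["block"], v, row[f"d{v}"], True))
    return pd.DataFrame(recs, columns=["participant_id", "group", "block", "variable", "value", "is_delta"])


# ---------------------------------------------------------------------------
# Signal file I/O: two-column CSV (time_s, value) + optional JSON sidecar
# ---------------------------------------------------------------------------


def read_signal_csv(path: str, channel: str, sampling_rate: float | None = None) -> RawSignal:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column")
    sidecar = os.path.splitext(path)[0] + ".json"
    start = 0.0
    if sampling_rate is None and os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
        sampling_rate = meta.get("sampling_rate")
        start = meta.get("start_time", 0.0)
    if sampling_rate is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError(f"{path}: sampling rate not provided and not inferable")
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        sampling_rate = 1.0 / dt
        start = float(df["time_s"].iloc[0])
    elif "time_s" in df.columns and len(df):
        start = float(df["time_s"].iloc[0])
    return RawSignal(channel, float(sampling_rate), df["value"].to_numpy(float), start)


def write_signal_csv(sig: RawSignal, path: str) -> None:
    pd.DataFrame({"time_s": sig.times, "value": sig.samples}).to_csv(path, index=False)
    with open(os.path.splitext(path)[0] + ".json", "w") as fh:
        json.dump({"channel": sig.channel, "sampling_rate": sig.sampling_rate,
                   "start_time": sig.start_time}, fh)
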