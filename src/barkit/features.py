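"""Spectral and temporal acoustic features of bark calls.

All spectral measures are taken on the first exhalation (Ex1) element of a
call, after 80 Hz highpass filtering, under three short-time analysis
presets:

* ``energy``  — 16 kHz rate, 1024-point FFT, Hamming window, 93.75 % overlap
  (4 ms frame step): spectral energy quartiles, peak frequency, frequency
  range.
* ``tonality`` — the energy preset plus a 1.2 kHz lowpass: barks are tonal
  only at low frequencies, and high-frequency noise otherwise corrupts the
  voicing decision.
* ``f0`` — 8 kHz rate, 1024-point FFT, Hamming window, 96.87 % overlap
  (4 ms frame step): the fundamental-frequency contour.

A "time segment" is one analysis frame. Per-frame energy quartiles q1-q3 are
the frequencies below which 25/50/75 % of the frame's spectral energy lies
(linear interpolation within bins); the peak frequency (PF) is the frequency
of maximal magnitude. Contour shape is summarized by a least-squares line:
the *linear trend factor* is the fitted total change divided by the contour
mean (dimensionless; sign gives direction), and the *deviation* is the mean
absolute residual from that line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .core import CallRecord, TooShortError, Waveform

__all__ = [
    "SpectrogramConfig",
    "PRESETS",
    "F0Contour",
    "FEATURE_COLUMNS",
    "compute_spectrogram",
    "extract_f0_contour",
    "frame_energy_quartiles",
    "frame_energy_percentiles",
    "linear_trend",
    "extract_features",
    "extract_feature_table",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """One short-time analysis preset."""

    target_rate: int
    fft_size: int = 1024
    window: str = "hamming"
    overlap_pct: float = 93.75
    highpass_hz: float | None = 80.0
    lowpass_hz: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_pct < 100:
            raise ValueError("overlap must be in [0, 100)")
        if self.fft_size & (self.fft_size - 1):
            raise ValueError("fft_size must be a power of two")
        nyq = self.target_rate / 2
        for f in (self.highpass_hz, self.lowpass_hz):
            if f is not None and not 0 < f < nyq:
                raise ValueError(f"filter edge {f} Hz outside (0, {nyq}) Hz")

    @property
    def hop(self) -> int:
        """Frame step in samples at the target rate."""
        return int(round(self.fft_size * (1.0 - self.overlap_pct / 100.0)))

    @property
    def bin_width_hz(self) -> float:
        return self.target_rate / self.fft_size


PRESETS: dict[str, SpectrogramConfig] = {
    "energy": SpectrogramConfig(target_rate=16000, overlap_pct=93.75),
    "tonality": SpectrogramConfig(target_rate=16000, overlap_pct=93.75,
                                  lowpass_hz=1200.0),
    "f0": SpectrogramConfig(target_rate=8000, overlap_pct=96.87),
}


def _condition(waveform: Waveform, config: SpectrogramConfig) -> Waveform:
    """Highpass, resample to the preset rate (anti-aliased), lowpass."""
    x, rate = waveform.samples, waveform.rate
    if config.highpass_hz is not None and config.highpass_hz < rate / 2:
        sos = sps.butter(4, config.highpass_hz, btype="highpass", fs=rate,
                         output="sos")
        x = sps.sosfiltfilt(sos, x)
    if rate != config.target_rate:
        frac = Fraction(config.target_rate, rate)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        rate = config.target_rate
    if config.lowpass_hz is not None:
        sos = sps.butter(8, config.lowpass_hz, btype="lowpass", fs=rate,
                         output="sos")
        x = sps.sosfiltfilt(sos, x)
    return Waveform(x, rate)


def _frames(x: np.ndarray, n: int, hop: int) -> np.ndarray:
    if len(x) < n:
        raise TooShortError(
            f"waveform of {len(x)} samples is shorter than one "
            f"{n}-sample analysis frame"
        )
    return sliding_window_view(x, n)[::hop]


def compute_spectrogram(
    waveform: Waveform, config: SpectrogramConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time magnitude spectrogram under a preset.

    Returns ``(freqs, times, mag)`` where ``mag[i, j]`` is the magnitude of
    frequency bin ``freqs[j]`` (bin centers, width = rate / fft_size) in the
    frame centered at ``times[i]`` seconds (relative to the input start).
    """
    cond = _condition(waveform, config)
    frames = _frames(cond.samples, config.fft_size, config.hop)
    win = sps.get_window(config.window, config.fft_size, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    freqs = np.fft.rfftfreq(config.fft_size, d=1.0 / config.target_rate)
    times = (np.arange(frames.shape[0]) * config.hop + config.fft_size / 2) \
        / config.target_rate
    return freqs, times, mag


# ---------------------------------------------------------------------------
# Fundamental frequency and tonality
# ---------------------------------------------------------------------------


@dataclass
class F0Contour:
    """Per-frame F0 (NaN where non-tonal) and the tonality percentage."""

    times: np.ndarray
    f0: np.ndarray
    tonality: float  # percent of frames with a valid F0 on the lowpassed path

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)


def _autocorr_f0(
    x: np.ndarray,
    rate: int,
    fft_size: int,
    hop: int,
    f0_min: float = 80.0,
    f0_max: float = 1000.0,
    voicing_threshold: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame autocorrelation F0 with parabolic peak interpolation.

    A frame is voiced when its strongest normalized autocorrelation peak in
    the candidate lag band exceeds ``voicing_threshold``; among near-maximal
    peaks (within 90 % of the best) the shortest lag wins, which guards
    against octave-down errors on strongly periodic frames.

    Signals shorter than one frame are center-padded with zeros to a single
    frame (elements can be shorter than the 128 ms frame at the F0 rate).
    """
    if len(x) < fft_size:
        left = (fft_size - len(x)) // 2
        x = np.pad(x, (left, fft_size - len(x) - left))
    frames = _frames(x, fft_size, hop)
    m = frames.shape[0]
    nfft = 2 * fft_size
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :fft_size]
    r0 = acf[:, 0].copy()
    energy_floor = 1e-12 * max(float(r0.max()), 1e-300)
    r0[r0 <= energy_floor] = np.inf  # silent frames -> normalized acf ~ 0
    racf = acf / r0[:, None]

    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = min(fft_size - 2, int(np.ceil(rate / f0_min)))
    times = (np.arange(m) * hop + fft_size / 2) / rate
    f0 = np.full(m, np.nan)
    for i in range(m):
        band = racf[i, lag_min:lag_max + 1]
        interior = (band[1:-1] >= band[:-2]) & (band[1:-1] > band[2:])
        peaks = np.flatnonzero(interior) + 1
        if len(peaks) == 0:
            continue
        best = band[peaks].max()
        if best < voicing_threshold:
            continue
        lag = lag_min + peaks[band[peaks] >= 0.9 * best][0]
        # parabolic interpolation around the peak
        ym1, y0, yp1 = racf[i, lag - 1], racf[i, lag], racf[i, lag + 1]
        denom = ym1 - 2 * y0 + yp1
        delta = 0.5 * (ym1 - yp1) / denom if denom < 0 else 0.0
        f0[i] = rate / (lag + delta)
    return times, f0


def extract_f0_contour(
    waveform: Waveform,
    span: tuple[float, float] | None = None,
    config: SpectrogramConfig | None = None,
    voicing_threshold: float = 0.4,
) -> F0Contour:
    """F0 contour and tonality of one element.

    F0 values come from the f0 preset path (80 Hz highpass, 8 kHz rate);
    the tonality percentage — the share of analysis frames in which a valid
    F0 can be found — is computed on the 1.2 kHz-lowpassed path, where the
    voicing decision is robust to high-frequency noise. ``span`` (seconds,
    relative to the waveform start) restricts both to frames whose centers
    fall inside it, e.g. to exclude silent padding.
    """
    config = config or PRESETS["f0"]
    cond = _condition(waveform, config)
    times, f0 = _autocorr_f0(cond.samples, cond.rate, config.fft_size,
                             config.hop, voicing_threshold=voicing_threshold)

    lp = replace(config, lowpass_hz=PRESETS["tonality"].lowpass_hz)
    cond_lp = _condition(waveform, lp)
    _, f0_lp = _autocorr_f0(cond_lp.samples, cond_lp.rate, config.fft_size,
                            config.hop, voicing_threshold=voicing_threshold)

    if span is not None:
        keep = (times >= span[0]) & (times <= span[1])
        times, f0 = times[keep], f0[keep]
        f0_lp = f0_lp[keep[: len(f0_lp)]] if len(f0_lp) == len(keep) else f0_lp
    n_lp = len(f0_lp)
    tonality = 100.0 * np.count_nonzero(~np.isnan(f0_lp)) / n_lp if n_lp else 0.0
    return F0Contour(times=times, f0=f0, tonality=float(tonality))


# ---------------------------------------------------------------------------
# Per-frame spectral summaries
# ---------------------------------------------------------------------------


def frame_energy_percentiles(
    mag: np.ndarray, freqs: np.ndarray, percentiles: tuple[float, ...]
) -> tuple[float, ...]:
    """Frequencies below which the given percentages of one frame's spectral
    energy lie, by linear interpolation within bins (each bin's energy is
    spread uniformly over its width)."""
    energy = np.square(np.asarray(mag, dtype=float))
    total = energy.sum()
    if total <= 0:
        raise ValueError("all-zero frame has no energy distribution")
    half = (freqs[1] - freqs[0]) / 2.0 if len(freqs) > 1 else 0.5
    edges = np.concatenate([[freqs[0] - half], freqs + half])
    cum = np.concatenate([[0.0], np.cumsum(energy)]) / total
    return tuple(float(np.interp(p / 100.0, cum, edges)) for p in percentiles)


def frame_energy_quartiles(
    mag: np.ndarray, freqs: np.ndarray
) -> tuple[float, float, float, float]:
    """(q1, q2, q3, peak) of one frame: energy quartile frequencies plus the
    frequency of maximal magnitude."""
    q1, q2, q3 = frame_energy_percentiles(mag, freqs, (25.0, 50.0, 75.0))
    peak = float(freqs[int(np.argmax(mag))])
    return q1, q2, q3, peak


def linear_trend(values: np.ndarray | list[float]) -> tuple[float, float]:
    """(trend_factor, deviation) of a contour.

    A least-squares line is fitted to value-vs-frame-index; the trend factor
    is the fitted total change over the contour divided by the contour mean
    (dimensionless), and the deviation is the mean absolute residual (same
    unit as the values). NaNs are dropped; fewer than two valid points give
    (nan, nan).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return float("nan"), float("nan")
    idx = np.arange(len(v), dtype=float)
    slope, intercept = np.polyfit(idx, v, 1)
    fitted = slope * idx + intercept
    mean = v.mean()
    trend = slope * (len(v) - 1) / mean if mean != 0 else float("nan")
    deviation = float(np.mean(np.abs(v - fitted)))
    return float(trend), deviation


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

_QUARTILE_COLS = [
    f"{q}_{s}" for q in ("q1", "q2", "q3", "pf")
    for s in ("median", "t1", "t2", "t3", "t4")
]

#: Column registry of the acoustic feature vector: 3 temporal + 28 spectral.
FEATURE_COLUMNS: tuple[str, ...] = (
    "duration", "ex1_duration", "element_number",
    "f0_mean", "f0_start", "f0_end", "f0_linear_trend", "tonality",
    *_QUARTILE_COLS[:15],          # q1/q2/q3 medians and temporal quartiles
    "frequency_range",
    *_QUARTILE_COLS[15:],          # pf median and temporal quartiles
    "pf_linear_trend", "pf_deviation",
)


def _temporal_quartile_means(
    times: np.ndarray, values: np.ndarray, t0: float, t1: float
) -> list[float]:
    """Mean of ``values`` within each temporal quarter of [t0, t1); frames
    are assigned by center time, half-open bins, the final frame to Q4."""
    if t1 <= t0:
        return [float("nan")] * 4
    quarter = np.clip(((times - t0) / (t1 - t0) * 4).astype(int), 0, 3)
    return [
        float(values[quarter == k].mean()) if np.any(quarter == k) else float("nan")
        for k in range(4)
    ]


def extract_features(
    call: CallRecord,
    bout_waveform: Waveform,
    pad_ms: float = 50.0,
    range_percentiles: tuple[float, float] = (2.5, 97.5),
    presets: dict[str, SpectrogramConfig] | None = None,
) -> dict[str, float]:
    """Compute the full acoustic feature vector for one call.

    Temporal features come from the call's element labels; spectral features
    from its Ex1 element, which is cut from the bout, padded with ``pad_ms``
    of silence on each side, and analysed under the three presets. The
    frequency range is the mean per-frame width of the band holding the
    central share of spectral energy given by ``range_percentiles``.
    """
    presets = presets or PRESETS
    ex1 = call.ex1  # raises if the call has no exhalation
    element = bout_waveform.slice(ex1.onset, ex1.offset)
    pad = np.zeros(int(round(pad_ms / 1000.0 * bout_waveform.rate)))
    padded = Waveform(np.concatenate([pad, element.samples, pad]),
                      bout_waveform.rate)
    pad_s = len(pad) / bout_waveform.rate
    el_dur_s = len(element.samples) / bout_waveform.rate
    span = (pad_s, pad_s + el_dur_s)

    out: dict[str, float] = {
        "duration": call.duration_ms,
        "ex1_duration": call.ex1_duration_ms,
        "element_number": float(call.element_number),
    }

    # --- F0 path -----------------------------------------------------------
    contour = extract_f0_contour(padded, span=span, config=presets["f0"])
    voiced = contour.f0[contour.voiced]
    out["tonality"] = contour.tonality
    if len(voiced):
        out["f0_mean"] = float(voiced.mean())
        out["f0_start"] = float(voiced[0])
        out["f0_end"] = float(voiced[-1])
        out["f0_linear_trend"] = linear_trend(voiced)[0]
    else:
        out.update(f0_mean=np.nan, f0_start=np.nan, f0_end=np.nan,
                   f0_linear_trend=np.nan)

    # --- energy path -------------------------------------------------------
    freqs, times, mag = compute_spectrogram(padded, presets["energy"])
    keep = (times >= span[0]) & (times <= span[1])
    keep &= np.square(mag).sum(axis=1) > 0
    mag, times = mag[keep], times[keep]
    if mag.shape[0] == 0:
        raise TooShortError("no analysis frames fall within the Ex1 element")

    qp = np.array([frame_energy_quartiles(m, freqs) for m in mag])
    ranges = np.array([
        np.subtract(*frame_energy_percentiles(m, freqs, range_percentiles[::-1]))
        for m in mag
    ])
    for j, name in enumerate(("q1", "q2", "q3", "pf")):
        out[f"{name}_median"] = float(np.median(qp[:, j]))
        t_means = _temporal_quartile_means(times, qp[:, j], *span)
        for k in range(4):
            out[f"{name}_t{k + 1}"] = t_means[k]
    out["frequency_range"] = float(ranges.mean())
    out["pf_linear_trend"], out["pf_deviation"] = linear_trend(qp[:, 3])

    return {name: out[name] for name in FEATURE_COLUMNS}


def extract_feature_table(
    calls: list[CallRecord],
    bout_waveform: Waveform,
    identifiers: dict[str, str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature vectors for every call of a bout, as one row per call."""
    rows = []
    for i, call in enumerate(calls):
        row = dict(identifiers or {})
        row["call_id"] = row.get("call_id", f"c{i + 1:03d}")
        row.update(extract_features(call, bout_waveform, **kwargs))
        rows.append(row)
    return pd.DataFrame(rows)
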