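"""Frame-level acoustic feature extraction.

Every 10 ms (25 ms Hamming window) we extract 37 base descriptors per
frame and append their first-order regression deltas, for 74 features
total:

========  ===========================================================
spectral  15 MFCCs (c1..c15, 26-filter mel bank), 8 log mel filterbank
          energies (MFB), 8 line spectral frequencies (LSF, from an
          order-8 LPC fit)
prosody   intensity (dB), pitch (Hz, voiced frames only), loudness
          (perceptual sum of compressed mel-band energies)
voice     jitter (relative), shimmer (relative), harmonics-to-noise
quality   ratio (dB) — defined on voiced frames only
========  ===========================================================

Unvoiced frames carry NaN (never zero) in the pitch and voice-quality
columns; all downstream statistics are missing-aware.  Deltas are
5-point local regression slopes per frame, computed over contiguous
non-missing runs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft, irfft
from scipy.linalg import solve_toeplitz
from scipy.signal import find_peaks

from .corpus import AudioSignal, FrameTrack

_LOG_FLOOR = 1e-10

N_MFCC = 15
N_MFB = 8
N_LSF = 8
BASE_NAMES: tuple[str, ...] = (
    tuple(f"mfcc{i}" for i in range(1, N_MFCC + 1))
    + tuple(f"mfb{i}" for i in range(1, N_MFB + 1))
    + tuple(f"lsf{i}" for i in range(1, N_LSF + 1))
    + ("intensity", "pitch", "loudness", "jitter", "shimmer", "hnr")
)
FEATURE_NAMES: tuple[str, ...] = BASE_NAMES + tuple(f"{n}_de" for n in BASE_NAMES)
# columns that are undefined on unvoiced frames
VOICED_ONLY = ("pitch", "jitter", "shimmer", "hnr")


@dataclass
class FeatureConfig:
    """Front-end parameters (hop/window in seconds, pitch range in Hz)."""

    hop: float = 0.010
    window: float = 0.025
    n_mel: int = 26               # mel bank behind MFCCs and loudness
    pitch_fmin: float = 75.0
    pitch_fmax: float = 500.0
    pitch_window: float = 0.040   # longer window so 75 Hz fits ~3 periods
    voicing_threshold: float = 0.45
    octave_cost: float = 0.05     # per-octave penalty toward shorter lags
    silence_db: float = -60.0     # frames below this are never voiced
    energy_floor: float = _LOG_FLOOR

    def __post_init__(self) -> None:
        if self.pitch_fmin >= self.pitch_fmax:
            raise ValueError(
                f"degenerate pitch search range [{self.pitch_fmin}, {self.pitch_fmax}]"
            )


# ---------------------------------------------------------------------------
# framing and mel geometry
# ---------------------------------------------------------------------------

def frame_signal(x: np.ndarray, rate: int, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Slice a signal into overlapping frames; returns (frames, centre times)."""
    win = int(round(cfg.window * rate))
    hop = int(round(cfg.hop * rate))
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    frames = sliding_window_view(x, win)[::hop]
    times = (np.arange(frames.shape[0]) * hop + win / 2) / rate
    return frames, times


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2+1)."""
    fmax = fmax if fmax is not None else rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_filters + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_filters, len(bins)))
    for i in range(n_filters):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
        total = fb[i].sum()
        if total > 0:  # unit-area filters: flat spectra give flat band energies
            fb[i] /= total
    return fb


def mel_band_center_hz(n_filters: int, rate: int) -> np.ndarray:
    """Centre frequency of each triangular filter (used in tests)."""
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2.0), n_filters + 2)
    return np.asarray(mel_to_hz(mel_pts))[1:-1]


# ---------------------------------------------------------------------------
# spectral block: MFCC, MFB, LSF
# ---------------------------------------------------------------------------

def _lpc_coefficients(frames: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC per frame; rows are [1, a1..a_order]."""
    n = frames.shape[1]
    spec = np.abs(rfft(frames, n=2 * n, axis=1)) ** 2
    ac = irfft(spec, axis=1)[:, : order + 1]
    coeffs = np.empty((frames.shape[0], order + 1))
    coeffs[:, 0] = 1.0
    for i, r in enumerate(ac):
        r = r.copy()
        r[0] += 1e-9 * max(r[0], 1.0)  # regularize flat/empty frames
        try:
            a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
        except np.linalg.LinAlgError:
            a = np.zeros(order)
        coeffs[i, 1:] = a
    return coeffs


def _lsf_from_lpc(a: np.ndarray) -> np.ndarray:
    """Line spectral frequencies in (0, pi) from one LPC row [1, a1..ap]."""
    p = len(a) - 1
    ext = np.concatenate([a, [0.0]])
    psum = ext + ext[::-1]       # palindromic, root at z = -1
    qdif = ext - ext[::-1]       # antipalindromic, root at z = +1
    psum = np.polydiv(psum, np.array([1.0, 1.0]))[0]
    qdif = np.polydiv(qdif, np.array([1.0, -1.0]))[0]
    angles = []
    for poly in (psum, qdif):
        roots = np.roots(poly)
        ang = np.angle(roots[np.imag(roots) > 0])
        angles.extend(ang.tolist())
    angles = np.sort(np.asarray(angles))
    if len(angles) != p:  # numerically degenerate frame: fall back to uniform grid
        angles = np.arange(1, p + 1) * np.pi / (p + 1)
    return np.clip(angles, 1e-6, np.pi - 1e-6)


def extract_spectral(audio: AudioSignal, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-frame 31-column spectral block: 15 MFCC + 8 MFB + 8 LSF."""
    cfg = cfg or FeatureConfig()
    frames, _ = frame_signal(audio.samples, audio.rate, cfg)
    win = frames.shape[1]
    windowed = frames * np.hamming(win)
    n_fft = int(2 ** np.ceil(np.log2(win)))
    power = np.abs(rfft(windowed, n=n_fft, axis=1)) ** 2

    fb26 = mel_filterbank(cfg.n_mel, n_fft, audio.rate)
    log_mel26 = np.log(power @ fb26.T + cfg.energy_floor)
    # c0 is excluded as redundant with intensity; keep c1..c15
    mfcc = dct(log_mel26, type=2, norm="ortho", axis=1)[:, 1 : N_MFCC + 1]

    fb8 = mel_filterbank(N_MFB, n_fft, audio.rate)
    mfb = np.log(power @ fb8.T + cfg.energy_floor)

    lpc = _lpc_coefficients(windowed, N_LSF)
    lsf = np.vstack([_lsf_from_lpc(row) for row in lpc])
    return np.hstack([mfcc, mfb, lsf])


# ---------------------------------------------------------------------------
# prosody and voice quality
# ---------------------------------------------------------------------------

def _autocorr_pitch(x: np.ndarray, rate: int, times: np.ndarray,
                    cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame pitch, voicing flag and peak autocorrelation.

    Autocorrelation over a dedicated pitch window centred on each frame,
    normalized; lag search limited to [rate/fmax, rate/fmin] with an
    octave-cost penalty that discourages halving errors.
    """
    pw = int(round(cfg.pitch_window * rate))
    half = pw // 2
    centers = np.round(times * rate).astype(int)
    padded = np.pad(x, (half, half + 1))
    frames = np.stack([padded[c : c + pw] for c in centers])
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.abs(rfft(frames, n=2 * pw, axis=1)) ** 2
    ac = irfft(spec, axis=1)[:, :pw]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = 1.0
    rnorm = ac / r0[:, None]
    # unbiased-lag correction: a finite window shrinks r(tau) by (1 - tau/N)
    taper = 1.0 - np.arange(pw) / pw
    rnorm = np.clip(rnorm / taper[None, :], -1.0, 1.0)

    lag_min = max(2, int(np.floor(rate / cfg.pitch_fmax)))
    lag_max = min(pw - 2, int(np.ceil(rate / cfg.pitch_fmin)))
    lags = np.arange(lag_min, lag_max + 1)
    penalty = cfg.octave_cost * np.log2(lags / lag_min)
    scores = rnorm[:, lag_min : lag_max + 1] - penalty
    best = np.argmax(scores, axis=1)
    best_lag = lags[best].astype(float)
    # parabolic refinement of the autocorrelation peak
    li = lags[best]
    r_m = rnorm[np.arange(len(li)), li - 1]
    r_0 = rnorm[np.arange(len(li)), li]
    r_p = rnorm[np.arange(len(li)), np.minimum(li + 1, pw - 1)]
    denom = r_m - 2 * r_0 + r_p
    with np.errstate(invalid="ignore", divide="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (r_m - r_p) / denom, 0.0)
    best_lag += np.clip(shift, -1, 1)

    peak_r = np.clip(r_0, 0.0, 0.999999)
    rms_db = 10.0 * np.log10(np.mean(frames**2, axis=1) + 1e-12)
    voiced = (peak_r > cfg.voicing_threshold) & (rms_db > cfg.silence_db)
    pitch = np.where(voiced, rate / best_lag, np.nan)
    return pitch, voiced, peak_r


def _jitter_shimmer(x: np.ndarray, rate: int, center: float, f0: float,
                    n_periods: int = 5) -> tuple[float, float]:
    """Relative jitter and shimmer from cycle peaks in a ±n_periods/2 window."""
    period = rate / f0
    half_span = int(round((n_periods + 1) / 2 * period))
    c = int(round(center * rate))
    lo, hi = max(0, c - half_span), min(len(x), c + half_span)
    seg = x[lo:hi]
    if len(seg) < 3 * period:
        return np.nan, np.nan
    peaks, _ = find_peaks(seg, distance=max(2, int(0.7 * period)))
    if len(peaks) < 3:
        return np.nan, np.nan
    # parabolic sub-sample refinement of peak position and height
    pos, amp = [], []
    for p in peaks:
        if 1 <= p < len(seg) - 1:
            ym, y0, yp = seg[p - 1], seg[p], seg[p + 1]
            denom = ym - 2 * y0 + yp
            d = 0.5 * (ym - yp) / denom if abs(denom) > 1e-15 else 0.0
            pos.append(p + np.clip(d, -1, 1))
            amp.append(y0 - 0.25 * (ym - yp) * np.clip(d, -1, 1))
    pos, amp = np.asarray(pos), np.asarray(amp)
    if len(pos) < 3:
        return np.nan, np.nan
    periods = np.diff(pos)
    ok = (periods > 0.5 * period) & (periods < 1.5 * period)
    periods = periods[ok]
    if len(periods) < 2:
        return np.nan, np.nan
    jitter = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))
    amp = np.abs(amp)
    if np.mean(amp) <= 0:
        return jitter, np.nan
    shimmer = float(np.mean(np.abs(np.diff(amp))) / np.mean(amp))
    return jitter, shimmer


def extract_prosody_voicequality(
    audio: AudioSignal, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (intensity, pitch, loudness, jitter, shimmer, HNR) + voiced mask.

    Order of the returned columns matches BASE_NAMES[31:].
    """
    cfg = cfg or FeatureConfig()
    frames, times = frame_signal(audio.samples, audio.rate, cfg)
    win = frames.shape[1]
    windowed = frames * np.hamming(win)

    intensity = 10.0 * np.log10(np.mean(frames**2, axis=1) + 1e-12)

    n_fft = int(2 ** np.ceil(np.log2(win)))
    power = np.abs(rfft(windowed, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mel, n_fft, audio.rate)
    band_energy = power @ fb.T
    loudness = np.sum(band_energy**0.3, axis=1)

    pitch, voiced, peak_r = _autocorr_pitch(audio.samples, audio.rate, times, cfg)
    hnr = np.full(len(times), np.nan)
    hnr[voiced] = 10.0 * np.log10(peak_r[voiced] / (1.0 - peak_r[voiced]))
    hnr = np.clip(hnr, -20.0, 60.0)

    jitter = np.full(len(times), np.nan)
    shimmer = np.full(len(times), np.nan)
    for i in np.flatnonzero(voiced):
        jitter[i], shimmer[i] = _jitter_shimmer(
            audio.samples, audio.rate, times[i], pitch[i]
        )
    cols = np.column_stack([intensity, pitch, loudness, jitter, shimmer, hnr])
    return cols, voiced


# ---------------------------------------------------------------------------
# deltas and assembly
# ---------------------------------------------------------------------------

def regression_delta(base: np.ndarray) -> np.ndarray:
    """5-point local regression slope per frame, missing-aware.

    For each frame t the slope is fit over offsets n in [-2, 2] using
    whichever neighbours exist and are non-missing (contiguous NaN gaps
    break the fit naturally); fewer than 2 usable points -> NaN.  A
    linear ramp maps to slope 1 per frame on interior frames.
    """
    base = np.asarray(base, dtype=float)
    squeeze = base.ndim == 1
    if squeeze:
        base = base[:, None]
    T, d = base.shape
    if T >= 5 and np.all(np.isfinite(base)):
        return _delta_dense(base)[:, 0] if squeeze else _delta_dense(base)
    offsets = np.arange(-2, 3)
    vals = np.full((5, T, d), np.nan)
    for k, n in enumerate(offsets):
        lo_src, hi_src = max(0, n), T + min(0, n)
        lo_dst, hi_dst = max(0, -n), T + min(0, -n)
        vals[k, lo_dst:hi_dst] = base[lo_src:hi_src]
    mask = np.isfinite(vals)
    nn = offsets[:, None, None] * np.ones((5, T, d))
    k_count = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sn = np.where(mask, nn, 0.0).sum(axis=0)
        sx = np.where(mask, vals, 0.0).sum(axis=0)
        snn = np.where(mask, nn**2, 0.0).sum(axis=0)
        snx = np.where(mask, nn * vals, 0.0).sum(axis=0)
        denom = snn - sn**2 / np.maximum(k_count, 1)
        slope = (snx - sn * sx / np.maximum(k_count, 1)) / denom
    slope[(k_count < 2) | ~np.isfinite(slope)] = np.nan
    slope[~np.isfinite(base)] = np.nan  # missing base value -> missing delta
    return slope[:, 0] if squeeze else slope


def _delta_dense(base: np.ndarray) -> np.ndarray:
    """Fast slope path for fully-finite input; edges shrink the window."""
    T = base.shape[0]
    out = np.empty_like(base)
    out[2 : T - 2] = (2 * (base[4:] - base[: T - 4]) + (base[3 : T - 1] - base[1 : T - 3])) / 10.0
    # shrunk windows at the boundaries (regression over available offsets)
    out[0] = (base[2] - base[0]) / 2.0
    out[1] = (-1.5 * base[0] - 0.5 * base[1] + 0.5 * base[2] + 1.5 * base[3]) / 5.0
    out[T - 2] = (1.5 * base[T - 1] + 0.5 * base[T - 2] - 0.5 * base[T - 3]
                  - 1.5 * base[T - 4]) / 5.0
    out[T - 1] = (base[T - 1] - base[T - 3]) / 2.0
    return out


def append_derivatives(base: np.ndarray, times: np.ndarray, voiced: np.ndarray,
                       hop: float = 0.010,
                       base_names: tuple[str, ...] = BASE_NAMES) -> FrameTrack:
    """Append 37 regression-delta columns to the 37 base columns."""
    base = np.asarray(base, dtype=float)
    if base.shape[1] != len(base_names):
        raise ValueError(
            f"expected {len(base_names)} base columns, got {base.shape[1]}"
        )
    deltas = regression_delta(base)
    values = np.hstack([base, deltas])
    names = base_names + tuple(f"{n}_de" for n in base_names)
    return FrameTrack(values=values, times=times, voiced=voiced,
                      feature_names=names, hop=hop)


def extract_frame_track(audio: AudioSignal, cfg: FeatureConfig | None = None) -> FrameTrack:
    """Full 74-column frame track for one signal (spectral + prosody + deltas)."""
    cfg = cfg or FeatureConfig()
    spectral = extract_spectral(audio, cfg)
    prosody, voiced = extract_prosody_voicequality(audio, cfg)
    n = min(len(spectral), len(prosody))
    base = np.hstack([spectral[:n], prosody[:n]])
    _, times = frame_signal(audio.samples, audio.rate, cfg)
    return append_derivatives(base, times[:n], voiced[:n], hop=cfg.hop)
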