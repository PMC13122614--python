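"""The 70-feature harmonic/spectral/temporal description of a segment.

Default registry (70 features per segment):

* 14 static MFCCs + 14 deltas + 14 delta-deltas         (42)
* three fundamental-frequency estimates:
  PEF_F0 (pitch-estimation filter bank), WT_F0 (wavelet
  ridge), NCF_F0 (normalized correlation function)        (3)
* HarmonicRatio (the detection statistic)                 (1)
* nine band-power fractions, 50 Hz bins over 50-500 Hz    (9)
* fifteen spectral/temporal descriptors                  (15)

The registry is configurable; the count invariant enforces the expected
total so a mis-specified configuration fails loudly rather than silently
producing a different feature space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as sfft
from scipy import signal

from .detection import MicroDopplerSegment, normalized_autocorrelation


class RegistryError(ValueError):
    """Raised when a feature registry does not produce the expected total."""


@dataclass(frozen=True)
class MelSpec:
    """MFCC internals tuned for 1 kHz baseband signals.

    Sub-frames are a fixed fraction of the segment (``subframe_div`` frames
    of length L/subframe_div with 50% hop -> 15 sub-frames), so delta
    features are defined for every supported segment duration.
    """

    n_coeffs: int = 14
    n_bands: int = 26
    filterbank_lo: float = 0.0
    filterbank_hi: float | None = None  # default fs/2
    subframe_div: int = 8
    delta_window: int = 2
    n_fft: int = 256

    def __post_init__(self) -> None:
        if self.n_coeffs > self.n_bands:
            raise ValueError("n_coeffs must not exceed n_bands")


@dataclass(frozen=True)
class F0SearchSpec:
    f_min: float = 50.0
    f_max: float = 400.0
    pef_harmonics: int = 5
    pef_valid_fraction: float = 0.15
    wt_n_scales: int = 80
    wt_valid_ratio: float = 3.0
    ncf_valid_peak: float = 0.3
    ncf_refine_lag_s: float = 0.1

    def __post_init__(self) -> None:
        if not (50.0 <= self.f_min < self.f_max <= 450.0):
            raise ValueError("require 50 <= f_min < f_max <= 450")


DEFAULT_BANDS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 50) for lo in range(50, 500, 50)
)

#: Feature names that must exist in any valid default registry (the named
#: high-importance features of the study).
CANONICAL_NAMES = (
    "mfccDelta1",
    "WT_F0",
    "PEF_F0",
    "NCF_F0",
    "HarmonicRatio",
    "bandPower_100_150",
    "bandPower_250_300",
    "bandPower_300_350",
    "bandPower_400_450",
    "mfcc0",
    "mfcc1",
    "mfcc3",
    "mfcc7",
    "mfccDelta5",
    "mfccDelta7",
    "mfccDeltaDelta0",
    "mfccDeltaDelta1",
    "mfccDeltaDelta3",
    "mfccDeltaDelta5",
    "mfccDeltaDelta7",
)

SPECTRAL_TEMPORAL_NAMES = (
    "spectralCentroid",
    "spectralSpread",
    "spectralSkewness",
    "spectralKurtosis",
    "spectralFlatness",
    "spectralEntropy",
    "spectralCrest",
    "spectralRolloff",
    "spectralSlope",
    "spectralDecrease",
    "spectralFlux",
    "peakFrequency",
    "rmsEnergy",
    "zeroCrossRate",
    "temporalCrest",
)


@dataclass(frozen=True)
class FeatureRegistry:
    mel: MelSpec = MelSpec()
    f0: F0SearchSpec = F0SearchSpec()
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
    expected_total: int = 70

    @property
    def names(self) -> tuple[str, ...]:
        n = self.mel.n_coeffs
        return (
            tuple(f"mfcc{i}" for i in range(n))
            + tuple(f"mfccDelta{i}" for i in range(n))
            + tuple(f"mfccDeltaDelta{i}" for i in range(n))
            + ("PEF_F0", "WT_F0", "NCF_F0", "HarmonicRatio")
            + tuple(f"bandPower_{lo}_{hi}" for lo, hi in self.bands)
            + SPECTRAL_TEMPORAL_NAMES
        )

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise RegistryError("duplicate feature names")
        if len(names) != self.expected_total:
            raise RegistryError(
                f"registry emits {len(names)} features, expected {self.expected_total}"
            )


@dataclass
class FeatureVector:
    """Named mapping of exactly ``len(values)`` finite real features."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite feature {k!r}")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


def default_registry() -> FeatureRegistry:
    reg = FeatureRegistry()
    reg.validate()
    return reg


# ---------------------------------------------------------------- sub-frames


def _subframes(x: np.ndarray, div: int) -> tuple[np.ndarray, int]:
    """Split into 2*div-1 half-overlapped sub-frames of length ~len(x)/div."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * div:
        x = np.concatenate([x, np.zeros(4 * div - len(x))])
    win = len(x) // div
    hop = max(1, win // 2)
    n = (len(x) - win) // hop + 1
    frames = np.stack([x[i * hop : i * hop + win] for i in range(n)])
    return frames, win


# --------------------------------------------------------------------- MFCC


def _mel(f: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(
    n_bands: int, n_fft: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    edges = _mel_inv(np.linspace(_mel(lo), _mel(hi), n_bands + 2))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_bands, bins.size))
    for b in range(n_bands):
        f_lo, f_c, f_hi = edges[b : b + 3]
        up = (bins - f_lo) / max(f_c - f_lo, 1e-9)
        down = (f_hi - bins) / max(f_hi - f_c, 1e-9)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _delta(c: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope over +-window neighbouring sub-frames (edge-padded)."""
    n = np.arange(1, window + 1)
    denom = 2.0 * np.sum(n**2)
    padded = np.pad(c, ((window, window), (0, 0)), mode="edge")
    out = np.zeros_like(c)
    for k in n:
        out += k * (padded[window + k : window + k + len(c)] - padded[window - k : window - k + len(c)])
    return out / denom


def mfcc_block(x: np.ndarray, fs: float, spec: MelSpec) -> dict[str, float]:
    """Static, delta and delta-delta MFCCs, each averaged over sub-frames."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("segment shorter than one sub-frame")
    frames, win = _subframes(x, spec.subframe_div)
    taper = signal.get_window("hann", win, fftbins=True)
    spectra = np.abs(np.fft.rfft(frames * taper, n=max(spec.n_fft, win), axis=1)) ** 2
    hi = spec.filterbank_hi if spec.filterbank_hi is not None else fs / 2
    fb = _mel_filterbank(spec.n_bands, max(spec.n_fft, win), fs, spec.filterbank_lo, hi)
    energies = spectra @ fb.T
    logmel = np.log(energies + 1e-12)
    ceps = sfft.dct(logmel, type=2, axis=1, norm="ortho")[:, : spec.n_coeffs]
    d1 = _delta(ceps, spec.delta_window)
    d2 = _delta(d1, spec.delta_window)
    out: dict[str, float] = {}
    for i in range(spec.n_coeffs):
        out[f"mfcc{i}"] = float(ceps[:, i].mean())
        out[f"mfccDelta{i}"] = float(d1[:, i].mean())
        out[f"mfccDeltaDelta{i}"] = float(d2[:, i].mean())
    return out


# ------------------------------------------------------------ F0 estimators


def _parabolic(y: np.ndarray, i: int) -> float:
    """Sub-sample peak offset from a 3-point parabola around index i."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))


def estimate_f0_ncf(x: np.ndarray, fs: float, spec: F0SearchSpec) -> float:
    """Normalized-correlation-function pitch.

    The fundamental period is seeded by the first convincing local maximum
    of the autocorrelation beyond the smallest admissible lag, then refined
    by locating the peak at progressively doubled multiples of the period
    (parabolic interpolation at each step).  Locking onto the m-th multiple
    divides the integer-lag quantization error by m, which matters at
    fs = 1 kHz where short wingbeat periods span only a few samples.
    Returns NaN when no peak is convincing (noise-only segments).
    """
    x = np.asarray(x, dtype=float)
    L = len(x)
    lag_lo = max(1, int(np.floor(fs / spec.f_max)))
    refine_cap = min(L - 2, int(round(spec.ncf_refine_lag_s * fs)))
    if refine_cap <= lag_lo + 1:
        return float("nan")
    psi = normalized_autocorrelation(x, refine_cap)
    gmax = psi[lag_lo - 1 :].max()
    if gmax < spec.ncf_valid_peak:
        return float("nan")
    lag_hi = min(int(np.ceil(fs / spec.f_min)) + 1, refine_cap - 1)
    p0 = None
    for k in range(lag_lo, lag_hi + 1):
        v = psi[k - 1]
        left = psi[k - 2] if k >= 2 else 1.0
        right = psi[k] if k < len(psi) else -np.inf
        if v >= max(0.5 * gmax, spec.ncf_valid_peak) and v >= left and v >= right:
            p0 = k
            break
    if p0 is None:
        return float("nan")
    period = p0 + _parabolic(psi, p0 - 1)
    m = 1
    while 2 * m * period <= refine_cap - 2:
        m *= 2
        target = m * period
        half = max(1.5, min(period / 3.0, 0.45 * period))
        w_lo = max(1, int(np.floor(target - half)))
        w_hi = min(refine_cap, int(np.ceil(target + half)))
        j = w_lo + int(np.argmax(psi[w_lo - 1 : w_hi]))
        period = (j + _parabolic(psi, j - 1)) / m
    f0 = fs / period
    if not (spec.f_min * 0.8 <= f0 <= spec.f_max * 1.2):
        return float("nan")
    return float(f0)


def estimate_f0_pef(x: np.ndarray, fs: float, spec: F0SearchSpec) -> float:
    """Pitch-estimation-filter bank: comb of harmonic bins over [f_min, f_max].

    Each candidate fundamental is scored by the mean periodogram power at
    its harmonics (mean, not sum, so low candidates gain no free energy from
    extra noise bins).  The candidate is validated by requiring that the
    harmonic neighbourhoods capture a minimum fraction of total power.
    """
    x = np.asarray(x, dtype=float)
    L = len(x)
    nfft = max(4096, 1 << int(np.ceil(np.log2(max(L, 2)))))
    f, P = signal.periodogram(x, fs=fs, window="hann", nfft=nfft)
    cand = f[(f >= spec.f_min) & (f <= spec.f_max)]
    if cand.size == 0 or P.sum() <= 0:
        return float("nan")
    f_top = 0.96 * fs / 2
    n_h = np.minimum(spec.pef_harmonics, np.floor(f_top / cand).astype(int))
    n_h = np.maximum(n_h, 1)
    scores = np.zeros(cand.size)
    for n in range(1, spec.pef_harmonics + 1):
        mask = n_h >= n
        scores[mask] += np.interp(n * cand[mask], f, P)
    scores /= n_h
    i = int(np.argmax(scores))
    f0 = cand[i] + _parabolic(scores, i) * (cand[1] - cand[0])
    # validity: fraction of total power within +-2 Hz of each harmonic
    df = f[1] - f[0]
    half = max(1, int(round(2.0 / df)))
    centers = np.arange(1, int(n_h[i]) + 1) * f0
    captured = 0.0
    for c in centers:
        j = int(round(c / df))
        captured += P[max(0, j - half) : j + half + 1].sum()
    if captured / P.sum() < spec.pef_valid_fraction:
        return float("nan")
    return float(f0)


def estimate_f0_wavelet(x: np.ndarray, fs: float, spec: F0SearchSpec) -> float:
    """Continuous-wavelet-transform ridge mapped to Hz.

    Morlet scales are log-spaced across the search band; the ridge is the
    scale of maximal mean squared coefficient magnitude, refined by
    parabolic interpolation in log-frequency.  The transform's built-in
    sqrt(scale) weighting leaves unit-tone ridge heights flat across the
    band (verified on pure tones while designing the estimator), so no
    further per-scale normalization is applied.
    """
    x = np.asarray(x, dtype=float)
    f_hi = min(spec.f_max, 0.45 * fs)
    freqs = np.geomspace(spec.f_min, f_hi, spec.wt_n_scales)
    scales = pywt.frequency2scale("morl", freqs / fs)
    coef, _ = pywt.cwt(x, scales, "morl")
    trim = max(1, len(x) // 10)
    power = np.mean(np.abs(coef[:, trim:-trim]) ** 2, axis=1)
    med = np.median(power)
    i = int(np.argmax(power))
    if med <= 0 or power[i] / med < spec.wt_valid_ratio:
        return float("nan")
    logf = np.log(freqs)
    offset = _parabolic(power, i)
    step = logf[1] - logf[0]
    return float(np.exp(logf[i] + offset * step))


# ----------------------------------------------------- band power & spectra


def band_power_ratios(
    x: np.ndarray, fs: float, bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Fraction of total periodogram power inside each [lo, hi) band."""
    x = np.asarray(x, dtype=float)
    f, P = signal.periodogram(x, fs=fs, window="hann")
    total = P.sum()
    out = {}
    for lo, hi in bands:
        frac = P[(f >= lo) & (f < hi)].sum() / total if total > 0 else 0.0
        out[f"bandPower_{lo}_{hi}"] = float(frac)
    return out


def spectral_temporal_block(x: np.ndarray, fs: float) -> dict[str, float]:
    """Standard spectral-shape and temporal descriptors on the Welch PSD."""
    x = np.asarray(x, dtype=float)
    L = len(x)
    nper = min(L, max(L // 4, 32))
    f, P = signal.welch(x, fs=fs, nperseg=nper)
    f, P = f[1:], P[1:]  # drop DC
    total = P.sum()
    if total <= 0:
        P = np.ones_like(P)
        total = P.sum()
    p = P / total
    centroid = float(np.sum(f * p))
    spread = float(np.sqrt(np.sum((f - centroid) ** 2 * p)))
    sd = max(spread, 1e-12)
    skew = float(np.sum(((f - centroid) / sd) ** 3 * p))
    kurt = float(np.sum(((f - centroid) / sd) ** 4 * p))
    flatness = float(np.exp(np.mean(np.log(P + 1e-30))) / np.mean(P + 1e-30))
    entropy = float(-np.sum(p * np.log(p + 1e-30)) / np.log(len(p)))
    crest = float(P.max() / np.mean(P))
    roll_idx = int(np.searchsorted(np.cumsum(p), 0.95))
    rolloff = float(f[min(roll_idx, len(f) - 1)])
    slope = float(np.polyfit(f, P, 1)[0])
    decrease = float(
        np.sum((P[1:] - P[0]) / np.arange(1, len(P))) / max(P[1:].sum(), 1e-30)
    )
    # flux over half-overlapped sub-frames of the segment
    frames, win = _subframes(x, 8)
    taper = signal.get_window("hann", win, fftbins=True)
    mags = np.abs(np.fft.rfft(frames * taper, axis=1))
    norms = np.linalg.norm(mags, axis=1, keepdims=True)
    mags = mags / np.where(norms > 0, norms, 1.0)
    flux = float(np.mean(np.linalg.norm(np.diff(mags, axis=0), axis=1))) if len(mags) > 1 else 0.0
    peak_freq = float(f[int(np.argmax(P))])
    rms = float(np.sqrt(np.mean(x**2)))
    zcr = float(np.mean(np.abs(np.diff(np.signbit(x))))) if L > 1 else 0.0
    t_crest = float(np.max(np.abs(x)) / rms) if rms > 0 else 0.0
    return {
        "spectralCentroid": centroid,
        "spectralSpread": spread,
        "spectralSkewness": skew,
        "spectralKurtosis": kurt,
        "spectralFlatness": flatness,
        "spectralEntropy": entropy,
        "spectralCrest": crest,
        "spectralRolloff": rolloff,
        "spectralSlope": slope,
        "spectralDecrease": decrease,
        "spectralFlux": flux,
        "peakFrequency": peak_freq,
        "rmsEnergy": rms,
        "zeroCrossRate": zcr,
        "temporalCrest": t_crest,
    }


# ----------------------------------------------------------------- assembly


def extract_features(
    segment: MicroDopplerSegment, registry: FeatureRegistry | None = None
) -> FeatureVector:
    """Run every extractor; exactly ``expected_total`` named finite values.

    Fundamental estimators that fail (noise-like segments) are imputed with
    the NCF estimate, falling back to ``f_min`` when that also fails; the
    HarmonicRatio feature is copied from the detection statistic.
    """
    registry = registry or default_registry()
    registry.validate()
    x = np.asarray(segment.samples, dtype=float)
    fs = segment.fs
    vals: dict[str, float] = {}
    vals.update(mfcc_block(x, fs, registry.mel))
    ncf = estimate_f0_ncf(x, fs, registry.f0)
    pef = estimate_f0_pef(x, fs, registry.f0)
    wt = estimate_f0_wavelet(x, fs, registry.f0)
    fallback = ncf if np.isfinite(ncf) else registry.f0.f_min
    vals["PEF_F0"] = float(pef) if np.isfinite(pef) else float(fallback)
    vals["WT_F0"] = float(wt) if np.isfinite(wt) else float(fallback)
    vals["NCF_F0"] = float(ncf) if np.isfinite(ncf) else float(registry.f0.f_min)
    vals["HarmonicRatio"] = float(segment.eta_hr)
    vals.update(band_power_ratios(x, fs, registry.bands))
    vals.update(spectral_temporal_block(x, fs))
    ordered = {name: vals[name] for name in registry.names}
    return FeatureVector(values=ordered)
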