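"""Harmonic-ratio detection of wing-flap (micro-Doppler) segments.

A frame containing wing flapping is nearly periodic at the wingbeat period,
so its normalized autocorrelation has a strong peak at a lag equal to that
period.  The harmonic ratio of a frame is the maximum normalized
autocorrelation over the lag interval [K0, K], where K = round(0.04 * fs)
(40 samples at 1 kHz, i.e. a minimum detectable fundamental of 25 Hz) and K0
is the first zero crossing of the autocorrelation — an adaptive lower bound
that skips the trivially-high small lags.  Frames whose harmonic ratio
exceeds a threshold (default 0.4) are retained as micro-Doppler segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FilterSpec, FrameSpec, frame, highpass, normalize

DEFAULT_DURATIONS = (2.0, 1.0, 0.8, 0.6, 0.4, 0.2, 0.1)


@dataclass(frozen=True)
class HarmonicRatioParams:
    max_lag_s: float = 0.04
    fallback_k0: int = 1
    threshold: float = 0.4
    channel: str = "real"  # real | imag | magnitude

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must lie in [0, 1]")
        if self.channel not in ("real", "imag", "magnitude"):
            raise ValueError("channel must be real, imag or magnitude")
        if self.fallback_k0 < 1:
            raise ValueError("fallback_k0 must be >= 1")

    def max_lag_samples(self, fs: float) -> int:
        return int(round(self.max_lag_s * fs))


@dataclass
class MicroDopplerSegment:
    """A real-valued analysis segment that passed harmonic-ratio detection."""

    samples: np.ndarray
    fs: float
    start_s: float
    duration_s: float
    eta_hr: float
    recording_id: str = ""
    subject_id: str = ""
    species_name: str = ""


def reduce_channel(iq: np.ndarray, channel: str) -> np.ndarray:
    iq = np.asarray(iq)
    if channel == "real":
        return np.real(iq).astype(float)
    if channel == "imag":
        return np.imag(iq).astype(float)
    if channel == "magnitude":
        mag = np.abs(iq)
        return mag - mag.mean()
    raise ValueError(f"unknown channel {channel!r}")


def normalized_autocorrelation(frame_x: np.ndarray, max_lag: int) -> np.ndarray:
    """Psi(k) for k = 1..max_lag.

    Psi(k) = sum_n x[n] x[n+k] / sqrt(sum_n x[n]^2 * sum_n x[n+k]^2), sums
    over n = 0..L-1-k.  Values lie in [-1, 1]; zero-energy sub-windows give
    Psi(k) = 0.
    """
    x = np.asarray(frame_x, dtype=float)
    L = len(x)
    if max_lag >= L:
        raise ValueError("max_lag must be smaller than the frame length")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("frame contains non-finite samples")
    sq = x * x
    csum = np.concatenate(([0.0], np.cumsum(sq)))  # csum[i] = sum sq[:i]
    psi = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        num = float(np.dot(x[: L - k], x[k:]))
        e0 = csum[L - k]  # energy of x[0..L-1-k]
        e1 = csum[L] - csum[k]  # energy of x[k..L-1]
        denom = np.sqrt(e0 * e1)
        psi[k - 1] = num / denom if denom > 0 else 0.0
    return np.clip(psi, -1.0, 1.0)


def first_zero_crossing(psi: np.ndarray, fallback_k0: int = 1) -> int:
    """Smallest k > 0 with Psi(k-1)*Psi(k) <= 0, taking Psi(0) = 1.

    Returns ``fallback_k0`` when no sign change occurs within the window.
    """
    psi = np.asarray(psi, dtype=float)
    if psi.size == 0:
        raise ValueError("empty psi")
    full = np.concatenate(([1.0], psi))
    prod = full[:-1] * full[1:]
    hits = np.nonzero(prod <= 0)[0]
    return int(hits[0]) + 1 if hits.size else int(fallback_k0)


def harmonic_ratio(
    frame_x: np.ndarray, params: HarmonicRatioParams, fs: float
) -> float:
    """Harmonic ratio of one real frame, clamped to [0, 1].

    Degenerate (zero-variance) frames return 0.
    """
    x = np.asarray(frame_x, dtype=float)
    K = params.max_lag_samples(fs)
    if K >= len(x):
        raise ValueError("frame too short for the requested lag window")
    if np.ptp(x) == 0:
        return 0.0
    psi = normalized_autocorrelation(x, K)
    k0 = first_zero_crossing(psi, params.fallback_k0)
    return float(np.clip(psi[k0 - 1 : K].max(), 0.0, 1.0))


def detect_segments(
    recording,
    frame_spec: FrameSpec,
    hr_params: HarmonicRatioParams,
    preprocessed_iq: np.ndarray | None = None,
) -> list[MicroDopplerSegment]:
    """One retained segment per frame whose harmonic ratio exceeds threshold.

    ``recording.iq`` is assumed already normalized and high-pass filtered
    (or pass ``preprocessed_iq``); the harmonic ratio is computed on the
    Hann-tapered frame of the configured channel while the stored segment
    samples are the un-tapered frame.
    """
    iq = recording.iq if preprocessed_iq is None else preprocessed_iq
    x = reduce_channel(iq, hr_params.channel)
    tapered, times = frame(x, frame_spec, recording.fs, taper=True)
    raw, _ = frame(x, frame_spec, recording.fs, taper=False)
    out = []
    for frame_x, raw_x, t0 in zip(tapered, raw, times):
        eta = harmonic_ratio(frame_x, hr_params, recording.fs)
        if eta > hr_params.threshold:
            out.append(
                MicroDopplerSegment(
                    samples=raw_x.copy(),
                    fs=recording.fs,
                    start_s=float(t0),
                    duration_s=frame_spec.window_s,
                    eta_hr=eta,
                    recording_id=getattr(recording, "recording_id", ""),
                    subject_id=getattr(recording, "subject_id", ""),
                    species_name=getattr(recording, "species_name", ""),
                )
            )
    return out


def run_detection(
    recording,
    filter_spec: FilterSpec | None = None,
    frame_spec: FrameSpec | None = None,
    hr_params: HarmonicRatioParams | None = None,
) -> list[MicroDopplerSegment]:
    """Full chain: normalize -> high-pass -> frame -> harmonic-ratio select."""
    filter_spec = filter_spec or FilterSpec()
    frame_spec = frame_spec or FrameSpec()
    hr_params = hr_params or HarmonicRatioParams()
    clean = highpass(normalize(recording.iq), filter_spec, recording.fs)
    return detect_segments(recording, frame_spec, hr_params, preprocessed_iq=clean)


def resegment_durations(
    recording,
    durations: tuple[float, ...],
    hr_params: HarmonicRatioParams,
    mode: str = "independent",
    preprocessed_iq: np.ndarray | None = None,
    max_segments_per_duration: int | None = None,
) -> dict[float, list[MicroDopplerSegment]]:
    """Scan the recording at several window lengths (50% overlap each).

    ``mode='independent'`` scans every duration over the whole recording
    (how per-duration segment inventories are counted); ``mode='exclusive'``
    lets each region of signal contribute only at the longest duration for
    which it qualifies, scanning durations longest-first and claiming the
    samples of every retained window.
    """
    durations = tuple(durations)
    if any(durations[i] < durations[i + 1] for i in range(len(durations) - 1)):
        raise ValueError("durations must be sorted descending")
    if mode not in ("independent", "exclusive"):
        raise ValueError("mode must be 'independent' or 'exclusive'")
    iq = recording.iq if preprocessed_iq is None else preprocessed_iq
    x = reduce_channel(iq, hr_params.channel)
    fs = recording.fs
    if any(int(round(d * fs)) < 2 for d in durations):
        raise ValueError("every duration must span at least 2 samples")
    claimed = np.zeros(len(x), dtype=bool)
    out: dict[float, list[MicroDopplerSegment]] = {}
    for d in durations:
        L = int(round(d * fs))
        spec = FrameSpec(window_s=d, overlap_s=d / 2.0)
        tapered, times = frame(x, spec, fs, taper=True)
        raw, _ = frame(x, spec, fs, taper=False)
        segs = []
        for frame_x, raw_x, t0 in zip(tapered, raw, times):
            i0 = int(round(t0 * fs))
            if mode == "exclusive" and claimed[i0 : i0 + L].any():
                continue
            eta = harmonic_ratio(frame_x, hr_params, fs)
            if eta > hr_params.threshold:
                if mode == "exclusive":
                    claimed[i0 : i0 + L] = True
                segs.append(
                    MicroDopplerSegment(
                        samples=raw_x.copy(),
                        fs=fs,
                        start_s=float(t0),
                        duration_s=d,
                        eta_hr=eta,
                        recording_id=getattr(recording, "recording_id", ""),
                        subject_id=getattr(recording, "subject_id", ""),
                        species_name=getattr(recording, "species_name", ""),
                    )
                )
        if max_segments_per_duration is not None and len(segs) > max_segments_per_duration:
            idx = np.linspace(0, len(segs) - 1, max_segments_per_duration).round().astype(int)
            segs = [segs[i] for i in np.unique(idx)]
        out[d] = segs
    return out
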