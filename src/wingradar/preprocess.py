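"""Recording normalization, high-pass filtering and overlapped framing.

The slow Doppler clutter from gross body motion and background reflectors
sits below ~50 Hz, while hymenopteran wingbeat fundamentals lie above it, so
a second-order Chebyshev high-pass at 50 Hz separates the two.  Detection
then operates on overlapping Hann-tapered frames (2 s window, 1 s overlap by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter design: Chebyshev type I unless configured otherwise."""

    family: str = "chebyshev"
    order: int = 2
    cutoff_hz: float = 50.0
    ripple_db: float = 1.0
    mode: str = "forward-backward"  # or "forward-only"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.mode not in ("forward-backward", "forward-only"):
            raise ValueError("mode must be 'forward-backward' or 'forward-only'")

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        if self.cutoff_hz >= fs / 2:
            raise ValueError("cutoff_hz must be below Nyquist")
        if self.family != "chebyshev":
            raise ValueError(f"unsupported filter family {self.family!r}")
        return signal.cheby1(
            self.order, self.ripple_db, self.cutoff_hz, btype="highpass", fs=fs
        )

    def response_at(self, freq_hz: float, fs: float) -> float:
        """|H(f)| of the applied operation (squared magnitude if zero-phase)."""
        b, a = self.design(fs)
        _, h = signal.freqz(b, a, worN=[freq_hz], fs=fs)
        mag = float(np.abs(h[0]))
        return mag * mag if self.mode == "forward-backward" else mag


@dataclass(frozen=True)
class FrameSpec:
    window_s: float = 2.0
    overlap_s: float = 1.0
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.overlap_s < self.window_s):
            raise ValueError("require 0 < overlap_s < window_s")

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s


def normalize(iq: np.ndarray) -> np.ndarray:
    """Remove the complex mean and scale to unit RMS magnitude.

    Per-recording (not per-frame), so detection thresholds are comparable
    across frames of a recording.  All-zero input is returned unchanged.
    """
    x = np.asarray(iq)
    if x.size == 0:
        raise ValueError("empty sequence")
    if not np.all(np.isfinite(x.real)) or not np.all(np.isfinite(np.imag(x))):
        raise ValueError("non-finite samples")
    centered = x - x.mean()
    rms = np.sqrt(np.mean(np.abs(centered) ** 2))
    if rms == 0:
        return centered
    return centered / rms


def highpass(iq: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the high-pass to the real and imaginary channels identically."""
    b, a = spec.design(fs)
    x = np.asarray(iq)
    if spec.mode == "forward-backward":
        filt = lambda v: signal.filtfilt(b, a, v)
    else:
        filt = lambda v: signal.lfilter(b, a, v)
    if np.iscomplexobj(x):
        return filt(x.real) + 1j * filt(x.imag)
    return filt(x)


def frame_starts(n_samples: int, spec: FrameSpec, fs: float) -> np.ndarray:
    """Start indices of the overlapping frames covering a signal."""
    L = int(round(spec.window_s * fs))
    hop = int(round(spec.hop_s * fs))
    if n_samples < L:
        return np.empty(0, dtype=int)
    n_frames = (n_samples - L) // hop + 1
    return np.arange(n_frames) * hop


def frame(
    x: np.ndarray, spec: FrameSpec, fs: float, taper: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Cut ``x`` into overlapping frames.

    Returns ``(frames, start_times_s)`` where frames are Hann-tapered unless
    ``taper=False``.  A too-short signal yields zero frames, not an error.
    """
    x = np.asarray(x)
    L = int(round(spec.window_s * fs))
    starts = frame_starts(len(x), spec, fs)
    if len(starts) == 0:
        return np.empty((0, L), dtype=x.dtype), np.empty(0)
    frames = np.stack([x[s : s + L] for s in starts])
    if taper:
        frames = frames * signal.get_window(spec.window_fn, L, fftbins=True)
    return frames, starts / fs
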