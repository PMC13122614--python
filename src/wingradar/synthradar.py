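"""Synthetic complex-baseband micro-Doppler recordings of flapping insects.

A continuous-wave radar observing an insect at close range returns, after
quadrature down-conversion, a complex I/Q time series that decomposes into
three additive parts: background noise, a slow Doppler component from gross
body motion, and a periodic micro-Doppler component produced by the beating
wings.  The wingbeat part is a sum of harmonics of the fundamental wingbeat
frequency ``f_w``:

    s_wingbeat(t) = sum_n A_n * exp(j * (2*pi*n*f_w*t + phi_n))

This module synthesizes labeled recordings with that structure so the whole
detection/feature/classification pipeline can be exercised and validated
without access to field data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal


class AliasingError(ValueError):
    """Raised when the highest requested harmonic would alias at fs."""


@dataclass(frozen=True)
class WingbeatSpec:
    """Harmonic description of one wingbeat signature.

    Parameters
    ----------
    f_w
        Fundamental wingbeat frequency in Hz.
    harmonics
        Ordered ``(amplitude, phase_rad)`` pairs for harmonics ``n = 1..N``.
    jitter_sd
        Relative standard deviation of slow per-frame frequency jitter
        (dimensionless, >= 0); 0 gives a strictly periodic signal.
    """

    f_w: float
    harmonics: tuple[tuple[float, float], ...]
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.f_w <= 0:
            raise ValueError("f_w must be positive")
        if len(self.harmonics) < 1:
            raise ValueError("at least one harmonic is required")
        if any(a < 0 for a, _ in self.harmonics):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    @property
    def total_power(self) -> float:
        """Mean power of the harmonic sum, sum(A_n^2)."""
        return float(sum(a * a for a, _ in self.harmonics))

    def check_aliasing(self, fs: float) -> None:
        f_top = self.n_harmonics * self.f_w * (1.0 + 3.0 * self.jitter_sd)
        if f_top >= fs / 2:
            raise AliasingError(
                f"highest harmonic {f_top:.1f} Hz >= Nyquist {fs / 2:.1f} Hz"
            )


@dataclass(frozen=True)
class SpeciesProfile:
    """Population-level parameters from which subjects are drawn."""

    species_name: str
    f_w_mean: float
    f_w_sd: float
    harmonic_envelope: tuple[float, ...]
    envelope_sd: float = 0.08  # per-subject multiplicative variation
    body_motion_amp: float = 1.0
    body_motion_bandwidth: float = 12.0
    snr_db: float = 15.0
    jitter_sd: float = 0.003

    def __post_init__(self) -> None:
        if self.f_w_mean - 3.0 * self.f_w_sd <= 50.0:
            raise ValueError(
                "f_w_mean - 3*f_w_sd must exceed the 50 Hz high-pass cutoff"
            )
        if not (0 <= self.body_motion_bandwidth < 50.0):
            raise ValueError("body_motion_bandwidth must lie in [0, 50) Hz")
        if len(self.harmonic_envelope) < 1:
            raise ValueError("harmonic_envelope must have at least one entry")


@dataclass(frozen=True)
class SceneConfig:
    """Recording geometry and schedule (what the capture rig would impose)."""

    fs: float = 1000.0
    duration_s: float = 60.0
    inclusive_endpoints: bool = True
    bout_schedule: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    carrier_ghz: float = 30.0  # metadata only

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        bouts = sorted(self.bout_schedule)
        for i, (a, b) in enumerate(bouts):
            if not (0.0 <= a < b <= self.duration_s):
                raise ValueError(f"bout ({a}, {b}) outside [0, {self.duration_s}]")
            if i > 0 and a < bouts[i - 1][1]:
                raise ValueError("bouts must not overlap")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s)) + (
            1 if self.inclusive_endpoints else 0
        )


@dataclass
class SyntheticRecording:
    """One synthetic I/Q capture with its ground truth."""

    iq: np.ndarray
    fs: float
    subject_id: str
    species_name: str
    truth_bouts: tuple[tuple[float, float], ...]
    truth_f_w: float
    recording_id: str = ""
    seed: int = 0

    @property
    def duration_s(self) -> float:
        return len(self.iq) / self.fs

    @property
    def n_samples(self) -> int:
        return len(self.iq)


def synthesize_wingbeat(
    spec: WingbeatSpec,
    fs: float,
    duration_s: float,
    seed: int | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Sum of complex harmonic exponentials at multiples of ``f_w``.

    With ``jitter_sd > 0`` the instantaneous fundamental drifts slowly
    (piecewise-constant over 0.25 s frames, phase kept continuous), which
    broadens the harmonic lines slightly as real wingbeats do.
    """
    spec.check_aliasing(fs)
    n = int(round(fs * duration_s)) if n_samples is None else int(n_samples)
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        frame_len = max(1, int(round(0.25 * fs)))
        n_frames = -(-n // frame_len)
        eps = rng.normal(0.0, spec.jitter_sd, size=n_frames)
        f_inst = spec.f_w * (1.0 + np.repeat(eps, frame_len)[:n])
        theta = 2.0 * np.pi * np.cumsum(f_inst) / fs
    else:
        t = np.arange(n) / fs
        theta = 2.0 * np.pi * spec.f_w * t
    out = np.zeros(n, dtype=complex)
    for i, (amp, phi) in enumerate(spec.harmonics, start=1):
        out += amp * np.exp(1j * (i * theta + phi))
    return out


def synthesize_body_motion(
    amp: float,
    bandwidth_hz: float,
    fs: float,
    duration_s: float,
    seed: int | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Slow complex Doppler process confined below ``bandwidth_hz``.

    Realized as low-pass filtered circularly symmetric Gaussian noise scaled
    to RMS ``amp``; only its spectral confinement matters downstream (the
    50 Hz high-pass removes it).
    """
    if bandwidth_hz >= fs / 2:
        raise ValueError("bandwidth_hz must be below Nyquist")
    n = int(round(fs * duration_s)) if n_samples is None else int(n_samples)
    if amp == 0 or bandwidth_hz <= 0:
        return np.zeros(n, dtype=complex)
    rng = np.random.default_rng(seed)
    white = rng.normal(size=n) + 1j * rng.normal(size=n)
    sos = signal.butter(4, bandwidth_hz, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white.real) + 1j * signal.sosfiltfilt(sos, white.imag)
    rms = np.sqrt(np.mean(np.abs(x) ** 2))
    return amp * x / rms if rms > 0 else x


def _draw_subject_wingbeat(
    profile: SpeciesProfile, rng: np.random.Generator
) -> WingbeatSpec:
    # clip at 2.5 sd so the aliasing invariant stays satisfiable by design
    f_w = float(
        np.clip(
            rng.normal(profile.f_w_mean, profile.f_w_sd),
            profile.f_w_mean - 2.5 * profile.f_w_sd,
            profile.f_w_mean + 2.5 * profile.f_w_sd,
        )
    )
    env = np.asarray(profile.harmonic_envelope, dtype=float)
    env = np.clip(env * (1.0 + rng.normal(0.0, profile.envelope_sd, env.size)), 0.0, None)
    env[0] = max(env[0], 1e-3)  # fundamental never vanishes
    phases = rng.uniform(0.0, 2.0 * np.pi, env.size)
    return WingbeatSpec(
        f_w=f_w,
        harmonics=tuple(zip(env.tolist(), phases.tolist())),
        jitter_sd=profile.jitter_sd,
    )


def synthesize_recording(
    profile: SpeciesProfile,
    scene: SceneConfig,
    subject_id: str,
    wingbeat: WingbeatSpec | None = None,
) -> SyntheticRecording:
    """Noise + (within bouts) body motion + wingbeat, per the signal model.

    The subject's fundamental is drawn once from the species population
    distribution using the scene seed, so repeated recordings of one subject
    share a wingbeat signature (pass ``wingbeat`` to reuse it explicitly).
    """
    rng = np.random.default_rng(scene.seed)
    if wingbeat is None:
        wingbeat = _draw_subject_wingbeat(profile, rng)
    n = scene.n_samples
    ref_power = float(np.sum(np.asarray(profile.harmonic_envelope) ** 2))
    noise_power = ref_power / 10.0 ** (profile.snr_db / 10.0)
    iq = np.sqrt(noise_power / 2.0) * (rng.normal(size=n) + 1j * rng.normal(size=n))
    for start_s, end_s in scene.bout_schedule:
        i0 = int(round(start_s * scene.fs))
        i1 = min(n, int(round(end_s * scene.fs)))
        m = i1 - i0
        if m <= 0:
            continue
        seed_w, seed_b = rng.integers(0, 2**31 - 1, size=2)
        iq[i0:i1] += synthesize_wingbeat(
            wingbeat, scene.fs, m / scene.fs, seed=int(seed_w), n_samples=m
        )
        iq[i0:i1] += synthesize_body_motion(
            profile.body_motion_amp,
            profile.body_motion_bandwidth,
            scene.fs,
            m / scene.fs,
            seed=int(seed_b),
            n_samples=m,
        )
    return SyntheticRecording(
        iq=iq,
        fs=scene.fs,
        subject_id=subject_id,
        species_name=profile.species_name,
        truth_bouts=tuple(scene.bout_schedule),
        truth_f_w=wingbeat.f_w,
        seed=scene.seed,
    )


def random_bout_schedule(
    rng: np.random.Generator,
    duration_s: float,
    n_bouts: tuple[int, int] = (3, 5),
    bout_len_s: tuple[float, float] = (3.0, 6.0),
    margin_s: float = 1.0,
) -> tuple[tuple[float, float], ...]:
    """Non-overlapping flight bouts placed uniformly inside the recording."""
    k = int(rng.integers(n_bouts[0], n_bouts[1] + 1))
    lengths = rng.uniform(bout_len_s[0], bout_len_s[1], size=k)
    free = duration_s - 2 * margin_s - lengths.sum()
    if free < 0:  # shrink proportionally for short recordings
        lengths *= (duration_s - 2 * margin_s) * 0.8 / lengths.sum()
        free = duration_s - 2 * margin_s - lengths.sum()
    gaps = rng.dirichlet(np.ones(k + 1)) * free
    bouts = []
    t = margin_s
    for i in range(k):
        t += gaps[i]
        bouts.append((round(t, 3), round(t + lengths[i], 3)))
        t += lengths[i]
    return tuple(bouts)


#: Default five-species study profiles.  Fundamentals are well separated and
#: each species keeps its harmonic stack below Nyquist at fs = 1 kHz, so
#: higher-fundamental species carry fewer harmonics.
DEFAULT_PROFILES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("Bombus terrestris", 120.0, 4.0, (1.0, 0.55, 0.28)),
    SpeciesProfile("Bombus lapidarius", 160.0, 4.0, (1.0, 0.40)),
    SpeciesProfile("Bombus muscorum", 200.0, 4.0, (1.0, 0.65)),
    SpeciesProfile("Apis mellifera", 240.0, 4.0, (1.0,)),
    SpeciesProfile("Vespula vulgaris", 300.0, 4.0, (1.0,)),
)


def generate_cohort(
    profiles: tuple[SpeciesProfile, ...],
    n_subjects_per_species: int,
    recordings_per_subject: int = 1,
    seed: int = 0,
    scene_template: SceneConfig | None = None,
) -> tuple[list[SyntheticRecording], pd.DataFrame]:
    """Deterministic multi-subject cohort with a manifest table.

    Each subject gets its own wingbeat draw; each recording its own bout
    schedule and noise.  The manifest lists one row per recording with the
    ground-truth fundamental.
    """
    if n_subjects_per_species < 1:
        raise ValueError("n_subjects_per_species must be >= 1")
    template = scene_template or SceneConfig()
    master = np.random.default_rng(seed)
    recordings: list[SyntheticRecording] = []
    rows = []
    seen_subjects: set[str] = set()
    for profile in profiles:
        slug = profile.species_name.replace(" ", "_")
        for s in range(n_subjects_per_species):
            subject_id = f"{slug}-S{s:02d}"
            if subject_id in seen_subjects:
                raise ValueError(f"duplicate subject id {subject_id}")
            seen_subjects.add(subject_id)
            subj_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
            wingbeat = _draw_subject_wingbeat(profile, subj_rng)
            for r in range(recordings_per_subject):
                schedule = (
                    template.bout_schedule
                    if template.bout_schedule
                    else random_bout_schedule(subj_rng, template.duration_s)
                )
                scene = replace(
                    template,
                    bout_schedule=schedule,
                    seed=int(subj_rng.integers(0, 2**31 - 1)),
                )
                rec = synthesize_recording(profile, scene, subject_id, wingbeat=wingbeat)
                rec.recording_id = f"{subject_id}-R{r:02d}"
                recordings.append(rec)
                rows.append(
                    {
                        "recording_id": rec.recording_id,
                        "subject_id": subject_id,
                        "species": profile.species_name,
                        "truth_f_w": rec.truth_f_w,
                        "n_samples": rec.n_samples,
                        "n_bouts": len(schedule),
                        "flight_s": round(sum(b - a for a, b in schedule), 3),
                        "seed": rec.seed,
                    }
                )
    return recordings, pd.DataFrame(rows)
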