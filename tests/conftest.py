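import numpy as np
import pytest

import wingradar as wr


@pytest.fixture(scope="session")
def cohort():
    """Standard five-species study cohort: 4 subjects each, 60 s recordings."""
    recs, manifest = wr.generate_cohort(wr.DEFAULT_PROFILES, 4, 1, seed=7)
    return recs, manifest


@pytest.fixture(scope="session")
def cohort_dataset(cohort):
    """2 s micro-Doppler segments of the cohort with their 70-feature table."""
    recs, _ = cohort
    segs = []
    for rec in recs:
        segs.extend(wr.run_detection(rec))
    return wr.build_dataset(segs)


@pytest.fixture(scope="session")
def sweep_table(cohort):
    """Duration-sweep (2 s vs 0.1 s) on the standard cohort, fixed seed."""
    recs, _ = cohort
    return wr.duration_sweep(
        recs, (2.0, 0.1), wr.CascadeConfig(seed=1), max_segments_per_recording=40
    )


@pytest.fixture(scope="session")
def wasp_recording():
    """Wasp analog: stationary 0-6 s, a single flight bout at 6-10 s."""
    profile = next(
        p for p in wr.DEFAULT_PROFILES if p.species_name == "Vespula vulgaris"
    )
    scene = wr.SceneConfig(duration_s=60.0, bout_schedule=((6.0, 10.0),), seed=3)
    return wr.synthesize_recording(profile, scene, "wasp-00")


def wingbeat_with_noise(
    f_w: float,
    envelope: tuple[float, ...],
    snr_db: float,
    duration_s: float = 2.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Real-valued test segment: harmonic wingbeat plus white noise."""
    rng = np.random.default_rng(seed)
    spec = wr.WingbeatSpec(
        f_w, tuple((a, rng.uniform(0, 2 * np.pi)) for a in envelope)
    )
    sig = wr.synthesize_wingbeat(spec, fs, duration_s, seed=seed)
    npow = spec.total_power / 10 ** (snr_db / 10)
    noise = np.sqrt(npow / 2) * (
        rng.normal(size=len(sig)) + 1j * rng.normal(size=len(sig))
    )
    return (sig + noise).real
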