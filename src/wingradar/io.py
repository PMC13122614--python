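"""Plain-text persistence for recordings, segments and reports.

A recording is stored as a three-column CSV (sample_index, I, Q) next to a
JSON sidecar carrying the sampling rate, identity and ground-truth bouts.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .synthradar import SyntheticRecording


def write_recording(rec: SyntheticRecording, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = rec.recording_id or rec.subject_id
    csv_path = out_dir / f"{stem}.csv"
    pd.DataFrame(
        {
            "sample_index": np.arange(rec.n_samples),
            "I": rec.iq.real,
            "Q": rec.iq.imag,
        }
    ).to_csv(csv_path, index=False)
    sidecar = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "species_name": rec.species_name,
        "recording_id": rec.recording_id,
        "seed": rec.seed,
        "truth_f_w": rec.truth_f_w,
        "truth_bouts": [list(b) for b in rec.truth_bouts],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_recording(csv_path: str | Path) -> SyntheticRecording:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    iq = df["I"].to_numpy() + 1j * df["Q"].to_numpy()
    return SyntheticRecording(
        iq=iq,
        fs=float(meta["fs"]),
        subject_id=meta["subject_id"],
        species_name=meta["species_name"],
        truth_bouts=tuple(tuple(b) for b in meta["truth_bouts"]),
        truth_f_w=float(meta["truth_f_w"]),
        recording_id=meta.get("recording_id", ""),
        seed=int(meta.get("seed", 0)),
    )


def segments_to_frame(segments) -> pd.DataFrame:
    """Segment manifest (one row per retained segment, no waveforms)."""
    return pd.DataFrame(
        [
            {
                "recording_id": s.recording_id,
                "subject_id": s.subject_id,
                "species": s.species_name,
                "start_s": s.start_s,
                "duration_s": s.duration_s,
                "eta_hr": s.eta_hr,
            }
            for s in segments
        ]
    )


def save_model(model, path: str | Path) -> None:
    Path(path).write_bytes(pickle.dumps(model))


def load_model(path: str | Path):
    return pickle.loads(Path(path).read_bytes())
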