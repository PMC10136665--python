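"""Plain-text cohort I/O.

One directory per subject-session containing ``ecg.csv`` (time_s, ecg_mv),
``gsr.csv`` (time_s, gsr_us), ``protocol.yaml`` and ``truth.yaml``
(generative parameters; present only for synthetic cohorts). Times are
seconds from record start; all CSVs carry a one-line header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import ECGRecord
from .eda import EDARecord
from .errors import ConfigurationError, DataError
from .protocol import SessionProtocol
from .synth import SessionRecording, SubjectGroundTruth


def session_dirname(subject_id: str, session: str) -> str:
    return f"{subject_id}_{session}"


def write_session(rec: SessionRecording, root: Path) -> Path:
    d = Path(root) / session_dirname(rec.subject_id, rec.session)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": np.round(rec.ecg.times, 6), "ecg_mv": np.round(rec.ecg.samples, 5)}
    ).to_csv(d / "ecg.csv", index=False)
    pd.DataFrame(
        {"time_s": np.round(rec.gsr.times, 6), "gsr_us": np.round(rec.gsr.samples, 5)}
    ).to_csv(d / "gsr.csv", index=False)
    rec.protocol.to_yaml(d / "protocol.yaml")
    with open(d / "truth.yaml", "w") as fh:
        yaml.safe_dump(rec.truth.to_dict(), fh, sort_keys=False)
    return d


def write_cohort(recordings: list[SessionRecording], root: Path) -> Path:
    """Write every session plus a manifest listing them."""
    root = Path(root)
    entries = []
    for rec in recordings:
        d = write_session(rec, root)
        entries.append(
            {
                "subject": rec.subject_id,
                "session": rec.session,
                "dir": d.name,
                "files": sorted(p.name for p in d.iterdir()),
            }
        )
    manifest = {"n_sessions": len(entries), "sessions": entries}
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return root


def manifest_hash(root: Path) -> str:
    """SHA-256 over the manifest plus every listed data file."""
    root = Path(root)
    h = hashlib.sha256()
    with open(root / "manifest.json", "rb") as fh:
        h.update(fh.read())
    manifest = json.loads((root / "manifest.json").read_text())
    for entry in manifest["sessions"]:
        for name in entry["files"]:
            h.update((root / entry["dir"] / name).read_bytes())
    return h.hexdigest()


def _read_signal_csv(path: Path, value_col: str) -> tuple[np.ndarray, float, float]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or value_col not in df.columns:
        raise DataError(f"{path} must have columns time_s,{value_col}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: record too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return df[value_col].to_numpy(dtype=float), fs, float(t[0])


def read_session(d: Path) -> SessionRecording:
    d = Path(d)
    ecg_samples, fs_ecg, t0_ecg = _read_signal_csv(d / "ecg.csv", "ecg_mv")
    gsr_samples, fs_gsr, t0_gsr = _read_signal_csv(d / "gsr.csv", "gsr_us")
    protocol = SessionProtocol.from_yaml(d / "protocol.yaml")
    truth_path = d / "truth.yaml"
    if truth_path.exists():
        with open(truth_path) as fh:
            td = yaml.safe_load(fh)
        truth = SubjectGroundTruth(
            subject_id=td["subject_id"],
            mean_hr=tuple(td["mean_hr"]),
            sd_scale=tuple(td["sd_scale"]),
            lf_power=td["lf_power"],
            hf_power=td["hf_power"],
            tonic_level=tuple(td["tonic_level"]),
            scr_amp_median=td["scr_amp_median"],
            scr_amp_sigma=td["scr_amp_sigma"],
            deltas={
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in td.get("deltas", {}).items()
            },
        )
    else:
        truth = SubjectGroundTruth(subject_id=d.name)
    subject, _, session = d.name.rpartition("_")
    if session not in ("T0", "T1"):
        raise ConfigurationError(f"cannot parse session from directory name {d.name!r}")
    return SessionRecording(
        subject_id=subject or d.name,
        session=session,
        ecg=ECGRecord(ecg_samples, fs_ecg, start_time=t0_ecg),
        gsr=EDARecord(gsr_samples, fs_gsr, start_time=t0_gsr),
        protocol=protocol,
        truth=truth,
    )


def read_cohort(root: Path) -> list[SessionRecording]:
    root = Path(root)
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        dirs = [root / e["dir"] for e in manifest["sessions"]]
    else:
        dirs = sorted(p for p in root.iterdir() if (p / "ecg.csv").exists())
    if not dirs:
        raise DataError(f"no session directories under {root}")
    return [read_session(d) for d in dirs]
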