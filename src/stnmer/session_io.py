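"""Session directory format: JSON manifest + raw float32 record files.

No established container covers depth-stepped MER sessions, so the package
stores one directory per hemisphere::

    session/
      manifest.json            # schema, axes, fs, file map, provenance
      ground_truth.json        # optional (synthetic sessions)
      signals/<track>_<idx>.f32  # little-endian 32-bit float, one per record

Round trip is byte-stable: write -> read -> write reproduces the signal
files exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import SessionFormatError
from .simulate import GroundTruth, MerSession

__all__ = ["write_session", "read_session", "read_ground_truth"]

SCHEMA_VERSION = 1


def _record_filename(track: str, depth_idx: int) -> str:
    return f"signals/{track}_{depth_idx:03d}.f32"


def write_session(session: MerSession, path, truth: GroundTruth | None = None,
                  provenance: dict | None = None) -> Path:
    path = Path(path)
    (path / "signals").mkdir(parents=True, exist_ok=True)
    n = session.n_samples()
    files = {}
    for trk in session.track_labels:
        for di, d in enumerate(session.depths_mm):
            rel = _record_filename(trk, di)
            arr = np.asarray(session.record(trk, d), dtype="<f4")
            arr.tofile(path / rel)
            files[f"{trk}|{di}"] = rel
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "session_id": session.session_id,
        "fs": session.fs,
        "channel_kind": session.channel_kind,
        "track_labels": list(session.track_labels),
        "depths_mm": [float(d) for d in session.depths_mm],
        "n_samples": n,
        "files": files,
        "provenance": provenance or {"source": "unspecified"},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        gt = {
            "stn_entry_mm": dict(truth.stn_entry_mm),
            "stn_exit_mm": dict(truth.stn_exit_mm),
            "dorsal_ventral_boundary_mm": truth.dorsal_ventral_boundary_mm,
            "best_track": truth.best_track,
            "depths_mm": [float(d) for d in truth.depths_mm],
            "in_stn": {t: np.asarray(v).astype(bool).tolist()
                       for t, v in truth.in_stn.items()},
        }
        (path / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    return path


def read_session(path) -> MerSession:
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise SessionFormatError("schema", f"no manifest.json under {path}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError("schema", f"manifest is not valid JSON: {exc}")
    for key in ("schema_version", "session_id", "fs", "track_labels",
                "depths_mm", "n_samples", "files"):
        if key not in manifest:
            raise SessionFormatError("schema", f"manifest missing field {key!r}")
    if manifest["schema_version"] != SCHEMA_VERSION:
        raise SessionFormatError(
            "schema", f"unsupported schema version {manifest['schema_version']}")
    depths = np.asarray(manifest["depths_mm"], dtype=float)
    n = int(manifest["n_samples"])
    signals: dict[tuple[str, float], np.ndarray] = {}
    for trk in manifest["track_labels"]:
        for di, d in enumerate(depths):
            key = f"{trk}|{di}"
            rel = manifest["files"].get(key)
            if rel is None or not (path / rel).exists():
                raise SessionFormatError(
                    "missing_record",
                    f"missing record for track {trk!r} at depth {d} mm")
            arr = np.fromfile(path / rel, dtype="<f4")
            if len(arr) != n:
                raise SessionFormatError(
                    "length_mismatch",
                    f"record ({trk!r}, {d} mm) has {len(arr)} samples, "
                    f"manifest says {n}")
            signals[(trk, float(d))] = arr.astype(float)
    return MerSession(
        session_id=manifest["session_id"],
        track_labels=tuple(manifest["track_labels"]),
        depths_mm=depths,
        fs=float(manifest["fs"]),
        signals=signals,
        channel_kind=manifest.get("channel_kind", "lfp"),
    )


def read_ground_truth(path) -> GroundTruth:
    gpath = Path(path) / "ground_truth.json"
    if not gpath.exists():
        raise SessionFormatError("schema", f"no ground_truth.json under {path}")
    d = json.loads(gpath.read_text())
    return GroundTruth(
        stn_entry_mm=d["stn_entry_mm"],
        stn_exit_mm=d["stn_exit_mm"],
        dorsal_ventral_boundary_mm=float(d["dorsal_ventral_boundary_mm"]),
        best_track=d["best_track"],
        in_stn={t: np.asarray(v, dtype=bool) for t, v in d["in_stn"].items()},
        depths_mm=np.asarray(d["depths_mm"], dtype=float),
    )
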