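"""End-to-end localization pipeline: session -> decision report.

Chains the stages in order: optional LMS decorrelation, per-depth
median-Welch spectra (with the adaptation transient excluded), per-track
depth-frequency maps, common-baseline normalization, beta/HFO feature
extraction, min-max normalization, per-depth LDA votes, and longest-span
track selection.  The report is a plain JSON-serializable dict and is fully
determined by (session, config, model, package version).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (BETA_BAND, HFO_BAND, LdaModel, classify_depths,
                       features_from_dfms, load_default_model,
                       minmax_normalize, select_track)
from .preprocess import LmsConfig, lms_decorrelate
from .session_io import read_session
from .simulate import MerSession
from .spectral import build_dfm, normalize_dfm, welch_median_spectrum

__all__ = ["PipelineConfig", "run_pipeline", "compute_normalized_dfms"]


@dataclass(frozen=True)
class PipelineConfig:
    lms_enabled: bool = True
    lms: LmsConfig = field(default_factory=LmsConfig)
    transient_s: float = 1.0          # residual settling time dropped per record
    window_s: float = 1.0
    overlap: float = 0.5
    n_baseline_depths: int = 3
    max_freq_hz: float = 500.0
    beta_band: tuple[float, float] = BETA_BAND
    hfo_band: tuple[float, float] = HFO_BAND
    feature_aggregate: str = "mean_db"
    selection_criterion: str = "span"

    def validate(self) -> None:
        self.lms.validate()
        if self.transient_s < 0:
            raise ValueError("transient_s must be non-negative")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lms" in d and isinstance(d["lms"], dict):
            d["lms"] = LmsConfig(**d["lms"])
        for key in ("beta_band", "hfo_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        return sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def compute_normalized_dfms(session: MerSession, config: PipelineConfig):
    """Decorrelate (optionally), estimate spectra, and normalize the DFMs.

    Returns ``(normalized_dfms, residual_session)``.
    """
    work = lms_decorrelate(session, config.lms) if config.lms_enabled else session
    skip = int(round(config.transient_s * session.fs)) if config.lms_enabled else 0
    linear = []
    for trk in work.track_labels:
        spectra = []
        for d in work.depths_mm:
            rec = work.record(trk, d)[skip:]
            spectra.append((float(d), welch_median_spectrum(
                rec, work.fs, config.window_s, config.overlap)))
        linear.append(build_dfm(spectra, trk, max_freq_hz=config.max_freq_hz))
    return normalize_dfm(linear, config.n_baseline_depths), work


def run_pipeline(session: MerSession | str | Path,
                 config: PipelineConfig | None = None,
                 model: LdaModel | None = None) -> dict:
    """Run the full localization chain and return the decision report.

    On a stage failure the report carries ``error = {stage, message}`` with
    all outputs computed so far preserved; otherwise ``error`` is None.
    """
    config = config or PipelineConfig()
    config.validate()
    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "decorrelation": "on" if config.lms_enabled else "off",
        "error": None,
        "log": [],
    }
    log = report["log"].append
    stage = "load"
    try:
        if not isinstance(session, MerSession):
            session = read_session(session)
        report["session_id"] = session.session_id
        log(f"loaded session {session.session_id}: "
            f"{len(session.track_labels)} tracks x {len(session.depths_mm)} depths")

        stage = "model"
        if model is None:
            model = load_default_model()
            log("using shipped default LDA model")
        report["model"] = json.loads(model.to_json())

        stage = "spectral"
        log("LMS decorrelation " + ("enabled (weights restart per depth, "
            f"step={config.lms.step_size}, taps={config.lms.n_taps_per_channel})"
            if config.lms_enabled else "disabled"))
        dfms, _ = compute_normalized_dfms(session, config)
        log(f"DFMs: {len(dfms)} tracks, baseline = {config.n_baseline_depths} "
            "most superior depths pooled across tracks, scale 10*log10")

        stage = "features"
        feats = minmax_normalize(features_from_dfms(
            dfms, config.beta_band, config.hfo_band, config.feature_aggregate))
        log(f"features: mean dB over beta {config.beta_band} Hz and HFO "
            f"{config.hfo_band} Hz bins, min-max pooled over the hemisphere")

        stage = "classify"
        decision = select_track(classify_depths(model, feats),
                                criterion=config.selection_criterion)
        report["tracks"] = {
            t: {
                "depths_mm": [float(x) for x in decision.depths_mm],
                "decision_distances": [float(x) for x in decision.decision_distances[t]],
                "votes": [bool(v) for v in decision.votes[t]],
                "spans": [asdict(s) for s in decision.spans[t]],
            }
            for t in decision.track_labels
        }
        report["selected_track"] = decision.selected_track
        report["estimated_entry_mm"] = decision.estimated_entry_mm
        log(f"selected track: {decision.selected_track} "
            f"(criterion={config.selection_criterion}, boundary votes out-STN)")
    except Exception as exc:  # noqa: BLE001 - preserved in the report
        report["error"] = {"stage": stage, "message": str(exc)}
    return report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path
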