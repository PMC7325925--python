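"""Per-depth in/out-STN classification and implantation-track selection.

Each depth of each track is summarized by two features taken from the
log-normalized depth-frequency map: mean dB power in the beta band (11-32 Hz)
and in the HFO band (200-400 Hz).  Features are min-max normalized across the
hemisphere (pooling all tracks and depths) to tame inter-subject power
differences, then fed to a binary linear discriminant: a positive decision
distance votes in-STN.  The implantation track is the one with the longest
contiguous run of in-STN votes along the descent, measured in mm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .simulate import TRACK_LABEL_ORDER
from .spectral import DepthFrequencyMap

__all__ = [
    "BandFeatures",
    "LdaModel",
    "Span",
    "TrackDecision",
    "extract_band_features",
    "minmax_normalize",
    "train_lda",
    "classify_depths",
    "select_track",
    "load_default_model",
    "BETA_BAND",
    "HFO_BAND",
]

BETA_BAND = (11.0, 32.0)
HFO_BAND = (200.0, 400.0)


@dataclass
class BandFeatures:
    """Beta/HFO band power per (track, depth) of one hemisphere.

    ``beta`` and ``hfo`` are ``(n_depths,)`` vectors per track; raw values
    are mean dB over band bins of the normalized DFM, normalized values lie
    in [0, 1].
    """

    track_labels: tuple[str, ...]
    depths_mm: np.ndarray
    beta: dict[str, np.ndarray]
    hfo: dict[str, np.ndarray]
    normalized: bool = False

    def stacked(self) -> np.ndarray:
        """(n_tracks*n_depths, 2) feature matrix in track-major order."""
        rows = [np.column_stack([self.beta[t], self.hfo[t]])
                for t in self.track_labels]
        return np.vstack(rows)


@dataclass(frozen=True)
class LdaModel:
    """Binary linear discriminant over (beta, hfo) features.

    ``decision_distance(x) = weights . x + bias``; positive means in-STN.
    """

    weights: tuple[float, float]
    bias: float
    class_order: tuple[str, str] = ("out_stn", "in_stn")
    training_meta: dict = field(default_factory=dict)

    def decision_distance(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ np.asarray(self.weights) + self.bias

    def to_json(self) -> str:
        return json.dumps({
            "weights": list(self.weights),
            "bias": self.bias,
            "class_order": list(self.class_order),
            "training_meta": self.training_meta,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LdaModel":
        d = json.loads(text)
        return cls(weights=tuple(d["weights"]), bias=float(d["bias"]),
                   class_order=tuple(d["class_order"]),
                   training_meta=d.get("training_meta", {}))


@dataclass(frozen=True)
class Span:
    start_mm: float   # most superior depth of the run
    end_mm: float     # most inferior depth of the run
    length_mm: float
    mean_distance: float


@dataclass
class TrackDecision:
    track_labels: tuple[str, ...]
    depths_mm: np.ndarray
    decision_distances: dict[str, np.ndarray]
    votes: dict[str, np.ndarray]
    spans: dict[str, list[Span]] = field(default_factory=dict)
    selected_track: str | None = None
    estimated_entry_mm: float | None = None


def extract_band_features(dfm: DepthFrequencyMap,
                          beta_band: tuple[float, float] = BETA_BAND,
                          hfo_band: tuple[float, float] = HFO_BAND,
                          aggregate: str = "mean_db") -> tuple[np.ndarray, np.ndarray]:
    """Per-depth band powers of one log-normalized DFM.

    The feature is the mean of map values over bins with
    ``band_lo <= f <= band_hi`` (in dB by default; ``aggregate='mean_linear'``
    averages linear power instead and returns its dB).
    """
    if dfm.scale != "log_normalized_db":
        raise ValueError("extract_band_features expects a log-normalized DFM")
    out = []
    for lo, hi in (beta_band, hfo_band):
        sel = (dfm.freqs_hz >= lo) & (dfm.freqs_hz <= hi)
        if not sel.any():
            raise ValueError(f"band ({lo}, {hi}) Hz outside the frequency axis")
        if aggregate == "mean_db":
            out.append(dfm.values[:, sel].mean(axis=1))
        elif aggregate == "mean_linear":
            lin = 10.0 ** (dfm.values[:, sel] / 10.0)
            out.append(10.0 * np.log10(lin.mean(axis=1)))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    return out[0], out[1]


def features_from_dfms(dfms: list[DepthFrequencyMap],
                       beta_band=BETA_BAND, hfo_band=HFO_BAND,
                       aggregate: str = "mean_db") -> BandFeatures:
    """Collect raw band features of a hemisphere's normalized DFMs."""
    beta, hfo = {}, {}
    for m in dfms:
        beta[m.track], hfo[m.track] = extract_band_features(
            m, beta_band, hfo_band, aggregate)
    return BandFeatures(
        track_labels=tuple(m.track for m in dfms),
        depths_mm=dfms[0].depths_mm.copy(),
        beta=beta, hfo=hfo, normalized=False)


def minmax_normalize(features: BandFeatures) -> BandFeatures:
    """Min-max scale each feature to [0, 1] across the pooled hemisphere.

    The min and max are taken over all tracks and depths together (per
    feature), so within-hemisphere contrasts are preserved while absolute
    power scale is removed.  A constant feature maps to 0.5 everywhere (with
    a warning) — degenerate but well-defined.
    """
    out_beta, out_hfo = {}, {}
    for name, src, dst in (("beta", features.beta, out_beta),
                           ("hfo", features.hfo, out_hfo)):
        pooled = np.concatenate([src[t] for t in features.track_labels])
        if pooled.size < 2:
            raise ValueError("need at least 2 values per feature")
        lo, hi = pooled.min(), pooled.max()
        if hi == lo:
            warnings.warn(f"constant {name} feature; mapping to 0.5",
                          stacklevel=2)
            for t in features.track_labels:
                dst[t] = np.full_like(src[t], 0.5)
        else:
            for t in features.track_labels:
                dst[t] = (src[t] - lo) / (hi - lo)
    return BandFeatures(track_labels=features.track_labels,
                        depths_mm=features.depths_mm.copy(),
                        beta=out_beta, hfo=out_hfo, normalized=True)


def train_lda(features: np.ndarray, labels: np.ndarray,
              training_meta: dict | None = None,
              ridge: float = 1e-8) -> LdaModel:
    """Closed-form Fisher/pooled-covariance LDA on (beta, hfo) features.

    ``weights`` is ``pooled_cov^-1 (mu_in - mu_out)`` and the bias places the
    boundary at the prior-weighted midpoint (Gaussian equal-covariance
    discriminant with estimated priors).  No iterative fitting.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("features must be (n, 2)")
    n_in, n_out = int(y.sum()), int((~y).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError("need at least 2 samples of each class")
    mu_in = X[y].mean(axis=0)
    mu_out = X[~y].mean(axis=0)
    cov = (np.cov(X[y].T, bias=False) * (n_in - 1)
           + np.cov(X[~y].T, bias=False) * (n_out - 1)) / (n_in + n_out - 2)
    cond_limit = 1e10
    if np.linalg.cond(cov) > cond_limit:
        eps = ridge * np.trace(cov) if np.trace(cov) > 0 else ridge
        warnings.warn(f"singular pooled covariance; ridge eps={eps:g}",
                      stacklevel=2)
        cov = cov + eps * np.eye(2)
    w = np.linalg.solve(cov, mu_in - mu_out)
    bias = float(-w @ (mu_in + mu_out) / 2.0 + np.log(n_in / n_out))
    meta = dict(training_meta or {})
    meta.setdefault("n_in", n_in)
    meta.setdefault("n_out", n_out)
    return LdaModel(weights=(float(w[0]), float(w[1])), bias=bias,
                    training_meta=meta)


def classify_depths(model: LdaModel, features: BandFeatures) -> TrackDecision:
    """Decision distances and in-STN votes per (track, depth).

    A depth votes in-STN iff its distance is strictly positive; a feature
    exactly on the boundary votes out-STN (conservative toward not declaring
    STN).
    """
    if not features.normalized:
        raise ValueError("classify_depths requires min-max normalized features")
    distances, votes = {}, {}
    for t in features.track_labels:
        X = np.column_stack([features.beta[t], features.hfo[t]])
        d = model.decision_distance(X)
        distances[t] = d
        votes[t] = d > 0
    return TrackDecision(track_labels=features.track_labels,
                         depths_mm=features.depths_mm.copy(),
                         decision_distances=distances, votes=votes)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (inclusive) of True runs."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _label_rank(label: str) -> int:
    return (TRACK_LABEL_ORDER.index(label)
            if label in TRACK_LABEL_ORDER else len(TRACK_LABEL_ORDER))


def select_track(decision: TrackDecision,
                 criterion: str = "span") -> TrackDecision:
    """Complete a decision with spans and the selected implantation track.

    A span is a maximal run of consecutive in-STN votes along the descending
    depth order; its length in mm is the distance from first to last depth of
    the run plus one local depth step (so a single vote counts one step, and
    runs keep their metric length when step size varies within a descent).
    The selected track maximizes the longest span length
    (``criterion='count'`` instead maximizes the total number of in-STN
    votes); ties break toward the larger mean decision distance over the
    winning span, then canonical track-label order (center first).  If no
    track votes in-STN anywhere, ``selected_track`` is None ("STN not
    found").
    """
    if criterion not in ("span", "count"):
        raise ValueError("criterion must be 'span' or 'count'")
    depths = decision.depths_mm
    steps = -np.diff(depths)
    spans: dict[str, list[Span]] = {}
    best: tuple | None = None
    for t in decision.track_labels:
        v = decision.votes[t]
        d = decision.decision_distances[t]
        tspans = []
        for i0, i1 in _runs(v):
            step = steps[min(i0, len(steps) - 1)] if len(steps) else 0.0
            length = depths[i0] - depths[i1] + step
            tspans.append(Span(start_mm=float(depths[i0]),
                               end_mm=float(depths[i1]),
                               length_mm=float(length),
                               mean_distance=float(d[i0:i1 + 1].mean())))
        spans[t] = tspans
        if not tspans:
            continue
        top = max(tspans, key=lambda s: (s.length_mm, s.mean_distance))
        score = (top.length_mm if criterion == "span" else float(v.sum()))
        key = (score, top.mean_distance, -_label_rank(t))
        if best is None or key > best[0]:
            best = (key, t, top)
    decision.spans = spans
    if best is None:
        decision.selected_track = None
        decision.estimated_entry_mm = None
    else:
        decision.selected_track = best[1]
        decision.estimated_entry_mm = best[2].start_mm
    return decision


def load_default_model() -> LdaModel:
    """The shipped discriminant, trained on labeled synthetic sessions.

    Training provenance (generator seeds and configuration) is recorded in
    ``training_meta``.
    """
    text = (resources.files("stnmer") / "data" / "default_lda.json").read_text()
    return LdaModel.from_json(text)
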