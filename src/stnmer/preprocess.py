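"""Raw-signal conditioning: downsampling, SUA high-pass, LMS decorrelation.

The decorrelation step addresses a practical problem of BenGun recordings:
all microelectrodes share the cannula as reference, so a large common
component masks the spatially specific LFP differences between tracks.  Each
track is predicted sample-by-sample as a linear combination of the other
tracks at the same depth (adaptive weights, steepest-descent update) and the
prediction residual — the spatially specific part — is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .simulate import MerSession

__all__ = ["LmsConfig", "downsample_lfp", "sua_highpass", "lms_decorrelate"]


@dataclass(frozen=True)
class LmsConfig:
    """Adaptive-filter parameters for :func:`lms_decorrelate`.

    ``step_size`` is the adaptation rate; with ``normalized=True`` (default)
    it is divided by a running estimate of the regressor power (NLMS), which
    keeps the update stable across amplitude scales.  ``n_taps_per_channel``
    sets the regressor memory; the default of 1 (instantaneous weights)
    reflects that a shared reference contaminates all tracks simultaneously,
    with no relative delay to model.
    """

    step_size: float = 0.01
    n_taps_per_channel: int = 1
    weight_init: float = 0.0
    normalized: bool = True
    power_smoothing: float = 0.99  # forgetting factor of the power estimate

    def validate(self) -> None:
        if not self.step_size > 0:
            raise ConfigurationError("step_size must be positive")
        if self.n_taps_per_channel < 1:
            raise ConfigurationError("n_taps_per_channel must be >= 1")
        if not 0.0 < self.power_smoothing < 1.0:
            raise ConfigurationError("power_smoothing must lie in (0, 1)")


def downsample_lfp(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased downsampling by an integer factor.

    A zero-phase FIR low-pass with cutoff ``0.45*fs_out`` is applied
    (forward-backward, so no group delay shifts depth records relative to
    each other), then every ``fs_in/fs_out``-th sample is kept.  Content
    above the output Nyquist is attenuated by >= 40 dB.
    """
    if fs_out >= fs_in:
        raise ValueError("fs_out must be below fs_in")
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer ratio, got {ratio}")
    ratio = int(round(ratio))
    x = np.asarray(x, dtype=float)
    # transition band 0.45*fs_out .. 0.5*fs_out; Hamming-window FIR reaches
    # ~53 dB stopband, doubled by the forward-backward pass
    trans = 0.05 * fs_out
    numtaps = int(np.ceil(3.3 * fs_in / trans)) | 1
    h = sps.firwin(numtaps, 0.45 * fs_out, fs=fs_in)
    y = sps.filtfilt(h, [1.0], x, padlen=min(len(x) - 1, 3 * numtaps))
    return y[::ratio]


def sua_highpass(x: np.ndarray, fs: float) -> np.ndarray:
    """Second-order IIR high-pass at 300 Hz for the spiking-band channel."""
    if fs <= 600:
        raise ValueError("fs must exceed 600 Hz for a 300 Hz high-pass")
    sos = sps.butter(2, 300.0, btype="highpass", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(x, dtype=float))


def _lms_batch(targets: np.ndarray, regressors: np.ndarray,
               cfg: LmsConfig) -> np.ndarray:
    """Run NLMS/LMS over many independent records simultaneously.

    targets : (n_records, n_samples)
    regressors : (n_records, n_channels, n_samples)
    Returns residuals of shape (n_records, n_samples).

    With ``n_taps_per_channel > 1`` each regressor channel contributes its
    current and past samples; the weight vector per record has
    ``n_channels * n_taps`` entries, updated by steepest descent on the
    instantaneous squared error.
    """
    n_rec, n_samp = targets.shape
    n_chan = regressors.shape[1]
    taps = cfg.n_taps_per_channel
    # delay-line expansion: (n_rec, n_chan*taps, n_samp)
    if taps == 1:
        X = regressors
    else:
        X = np.zeros((n_rec, n_chan * taps, n_samp))
        for k in range(taps):
            X[:, k * n_chan:(k + 1) * n_chan, k:] = regressors[:, :, : n_samp - k]
    n_w = X.shape[1]
    w = np.full((n_rec, n_w), cfg.weight_init, dtype=float)
    resid = np.empty((n_rec, n_samp))
    power = np.full(n_rec, 1e-12)
    lam = cfg.power_smoothing
    mu = cfg.step_size
    eps = 1e-12
    for t in range(n_samp):
        xt = X[:, :, t]                      # (n_rec, n_w)
        yt = np.einsum("ij,ij->i", w, xt)    # prediction
        et = targets[:, t] - yt
        resid[:, t] = et
        if cfg.normalized:
            inst = np.einsum("ij,ij->i", xt, xt)
            power = lam * power + (1.0 - lam) * inst
            step = mu / (power + eps)
        else:
            step = mu
        w += (step * et)[:, None] * xt
    return resid


def lms_decorrelate(session: MerSession, config: LmsConfig | None = None
                    ) -> MerSession:
    """Remove the shared-reference component by adaptive linear prediction.

    For every (track, depth) record the target is that track and the
    regressors are the other tracks at the same depth; weights restart at
    ``weight_init`` for each depth record, so depths are processed
    independently.  The returned session holds the prediction residuals.
    """
    cfg = config or LmsConfig()
    cfg.validate()
    if len(session.track_labels) < 2:
        raise ValueError("lms_decorrelate needs at least 2 tracks")
    n = session.n_samples()
    tracks = session.track_labels
    depths = session.depths_mm

    stack = np.empty((len(tracks), len(depths), n))
    for ti, trk in enumerate(tracks):
        for di, d in enumerate(depths):
            rec = session.record(trk, d)
            if len(rec) != n:
                raise ValueError("all records must have equal length")
            if not np.all(np.isfinite(rec)):
                raise ValueError(f"non-finite input in record ({trk}, {d})")
            stack[ti, di] = rec

    residuals: dict[tuple[str, float], np.ndarray] = {}
    for ti, trk in enumerate(tracks):
        others = [j for j in range(len(tracks)) if j != ti]
        targets = stack[ti]                              # (n_depths, n)
        regressors = stack[others].transpose(1, 0, 2)    # (n_depths, n_chan, n)
        res = _lms_batch(targets, regressors, cfg)
        for di, d in enumerate(depths):
            residuals[(trk, float(d))] = res[di]

    return _dc_replace_session(session, residuals)


def _dc_replace_session(session: MerSession,
                        signals: dict[tuple[str, float], np.ndarray]) -> MerSession:
    return MerSession(
        session_id=session.session_id,
        track_labels=session.track_labels,
        depths_mm=session.depths_mm.copy(),
        fs=session.fs,
        signals=signals,
        channel_kind=session.channel_kind,
    )
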