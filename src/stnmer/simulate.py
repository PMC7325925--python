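"""Synthetic depth-stepped microelectrode (MER) sessions with ground truth.

The generator emulates the LFP structure an STN-DBS mapping pipeline relies
on: several parallel tracks descend in 0.5-1 mm steps from well above the
planned target to a few mm below it, recording >= 20 s per depth.  Outside the
subthalamic nucleus a record is 1/f background plus a common-reference
component shared across tracks (the cannula reference picks up the same
activity on every electrode, plus mains line interference).  Inside the STN
the record additionally carries a beta-band (11-32 Hz) oscillation and
high-frequency oscillations (HFO, 200-400 Hz) whose envelope is modulated by
the beta phase; the HFO band is slow (default 200-280 Hz) dorsally and fast
(default 280-400 Hz) ventrally.

All randomness flows from ``SimConfig.seed`` through the counter-based
splitting rule in :mod:`stnmer._seeding`: each (component, track, depth)
triple owns an independent substream, so e.g. changing an SNR parameter
rescales the oscillatory components without redrawing the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._seeding import substream
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MerSession",
    "simulate_session",
    "generate_pink_noise",
    "generate_pac_signal",
    "simulate_clinical_scores",
    "TRACK_LABEL_ORDER",
]

#: Canonical BenGun track-label order (center first).
TRACK_LABEL_ORDER = ("center", "anterior", "posterior", "lateral", "medial")

# substream component ids
_LOCAL, _COMMON, _LINE, _BETA, _HFO, _GAIN, _CLIN = range(7)

_LINE_FREQ_HZ = 60.0
_LINE_AMPLITUDE = 1.0
_TRACK_GAIN_JITTER = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated hemisphere descent.

    Geometry uses the intraoperative depth axis: mm above the planned target,
    positive superior, so the electrodes start at ``depth_start_mm`` (default
    15 mm above target) and stop at ``depth_stop_mm`` (default 5 mm below).
    ``stn_entry_mm``/``stn_exit_mm`` give the STN borders crossed by each
    track that intersects the nucleus (entry > exit on this axis).
    """

    n_tracks: int = 3
    track_labels: tuple[str, ...] = ("center", "anterior", "posterior")
    depth_start_mm: float = 15.0
    depth_step_mm: float = 0.5
    depth_stop_mm: float = -5.0
    record_duration_s: float = 20.0
    fs_raw: float = 30000.0
    fs_lfp: float = 2000.0
    noise_exponent: float = 1.0
    common_gain: float = 1.0
    beta_freq_hz: float = 20.0
    beta_snr_db: float = 6.0
    hfo_slow_band: tuple[float, float] = (200.0, 280.0)
    hfo_fast_band: tuple[float, float] = (280.0, 400.0)
    hfo_snr_db: float = 6.0
    pac_strength: float = 0.8
    stn_entry_mm: Mapping[str, float] = field(
        default_factory=lambda: {"center": 2.0, "anterior": 1.0, "posterior": 0.5}
    )
    stn_exit_mm: Mapping[str, float] = field(
        default_factory=lambda: {"center": -3.0, "anterior": -1.0, "posterior": -1.5}
    )
    dorsal_span_mm: float = 2.0
    best_track: str = "center"
    channel_kind: str = "lfp"
    supra_stn_hfo: bool = False
    seed: int = 0

    # bands used for SNR calibration (match the classifier's feature bands)
    beta_band_hz: tuple[float, float] = (11.0, 32.0)
    hfo_band_hz: tuple[float, float] = (200.0, 400.0)

    def validate(self) -> None:
        if self.n_tracks < 1 or len(self.track_labels) != self.n_tracks:
            raise ConfigurationError(
                "track_labels must name exactly n_tracks tracks "
                f"(n_tracks={self.n_tracks}, labels={self.track_labels})"
            )
        unknown = set(self.track_labels) - set(TRACK_LABEL_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown track labels {sorted(unknown)}")
        if not self.depth_start_mm > self.depth_stop_mm:
            raise ConfigurationError("depth_start_mm must exceed depth_stop_mm")
        if not (0.5 <= self.depth_step_mm <= 1.0):
            raise ConfigurationError("depth_step_mm must lie in [0.5, 1] mm")
        if not self.fs_lfp < self.fs_raw:
            raise ConfigurationError("fs_lfp must be below fs_raw")
        if not (11.0 <= self.beta_freq_hz <= 32.0):
            raise ConfigurationError("beta_freq_hz must lie in the 11-32 Hz beta band")
        if not (0.0 <= self.pac_strength <= 1.0):
            raise ConfigurationError("pac_strength must lie in [0, 1]")
        if self.best_track not in self.track_labels:
            raise ConfigurationError(
                f"best_track {self.best_track!r} not among track_labels"
            )
        if self.channel_kind not in ("lfp", "sua_wideband"):
            raise ConfigurationError("channel_kind must be 'lfp' or 'sua_wideband'")
        for trk in self.stn_entry_mm:
            if trk not in self.stn_exit_mm:
                raise ConfigurationError(f"track {trk!r} has entry but no exit depth")
            if not self.stn_exit_mm[trk] < self.stn_entry_mm[trk]:
                raise ConfigurationError(
                    f"track {trk!r}: stn_exit_mm must be below stn_entry_mm"
                )
        spans = self.stn_span_lengths()
        if self.best_track not in spans:
            raise ConfigurationError("best_track must intersect the STN")
        best_len = spans[self.best_track]
        for trk, length in spans.items():
            if trk != self.best_track and length >= best_len:
                raise ConfigurationError(
                    "best_track must have the strictly longest in-STN span "
                    f"({trk!r} span {length} mm >= {self.best_track!r} span {best_len} mm)"
                )

    def stn_span_lengths(self) -> dict[str, float]:
        """STN chord length (mm) per track that intersects the nucleus."""
        return {
            trk: self.stn_entry_mm[trk] - self.stn_exit_mm[trk]
            for trk in self.stn_entry_mm
            if trk in self.track_labels
        }

    def depths_mm(self) -> np.ndarray:
        """Descending depth grid from start to stop (inclusive)."""
        n_steps = int(round((self.depth_start_mm - self.depth_stop_mm) / self.depth_step_mm))
        return self.depth_start_mm - self.depth_step_mm * np.arange(n_steps + 1)

    @property
    def fs(self) -> float:
        return self.fs_lfp if self.channel_kind == "lfp" else self.fs_raw


@dataclass(frozen=True)
class GroundTruth:
    """Synthetic annotations matched to one session."""

    stn_entry_mm: Mapping[str, float]
    stn_exit_mm: Mapping[str, float]
    dorsal_ventral_boundary_mm: float
    best_track: str
    in_stn: Mapping[str, np.ndarray]  # track -> bool array over depths
    depths_mm: np.ndarray


@dataclass
class MerSession:
    """One hemisphere's depth-stepped recordings.

    ``signals`` maps ``(track_label, depth_mm)`` to the record at that site;
    ``depth_mm`` keys are exactly the floats in ``depths_mm``.
    """

    session_id: str
    track_labels: tuple[str, ...]
    depths_mm: np.ndarray
    fs: float
    signals: dict[tuple[str, float], np.ndarray]
    channel_kind: str = "lfp"

    def record(self, track: str, depth_mm: float) -> np.ndarray:
        return self.signals[(track, float(depth_mm))]

    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    def validate(self) -> None:
        n = self.n_samples()
        if np.any(np.diff(self.depths_mm) >= 0):
            raise ConfigurationError("depths_mm must be strictly decreasing")
        for trk in self.track_labels:
            for d in self.depths_mm:
                key = (trk, float(d))
                if key not in self.signals:
                    raise ConfigurationError(f"missing record for {key}")
                x = self.signals[key]
                if len(x) != n or not np.all(np.isfinite(x)):
                    raise ConfigurationError(f"bad record for {key}")


def in_stn_flag(depth_mm: float, entry_mm: float, exit_mm: float) -> bool:
    """In-STN membership: entry depth included, exit depth excluded."""
    return exit_mm < depth_mm <= entry_mm


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return substream(int(seed))


def generate_pink_noise(n_samples: int, exponent: float, seed) -> np.ndarray:
    """Zero-mean, unit-variance noise with power spectrum ~ 1/f**exponent.

    Synthesized in the frequency domain: each positive-frequency bin gets an
    independent complex-Gaussian coefficient scaled by ``k**(-exponent/2)``
    (DC forced to zero), then inverse-transformed and variance-normalized.
    ``exponent = 0`` reduces to white Gaussian noise.
    """
    n_samples = int(n_samples)
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = _as_rng(seed)
    n_bins = n_samples // 2 + 1
    k = np.arange(n_bins, dtype=float)
    amp = np.zeros(n_bins)
    amp[1:] = k[1:] ** (-exponent / 2.0)
    coef = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    coef[0] = 0.0
    if n_samples % 2 == 0:
        coef[-1] = coef[-1].real * np.sqrt(2.0)
    x = np.fft.irfft(coef * amp, n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _pink_band_fraction(n_samples: int, fs: float, exponent: float,
                        band: tuple[float, float]) -> float:
    """Expected fraction of pink-noise variance inside ``band`` (Hz)."""
    n_bins = n_samples // 2 + 1
    k = np.arange(1, n_bins, dtype=float)
    power = k ** (-exponent)
    freqs = k * fs / n_samples
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[sel].sum() / power.sum())


def band_limited_noise(n_samples: int, fs: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` (brick-wall in FFT)."""
    n_bins = n_samples // 2 + 1
    freqs = np.arange(n_bins) * fs / n_samples
    coef = np.zeros(n_bins, dtype=complex)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains no FFT bin at fs={fs}")
    coef[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    x = np.fft.irfft(coef, n_samples)
    x -= x.mean()
    x /= x.std()
    return x


def generate_pac_signal(phase_freq: float, amp_band: tuple[float, float],
                        strength: float, duration_s: float, fs: float,
                        seed) -> np.ndarray:
    """Phase-amplitude-coupled test signal.

    Band-limited carrier noise in ``amp_band`` whose instantaneous amplitude
    follows ``(1 + strength*cos(2*pi*phase_freq*t))/2`` times its baseline,
    summed with a unit cosine at ``phase_freq`` (the phase-providing rhythm).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    nyq = fs / 2.0
    if not (phase_freq < amp_band[0] < amp_band[1] < nyq):
        raise ValueError(
            f"amp_band {amp_band} must lie inside ({phase_freq}, {nyq}) Hz"
        )
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    theta = 2 * np.pi * phase_freq * t + phi0
    carrier = band_limited_noise(n, fs, amp_band, rng)
    envelope = (1.0 + strength * np.cos(theta)) / 2.0
    return carrier * envelope + np.cos(theta)


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def _record_components(cfg: SimConfig, track_idx: int, depth_idx: int,
                       depth_mm: float, gain: float,
                       in_stn: bool, hfo_band: tuple[float, float],
                       ) -> dict[str, np.ndarray]:
    """All additive components of one record, keyed by name."""
    fs = cfg.fs
    n = int(round(cfg.record_duration_s * fs))
    t = np.arange(n) / fs
    seed = cfg.seed

    local = generate_pink_noise(n, cfg.noise_exponent,
                                substream(seed, _LOCAL, track_idx, depth_idx))
    common_pink = generate_pink_noise(n, cfg.noise_exponent,
                                      substream(seed, _COMMON, depth_idx))
    line_phi = substream(seed, _LINE, depth_idx).uniform(0, 2 * np.pi)
    line = _LINE_AMPLITUDE * np.sin(2 * np.pi * _LINE_FREQ_HZ * t + line_phi)
    comps = {
        "local": local,
        "common": gain * (common_pink + line),
    }
    if not in_stn:
        return comps

    # background band power seen by the feature bands (local + common pink;
    # the 60 Hz line sits outside both bands)
    frac_beta = _pink_band_fraction(n, fs, cfg.noise_exponent, cfg.beta_band_hz)
    frac_hfo = _pink_band_fraction(n, fs, cfg.noise_exponent, cfg.hfo_band_hz)
    bg_var = 1.0 + gain ** 2

    beta_rng = substream(seed, _BETA, track_idx, depth_idx)
    phi_b = beta_rng.uniform(0, 2 * np.pi)
    theta = 2 * np.pi * cfg.beta_freq_hz * t + phi_b
    r_beta = 10.0 ** (cfg.beta_snr_db / 10.0)
    beta_amp = np.sqrt(2.0 * (r_beta - 1.0) * frac_beta * bg_var)
    comps["beta"] = beta_amp * np.cos(theta)

    hfo_rng = substream(seed, _HFO, track_idx, depth_idx)
    carrier = band_limited_noise(n, fs, hfo_band, hfo_rng)
    modulated = carrier * (1.0 + cfg.pac_strength * np.cos(theta)) / 2.0
    r_hfo = 10.0 ** (cfg.hfo_snr_db / 10.0)
    target_var = (r_hfo - 1.0) * frac_hfo * bg_var
    sd = modulated.std()
    if sd > 0 and target_var > 0:
        modulated *= np.sqrt(target_var) / sd
    else:
        modulated[:] = 0.0
    comps["hfo"] = modulated
    return comps


def simulate_session(config: SimConfig) -> tuple[MerSession, GroundTruth]:
    """Generate one seeded MER session plus its ground truth.

    Deterministic given ``config.seed``.  Out-of-STN records contain 1/f
    background and the shared-reference component only; in-STN records add a
    beta oscillation and a beta-phase-modulated HFO whose band is slow above
    the track's dorsal/ventral boundary and fast below it.
    """
    config.validate()
    depths = config.depths_mm()
    fs = config.fs
    gain_rng = substream(config.seed, _GAIN)
    gains = config.common_gain * (
        1.0 + _TRACK_GAIN_JITTER * gain_rng.standard_normal(config.n_tracks)
    )

    signals: dict[tuple[str, float], np.ndarray] = {}
    in_stn_map: dict[str, np.ndarray] = {}
    for ti, trk in enumerate(config.track_labels):
        entry = config.stn_entry_mm.get(trk)
        exit_ = config.stn_exit_mm.get(trk)
        boundary = entry - config.dorsal_span_mm if entry is not None else None
        flags = np.zeros(len(depths), dtype=bool)
        for di, d in enumerate(depths):
            inside = entry is not None and in_stn_flag(d, entry, exit_)
            flags[di] = inside
            band = (
                config.hfo_slow_band
                if inside and d > boundary
                else config.hfo_fast_band
            )
            comps = _record_components(config, ti, di, d, gains[ti], inside, band)
            signals[(trk, float(d))] = sum(comps.values())
        in_stn_map[trk] = flags

    session = MerSession(
        session_id=f"sim-{config.seed:08d}",
        track_labels=tuple(config.track_labels),
        depths_mm=depths,
        fs=fs,
        signals=signals,
        channel_kind=config.channel_kind,
    )
    best_entry = config.stn_entry_mm[config.best_track]
    truth = GroundTruth(
        stn_entry_mm={t: config.stn_entry_mm[t] for t in config.track_labels
                      if t in config.stn_entry_mm},
        stn_exit_mm={t: config.stn_exit_mm[t] for t in config.track_labels
                     if t in config.stn_exit_mm},
        dorsal_ventral_boundary_mm=best_entry - config.dorsal_span_mm,
        best_track=config.best_track,
        in_stn=in_stn_map,
        depths_mm=depths,
    )
    return session, truth


def simulate_clinical_scores(n_hemispheres: int, effect: float,
                             dispersion: float, seed: int,
                             off_mean: float = 16.3,
                             max_score: int = 72) -> list[tuple[int, int]]:
    """Paired OFF/ON contralateral motor scores for ``n_hemispheres``.

    OFF scores are Poisson(``off_mean``) integers clipped to [1, max_score]
    (MDS-UPDRS-III item sums are small non-negative integers; the default
    mean matches a moderately affected hemibody).  Each hemisphere's
    fractional improvement is drawn as Normal(``effect``, ``dispersion``)
    clipped to [0, 1], so the expected relative improvement (off-on)/off is
    ``effect`` up to integer rounding.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    if n_hemispheres < 0:
        raise ValueError("n_hemispheres must be non-negative")
    if n_hemispheres == 0:
        return []
    rng = substream(seed, _CLIN)
    off = np.clip(rng.poisson(off_mean, n_hemispheres), 1, max_score)
    frac = np.clip(rng.normal(effect, dispersion, n_hemispheres), 0.0, 1.0)
    on = np.clip(np.rint(off * (1.0 - frac)), 0, max_score).astype(int)
    return list(zip(off.astype(int).tolist(), on.tolist()))


def config_for_seed(seed: int, **overrides) -> SimConfig:
    """Default configuration rebased on ``seed`` (convenience for batches)."""
    return replace(SimConfig(), seed=int(seed), **overrides)
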