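"""Median-Welch spectra and baseline-normalized depth-frequency maps (DFMs).

A DFM is the depth-varying power spectrum of one track's LFPs: one
median-Welch spectrum per depth, stacked with the most superior depth first.
Maps of all tracks in a hemisphere are normalized by a SINGLE baseline — the
mean spectrum of the most superior depths pooled across tracks (assumed to
lie in white matter) — and expressed in dB, so power is directly comparable
between tracks.  The per-depth MEDIAN across Welch segments (rather than the
mean) suppresses localized artifacts such as movement or stimulation
transients confined to a few segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectrumEstimate",
    "DepthFrequencyMap",
    "welch_median_spectrum",
    "build_dfm",
    "normalize_dfm",
    "region_average",
    "DEFAULT_REGIONS",
]

#: Border-relative spatial regions (mm): interval (low, high]; the border
#: (re-referenced depth 0) belongs to `dorsal`, -2 belongs to `ventral`.
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "above": (0.0, 5.0),
    "dorsal": (-2.0, 0.0),
    "ventral": (-5.0, -2.0),
}


@dataclass(frozen=True)
class SpectrumEstimate:
    freqs_hz: np.ndarray
    power: np.ndarray  # linear PSD units (x**2 / Hz)
    n_segments: int


@dataclass
class DepthFrequencyMap:
    track: str
    depths_mm: np.ndarray        # descending
    freqs_hz: np.ndarray
    values: np.ndarray           # (n_depths, n_freqs)
    scale: str = "linear"        # or "log_normalized_db"
    baseline_depths_mm: np.ndarray | None = None

    def row(self, depth_mm: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.depths_mm - depth_mm)))
        return self.values[idx]


def _segment_periodograms(x: np.ndarray, fs: float, window_s: float,
                          overlap: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD periodograms of Hamming-tapered, mean-removed segments."""
    nper = int(round(window_s * fs))
    step = int(round(nper * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large")
    n = len(x)
    if n < nper + step:
        raise ValueError(
            f"signal too short: need at least {nper + step} samples "
            f"(2 segments of {nper} at {overlap:.0%} overlap), got {n}"
        )
    win = sps.get_window("hamming", nper)
    scale = 1.0 / (fs * np.sum(win ** 2))
    n_seg = (n - nper) // step + 1
    idx = np.arange(nper)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs * win, axis=1)) ** 2 * scale
    spec[:, 1:] *= 2.0
    if nper % 2 == 0:
        spec[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, spec


def welch_median_spectrum(x: np.ndarray, fs: float, window_s: float = 1.0,
                          overlap: float = 0.5) -> SpectrumEstimate:
    """Welch estimate with pointwise median across segments.

    Segments of ``window_s`` seconds (default 1 s, giving 1 Hz resolution)
    with 50% overlap are Hamming-tapered and mean-removed; the returned power
    at each frequency bin is the raw median across segment periodograms.  For
    stationary input the median tracks the mean; a short large-amplitude
    artifact moves only the segments it touches and leaves the median nearly
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    freqs, spec = _segment_periodograms(x, fs, window_s, overlap)
    return SpectrumEstimate(freqs_hz=freqs,
                            power=np.median(spec, axis=0),
                            n_segments=spec.shape[0])


def welch_mean_spectrum(x: np.ndarray, fs: float, window_s: float = 1.0,
                        overlap: float = 0.5) -> SpectrumEstimate:
    """Conventional (mean-averaged) Welch estimate with the same conventions."""
    x = np.asarray(x, dtype=float)
    freqs, spec = _segment_periodograms(x, fs, window_s, overlap)
    return SpectrumEstimate(freqs_hz=freqs,
                            power=spec.mean(axis=0),
                            n_segments=spec.shape[0])


def build_dfm(spectra: list[tuple[float, SpectrumEstimate]], track: str,
              max_freq_hz: float | None = 500.0) -> DepthFrequencyMap:
    """Stack per-depth spectra into a linear-scale depth-frequency map.

    ``spectra`` holds (depth_mm, estimate) pairs in any order; rows are
    sorted most-superior first.  The frequency axis is capped at
    ``max_freq_hz`` (default 500 Hz, comfortably covering the 200-400 Hz HFO
    band); pass ``None`` to keep the full Nyquist range.
    """
    if not spectra:
        raise ValueError("no spectra given")
    ref = spectra[0][1].freqs_hz
    for _, est in spectra[1:]:
        if len(est.freqs_hz) != len(ref) or not np.allclose(est.freqs_hz, ref):
            raise ValueError("all spectra must share the same frequency axis")
    order = np.argsort([-d for d, _ in spectra])
    depths = np.array([spectra[i][0] for i in order], dtype=float)
    values = np.vstack([spectra[i][1].power for i in order])
    freqs = ref
    if max_freq_hz is not None:
        keep = freqs <= max_freq_hz
        freqs, values = freqs[keep], values[:, keep]
    return DepthFrequencyMap(track=track, depths_mm=depths,
                             freqs_hz=freqs, values=values, scale="linear")


def normalize_dfm(maps: list[DepthFrequencyMap], n_baseline_depths: int = 3
                  ) -> list[DepthFrequencyMap]:
    """Normalize a hemisphere's linear DFMs to a common white-matter baseline.

    The baseline at each frequency is the mean linear power over the
    ``n_baseline_depths`` most superior depths of ALL tracks pooled — not a
    per-track baseline — so that between-track power differences survive
    normalization.  Output values are ``10*log10(power/baseline)`` dB.
    """
    if n_baseline_depths < 1:
        raise ValueError("n_baseline_depths must be >= 1")
    ref = maps[0]
    for m in maps[1:]:
        if not (np.allclose(m.depths_mm, ref.depths_mm)
                and np.allclose(m.freqs_hz, ref.freqs_hz)):
            raise ValueError("all tracks must share depth and frequency axes")
    if any(m.scale != "linear" for m in maps):
        raise ValueError("normalize_dfm expects linear-scale maps")
    baseline_rows = np.vstack([m.values[:n_baseline_depths] for m in maps])
    baseline = baseline_rows.mean(axis=0)
    if np.any(baseline <= 0):
        raise ValueError("degenerate input: zero baseline power at some bin")
    out = []
    for m in maps:
        vals = 10.0 * np.log10(m.values / baseline)
        out.append(replace(
            m, values=vals, scale="log_normalized_db",
            baseline_depths_mm=ref.depths_mm[:n_baseline_depths].copy()))
    return out


def region_average(dfm: DepthFrequencyMap, border_mm: float,
                   regions: dict[str, tuple[float, float]] | None = None
                   ) -> dict[str, np.ndarray | None]:
    """Mean spectrum per border-relative spatial region.

    Depths are re-referenced so the dorsal STN border is 0 mm; each region
    ``(low, high]`` collects the rows whose re-referenced depth satisfies
    ``low < d <= high`` and returns their mean spectrum.  An empty region
    maps to ``None`` (flagged missing, not an error).
    """
    regions = DEFAULT_REGIONS if regions is None else regions
    rel = dfm.depths_mm - border_mm
    out: dict[str, np.ndarray | None] = {}
    for name, (lo, hi) in regions.items():
        sel = (rel > lo) & (rel <= hi)
        out[name] = dfm.values[sel].mean(axis=0) if sel.any() else None
    return out


def region_rows(depths_mm: np.ndarray, border_mm: float,
                region: tuple[float, float]) -> np.ndarray:
    """Boolean row mask for one border-relative region (same rule as above)."""
    rel = np.asarray(depths_mm, dtype=float) - border_mm
    lo, hi = region
    return (rel > lo) & (rel <= hi)
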