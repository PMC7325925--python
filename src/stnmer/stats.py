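"""Statistical tests and clinical-outcome summaries.

Distributions are screened with the Anderson-Darling normality test (both
parameters estimated); paired contrasts — OFF vs ON clinical scores, and
selected-track vs other-track band powers or coupling strengths — use the
non-parametric Wilcoxon signed-rank test.  The exact null distribution is
used up to n = 25 informative pairs (rank-sum convolution, equivalent to
enumerating all 2^n sign assignments, with midranked ties); a normal
approximation with tie and continuity corrections is used above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "PairedSamples",
    "ClinicalRecord",
    "anderson_darling_normality",
    "wilcoxon_signed_rank",
    "improvement_pct",
    "contrast_selected_vs_other",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedSamples:
    x: np.ndarray
    y: np.ndarray
    unit: str = ""

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
            raise ValueError("x and y must be equal-length vectors (n >= 1)")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class ClinicalRecord:
    hemisphere_id: str
    off_score: float
    on_score: float

    @property
    def improvement_pct(self) -> float:
        return improvement_pct(self.off_score, self.on_score)


def anderson_darling_normality(sample) -> tuple[float, float]:
    """Anderson-Darling test of composite normality.

    Returns ``(A2, p)`` where ``A2`` is the uncorrected statistic (mean and
    variance estimated from the sample) and ``p`` comes from the standard
    approximation for that case after the small-sample correction
    ``A2* = A2 * (1 + 0.75/n + 2.25/n^2)``.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = np.clip(spstats.norm.cdf(z), 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1)
                            * (np.log(cdf) + np.log1p(-cdf[::-1]))))
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
    elif a2s > 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s ** 2)
    elif a2s > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s ** 2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s ** 2)
    return a2, float(min(max(p, 0.0), 1.0))


def _exact_signed_rank_p(ranks: np.ndarray, signs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p and W by convolution over the signed-rank null.

    ``ranks`` are midranks of |d|; doubling them makes every achievable sum
    an integer, and the distribution of W (sum of positive ranks) under
    random signs is the convolution of n two-point distributions — identical
    to enumerating all 2^n sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    w2 = int(np.sum(r2[signs > 0]))
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = 0.5 * (counts + shifted)
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w2 / 2.0, p


def wilcoxon_signed_rank(pairs: PairedSamples,
                         alternative: str = "two-sided",
                         zero_method: str = "wilcox") -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns ``(W, p)``.

    W is the sum of ranks of positive differences (x - y).  Zero differences
    are dropped (``zero_method='wilcox'``, the default discard rule) or kept
    and signed-ranked as zeros (``'pratt'``); ties are midranked.  Exact p by
    enumeration for up to 25 informative pairs, normal approximation with tie
    and continuity corrections above.
    """
    if alternative != "two-sided":
        raise NotImplementedError("only the two-sided alternative is provided")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    d = pairs.x - pairs.y
    if np.all(d == 0):
        raise ValueError("no informative pairs: all differences are zero")
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = spstats.rankdata(np.abs(d))
    else:
        ranks = spstats.rankdata(np.abs(d))
        ranks = ranks[d != 0]
        d = d[d != 0]
    n = len(d)
    signs = np.sign(d)
    if n <= _EXACT_N_MAX:
        return _exact_signed_rank_p(ranks, signs)
    w = float(ranks[signs > 0].sum())
    mean = ranks.sum() / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0  # midranks absorb the tie correction
    cc = 0.5 * np.sign(w - mean)
    z = (w - mean - cc) / np.sqrt(var)
    p = 2.0 * spstats.norm.sf(abs(z))
    return w, float(min(p, 1.0))


def improvement_pct(off: float, on: float) -> float:
    """Relative clinical improvement, ``100*(off - on)/off`` percent."""
    if off <= 0:
        raise ValueError("off score must be positive")
    return 100.0 * (off - on) / off


def contrast_selected_vs_other(values: pd.DataFrame,
                               pairing: str = "mean",
                               min_n_warn: int = 6) -> pd.DataFrame:
    """Paired selected-track vs other-track contrasts per region and band.

    ``values`` must have columns ``stn_id, region, band, track_role, value``
    where ``track_role`` is ``selected`` or ``other`` (several ``other`` rows
    per STN are allowed).  Per STN the other tracks are collapsed to their
    mean (``pairing='mean'``, default) before the paired Wilcoxon test; with
    ``pairing='per_track'`` each other track is paired with the same
    selected value.  Returns one row per (region, band) with columns
    ``region, band, n, W, p``.
    """
    required = {"stn_id", "region", "band", "track_role", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    rows = []
    for (region, band), grp in values.groupby(["region", "band"], sort=True):
        sel = grp[grp.track_role == "selected"].set_index("stn_id")["value"]
        oth = grp[grp.track_role == "other"]
        if pairing == "mean":
            oth_v = oth.groupby("stn_id")["value"].mean()
            ids = sel.index.intersection(oth_v.index)
            x, y = sel.loc[ids].to_numpy(), oth_v.loc[ids].to_numpy()
        elif pairing == "per_track":
            ids = oth["stn_id"]
            x = sel.loc[ids].to_numpy()
            y = oth["value"].to_numpy()
        else:
            raise ValueError("pairing must be 'mean' or 'per_track'")
        n = len(x)
        if n < min_n_warn:
            warnings.warn(
                f"only {n} STNs for ({region}, {band}); exact test still "
                "computed", stacklevel=2)
        w, p = wilcoxon_signed_rank(PairedSamples(x, y))
        rows.append({"region": region, "band": band, "n": n, "W": w, "p": p})
    return pd.DataFrame(rows)
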