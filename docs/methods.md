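# Methods

## The localization problem

During bilateral STN-DBS implantation, up to five parallel microelectrodes
(2 mm apart in a BenGun holder; three used here) descend from ≥ 15 mm above
the stereotactic target in 0.5–1 mm steps, pausing ≥ 20 s per depth.
Acquisition is modeled at 30 kHz with LFPs analyzed at 2 kHz. The task is to
decide, per track and depth, whether the electrode is inside the STN, and to
pick the track whose in-STN traversal is longest — the implantation site.
The package implements that decision chain for LFPs, plus the postoperative
coupling and outcome analyses, driven end-to-end by a synthetic generator.

## Synthetic sessions

Each (track, depth) record is a sum of independent components:

* **Local background**: 1/f^α noise, α = 1 by default, unit variance —
  synthesized in the frequency domain and variance-normalized.
* **Common reference**: one per-depth 1/f process plus a 60 Hz mains
  sinusoid (amplitude 1), added to every track with per-track gain
  `common_gain × (1 + 0.05 z)`, z standard normal per track. This emulates
  the cannula reference contaminating all tracks simultaneously, which is
  what the LMS stage removes.
* **In-STN oscillations** (only between a track's STN entry and exit): a
  beta cosine at `beta_freq_hz` (20 Hz) with random phase, scaled so the
  11–32 Hz band power sits `beta_snr_db` (6 dB) above the record's
  background in that band, and a band-limited HFO carrier whose envelope is
  `(1 + pac_strength·cos θ_beta)/2` (pac_strength 0.8), scaled for a
  `hfo_snr_db` (6 dB) elevation of 200–400 Hz band power. The HFO band is
  slow (200–280 Hz) above the track's dorsal/ventral boundary
  (entry − 2 mm) and fast (280–400 Hz) below it.

Default geometry: center track crosses the STN from +2 to −3 mm (5 mm
chord), anterior +1 to −1, posterior +0.5 to −1.5, so the center track is
the correct choice by the longest-span rule. In-STN membership is
entry-inclusive and exit-exclusive (the entry depth itself already shows the
power increase). A record's SNR calibration uses the analytic band fraction
of the synthesized noise spectrum, so the programmed elevations are exact in
expectation; a Welch-based test verifies them empirically.

All randomness flows from one integer seed through `SeedSequence` keyed by
(component, track, depth). Consequences: identical configs reproduce
bit-identical sessions, and changing an SNR parameter rescales oscillations
without redrawing noise — which is what makes selection-rate-vs-SNR ladders
monotone per seed.

**What the generator does not emulate**: nonstationary beta bursting,
spike waveforms (the optional wideband channel is background-only),
depth-varying noise floors, electrode drift, movement artifacts beyond what
the median spectrum is tested with, or supra-STN HFOs (a config flag exists
but is off by default; no parametric description is available). Passing
tests therefore demonstrate internal consistency of the pipeline under its
stated signal model, not clinical performance.

Clinical scores are Poisson-like integers: OFF ~ Poisson(16.3) clipped to
[1, 72] (an MDS-UPDRS-III contralateral item sum for a moderately affected
hemibody), and ON = OFF × (1 − δ) rounded, with per-hemisphere improvement
δ ~ Normal(effect, dispersion) clipped to [0, 1].

## Preprocessing

* `downsample_lfp`: zero-phase FIR low-pass at 0.45·fs_out, then index
  decimation (integer ratios only). Forward-backward filtering avoids group
  delay, which would misalign tracks; stopband ≥ 40 dB above the output
  Nyquist.
* `sua_highpass`: second-order Butterworth high-pass at 300 Hz (causal),
  the standard spiking-band front end.
* `lms_decorrelate`: per record, target = one track, regressors = the other
  tracks at the same depth; default one instantaneous tap per regressor
  (the shared reference has no relative delay), NLMS normalization of the
  step by a running regressor-power estimate (forgetting factor 0.99,
  step 0.01), weights restarting at every depth so nonstationarity cannot
  leak across depths. The first 1 s of each residual is excluded from
  spectral estimation as adaptation transient (configurable). Raw
  steepest-descent (un-normalized) updates and multi-tap regressors are
  available via `LmsConfig`.

## Spectra and maps

Median-Welch: 1 s Hamming segments, 50% overlap, per-segment mean removal,
one-sided density-scaled periodograms, pointwise median across segments.
The median, not the mean, makes single-segment artifacts (a 100× burst in
one second) move the estimate by < 5%; for stationary input it tracks the
mean within 1%. Density scaling with window-energy correction makes the
Parseval check well-defined; that check (band sum ≈ variance within 5%) is
stated for the mean estimator — the median of few chi-squared-distributed
segments is biased low by a known constant and is used for *relative* maps,
where the bias cancels in normalization.

Maps are normalized by the mean linear power of the `n_baseline_depths = 3`
most superior depths pooled across **all** tracks ("highest depths" in white
matter), per frequency bin, and expressed as 10·log10 ratios. Pooling across
tracks is essential: per-track baselines would erase exactly the
between-track power differences the selection relies on. The frequency axis
is capped at 500 Hz by default (HFO band plus margin). Border-relative
region averages use intervals above (0, 5], dorsal (−2, 0], ventral
(−5, −2] mm re-referenced to the dorsal border, with empty regions flagged
as missing rather than erroring.

## Classification and selection

Features are the mean of normalized dB values over beta (11–32 Hz) and HFO
(200–400 Hz) bins (mean-of-dB chosen over linear-power mean for robustness
to single-bin spikes; configurable), min-max normalized per hemisphere
pooling tracks × depths. The discriminant is closed-form pooled-covariance
LDA (weights ∝ Σ⁻¹(μ_in − μ_out), bias at the prior-weighted midpoint,
ridge fallback for singular covariance). The shipped default model
(`data/default_lda.json`) is trained on 12 seeded synthetic sessions
(seeds 1000–1011, default conditions) with ground-truth labels; provenance
is stored in `training_meta`. Min-max normalization makes the model
transferable across sessions with different absolute power.

A depth with decision distance exactly 0 votes **out**-STN — conservative
toward not declaring the nucleus. "Longest span" is the longest contiguous
run of in-STN votes, measured in mm (first-to-last depth plus one local
step, so a single vote counts one step and variable step sizes keep their
metric length); total vote count is an alternative criterion. Ties break by
larger mean decision distance over the winning span, then canonical track
order (center first). If no depth votes in-STN, the decision is "STN not
found" rather than an arbitrary track.

## Cross-frequency coupling

The coupling statistic is the phase-locking value between the beta-band
phase and the phase of the band-passed HFO envelope (both phases from the
analytic signal). The mean-vector-length statistic is deliberately not
used: PLV is amplitude-invariant, which decouples the coupling measure from
the band-power features the classifier already uses. Filters are
linear-phase FIR applied forward-backward; the order is
max(3 cycles of the band's low edge, 3.3·fs/bandwidth) — the second term
guarantees ≥ 40 dB attenuation one bandwidth outside the passband, which
three cycles alone cannot deliver for the 3 Hz phase bands. One filter
length per involved filter is trimmed at each record edge.

The default comodulogram grid is phase 6–40 Hz (1 Hz steps, 3 Hz bandwidth)
× amplitude 150–450 Hz (10 Hz steps, 50 Hz bandwidth) — 35 × 31 cells. Grid
evaluation uses a spectral-domain shortcut (multiplying the record's FFT by
the squared FIR magnitude response, the circular equivalent of
forward-backward filtering); a test pins it to the direct
filtfilt-plus-Hilbert path within 0.01 PLV. Region-level coupling processes
each depth separately and averages PLVs — concatenating records across
depths would fabricate phase jumps at the seams. Batch contrasts use a
coarse grid (phase 12–32 Hz step 4, amplitude 160–440 Hz step 40, same
bandwidths) to keep a 19-STN analysis in minutes; the full grid yields the
same contrasts at ~30× the cost.

Note one resolution limit: with 50 Hz-wide analysis bands and a 50 Hz-wide
coupled carrier, the PLV is near-ceiling on a plateau of adjacent amplitude
cells (PLV is amplitude-invariant, so partial band overlap suffices for
locking). Peak localization to one grid step therefore requires background
noise (which grades the plateau by carrier-to-noise ratio) and benefits
from averaging PLV maps over records, exactly as the region analysis does.

## Statistics

* Anderson–Darling composite normality: statistic from the sorted-CDF
  formula (mean and variance estimated), small-sample correction
  A²(1 + 0.75/n + 2.25/n²), and the standard four-branch p approximation.
* Wilcoxon signed rank: zeros dropped (Pratt's method optional), midranked
  ties, and an exact two-sided p for ≤ 25 informative pairs computed by
  convolving the signed-rank null — identical to enumerating all 2ⁿ sign
  assignments, verified against literal enumeration. Above 25, normal
  approximation with tie and continuity corrections.
* Group contrasts pair the selected track's value with the **mean** of the
  other tracks per STN (per-track pairing optional), per region × band. No
  multiple-testing correction is applied by default (contrasts are reported
  at stated α); the empirical type-I error of the full chain is checked
  under an exchangeable-tracks null with a-priori selection labels — with
  data-driven selection on the *same* features the contrast would be
  circular, which is why the batch analyses take the selection from an
  independent pipeline run and the null check fixes labels a priori.
* Group improvement is the mean of per-hemisphere percentages
  (mean-of-ratios, not ratio-of-means).

## Problem sizes

Defaults were chosen once as the analysis scale of this package: recovery
rate over 50 seeded default sessions, SNR ladders over 12 sessions × 3
rungs on a shortened descent (5 to −5 mm, 10 s records — same signal
structure, smaller grid), group contrasts over 19 STNs, 200 surrogate
records for coupling nulls, and 200 batches for the contrast-level check.

## Known limitations

* The LDA is trained on synthetic labels; no claim transfers to patient
  recordings without retraining on labeled clinical data.
* The generator's beta rhythm is a stationary sinusoid; estimators that
  exploit burstiness are neither represented nor testable here.
* The common-reference model is additive and instantaneous; reference
  artifacts with track-dependent delays would need multi-tap LMS
  (supported, untested against such data).
* Exact Wilcoxon p-values assume exchangeable signs under H0; heavily
  discretized scores with many zeros lose power under the default discard
  rule.
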