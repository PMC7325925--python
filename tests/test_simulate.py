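"""Synthetic MER session generator: determinism, spectra, and calibration."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnmer import (ConfigurationError, SimConfig, generate_pac_signal,
                    generate_pink_noise, plv_pac, simulate_clinical_scores,
                    simulate_session)
from stnmer.simulate import _record_components, in_stn_flag
from stnmer.spectral import welch_mean_spectrum

FS = 2000.0


def band_power(x, fs, band):
    est = welch_mean_spectrum(x, fs)
    sel = (est.freqs_hz >= band[0]) & (est.freqs_hz <= band[1])
    return est.power[sel].sum()


# ---------------------------------------------------------------------------
# pink noise
# ---------------------------------------------------------------------------

def test_white_noise_is_uncorrelated():
    n = 2 ** 14
    x = generate_pink_noise(n, 0.0, 1)
    for lag in (1, 2, 5):
        r = np.corrcoef(x[:-lag], x[lag:])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)


def test_pink_noise_spectral_slope():
    # periodogram regression oracle: log-log slope of binned power vs freq
    n = 2 ** 16
    x = generate_pink_noise(n, 1.0, 2)
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(n)
    edges = np.logspace(np.log10(4 / n), np.log10(0.4), 25)
    logf, logp = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f >= lo) & (f < hi)
        if sel.sum() >= 2:
            logf.append(np.log10(f[sel].mean()))
            logp.append(np.log10(p[sel].mean()))
    slope = np.polyfit(logf, logp, 1)[0]
    assert -1.2 <= slope <= -0.8
    assert abs(x.mean()) < 1e-12


def test_pink_noise_determinism_and_errors():
    a = generate_pink_noise(4096, 1.0, 42)
    b = generate_pink_noise(4096, 1.0, 42)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        generate_pink_noise(1, 1.0, 0)


# ---------------------------------------------------------------------------
# PAC generator
# ---------------------------------------------------------------------------

def test_pac_signal_plv_tracks_strength():
    x0 = generate_pac_signal(20.0, (225.0, 275.0), 0.0, 20.0, FS, 3)
    x1 = generate_pac_signal(20.0, (225.0, 275.0), 1.0, 20.0, FS, 3)
    assert plv_pac(x0, FS, 20.0, 3.0, 250.0, 50.0) < 0.15
    assert plv_pac(x1, FS, 20.0, 3.0, 250.0, 50.0) >= 0.9


def test_pac_signal_plv_stable_in_duration():
    v = [plv_pac(generate_pac_signal(20.0, (225.0, 275.0), 0.7, dur, FS, 5),
                 FS, 20.0, 3.0, 250.0, 50.0) for dur in (20.0, 40.0)]
    assert abs(v[0] - v[1]) < 0.05


def test_pac_signal_band_errors():
    with pytest.raises(ValueError):
        generate_pac_signal(20.0, (900.0, 1100.0), 1.0, 5.0, FS, 0)
    with pytest.raises(ValueError):
        generate_pac_signal(20.0, (225.0, 275.0), 1.5, 5.0, FS, 0)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def test_session_determinism(small_config):
    cfg = replace(small_config, record_duration_s=2.0)
    s1, g1 = simulate_session(cfg)
    s2, g2 = simulate_session(cfg)
    assert s1.session_id == s2.session_id
    for key in s1.signals:
        np.testing.assert_array_equal(s1.signals[key], s2.signals[key])
    assert g1.best_track == g2.best_track


@pytest.mark.parametrize("bad, fragment", [
    (dict(depth_start_mm=-6.0), "depth_start_mm"),
    (dict(fs_lfp=40000.0), "fs_lfp"),
    (dict(pac_strength=1.5), "pac_strength"),
    (dict(best_track="medial"), "best_track"),
    (dict(stn_exit_mm={"center": 3.0, "anterior": -1.0, "posterior": -1.5}),
     "stn_exit_mm"),
    (dict(depth_step_mm=0.2), "depth_step_mm"),
])
def test_invalid_config_names_violated_invariant(bad, fragment):
    with pytest.raises(ConfigurationError, match=fragment):
        simulate_session(SimConfig(**bad))


def test_in_stn_interval_is_entry_inclusive():
    assert in_stn_flag(2.0, 2.0, -3.0)       # entry depth is inside
    assert not in_stn_flag(-3.0, 2.0, -3.0)  # exit depth is outside
    assert in_stn_flag(0.0, 2.0, -3.0)


def test_ground_truth_consistency(small_session):
    session, truth = small_session
    assert truth.best_track == "center"
    for trk, flags in truth.in_stn.items():
        entry, exit_ = truth.stn_entry_mm[trk], truth.stn_exit_mm[trk]
        expect = np.array([in_stn_flag(d, entry, exit_)
                           for d in session.depths_mm])
        np.testing.assert_array_equal(flags, expect)
    e = truth.stn_entry_mm[truth.best_track]
    x = truth.stn_exit_mm[truth.best_track]
    assert x < truth.dorsal_ventral_boundary_mm < e
    session.validate()


def test_power_conservation_of_components(small_config):
    # single records fluctuate (1/f noise has few low-frequency cycles per
    # record), so the independence check is averaged over records
    ratios = []
    for di in range(8):
        comps = _record_components(small_config, 0, di, 0.0, gain=1.0,
                                   in_stn=True, hfo_band=(200.0, 280.0))
        total = sum(comps.values())
        var_sum = sum(np.var(c) for c in comps.values())
        ratios.append(np.var(total) / var_sum - 1.0)
    assert abs(np.mean(ratios)) < 0.05


def _snr_probe_config(seed, **kw):
    return SimConfig(depth_start_mm=4.0, depth_stop_mm=-4.0,
                     depth_step_mm=1.0, record_duration_s=8.0,
                     seed=seed, **kw)


def test_zero_snr_gives_flat_depth_profile():
    """With no oscillatory injection, in- and out-STN band power agree."""
    diffs = []
    for seed in range(20):
        cfg = _snr_probe_config(seed, beta_snr_db=0.0, hfo_snr_db=0.0,
                                pac_strength=0.0)
        session, truth = simulate_session(cfg)
        for trk in session.track_labels:
            flags = truth.in_stn[trk]
            p_in = np.mean([band_power(session.record(trk, d), FS, (11, 32))
                            for d in session.depths_mm[flags]])
            p_out = np.mean([band_power(session.record(trk, d), FS, (11, 32))
                             for d in session.depths_mm[~flags]])
            diffs.append(10 * np.log10(p_in / p_out))
    assert abs(np.mean(diffs)) < 1.0


def test_default_snr_elevation_matches_calibration():
    """In-STN beta band power exceeds out-STN by >= beta_snr_db - 2 dB."""
    diffs = []
    for seed in range(3):
        cfg = _snr_probe_config(seed)
        session, truth = simulate_session(cfg)
        for trk in session.track_labels:
            flags = truth.in_stn[trk]
            p_in = np.mean([band_power(session.record(trk, d), FS, (11, 32))
                            for d in session.depths_mm[flags]])
            p_out = np.mean([band_power(session.record(trk, d), FS, (11, 32))
                             for d in session.depths_mm[~flags]])
            diffs.append(10 * np.log10(p_in / p_out))
    assert np.mean(diffs) >= SimConfig().beta_snr_db - 2.0


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def test_clinical_scores_trivial_cases():
    assert simulate_clinical_scores(0, 0.5, 0.1, 0) == []
    pairs = simulate_clinical_scores(50, 0.0, 0.0, 1)
    assert all(off == on for off, on in pairs)
    with pytest.raises(ValueError):
        simulate_clinical_scores(5, 1.2, 0.1, 0)


def test_clinical_scores_mean_improvement():
    pairs = simulate_clinical_scores(200, 0.5, 0.1, 2)
    imp = [(off - on) / off for off, on in pairs]
    assert 0.45 <= np.mean(imp) <= 0.55


@settings(max_examples=25, derandomize=True, deadline=None)
@given(effect=st.floats(0.0, 1.0), seed=st.integers(0, 1000))
def test_clinical_scores_always_valid(effect, seed):
    for off, on in simulate_clinical_scores(10, effect, 0.2, seed):
        assert 1 <= off <= 72
        assert 0 <= on <= off
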