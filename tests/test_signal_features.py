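"""Feature-extraction tests: closed forms, oracles, and recovery from generators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imvest.signal_features import (
    BLOCKS,
    VARIABLES,
    NNSeries,
    RawSignal,
    build_feature_table,
    clean_nn,
    decimate_signal,
    detect_r_peaks,
    extract_block_features,
    hrv_entropy,
    hrv_geometric,
    hrv_prsa,
    hrv_spectral,
    hrv_time_poincare,
    respiration_features,
    rr_hrv,
    scr_cda,
    scr_trough_to_peak,
    segment_blocks,
    segment_raw_signal,
)
from imvest.synthetic_data import render_ecg


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------


def test_decimate_length_and_rate():
    sig = RawSignal("eda", 1000.0, np.zeros(1000))
    out = decimate_signal(sig, 10)
    assert out.sampling_rate == 100.0
    assert len(out.samples) == 100


def test_decimate_passband_preserved():
    fs = 1000.0
    t = np.arange(0, 10, 1 / fs)
    sig = RawSignal("resp", fs, np.sin(2 * np.pi * 1.0 * t))
    out = decimate_signal(sig, 10)
    mid = out.samples[50:-50]  # skip filter edges
    assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)


def test_decimate_stopband_attenuated():
    fs = 1000.0
    t = np.arange(0, 10, 1 / fs)
    sig = RawSignal("resp", fs, np.sin(2 * np.pi * 48.0 * t))
    out = decimate_signal(RawSignal("resp", fs, sig.samples), 10)
    # alias at 48 Hz folds to 48 Hz > new Nyquist; must be cut by > 20 dB
    assert np.max(np.abs(out.samples[50:-50])) < 0.1


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------


def test_r_peaks_recovered_within_5ms():
    bt = np.cumsum(np.r_[1.0, np.full(80, 0.8)])
    ecg = render_ecg(NNSeries.from_beat_times(bt), fs=1000.0)
    det = detect_r_peaks(ecg)
    assert len(det.beat_times) == len(bt)
    err = np.array([np.min(np.abs(det.beat_times - t)) for t in bt])
    assert np.max(err) <= 0.005


def test_r_peaks_flat_signal_flagged():
    det = detect_r_peaks(RawSignal("ecg", 1000.0, np.zeros(5000)))
    assert det.n == 0 and det.flagged


def test_r_peaks_sensitivity_at_20db():
    rng = np.random.default_rng(1)
    nn = 800 + rng.normal(0, 40, 150)
    bt = np.cumsum(nn) / 1000.0 + 1.0
    ecg = render_ecg(NNSeries.from_beat_times(bt), fs=1000.0, snr_db=20, rng=2)
    det = detect_r_peaks(ecg)
    hits = sum(np.min(np.abs(det.beat_times - t)) <= 0.05 for t in bt)
    assert hits / len(bt) >= 0.99


# ---------------------------------------------------------------------------
# NN cleaning
# ---------------------------------------------------------------------------


def test_clean_nn_rules():
    base = np.full(50, 800.0)
    nn = NNSeries(np.cumsum(base) / 1000.0, base)
    out, rej = clean_nn(nn)
    assert rej == 0.0 and out.n == 50 and not out.flagged

    with_range_outlier = np.r_[base[:20], 3000.0, base[20:]]
    nn2 = NNSeries(np.cumsum(with_range_outlier) / 1000.0, with_range_outlier)
    out2, rej2 = clean_nn(nn2)
    assert 3000.0 not in out2.nn_intervals
    assert rej2 == pytest.approx(1 / 51)

    jump = np.r_[np.full(10, 800.0), 1200.0, np.full(10, 800.0)]
    nn3 = NNSeries(np.cumsum(jump) / 1000.0, jump)
    out3, _ = clean_nn(nn3)
    assert 1200.0 not in out3.nn_intervals  # 50% change from previous accepted


def test_clean_nn_unusable_flag():
    vals = np.full(20, 100.0)  # all outside the plausible range
    nn = NNSeries(np.cumsum(vals) / 1000.0, vals)
    out, rej = clean_nn(nn)
    assert rej == 1.0 and out.flagged


# ---------------------------------------------------------------------------
# block segmentation
# ---------------------------------------------------------------------------


def _schedule():
    return [(b, 150.0 * i, 150.0 * (i + 1)) for i, b in enumerate(BLOCKS)]


def test_segment_raw_signal_slices():
    fs = 10.0
    sig = RawSignal("eda", fs, np.arange(12000, dtype=float))
    parts = segment_raw_signal(sig, _schedule())
    assert len(parts) == 8
    assert all(len(p.samples) == 1500 for p in parts.values())
    # boundary sample at t = 150.0 belongs to the second block
    assert parts["BL2"].samples[0] == 1500.0


def test_segment_blocks_beat_assignment():
    bt = np.array([149.5, 150.0, 150.5])
    nn = NNSeries.from_beat_times(bt)
    parts = segment_blocks(nn, _schedule())
    # interval ending exactly at 150.0 belongs to block 2 (half-open windows)
    assert parts["BL1"].n == 0
    assert parts["BL2"].n == 2


def test_segment_blocks_gap_is_error():
    bad = [("BL1", 0.0, 150.0), ("BL2", 151.0, 301.0)]
    with pytest.raises(ValueError):
        segment_blocks(NNSeries(np.array([1.0]), np.array([800.0])), bad)


# ---------------------------------------------------------------------------
# time-domain / Poincare
# ---------------------------------------------------------------------------


def test_poincare_constant_series():
    f = hrv_time_poincare(np.full(100, 800.0))
    assert f["HR"] == pytest.approx(75.0)
    assert f["RMSSD"] == 0.0 and f["SDNN"] == 0.0 and f["pnn50"] == 0.0


def test_poincare_alternating_closed_form():
    nn = np.tile([800.0, 850.0], 50)
    f = hrv_time_poincare(nn)
    assert f["RMSSD"] == pytest.approx(50.0)
    assert f["SD1"] == pytest.approx(50.0 / math.sqrt(2), rel=1e-12)
    assert f["pnn50"] == 0.0  # differences of exactly 50 ms are not > 50


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_poincare_identities_random_series(seed):
    rng = np.random.default_rng(seed)
    nn = rng.uniform(400, 1200, size=rng.integers(10, 300))
    f = hrv_time_poincare(nn)
    assert f["SD1"] == pytest.approx(f["RMSSD"] / math.sqrt(2), rel=1e-9)
    assert f["SD1"] ** 2 + f["SD2"] ** 2 == pytest.approx(2 * f["SDNN"] ** 2, rel=1e-9)


# ---------------------------------------------------------------------------
# geometric
# ---------------------------------------------------------------------------


def test_geometric_constant_series():
    f = hrv_geometric(np.full(50, 800.0))
    assert f["TRI"] == 1.0 and f["TINN"] == 0.0


def test_geometric_uniform_k_bins():
    # 20 intervals in each of 5 adjacent bins -> TRI = 5
    bw = 7.8125
    vals = np.concatenate([np.full(20, 800.0 + i * bw) for i in range(5)])
    f = hrv_geometric(vals, bin_width=bw)
    assert f["TRI"] == pytest.approx(5.0)


def test_geometric_triangular_base_recovered():
    # symmetric triangular distribution over ~100 ms base
    rng = np.random.default_rng(3)
    vals = rng.triangular(750.0, 800.0, 850.0, size=5000)
    f = hrv_geometric(vals)
    assert f["TINN"] == pytest.approx(100.0, abs=20.0)


# ---------------------------------------------------------------------------
# PRSA
# ---------------------------------------------------------------------------


def test_prsa_ramp():
    ramp = 800.0 + 5.0 * np.arange(30)
    f = hrv_prsa(ramp)
    assert f["dc"] == pytest.approx(5.0)
    assert math.isnan(f["ac"])  # no decelerating... no shorter-than-predecessor anchors


def test_prsa_alternating_zero():
    nn = np.tile([800.0, 850.0], 20)
    f = hrv_prsa(nn)
    assert f["dc"] == pytest.approx(0.0, abs=1e-12)
    assert f["ac"] == pytest.approx(0.0, abs=1e-12)


def test_prsa_constant_absent():
    f = hrv_prsa(np.full(30, 800.0))
    assert math.isnan(f["ac"]) and math.isnan(f["dc"])


# ---------------------------------------------------------------------------
# entropies vs brute-force oracle
# ---------------------------------------------------------------------------


def _brute_entropies(x, m, r):
    """Direct template-counting implementations of SampEn and ApEn."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def cheb(i, j, length):
        return max(abs(x[i + k] - x[j + k]) for k in range(length))

    # SampEn: pairs i < j among the first n-m templates
    B = sum(
        1
        for i in range(n - m)
        for j in range(i + 1, n - m)
        if cheb(i, j, m) <= r
    )
    A = sum(
        1
        for i in range(n - m)
        for j in range(i + 1, n - m)
        if cheb(i, j, m + 1) <= r
    )
    sampen = -math.log(A / B) if A > 0 and B > 0 else float("nan")

    def phi(length):
        nt = n - length + 1
        tot = 0.0
        for i in range(nt):
            c = sum(1 for j in range(nt) if cheb(i, j, length) <= r)
            tot += math.log(c / nt)
        return tot / nt

    apen = phi(m) - phi(m + 1)
    return sampen, apen


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_entropy_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(800, 30, 40)
    r = 0.2 * float(np.std(x))
    got = hrv_entropy(x, m=2, r=r)
    want_s, want_a = _brute_entropies(x, 2, r)
    if math.isnan(want_s):  # no template pairs matched at m+1
        assert math.isnan(got["SampEn"])
    else:
        assert got["SampEn"] == pytest.approx(want_s, rel=1e-12)
    assert got["ApEn"] == pytest.approx(want_a, rel=1e-12)


def test_entropy_ordering_periodic_vs_noise():
    rng = np.random.default_rng(5)
    periodic = 800 + 30 * np.sin(np.arange(200) * 2 * np.pi / 10)
    noise = 800 + 30 * rng.standard_normal(200)
    assert hrv_entropy(periodic)["SampEn"] < hrv_entropy(noise)["SampEn"]


def test_entropy_constant_series():
    f = hrv_entropy(np.full(60, 800.0))
    assert f["ApEn"] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------


def _tone_series(freq, amp=50.0, n=200):
    t = np.cumsum(np.full(n, 0.8))
    nn = 800 + amp * np.sin(2 * np.pi * freq * t)
    return NNSeries(t, nn)


def test_spectral_lf_tone_concentration():
    s = hrv_spectral(_tone_series(0.10))
    assert s["lf"] / s["ttlpwr"] >= 0.90


def test_spectral_hf_tone():
    s = hrv_spectral(_tone_series(0.25))
    assert s["hf"] > 5 * s["lf"]


def test_spectral_parseval():
    rng = np.random.default_rng(2)
    t = np.cumsum(rng.uniform(0.7, 0.9, 300))
    nn = 800 + 40 * np.sin(2 * np.pi * 0.1 * t) + 30 * np.sin(2 * np.pi * 0.3 * t)
    s = hrv_spectral(NNSeries(t, nn))
    assert s["ttlpwr"] == pytest.approx(float(np.var(nn)), rel=0.10)


# ---------------------------------------------------------------------------
# rrHRV
# ---------------------------------------------------------------------------


def test_rrhrv_constant_zero():
    assert rr_hrv(np.full(50, 800.0)) == 0.0


def test_rrhrv_scale_invariant():
    rng = np.random.default_rng(4)
    nn = rng.uniform(700, 900, 100)
    assert rr_hrv(nn) == pytest.approx(rr_hrv(3.7 * nn), rel=1e-12)


def test_rrhrv_alternating_closed_form():
    nn = np.tile([800.0, 850.0], 30)
    # rr alternates +-100/1650; return-map points are (+v,-v)/(-v,+v), center 0
    v = 100.0 / 1650.0
    assert rr_hrv(nn) == pytest.approx(math.sqrt(2) * v, rel=1e-9)


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------


def test_respiration_sinusoid_rate():
    fs = 20.0
    t = np.arange(0, 150, 1 / fs)
    f = respiration_features(RawSignal("resp", fs, np.sin(2 * np.pi * 0.25 * t)))
    assert f["RespRate"] == pytest.approx(15.0, abs=0.1)
    assert f["RespRatio"] == pytest.approx(f["RespDepth"] / f["RespWidth"])


def test_respiration_separation_rule():
    # 2 Hz oscillation: peaks 0.5 s apart are rejected by the 0.8 s rule
    # (and largely removed by the 1 Hz low-pass)
    fs = 50.0
    t = np.arange(0, 60, 1 / fs)
    f = respiration_features(RawSignal("resp", fs, np.sin(2 * np.pi * 2.0 * t)))
    assert math.isnan(f["RespRate"]) or f["RespRate"] < 100.0


def test_respiration_subthreshold_ripples_ignored():
    fs = 20.0
    t = np.arange(0, 150, 1 / fs)
    base = np.sin(2 * np.pi * 0.2 * t)
    ripple = 0.05 * np.sin(2 * np.pi * 0.45 * t)  # small, below robust SD
    f = respiration_features(RawSignal("resp", fs, base + ripple))
    assert f["RespRate"] == pytest.approx(12.0, abs=0.5)


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------


def _bateman(t, tau1=1.0, tau2=3.75):
    k = np.exp(-t / tau2) - np.exp(-t / tau1)
    return k / k.max()


def test_scr_tonic_only_zero():
    fs = 20.0
    sig = RawSignal("eda", fs, np.full(int(150 * fs), 2.0))
    assert scr_trough_to_peak(sig) == 0.0
    cda = scr_cda(sig)
    assert cda["nSCRcda"] == 0.0
    assert cda["Toniccda"] == pytest.approx(2.0, rel=1e-6)


def test_scr_counts_recover_ground_truth():
    fs = 20.0
    n = int(150 * fs)
    t = np.arange(n) / fs
    y = 2.0 + 0.002 * t  # tonic with linear drift
    events = [20.0, 45.0, 70.0, 95.0, 120.0, 140.0]
    tk = np.arange(0, 25, 1 / fs)
    k = _bateman(tk)
    for e in events:
        i = int(e * fs)
        seg = min(len(k), n - i)
        y[i : i + seg] += 0.25 * k[:seg]
    sig = RawSignal("eda", fs, y)
    assert scr_trough_to_peak(sig) == pytest.approx(len(events) * 60 / 150)
    cda = scr_cda(sig)
    assert cda["nSCRcda"] == pytest.approx(len(events) * 60 / 150)
    assert cda["Toniccda"] == pytest.approx(float(np.mean(2.0 + 0.002 * t)), rel=0.05)


def test_scr_normalization_is_per_minute():
    # 6 SCRs in a 150 s block -> 2.4 per minute
    fs = 20.0
    n = int(150 * fs)
    y = np.full(n, 1.0)
    tk = np.arange(0, 25, 1 / fs)
    k = _bateman(tk)
    for e in (10.0, 32.0, 55.0, 80.0, 105.0, 130.0):
        i = int(e * fs)
        seg = min(len(k), n - i)
        y[i : i + seg] += 0.3 * k[:seg]
    assert scr_trough_to_peak(RawSignal("eda", fs, y)) == pytest.approx(2.4)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


def _fake_blocks(hr_by_block):
    from imvest.signal_features import FeatureBlock

    out = {}
    for block, hr in hr_by_block.items():
        vals = {v: 1.0 for v in VARIABLES}
        vals["HR"] = hr
        out[block] = FeatureBlock(block=block, values=vals)
    return out


def test_build_feature_table_deltas_and_width():
    table = build_feature_table(
        {"P1": ("stress", _fake_blocks({"BL1": 70.0, "T1": 85.0}))}
    )
    t1 = table[table["block"] == "T1"].iloc[0]
    bl1 = table[table["block"] == "BL1"].iloc[0]
    assert t1["dHR"] == pytest.approx(15.0)
    assert bl1["dHR"] == 0.0
    analysis_cols = [c for c in table.columns if c not in ("participant_id", "group", "block")]
    assert len(analysis_cols) == 50


def test_build_feature_table_missing_bl1_excluded():
    with pytest.warns(UserWarning, match="BL1"):
        table = build_feature_table({"P1": ("stress", _fake_blocks({"T1": 85.0}))})
    assert len(table) == 0


def test_extract_block_features_covers_all_variables(small_stress_cohort):
    row = small_stress_cohort.features.iloc[0]
    for v in VARIABLES:
        assert v in small_stress_cohort.features.columns
        assert f"d{v}" in small_stress_cohort.features.columns
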