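"""Per-sample metric operations: preprocessing, variance, nonperiodic
power, binarization, synchrony/asynchrony power, frequency and phase."""

import numpy as np
import pytest

from aurea.config import AnalysisConfig, seconds_to_odd_samples
from aurea.metrics import (
    compute_metrics,
    nonperiodic_power,
    normalized_variance,
    phase_metric,
    preprocess_rip,
    respiratory_frequency,
    smooth_and_binarize,
    syb_asb_metrics,
)
from aurea.record import RIPRecord
from aurea.synthetic import PatternSpec, generate_record

FS = 50.0
CFG = AnalysisConfig()


def _square_wave(freq_hz, n, fs=FS, shift_samples=0):
    t = np.arange(n) - shift_samples
    return (np.sin(2 * np.pi * freq_hz * t / fs) >= 0).astype(float)


def _exact_square(period_samples, n, shift_samples=0):
    """Square wave with an exactly integer period (no float sign flips)."""
    t = np.arange(n) - shift_samples
    return ((t % period_samples) < period_samples // 2).astype(float)


# --- preprocessing ----------------------------------------------------

def test_preprocess_constant_series_removes_everything():
    rip, rip_lf = preprocess_rip(np.full(500, 3.7), CFG, 5.0, FS)
    np.testing.assert_allclose(rip, 0.0, atol=1e-12)
    np.testing.assert_allclose(rip_lf, 3.7, atol=1e-12)


def test_preprocess_linear_ramp_is_fully_removed():
    # the centered mean of a symmetric window on a ramp equals the center
    # value, so the detrended signal is identically zero
    rip, _ = preprocess_rip(0.01 * np.arange(600), CFG, 5.0, FS)
    np.testing.assert_allclose(rip, 0.0, atol=1e-9)


def test_preprocess_sinusoid_attenuation_matches_filter_response():
    # interior samples of the low-frequency estimate equal the moving
    # average magnitude response at the probe frequency
    f, n = 1.0, 3000
    x = np.sin(2 * np.pi * f * np.arange(n) / FS)
    _, rip_lf = preprocess_rip(x, CFG, 5.0, FS)
    width = seconds_to_odd_samples(5.0, FS)
    gain = abs(np.sin(np.pi * f * width / FS) / (width * np.sin(np.pi * f / FS)))
    interior = slice(width, n - width)
    np.testing.assert_allclose(
        np.max(np.abs(rip_lf[interior])), gain, rtol=1e-2
    )


def test_preprocess_too_short_series_raises_with_minimum_length():
    with pytest.raises(ValueError, match="at least"):
        preprocess_rip(np.zeros(10), CFG, 5.0, FS)


# --- normalized variance ----------------------------------------------

def test_nv_of_stationary_noise_concentrates_at_zero():
    # with the median as normalization quantile, ln(V / V_median) ~ 0
    rng = np.random.default_rng(0)
    rip = rng.standard_normal(20_000)
    nv = normalized_variance(rip, CFG, FS)
    assert abs(np.median(nv[6000:])) < 0.1


def test_nv_is_scale_invariant():
    rng = np.random.default_rng(1)
    rip = rng.standard_normal(5000)
    nv1 = normalized_variance(rip, CFG, FS)
    nv2 = normalized_variance(1234.5 * rip, CFG, FS)
    np.testing.assert_allclose(nv1, nv2, rtol=0, atol=1e-9)


def test_nv_drops_sharply_in_a_silent_stretch():
    rng = np.random.default_rng(2)
    t = np.arange(30_000) / FS
    rip = np.sin(2 * np.pi * 0.7 * t) + 0.02 * rng.standard_normal(t.size)
    rip[15_000:17_500] = 0.001 * rng.standard_normal(2500)  # 50 s pause
    nv = normalized_variance(rip, CFG, FS)
    breathing = np.r_[nv[6000:14_500], nv[18_000:]]
    pause = nv[15_500:17_000]
    assert pause.mean() < breathing.mean() - 2 * breathing.std()


# --- nonperiodic power -------------------------------------------------

def test_moving_average_null_at_fs_over_nma():
    # a sinusoid whose period equals the filter width sits exactly on the
    # first spectral null: interior output is < 1e-6 of the DC gain
    from aurea._sliding import centered_mean

    width = seconds_to_odd_samples(CFG.n_ma, FS)
    f_null = FS / width
    n = 5000
    x = np.sin(2 * np.pi * f_null * np.arange(n) / FS)
    y = centered_mean(x, width)
    assert np.max(np.abs(y[width:-width])) < 1e-6


def test_npp_negative_in_on_null_stretch_within_off_null_breathing():
    # the notch removes a sinusoid sitting on the filter null but passes
    # one well below it, so an on-null stretch embedded in off-null
    # breathing shows up as strongly negative normalized power
    width = seconds_to_odd_samples(CFG.n_ma, FS)
    f_null = FS / width
    n = 60_000
    t = np.arange(n) / FS
    rip = np.sin(2 * np.pi * 0.35 * t)  # passes the notch
    stretch = slice(35_000, 40_000)
    rip[stretch] = np.sin(2 * np.pi * f_null * t[stretch])
    npp = nonperiodic_power(rip, CFG, FS)
    baseline = np.r_[npp[5000:34_000], npp[41_000:-1000]]
    assert np.median(npp[36_000:39_000]) < np.median(baseline) - 2 * baseline.std()


def test_npp_elevated_during_low_frequency_movement(study_roundtrip):
    ms = study_roundtrip["metrics"]
    truth = study_roundtrip["synth"].truth.labels
    mvt = truth == "MVT"
    rest = ~mvt & (truth != "PAU")
    elevated = ms.npp_abd[mvt].mean()
    baseline, sd = ms.npp_abd[rest].mean(), ms.npp_abd[rest].std()
    assert elevated > baseline + 2 * sd


def test_npp_finite_for_constant_input():
    npp = nonperiodic_power(np.zeros(5000), CFG, FS)
    assert np.all(np.isfinite(npp))


# --- binarization -----------------------------------------------------

def test_binarize_sinusoid_gives_half_duty_square_wave():
    t = np.arange(10_000) / FS
    rip = np.sin(2 * np.pi * 0.7 * t)
    b = smooth_and_binarize(rip, np.zeros_like(rip), CFG, FS)
    assert set(np.unique(b)) <= {0.0, 1.0}
    assert abs(b.mean() - 0.5) < 0.02


def test_binarize_zero_signal_is_all_zero():
    z = np.zeros(1000)
    b = smooth_and_binarize(z, z, CFG, FS)
    assert np.all(b == 0.0)


def test_binarize_transition_rate_robust_to_noise():
    rng = np.random.default_rng(4)
    t = np.arange(30_000) / FS
    clean = np.sin(2 * np.pi * 0.7 * t)
    noisy = clean + 0.15 * rng.standard_normal(t.size)
    rate_clean = np.sum(np.diff(smooth_and_binarize(clean, 0 * t, CFG, FS)) != 0)
    rate_noisy = np.sum(np.diff(smooth_and_binarize(noisy, 0 * t, CFG, FS)) != 0)
    assert rate_noisy == pytest.approx(rate_clean, rel=0.2)


# --- synchrony / asynchrony metrics -----------------------------------

def test_in_phase_square_waves_have_zero_b_minus():
    b = _square_wave(0.7, 20_000)
    b_plus, b_minus = syb_asb_metrics(b, b.copy(), CFG, FS)
    np.testing.assert_allclose(b_minus, 0.0, atol=1e-12)
    assert b_plus[5000:-5000].min() > 0.0


def test_anti_phase_square_waves_have_zero_b_plus():
    b = _square_wave(0.7, 20_000)
    b_plus, b_minus = syb_asb_metrics(b, 1.0 - b, CFG, FS)
    interior = slice(5000, -5000)
    assert np.max(b_plus[interior]) < 1e-6  # constant 0.5 removed by high-pass
    assert b_minus[interior].min() > 0.0


def test_quarter_cycle_shift_balances_b_plus_and_b_minus():
    n = 40_000
    period = 72  # ~0.69 Hz at 50 Hz sampling, exactly periodic
    rcg_b = _exact_square(period, n)
    abd_b = _exact_square(period, n, shift_samples=period // 4)
    b_plus, b_minus = syb_asb_metrics(rcg_b, abd_b, CFG, FS)
    interior = slice(5000, -5000)
    assert np.mean(b_plus[interior]) == pytest.approx(
        np.mean(b_minus[interior]), rel=0.05
    )


def test_syb_asb_rejects_non_binary_input():
    with pytest.raises(ValueError, match="binary"):
        syb_asb_metrics(np.linspace(0, 1, 100), np.zeros(100), CFG, FS)


# --- respiratory frequency --------------------------------------------

def test_square_wave_frequency_recovered_exactly():
    b = _exact_square(100, 5000)  # transitions every 50 samples = 1 s
    f = respiratory_frequency(b, FS)
    np.testing.assert_allclose(f, 0.5, atol=1e-12)


def test_constant_series_has_undefined_frequency():
    f = respiratory_frequency(np.ones(1000), FS)
    assert np.all(np.isnan(f))


def test_frequency_step_tracked_outside_transition_zone():
    n_half = 25_000
    b = np.concatenate([_square_wave(0.5, n_half), _square_wave(1.0, n_half)])
    f = respiratory_frequency(b, FS)
    zone = int(2 * FS / 0.5)  # two slow cycles around the step
    first = f[500 : n_half - zone]
    second = f[n_half + zone : -500]
    ok = np.concatenate([np.abs(first - 0.5) / 0.5, np.abs(second - 1.0) / 1.0])
    assert np.mean(ok < 0.05) >= 0.9


def test_frequency_rejects_non_binary_input():
    with pytest.raises(ValueError, match="binary"):
        respiratory_frequency(np.linspace(0, 1, 50), FS)


# --- phase -------------------------------------------------------------

def test_phase_of_identical_signals_is_zero():
    b = _square_wave(0.7, 3000)
    np.testing.assert_allclose(phase_metric(b, b.copy(), CFG), 0.0, atol=1e-12)


def test_phase_of_complementary_signals_is_one():
    b = _square_wave(0.7, 3000)
    np.testing.assert_allclose(phase_metric(b, 1.0 - b, CFG), 1.0, atol=1e-12)


def test_phase_of_quarter_cycle_shift_is_half():
    n = 20_000
    quarter = int(FS / 0.7 / 4)
    rcg_b = _square_wave(0.7, n)
    abd_b = _square_wave(0.7, n, shift_samples=quarter)
    phi = phase_metric(rcg_b, abd_b, CFG)
    assert np.mean(phi[1000:-1000]) == pytest.approx(0.5, abs=0.03)


# --- orchestration ----------------------------------------------------

def _breathing_record(seconds=700.0, seed=0, phase_deg=4.0, freq=0.76):
    spec = PatternSpec(label="SYB" if phase_deg < 45 else "ASB",
                       duration_s=seconds, breath_freq_hz=freq,
                       phase_deg=phase_deg)
    return generate_record([spec], fs=FS, seed=seed)


def test_compute_metrics_aligns_all_series():
    synth = _breathing_record(seconds=650.0)
    ms = compute_metrics(synth.record, CFG)
    n = synth.record.n_samples
    for name in ("nv_rcg", "nv_abd", "npp_rcg", "npp_abd", "b_plus",
                 "b_minus", "f_resp", "phi", "valid_mask"):
        assert getattr(ms, name).size == n
    assert np.all(ms.b_plus >= 0) and np.all(ms.b_minus >= 0)
    assert np.all((ms.phi >= 0) & (ms.phi <= 1))
    assert ms.valid_mask.any()


def test_compute_metrics_recovers_breathing_frequency():
    synth = _breathing_record(seconds=650.0, freq=0.76)
    ms = compute_metrics(synth.record, CFG)
    assert abs(np.nanmedian(ms.f_resp) - 0.76) <= 0.05


def test_compute_metrics_recovers_asynchronous_phase():
    synth = _breathing_record(seconds=650.0, phase_deg=100.0, freq=0.71)
    ms = compute_metrics(synth.record, CFG)
    hist, edges = np.histogram(180 * ms.phi, bins=36, range=(0, 180))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert abs(mode - 100.0) <= 15.0


def test_all_metrics_are_scale_invariant():
    synth = _breathing_record(seconds=650.0)
    rec = synth.record
    scaled = RIPRecord(rcg=713.0 * rec.rcg, abd=713.0 * rec.abd, fs=rec.fs)
    m1 = compute_metrics(rec, CFG)
    m2 = compute_metrics(scaled, CFG)
    for name in ("nv_rcg", "nv_abd", "npp_rcg", "npp_abd", "b_plus",
                 "b_minus", "phi"):
        np.testing.assert_allclose(
            getattr(m1, name), getattr(m2, name), rtol=1e-7, atol=1e-9,
            err_msg=name,
        )
    np.testing.assert_array_equal(np.isnan(m1.f_resp), np.isnan(m2.f_resp))
    np.testing.assert_allclose(np.nan_to_num(m1.f_resp),
                               np.nan_to_num(m2.f_resp), rtol=1e-9)
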