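import numpy as np
import pytest

from latentrl.diagnostics import (
    autocorrelation,
    default_lags,
    dprime,
    mai_profile,
    mai_whiteness,
    ms2d,
    normalize_mai,
    normalized_final_pitch,
    self_consistency_check,
    smoothed_rmse,
)

from conftest import make_traj


def test_default_lags_log_spaced_integers():
    lags = default_lags()
    assert lags[0] == 1 and lags[-1] == 1000
    assert np.all(np.diff(lags) > 0)
    assert lags.size <= 50


def test_mai_iid_within_reference_band():
    rng = np.random.default_rng(0)
    # n_ref=8 surrogates keep the per-lag 3-SD band's false-alarm rate
    # low across ~50 simultaneous lags
    prof = mai_profile(rng.standard_normal(10000), seed=1, n_ref=8)
    assert mai_whiteness(prof)


def test_mai_detects_deterministic_lag_dependence():
    # c_t = c_{t-1}-style copy dependence at lag 1
    rng = np.random.default_rng(2)
    z = rng.standard_normal(5000)
    x = np.repeat(z[:2500], 2)
    prof = mai_profile(x, seed=3)
    assert prof.lag1 > prof.ref_mean + 10 * prof.ref_sd


def test_mai_ar1_matches_gaussian_closed_form():
    """AR(1) MAI decays with lag; values track -0.5 ln(1 - rho^2)."""
    rng = np.random.default_rng(4)
    T = 200000
    phi = 0.9
    x = np.empty(T)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(T) * np.sqrt(1 - phi * phi)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + innov[t]
    prof = mai_profile(x, lags=np.array([1, 2, 5, 10, 50]), seed=5)
    excess = prof.raw - prof.ref_by_lag
    for lag, val in zip(prof.lags, excess):
        closed = -0.5 * np.log(1 - phi ** (2 * lag))
        assert val == pytest.approx(closed, rel=0.25, abs=0.01)
    # monotone decay over the first decade
    assert excess[0] > excess[2] > excess[4]


def test_mai_affine_invariance():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(3000)
    p1 = mai_profile(x, seed=7)
    p2 = mai_profile(5.0 * x - 40.0, seed=7)
    np.testing.assert_allclose(p1.raw, p2.raw, atol=1e-12)


def test_mai_constant_series_zero():
    prof = mai_profile(np.full(2000, 3.0), seed=8)
    np.testing.assert_array_equal(prof.raw, 0.0)


def test_mai_drops_long_lags_with_warning():
    rng = np.random.default_rng(9)
    with pytest.warns(UserWarning, match="dropping"):
        prof = mai_profile(rng.standard_normal(300), seed=10)
    assert prof.lags.max() <= 150


def test_normalize_mai_anchors():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(5000)
    y = x + np.concatenate([[0.0], 0.8 * x[:-1]])  # correlated anchor series
    anchor = mai_profile(y, seed=12)
    prof = normalize_mai(mai_profile(x, seed=12), anchor=anchor)
    # white-noise input normalized against a correlated anchor scatters
    # around zero
    assert abs(np.mean(prof.normalized)) < 0.2
    anch_norm = normalize_mai(anchor)
    assert anch_norm.normalized[anch_norm.lags == 1][0] == pytest.approx(1.0)


def test_normalize_mai_degenerate_flag():
    prof = mai_profile(np.full(2000, 1.0), seed=13)
    with pytest.warns(UserWarning):
        out = normalize_mai(prof)
    assert out.degenerate


def test_staircase_of_residual_stages(baseline_bird, baseline_fit):
    """Successively subtracting fitted components walks the normalized
    MAI down to the white-noise reference."""
    d = baseline_fit.decomposition
    p = d.pitch
    anchor = mai_profile(p, seed=11)
    stages = [p, p - d.d, p - d.d - d.c, p - d.d - d.c - d.o, d.eps]
    means = []
    for s in stages:
        prof = normalize_mai(mai_profile(s, seed=11), anchor=anchor)
        means.append(float(np.mean(prof.normalized)))
    for a, b in zip(means, means[1:]):
        assert b <= a + 0.05  # non-increasing within noise
    assert means[0] > 0.3
    assert abs(means[-1]) < 0.05  # explorations at the reference level


def test_ms2d_closed_forms():
    day = np.zeros(1000, int)
    lin = np.linspace(0, 50, 1000)
    assert ms2d(lin, day) == pytest.approx(0.0, abs=1e-18)
    # quadratic on a grid matching the resampling resolution: the second
    # difference is the constant 2*step^2
    quad = np.arange(1000.0) ** 2
    assert ms2d(quad, day, resample_n=1000) == pytest.approx(4.0, rel=1e-9)
    # white noise is rougher than a smooth ramp
    rng = np.random.default_rng(14)
    assert ms2d(rng.standard_normal(1000), day) > ms2d(lin, day)


def test_ms2d_skips_small_days():
    b = np.arange(10.0)
    day = np.array([0] * 8 + [1] * 2)
    with pytest.warns(UserWarning, match="fewer than 3"):
        ms2d(b, day)
    with pytest.raises(ValueError):
        ms2d(np.arange(2.0), np.zeros(2, int))


def test_smoothed_rmse():
    rng = np.random.default_rng(15)
    x = rng.standard_normal(500) + 100
    assert smoothed_rmse(x, x) == 0.0
    assert smoothed_rmse(x + 3.0, x) == pytest.approx(3.0)
    # smoothing shrinks zero-mean noise discrepancies
    noisy = x + rng.standard_normal(500)
    raw_rmse = np.sqrt(np.mean((noisy - x) ** 2))
    assert smoothed_rmse(noisy, x) < raw_rmse / 3
    with pytest.raises(ValueError):
        smoothed_rmse(x, x[:-1])


def test_normalized_final_pitch():
    n = 40
    day = np.repeat([0, 1], n // 2)
    h = np.tile(np.linspace(0.3, 0.6, n // 2), 2)
    pitch = np.concatenate([np.full(n // 2, 1000.0), np.full(n // 2, 1010.0)])
    thr = np.concatenate([np.full(n // 2, 1000.0), np.full(n // 2, 1010.0)])
    hit = (pitch < thr).astype(float)
    traj = make_traj(day, h, pitch, threshold_hz=thr, hit=hit,
                     contingency=["low"] * n)
    # last-day mean equals the last threshold -> 1
    assert normalized_final_pitch(traj) == pytest.approx(1.0)
    # equal to the first threshold -> 0
    assert normalized_final_pitch(traj, 1010.0, 1020.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        normalized_final_pitch(traj, 5.0, 5.0)


def test_dprime():
    a = np.array([1.0, 2.0, 3.0])
    assert dprime(a, a) == 0.0
    b = a + 1.0
    assert dprime(a, b) == pytest.approx(-dprime(b, a))
    rng = np.random.default_rng(16)
    x = rng.normal(0, 1, 50000)
    assert dprime(x + 1.0, x) == pytest.approx(1.0, abs=0.05)
    with pytest.raises(ValueError):
        dprime([1.0, 1.0], [1.0, 1.0])


def test_autocorrelation_basics():
    rng = np.random.default_rng(17)
    x = rng.standard_normal(20000)
    acf = autocorrelation(x, 5)
    assert acf[0] == 1.0
    assert np.all(np.abs(acf[1:]) < 0.03)
    with pytest.raises(ValueError):
        autocorrelation(x[:3], 5)


def test_self_consistency_battery_on_raw_noise():
    rng = np.random.default_rng(18)
    good = self_consistency_check(rng.standard_normal(5000), seed=19)
    assert good["passes"]
    heavy = rng.standard_normal(5000) * np.where(rng.random(5000) < 0.1, 5, 1)
    assert not self_consistency_check(heavy, seed=19)["gaussian"]
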