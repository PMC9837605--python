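"""FIR design, GLM, gamma-variate fitting, smoothing, smoothness estimation."""

import warnings

import numpy as np
import pytest
from scipy import integrate

from erroraware.classify import AWARE_ERROR, UNAWARE_ERROR, classify_trials
from erroraware.cohort import BehaviorParams, NeuroParams, Region, simulate_bold, simulate_responses
from erroraware.deconvolve import (
    GammaHRF,
    RankDeficientDesignError,
    activation_maps,
    build_design_matrix,
    estimate_fwhm,
    fit_gamma_variate,
    fit_gamma_variate_map,
    fit_glm,
    gamma_auc,
    percent_signal,
    roi_activation,
    smooth_volume,
)

from conftest import build_responses, build_toy_sequence

TR = 2.46


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def test_single_event_fir_block_is_shifted_identity():
    seq = build_toy_sequence(["nogo"] + ["go"] * 29)
    # No-Go at t=0, withheld -> one correct-inhibition event at volume 0
    resp = build_responses(["none"] + ["left"] * 29)
    out = classify_trials(seq, resp)
    design = build_design_matrix(seq, out, n_volumes=20, tr_s=TR)
    sl = design.condition_slices["correct_inhibition"]
    block = design.X[:, sl]
    expected = np.zeros((20, design.n_lags))
    expected[np.arange(design.n_lags), np.arange(design.n_lags)] = 1.0
    np.testing.assert_array_equal(block, expected)


def test_zero_event_condition_dropped_with_warning(small_sequence):
    resp = simulate_responses(small_sequence, BehaviorParams(p_inhibit=1.0), seed=0)
    out = classify_trials(small_sequence, resp)
    with pytest.warns(UserWarning, match="zero events"):
        design = build_design_matrix(small_sequence, out, 60, TR)
    assert AWARE_ERROR in design.dropped_conditions
    assert UNAWARE_ERROR in design.dropped_conditions
    assert AWARE_ERROR not in design.condition_slices


def test_overlapping_events_match_convolution_oracle(small_sequence):
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=4)
    out = classify_trials(small_sequence, resp)
    n_vol = 80
    design = build_design_matrix(small_sequence, out, n_vol, TR)
    from erroraware.classify import event_onsets_by_class

    onsets = event_onsets_by_class(small_sequence, out)
    for cond, sl in design.condition_slices.items():
        train = np.zeros(n_vol)
        for onset in onsets[cond]:
            k = int(round(onset / TR))
            if k < n_vol:
                train[k] += 1
        for lag in range(design.n_lags):
            kernel = np.zeros(design.n_lags)
            kernel[lag] = 1.0
            oracle = np.convolve(train, kernel)[:n_vol]
            np.testing.assert_array_equal(design.X[:, sl][:, lag], oracle)


def test_rank_deficient_design_raises_naming_columns():
    seq = build_toy_sequence(["nogo"] + ["go"] * 29)
    resp = build_responses(["none"] + ["left"] * 29)
    out = classify_trials(seq, resp)
    # 4 volumes cannot support 8 FIR lags: late-lag columns are all zero
    with pytest.raises(RankDeficientDesignError, match="lag"):
        build_design_matrix(seq, out, n_volumes=4, tr_s=TR, drift_order=0)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def noiseless_subject(small_sequence):
    neuro = NeuroParams(
        grid_shape=(6, 6, 4),
        noise_sd=0.0,
        drift_amp=0.0,
        regions=(
            Region("fx", ((1, 4), (1, 4), (1, 3)), amp_aware=1.0, amp_unaware=0.4,
                   amp_correct=0.2),
        ),
    )
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=4)
    out = classify_trials(small_sequence, resp)
    bold = simulate_bold(small_sequence, out, neuro, seed=0)
    design = build_design_matrix(small_sequence, out, bold.shape[3], neuro.tr_s)
    return neuro, out, bold, design


def test_noiseless_fir_recovery(noiseless_subject):
    neuro, out, bold, design = noiseless_subject
    glm = fit_glm(bold, design)
    h = neuro.true_hrf().sample(neuro.tr_s, design.n_lags)
    m = neuro.regions[0].mask(neuro.grid_shape).ravel()
    for cond, amp in ((AWARE_ERROR, 1.0), (UNAWARE_ERROR, 0.4)):
        if cond not in design.condition_slices:
            continue
        expected = amp / 100.0 * neuro.baseline * neuro.window_s * h
        got = glm.irf(cond)[m]
        np.testing.assert_allclose(got, np.broadcast_to(expected, got.shape), atol=1e-6)


def test_glm_residuals_orthogonal_to_design(noiseless_subject):
    neuro, out, bold, design = noiseless_subject
    rng = np.random.default_rng(0)
    noisy = bold + rng.normal(0, 1.0, bold.shape)
    glm = fit_glm(noisy, design)
    xtr = design.X.T @ glm.residuals
    scale = np.abs(design.X).sum(axis=0).max() * np.abs(noisy).max()
    assert np.abs(xtr).max() / scale < 1e-9


def test_intercept_only_design_recovers_mean():
    from erroraware.deconvolve import DesignMatrix

    X = np.ones((50, 1))
    design = DesignMatrix(
        X=X, labels=["intercept"], tr_s=TR, n_lags=8,
        condition_slices={}, intercept_col=0,
    )
    rng = np.random.default_rng(1)
    Y = rng.normal(10.0, 2.0, size=(50, 7))
    glm = fit_glm(Y, design)
    np.testing.assert_allclose(glm.beta0, Y.mean(axis=0), rtol=1e-12)


def test_nonfinite_voxels_masked(noiseless_subject):
    neuro, out, bold, design = noiseless_subject
    bad = bold.copy()
    bad[0, 0, 0, 10] = np.nan
    with pytest.warns(UserWarning, match="non-finite"):
        glm = fit_glm(bad, design)
    assert not glm.mask[0]
    assert np.isnan(glm.beta[:, 0]).all()


# ---------------------------------------------------------------------------
# Gamma variate
# ---------------------------------------------------------------------------


def test_gamma_auc_analytic_cases():
    assert gamma_auc(GammaHRF(A=1.0, r=0.0, b=1.0)) == pytest.approx(1.0)
    assert gamma_auc(GammaHRF(A=1.0, r=1.0, b=1.0)) == pytest.approx(1.0)
    h = GammaHRF(A=2.0, r=8.6, b=0.547)
    oracle, _ = integrate.quad(lambda t: h(np.array([t]))[0], 0, np.inf, limit=200)
    assert gamma_auc(h) == pytest.approx(oracle, rel=1e-6)


def test_gamma_fit_self_consistency():
    true = GammaHRF(A=1.0, r=8.6, b=0.547)
    irf = true.sample(TR, 8)
    fit = fit_gamma_variate(irf, TR)
    fitted = fit.hrf.sample(TR, 8)
    rel_rss = np.sum((fitted - irf) ** 2) / np.sum(irf**2)
    assert rel_rss < 1e-4  # within 1% RSS-equivalent
    assert gamma_auc(fit.hrf) == pytest.approx(gamma_auc(true), rel=0.01)
    assert fit.hrf.peak_time_s == pytest.approx(true.peak_time_s, rel=0.05)


def test_gamma_fit_all_zero_flagged():
    fit = fit_gamma_variate(np.zeros(8), TR)
    assert fit.flagged
    assert fit.hrf.A == 0.0
    assert percent_signal(gamma_auc(fit.hrf), 100.0, 17.22) == pytest.approx(0.0)


def test_gamma_fit_beats_true_curve_on_noisy_data():
    """The fitted RSS can never exceed the true curve's RSS + tolerance."""
    rng = np.random.default_rng(5)
    true = GammaHRF(A=1.5, r=8.6, b=0.547)
    t = np.arange(8) * TR
    for _ in range(10):
        irf = true(t) + rng.normal(0, 0.2, 8)
        fit = fit_gamma_variate(irf, TR)
        rss_true = np.sum((true(t) - irf) ** 2)
        assert fit.rss <= rss_true + 1e-9


def test_gamma_fit_map_matches_scalar_path():
    rng = np.random.default_rng(2)
    true = GammaHRF(A=1.0, r=9.0, b=0.5)
    irfs = true(np.arange(8) * TR)[None, :] + rng.normal(0, 0.05, (20, 8))
    A, r, b, rss = fit_gamma_variate_map(irfs, TR)
    for i in range(0, 20, 5):
        single = fit_gamma_variate(irfs[i], TR, polish=True)
        assert rss[i] == pytest.approx(single.rss, rel=1e-2, abs=1e-8)


def test_gamma_fit_requires_enough_lags():
    with pytest.raises(ValueError):
        fit_gamma_variate(np.ones(3), TR)


# ---------------------------------------------------------------------------
# Percent signal
# ---------------------------------------------------------------------------


def test_percent_signal_arithmetic():
    assert percent_signal(0.0, 100.0, 17.22) == pytest.approx(0.0)
    assert percent_signal(17.22, 100.0, 17.22) == pytest.approx(1.0)
    assert np.isnan(percent_signal(1.0, 0.0, 17.22))
    assert np.isnan(percent_signal(1.0, -5.0, 17.22))


def test_noiseless_end_to_end_percent_area(noiseless_subject):
    neuro, out, bold, design = noiseless_subject
    maps, glm = activation_maps(bold, design, window_s=neuro.window_s)
    m = neuro.regions[0].mask(neuro.grid_shape)
    for cond, amp in ((AWARE_ERROR, 1.0), (UNAWARE_ERROR, 0.4)):
        if cond not in maps:
            continue
        np.testing.assert_allclose(maps[cond][m], amp, atol=0.05)
        outside = maps[cond][~m]
        np.testing.assert_allclose(outside, 0.0, atol=1e-6)
    # ROI-level estimate is exact in the noiseless case
    est = roi_activation(glm, m, window_s=neuro.window_s)
    assert est[AWARE_ERROR] == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# Smoothing and smoothness estimation
# ---------------------------------------------------------------------------


def test_smooth_zero_fwhm_is_identity():
    rng = np.random.default_rng(0)
    vol = rng.normal(size=(10, 10, 8))
    np.testing.assert_array_equal(smooth_volume(vol, 0.0, 3.0), vol)


def test_smooth_constant_volume_unchanged():
    vol = np.full((10, 10, 8), 3.7)
    np.testing.assert_allclose(smooth_volume(vol, 6.0, 3.0), vol, rtol=1e-12)


def test_smooth_negative_fwhm_rejected():
    with pytest.raises(ValueError):
        smooth_volume(np.zeros((4, 4, 4)), -1.0, 3.0)


def test_smoothed_delta_has_requested_fwhm():
    """Measure the FWHM of the impulse response on a fine 1-mm grid."""
    vol = np.zeros((81, 81, 81))
    vol[40, 40, 40] = 1.0
    sm = smooth_volume(vol, fwhm_mm=8.0, voxel_mm=1.0)
    profile = sm[:, 40, 40]
    half = profile.max() / 2.0
    above = np.flatnonzero(profile >= half)
    # linear interpolation at the half-maximum crossings
    lo, hi = above[0], above[-1]
    f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)
    width = f(hi, hi + 1) - f(lo, lo - 1)
    assert width == pytest.approx(8.0, rel=0.05)


def test_fwhm_white_noise_near_zero():
    rng = np.random.default_rng(3)
    res = rng.standard_normal((24, 24, 18, 4))
    est = estimate_fwhm(res, voxel_mm=3.0)
    assert est.geometric_mean < 0.5 * 3.0


def test_fwhm_recovers_applied_smoothness():
    rng = np.random.default_rng(4)
    vols = []
    for _ in range(4):
        vols.append(smooth_volume(rng.standard_normal((24, 24, 18)), 6.0, 3.0, mode="wrap"))
    est = estimate_fwhm(np.stack(vols, axis=-1), voxel_mm=3.0)
    assert est.geometric_mean == pytest.approx(6.0, rel=0.15)


def test_fwhm_constant_map_inestimable():
    with pytest.warns(UserWarning, match="inestimable"):
        est = estimate_fwhm(np.ones((8, 8, 8)), voxel_mm=3.0)
    assert np.isnan(est.geometric_mean)


def test_fwhm_rho_matches_direct_autocorrelation_oracle():
    """The lag-1 spatial correlation implied by the reported FWHM equals a
    from-scratch loop computation of 1 - var(diff)/(2 var)."""
    rng = np.random.default_rng(5)
    vol = smooth_volume(rng.standard_normal((12, 12, 10)), 5.0, 3.0, mode="wrap")
    est = estimate_fwhm(vol, voxel_mm=3.0)
    for axis in range(3):
        diffs = []
        moved = np.moveaxis(vol, axis, 0)
        for i in range(moved.shape[0] - 1):
            diffs.extend((moved[i + 1] - moved[i]).ravel().tolist())
        rho_oracle = 1.0 - np.var(diffs) / (2.0 * np.var(vol))
        fwhm_oracle = 3.0 * np.sqrt(2 * np.log(2) / (-np.log(rho_oracle)))
        assert est.fwhm_mm[axis] == pytest.approx(fwhm_oracle, abs=1e-10)
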