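"""Synthetic cohort generator: behavior boundaries, traits, BOLD forward model."""

import json

import numpy as np
import pytest
from scipy import stats

from erroraware.classify import classify_trials
from erroraware.cohort import (
    TRAIT_NAMES,
    BehaviorParams,
    NeuroParams,
    Region,
    TraitParams,
    simulate_bold,
    simulate_cohort,
    simulate_responses,
    simulate_traits,
)
from erroraware.task import TaskConfig, generate_sequence


def test_perfect_inhibition_means_no_presses_on_nogo(small_sequence):
    resp = simulate_responses(small_sequence, BehaviorParams(p_inhibit=1.0), seed=0)
    nogo = small_sequence.is_nogo
    assert all(resp.button[i] == "none" for i in np.flatnonzero(nogo))
    assert "right" not in resp.button  # no errors -> no awareness presses


def test_no_awareness_means_left_press_after_every_error(small_sequence):
    resp = simulate_responses(
        small_sequence, BehaviorParams(p_inhibit=0.3, p_aware=0.0, p_omission=0.0), seed=1
    )
    n = len(small_sequence)
    for i in np.flatnonzero(small_sequence.is_nogo):
        if resp.button[i] != "none" and i + 1 < n:
            assert resp.button[i + 1] == "left"
    assert "right" not in resp.button


def test_cohort_rates_match_binomial_oracle(default_sequence):
    """Empirical inhibition and awareness converge on the generative rates."""
    params = BehaviorParams()
    inh, aware = [], []
    n_subj = 150
    for s in range(n_subj):
        resp = simulate_responses(default_sequence, params, seed=s)
        out = classify_trials(default_sequence, resp)
        n_err = out.summary["aware_error"] + out.summary["unaware_error"]
        inh.append(out.summary["correct_inhibition"] / out.summary["n_nogo"])
        if n_err:
            aware.append(out.summary["aware_error"] / n_err)
    # binomial sampling bound: 3 * SE of the cohort mean
    se_inh = np.std(inh, ddof=1) / np.sqrt(len(inh))
    se_aw = np.std(aware, ddof=1) / np.sqrt(len(aware))
    assert abs(np.mean(inh) - params.p_inhibit) < 3 * se_inh + 1e-9
    assert abs(np.mean(aware) - params.p_aware) < 3 * se_aw + 1e-9


def test_rt_profile_matches_targets(default_sequence):
    params = BehaviorParams()
    rts = []
    for s in range(40):
        resp = simulate_responses(default_sequence, params, seed=1000 + s)
        go_left = [
            resp.rt_ms[i]
            for i in np.flatnonzero(~default_sequence.is_nogo)
            if resp.button[i] == "left"
        ]
        rts.append(np.mean(go_left))
    assert np.mean(rts) == pytest.approx(params.go_rt_mean_ms, abs=10.0)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def test_traits_shape_and_names():
    df, mask = simulate_traits(50, TraitParams(), np.zeros(50), seed=0)
    assert list(df.columns) == list(TRAIT_NAMES)
    assert df.shape == (50, 22)
    assert mask.shape == (50, 22)


def test_null_effects_give_null_correlations():
    rng = np.random.default_rng(0)
    outcome = rng.standard_normal(400)
    df, _ = simulate_traits(400, TraitParams(mcar_rate=0.0), outcome, seed=1)
    # under the null, |r| stays within the 99.9% sampling band ~ 3.3/sqrt(n)
    for name in TRAIT_NAMES:
        r = np.corrcoef(df[name], outcome)[0, 1]
        assert abs(r) < 3.3 / np.sqrt(400)


def test_planted_effect_recovered_within_fisher_bound():
    rng = np.random.default_rng(2)
    outcome = rng.standard_normal(400)
    beta = 0.5
    df, _ = simulate_traits(
        400,
        TraitParams(mcar_rate=0.0, true_effects={"HADS—depression": beta}),
        outcome,
        seed=3,
    )
    r = np.corrcoef(df["HADS—depression"], outcome)[0, 1]
    # Fisher-z sampling bound: 3 SE around atanh(beta)
    z_err = abs(np.arctanh(r) - np.arctanh(beta))
    assert z_err < 3.0 / np.sqrt(400 - 3)


def test_mcar_count_within_binomial_interval():
    df, mask = simulate_traits(400, TraitParams(mcar_rate=0.05), np.zeros(400), seed=4)
    n_missing = int(mask.any(axis=1).sum())
    lo, hi = stats.binom.interval(0.99, 400, 0.05)
    assert lo <= n_missing <= hi
    assert df.isna().any(axis=1).sum() == n_missing


def test_invalid_trait_params_rejected():
    with pytest.raises(ValueError):
        TraitParams(mcar_rate=1.5).validate()
    with pytest.raises(ValueError):
        TraitParams(true_effects={"not a subscale": 0.3}).validate()
    with pytest.raises(ValueError):
        simulate_traits(10, TraitParams(rho_within=-0.9, rho_between=0.8),
                        np.zeros(10), seed=0)


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_neuro():
    return NeuroParams(
        grid_shape=(8, 8, 6),
        regions=(
            Region("fx", ((2, 5), (2, 5), (2, 4)), amp_aware=1.0, amp_unaware=0.4),
        ),
    )


def test_zero_signal_run_is_baseline_plus_drift(small_sequence, tiny_neuro):
    from dataclasses import replace

    params = replace(tiny_neuro, noise_sd=0.0, regions=())
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=0)
    out = classify_trials(small_sequence, resp)
    bold = simulate_bold(small_sequence, out, params, seed=1)
    # baseline + drift only: removing the per-voxel temporal mean leaves a
    # low-order polynomial; projecting onto the drift basis must be exact
    from numpy.polynomial import legendre

    nt = bold.shape[3]
    x = np.linspace(-1, 1, nt)
    basis = np.column_stack(
        [np.ones(nt)]
        + [legendre.legval(x, np.eye(q + 1)[q]) for q in range(1, 4)]
    )
    flat = bold.reshape(-1, nt).T
    resid = flat - basis @ np.linalg.lstsq(basis, flat, rcond=None)[0]
    assert np.abs(resid).max() < 1e-8


def test_noiseless_run_reproducible_from_ground_truth(small_sequence, tiny_neuro):
    from dataclasses import replace

    params = replace(tiny_neuro, noise_sd=0.0, drift_amp=0.0)
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=3)
    out = classify_trials(small_sequence, resp)
    a = simulate_bold(small_sequence, out, params, seed=9)
    b = simulate_bold(small_sequence, out, params, seed=10)  # seed irrelevant
    assert np.abs(a - b).max() < 1e-8


def test_masks_outside_grid_rejected(small_sequence):
    bad = NeuroParams(
        grid_shape=(8, 8, 6), regions=(Region("off", ((2, 9), (0, 2), (0, 2))),)
    )
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=0)
    out = classify_trials(small_sequence, resp)
    with pytest.raises(ValueError):
        simulate_bold(small_sequence, out, bad, seed=0)


def test_overlapping_regions_rejected():
    p = NeuroParams(
        grid_shape=(8, 8, 6),
        regions=(
            Region("a", ((0, 4), (0, 4), (0, 4))),
            Region("b", ((2, 6), (2, 6), (2, 6))),
        ),
    )
    with pytest.raises(ValueError):
        p.validate()


def test_noise_sd_and_ar1_realized(small_sequence, tiny_neuro):
    from dataclasses import replace

    params = replace(tiny_neuro, regions=(), drift_amp=0.0, ar1_rho=0.5,
                     smooth_fwhm_mm=0.0, noise_sd=2.0)
    resp = simulate_responses(small_sequence, BehaviorParams(), seed=0)
    out = classify_trials(small_sequence, resp)
    bold = simulate_bold(small_sequence, out, params, seed=5)
    noise = bold - 100.0
    assert noise.std() == pytest.approx(2.0, rel=0.02)
    flat = noise.reshape(-1, noise.shape[3])
    rho = np.mean(
        [np.corrcoef(v[:-1], v[1:])[0, 1] for v in flat[::16]]
    )
    assert rho == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# Cohort on disk
# ---------------------------------------------------------------------------


def test_cohort_smoke_roundtrip(tmp_path, small_config):
    neuro = NeuroParams(grid_shape=(8, 8, 6), regions=())
    truth = simulate_cohort(
        2, tmp_path / "c", seed=1, task=small_config, neuro=neuro
    )
    assert truth["n_subjects"] == 2
    from erroraware.pipeline import load_cohort

    seq, truth2, subs = load_cohort(tmp_path / "c")
    assert len(subs) == 2
    assert len(seq) == small_config.n_trials
    from erroraware.io import load_nifti

    data, _, voxel_mm, tr = load_nifti(subs[0] / "bold.nii.gz")
    assert data.shape[:3] == (8, 8, 6)
    assert voxel_mm == pytest.approx(3.0)
    assert tr == pytest.approx(2.46, abs=1e-6)


def test_cohort_ground_truth_deterministic(tmp_path, small_config):
    neuro = NeuroParams(grid_shape=(6, 6, 4), regions=())
    for d in ("a", "b"):
        simulate_cohort(
            2, tmp_path / d, seed=42, task=small_config, neuro=neuro, write_bold=False
        )
    ja = (tmp_path / "a" / "ground_truth.json").read_bytes()
    jb = (tmp_path / "b" / "ground_truth.json").read_bytes()
    assert ja == jb
    ea = (tmp_path / "a" / "events.tsv").read_bytes()
    eb = (tmp_path / "b" / "events.tsv").read_bytes()
    assert ea == eb
    json.loads(ja)  # valid JSON
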