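"""Deconvolution regression: design expansion, estimation, CV and comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from melotrf.note_io import NoteEvent, NoteSequence
from melotrf.synthetic_data import (
    MelodyGenConfig,
    NeuralSimConfig,
    default_trf_kernel,
    generate_melody,
    simulate_neural,
)
from melotrf.feature_regressors import to_impulse_regressors
from melotrf.trf_core import (
    CVResult,
    DesignMatrix,
    ImpulseRegressors,
    NeuralRecording,
    bandpass,
    compare_models,
    cv_predictive_r,
    fit_ols,
    fit_ridge,
    holm_adjust,
    select_channels,
    time_expand,
)

SRATE = 60.0


def standard_sim(n_notes=200, noise_sd=0.0, seed=0, n_channels=3):
    rng = np.random.default_rng(seed + 500)
    cfg = MelodyGenConfig(n_notes=n_notes, seed=seed, tempo=3.0)
    seq = generate_melody(cfg)
    s = rng.normal(size=n_notes)
    driver = {"onset": np.ones(n_notes), "surprise": (s - s.mean()) / s.std()}
    sim = NeuralSimConfig(
        n_channels=n_channels, srate=SRATE, noise_sd=noise_sd, seed=seed,
        channel_gains=np.ones(n_channels),
    )
    rec, truth = simulate_neural(seq, driver, sim)
    tab = pd.DataFrame({"onset_time": seq.onsets, **driver})
    regs = to_impulse_regressors(
        tab, SRATE, rec.n_samples, columns=list(driver)
    )
    return rec, truth, regs


# ---------------------------------------------------------------------------
# bandpass
# ---------------------------------------------------------------------------


def frequency_gain(freq):
    n = int(60 * SRATE)
    t = np.arange(n) / SRATE
    x = np.sin(2 * np.pi * freq * t)
    rec = NeuralRecording(x[None, :], SRATE)
    out = bandpass(rec, 0.5, 8.0).data[0]
    core = slice(n // 4, 3 * n // 4)  # avoid filter edges
    return out[core].std() / x[core].std()


def test_bandpass_dc_removed():
    rec = NeuralRecording(np.full((1, 3600), 5.0), SRATE)
    out = bandpass(rec, 0.5, 8.0).data[0]
    assert np.abs(out[900:2700]).max() < 0.05


def test_bandpass_passband_and_stopband():
    assert 0.9 < frequency_gain(4.0) < 1.1
    assert frequency_gain(20.0) < 0.1


def test_bandpass_invalid_band():
    rec = NeuralRecording(np.zeros((1, 100)), SRATE)
    with pytest.raises(ValueError):
        bandpass(rec, 8.0, 0.5)


def test_bandpass_dilates_bad_mask():
    bad = np.zeros(3600, dtype=bool)
    bad[1800] = True
    rec = NeuralRecording(np.zeros((1, 3600)), SRATE, bad_mask=bad)
    out = bandpass(rec, 0.5, 8.0)
    assert out.bad_mask.sum() > 100  # edge dilation around the bad sample


# ---------------------------------------------------------------------------
# time expansion
# ---------------------------------------------------------------------------


def test_lag_column_counts():
    regs = ImpulseRegressors(np.zeros((600, 1)), ["x"], SRATE)
    M = time_expand(regs, -0.2, 1.0)
    assert M.n_lags == 73
    regs10 = ImpulseRegressors(np.zeros((100, 1)), ["x"], 10.0)
    assert time_expand(regs10, 0.0, 0.5).n_lags == 6


def test_time_expansion_is_convolution():
    """Design @ kernel equals the convolution of the impulse train."""
    rng = np.random.default_rng(1)
    n = 400
    train = np.zeros(n)
    train[[50, 120, 200, 310]] = rng.normal(size=4)
    regs = ImpulseRegressors(train[:, None], ["x"], SRATE)
    M = time_expand(regs, -0.2, 1.0)
    kernel = rng.normal(size=M.n_lags)
    produced = M.matrix @ kernel
    lag0 = round(-0.2 * SRATE)
    full = np.convolve(train, kernel)
    expected = full[-lag0 : -lag0 + n]
    np.testing.assert_allclose(produced, expected, atol=1e-12)


def test_lag_span_longer_than_recording_raises():
    regs = ImpulseRegressors(np.zeros((30, 1)), ["x"], SRATE)
    with pytest.raises(ValueError, match="lag span"):
        time_expand(regs, -0.2, 1.0)


# ---------------------------------------------------------------------------
# OLS / ridge estimation
# ---------------------------------------------------------------------------


def test_ols_recovers_kernels_noiselessly():
    rec, truth, regs = standard_sim(noise_sd=0.0)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    trf = fit_ols(M, rec)
    for name in ("onset", "surprise"):
        assert np.abs(trf.kernel(name).T - truth[name]).max() < 1e-8


def test_ols_identity_regressor():
    """y equal to an unshifted regressor gives beta = 1 at lag 0 only."""
    rng = np.random.default_rng(2)
    train = np.zeros(500)
    train[rng.choice(500, 30, replace=False)] = rng.normal(size=30)
    regs = ImpulseRegressors(train[:, None], ["x"], SRATE)
    M = time_expand(regs, -0.2, 0.5, None)
    rec = NeuralRecording(train[None, :], SRATE)
    trf = fit_ols(M, rec)
    k = trf.kernel("x")[:, 0]
    lag0_idx = int(np.where(M.lag_samples == 0)[0][0])
    assert k[lag0_idx] == pytest.approx(1.0, abs=1e-8)
    k[lag0_idx] = 0.0
    assert np.abs(k).max() < 1e-8


def test_duplicated_column_raises_rank_error():
    rec, _, regs = standard_sim(n_notes=100)
    dup = ImpulseRegressors(
        np.column_stack([regs.matrix, regs.matrix[:, 0]]),
        regs.names + ["onset_copy"],
        SRATE,
    )
    M = time_expand(dup, -0.2, 1.0, rec.bad_mask)
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
        fit_ols(M, rec)
    trf = fit_ols(M, rec, allow_rank_deficient=True)  # pseudo-inverse mode
    assert trf.method == "ols-pinv"


def test_ridge_alpha_zero_equals_ols():
    rec, _, regs = standard_sim(n_notes=120, noise_sd=0.5)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    ols = fit_ols(M, rec)
    ridge = fit_ridge(M, rec, alphas=(0.0,))
    np.testing.assert_allclose(ridge.coefficients, ols.coefficients, atol=1e-7)


def test_ridge_large_alpha_shrinks_to_zero():
    from melotrf.trf_core import _ridge_beta

    rec, _, regs = standard_sim(n_notes=120, noise_sd=0.5)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    ols = fit_ols(M, rec)
    use = M.valid
    beta_huge = _ridge_beta(M.matrix[use], rec.data[:, use].T, 1e12)[1:]
    assert np.abs(beta_huge).max() < 1e-3 * np.abs(ols.coefficients).max()


def test_ridge_requires_alpha_zero():
    rec, _, regs = standard_sim(n_notes=100)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    with pytest.raises(ValueError, match="include 0"):
        fit_ridge(M, rec, alphas=(1.0,))


# ---------------------------------------------------------------------------
# cross-validated prediction
# ---------------------------------------------------------------------------


def test_cv_r_noiseless_near_one():
    rec, _, regs = standard_sim(noise_sd=0.0)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    cv = cv_predictive_r(M, rec)
    assert cv.summary_r() > 0.99


def test_cv_r_null_centered_on_zero():
    vals = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        rec, _, regs = standard_sim(n_notes=80, noise_sd=0.0, seed=seed, n_channels=1)
        rec = NeuralRecording(
            rng.standard_normal(rec.data.shape), SRATE, rec.bad_mask
        )
        M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
        vals.append(cv_predictive_r(M, rec).summary_r())
    assert abs(np.mean(vals)) < 0.02


def test_cv_duplicated_channels_identical():
    rec, _, regs = standard_sim(n_notes=120, noise_sd=1.0, n_channels=1)
    two = NeuralRecording(np.vstack([rec.data, rec.data]), SRATE, rec.bad_mask)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    cv = cv_predictive_r(M, two)
    np.testing.assert_array_equal(cv.r[:, 0], cv.r[:, 1])


def test_cv_never_uses_test_rows_in_fitting():
    """Mutating a fold's held-out samples must leave that fold's fitted
    coefficients (and training z-scoring statistics) unchanged."""
    rec, _, regs = standard_sim(n_notes=120, noise_sd=0.5, n_channels=1)
    M = time_expand(regs, -0.2, 1.0, rec.bad_mask)
    _, betas1 = cv_predictive_r(M, rec, return_betas=True)
    corrupted = rec.data.copy()
    n = rec.n_samples
    corrupted[:, : n // 5] = 1e3  # fold 0's test block
    _, betas2 = cv_predictive_r(
        M, NeuralRecording(corrupted, SRATE, rec.bad_mask), return_betas=True
    )
    np.testing.assert_allclose(betas1[0], betas2[0], atol=1e-10)


# ---------------------------------------------------------------------------
# channel selection and model comparison
# ---------------------------------------------------------------------------


def test_select_channels_top_third():
    r = np.tile(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]), (5, 1))
    cv = CVResult(r=r, channel_ids=[f"c{i}" for i in range(6)])
    sel = select_channels(cv)
    assert sel.sum() == 2
    assert sel[-2:].all()


def test_select_channels_tie_falls_back_to_all():
    cv = CVResult(r=np.full((5, 4), 0.3), channel_ids=list("abcd"))
    with pytest.warns(UserWarning, match="no channels"):
        sel = select_channels(cv)
    assert sel.all()


def test_select_channels_order_invariant():
    rng = np.random.default_rng(3)
    r = rng.uniform(0, 0.5, size=(5, 6))
    cv = CVResult(r=r, channel_ids=[f"c{i}" for i in range(6)])
    perm = rng.permutation(6)
    cv_perm = CVResult(r=r[:, perm], channel_ids=[f"c{i}" for i in perm])
    np.testing.assert_array_equal(select_channels(cv)[perm], select_channels(cv_perm))


def test_holm_matches_textbook_definition():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 0.2, size=7)
    adj = holm_adjust(p)
    # brute-force step-down on the sorted vector
    order = np.argsort(p)
    m = len(p)
    expected = np.empty(m)
    run = 0.0
    for i, idx in enumerate(order):
        run = max(run, (m - i) * p[idx])
        expected[idx] = min(1.0, run)
    np.testing.assert_allclose(adj, expected)
    # cross-check against the reference implementation
    from statsmodels.stats.multitest import multipletests

    _, adj_sm, *_ = multipletests(p, method="holm")
    np.testing.assert_allclose(adj, adj_sm, atol=1e-12)


def test_compare_identical_models_degenerate():
    r = np.tile(np.linspace(0.1, 0.3, 4), (5, 1))
    cvs = [CVResult(r=r, channel_ids=list("abcd")) for _ in range(4)]
    out = compare_models({"a": cvs, "b": cvs}, pairs=[("a", "b")])
    assert out.loc[0, "mean_delta_r"] == 0.0
    assert out.loc[0, "t"] == 0.0


def test_compare_detects_true_difference():
    rng = np.random.default_rng(5)
    base = [
        CVResult(r=rng.normal(0.1, 0.01, (5, 3)), channel_ids=list("abc"))
        for _ in range(10)
    ]
    better = [
        CVResult(r=rng.normal(0.15, 0.01, (5, 3)), channel_ids=list("abc"))
        for _ in range(10)
    ]
    out = compare_models({"better": better, "base": base}, pairs=[("better", "base")])
    assert out.loc[0, "mean_delta_r"] > 0.03
    assert out.loc[0, "p_holm"] < 0.01
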