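"""VAR fitting, Granger causality, condition contrast and the standardized
statistic — checked against a closed-form oracle for known VAR(1) systems."""

import numpy as np
import pytest
from scipy import linalg

from catring.connectivity import (
    condition_gc,
    condition_gc_table,
    fit_var,
    granger,
    standardized_gc,
)
from catring.synthetic import SyntheticConfig, generate_experiment
from conftest import small_config


def simulate_var1(a, n, rng, burn=200):
    """x_t = A x_{t-1} + eps_t with unit innovations."""
    a = np.asarray(a, float)
    x = np.zeros(2)
    out = np.empty((n + burn, 2))
    for t in range(n + burn):
        x = a @ x + rng.standard_normal(2)
        out[t] = x
    return out[burn:, 0], out[burn:, 1]


def analytic_gc(a):
    """Closed-form GC(x->y) and GC(y->x) for a stationary VAR(1) with unit
    innovation covariance, via the discrete Lyapunov stationary covariance.

    The full-model residual variance is the innovation variance (1); the
    restricted one is the prediction error of a series from its own lag:
    Var(z_t) - Cov(z_t, z_{t-1})^2 / Var(z_{t-1}).
    """
    a = np.asarray(a, float)
    sigma = linalg.solve_discrete_lyapunov(a, np.eye(2))
    lag1 = a @ sigma
    out = []
    for i in (1, 0):  # y for x->y, x for y->x
        resid_r = sigma[i, i] - lag1[i, i] ** 2 / sigma[i, i]
        out.append(np.log(resid_r / 1.0))
    return tuple(out)  # (gc_xy, gc_yx)


def test_white_noise_has_near_zero_cross_coefficients():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(5000), rng.standard_normal(5000)
    fit = fit_var(x, y, order=1)
    # coef layout: [intercept, x lags, y lags]
    assert abs(fit.coef_y[1]) < 0.05  # x -> y cross coefficient
    assert abs(fit.coef_x[2]) < 0.05  # y -> x cross coefficient
    gc_xy, gc_yx = granger(fit)
    assert gc_xy < 0.01 and gc_yx < 0.01


def test_cross_coefficient_recovered_consistently():
    rng = np.random.default_rng(1)
    x, y = simulate_var1([[0.0, 0.0], [0.9, 0.0]], 20000, rng)
    fit = fit_var(x, y, order=1)
    assert fit.coef_y[1] == pytest.approx(0.9, abs=0.02)


def test_restricted_variance_never_below_full():
    rng = np.random.default_rng(2)
    for _ in range(5):
        x, y = simulate_var1([[0.4, 0.1], [0.3, 0.2]], 500, rng)
        fit = fit_var(x, y, order=1)
        assert fit.sigma_restricted[0] >= fit.sigma_full[0] - 1e-12
        assert fit.sigma_restricted[1] >= fit.sigma_full[1] - 1e-12


def test_gc_matches_analytic_oracle_for_known_var():
    """Estimated GC within 3 Monte-Carlo SEs of the closed-form value."""
    a = [[0.3, 0.0], [0.5, 0.3]]
    want_xy, want_yx = analytic_gc(a)
    rng = np.random.default_rng(3)
    reps = 8
    est = np.array([granger(fit_var(*simulate_var1(a, 5000, rng), order=1))
                    for _ in range(reps)])
    se = est.std(axis=0, ddof=1) / np.sqrt(reps)
    assert abs(est[:, 0].mean() - want_xy) < 3 * se[0]
    assert abs(est[:, 1].mean() - want_yx) < 3 * max(se[1], 1e-4) + 2.0 / 5000
    assert want_yx == pytest.approx(0.0, abs=1e-12)
    assert want_xy > 0.1


def test_gc_invariant_to_positive_rescaling():
    rng = np.random.default_rng(4)
    x, y = simulate_var1([[0.3, 0.0], [0.5, 0.3]], 2000, rng)
    g1 = granger(fit_var(x, y))
    g2 = granger(fit_var(7.5 * x, 0.2 * y))
    assert g1 == pytest.approx(g2, rel=1e-9)


def test_segment_boundaries_never_bridged():
    """Inserting a junk timepoint between segments (excluded from the
    segment index lists) does not change the fit."""
    rng = np.random.default_rng(5)
    x, y = simulate_var1([[0.3, 0.0], [0.5, 0.3]], 300, rng)
    segs = [np.arange(0, 150), np.arange(150, 300)]
    fit1 = fit_var(x, y, segments=segs)
    xj = np.insert(x, 150, 99.0)
    yj = np.insert(y, 150, -99.0)
    segs_j = [np.arange(0, 150), np.arange(151, 301)]
    fit2 = fit_var(xj, yj, segments=segs_j)
    assert granger(fit1) == pytest.approx(granger(fit2), rel=1e-12)


def test_fit_var_input_validation():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(50)
    with pytest.raises(ValueError):
        fit_var(x, x[:-1])
    with pytest.raises(ValueError):
        fit_var(x, x * np.nan)
    with pytest.raises(ValueError):
        fit_var(x[:8], x[:8], order=1)  # too short
    with pytest.raises(ValueError):
        fit_var(x, x.copy())  # duplicated series -> rank-deficient design


def test_condition_gc_counts_and_condition_effect():
    cfg = SyntheticConfig(n_subjects=1, seed=8)
    sub = generate_experiment(cfg).subjects[0]
    res = condition_gc(sub.series, "categorization")
    assert len(res) == cfg.n_runs
    # 16 trials x (7 - 2) timepoints, minus one lagged obs per segment
    df = condition_gc_table(sub.series)
    td = df[df.direction == "IPS12->V1"]
    gcc = td[td.condition == "categorization"].gc.mean()
    gcf = td[td.condition == "fixation"].gc.mean()
    assert gcc > gcf  # coupling injected during categorization only
    rev = df[df.direction == "V1->IPS12"]
    assert gcc > rev[rev.condition == "categorization"].gc.mean()
    with pytest.raises(ValueError):
        condition_gc(sub.series, "rest")


def test_condition_gc_uses_80_timepoints_per_run():
    cfg = SyntheticConfig(n_subjects=1, seed=9)
    sub = generate_experiment(cfg).subjects[0]
    run0 = sub.series.run_labels == 0
    cat = run0 & (sub.series.conditions == "categorization")
    n_trials = len(np.unique(sub.series.trial_ids[cat]))
    assert n_trials * (7 - 2) == 80


def test_directionality_recovered_across_seeds():
    hits = 0
    n = 20
    for seed in range(n):
        cfg = small_config(seed=seed)
        sub = generate_experiment(cfg).subjects[0]
        res = condition_gc(sub.series, "categorization")
        mean_xy = np.mean([r.gc_xy for r in res])
        mean_yx = np.mean([r.gc_yx for r in res])
        hits += mean_xy > mean_yx
    assert hits >= int(0.9 * n)


def test_standardized_gc_arithmetic():
    assert standardized_gc(0.03, 0.01) == pytest.approx(0.5)
    assert standardized_gc(0.02, 0.02) == 0.0
    assert standardized_gc(0.02, 0.0) == 1.0
    assert standardized_gc(-0.01, 0.02) == -1.0  # negative estimate clamped
    with pytest.raises(ValueError):
        standardized_gc(0.0, 0.0)
    with pytest.raises(ValueError):
        standardized_gc(-0.01, -0.02)
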