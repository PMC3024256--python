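"""LN cascade construction, its exactly-solvable limits, and the rate models."""

import numpy as np
import pytest

from lncascade import (
    CascadeModel,
    NoiseParams,
    RateModelParams,
    SignalParams,
    SignalTrace,
    TauEffTable,
    effective_timescale,
    exp_filter_mismatch,
    exponential_filter,
    generate_signal,
    log_frequency_grid,
    mu_for_rate,
    predict_adaptive,
    predict_linear,
    predict_ln,
    predict_nonlinear,
    predict_rate_model,
    threshold_response,
    transfer_slope,
)
from lncascade.fokker_planck import AccuracyError, FrequencyResponse


def _lorentzian(g0, tau, grid):
    return FrequencyResponse(
        freq_hz=grid, values=g0 / (1 + 2j * np.pi * grid * tau / 1000.0), mu0=0.0, sigma0=1.0
    )


# ---------------------------------------------------------------------------
# static nonlinearity
# ---------------------------------------------------------------------------


def test_nonlinearity_baseline_and_unit_slope(eif_nonlinearity):
    """F(0) is the baseline rate and F has unit slope at the origin."""
    nl = eif_nonlinearity
    assert nl(0.0) == pytest.approx(nl.nu0, rel=1e-6)
    slope = (nl(1e-3) - nl(-1e-3)) / 2e-3
    assert slope == pytest.approx(1.0, abs=1e-3)


def test_nonlinearity_silent_limit_and_monotonicity(eif_nonlinearity):
    nl = eif_nonlinearity
    assert nl(-10.0 * nl.g0 * nl.sigma0) < 1e-10
    x = np.linspace(-5 * nl.g0, 5 * nl.g0, 101)
    y = nl(x)
    assert np.all(np.diff(y) >= -1e-9)
    assert np.all(y >= 0.0)


def test_cascade_rejects_mismatched_filter(eif_filter, eif_nonlinearity):
    from dataclasses import replace

    bad = replace(eif_filter, values=eif_filter.values * 1.5)
    with pytest.raises(ValueError):
        CascadeModel(filter=bad, nonlinearity=eif_nonlinearity)


# ---------------------------------------------------------------------------
# linear / nonlinear / LN predictions
# ---------------------------------------------------------------------------


def test_zero_signal_predictions_stay_at_baseline(eif_cascade, eif_filter, eif_nonlinearity):
    sig = SignalTrace(dt=0.25, values=np.zeros(2000))
    nl = eif_nonlinearity
    np.testing.assert_allclose(predict_linear(sig, eif_filter, nl.nu0), nl.nu0)
    np.testing.assert_allclose(predict_nonlinear(sig, nl), nl.nu0, rtol=1e-6)
    np.testing.assert_allclose(predict_ln(sig, eif_cascade), nl.nu0, rtol=1e-6)


def test_linear_prediction_matches_response_for_sinusoids(
    eif_filter, eif_nonlinearity, eif_resp_uniform
):
    """Convolution theorem: a cosine input comes out scaled by |R^| and
    shifted by arg R^ (to 1% after the filter transient)."""
    nl = eif_nonlinearity
    t = np.arange(0, 4000.0, 0.25)
    for f in (10.0, 50.0):
        sig = SignalTrace(dt=0.25, values=0.5 * np.cos(2 * np.pi * f * t / 1000.0))
        pred = predict_linear(sig, eif_filter, nl.nu0)
        R = eif_resp_uniform.at(f)
        expect = nl.nu0 + 0.5 * abs(R) * np.cos(2 * np.pi * f * t / 1000.0 + np.angle(R))
        m = t > 500.0
        assert np.max(np.abs(pred[m] - expect[m])) < 0.01 * (0.5 * abs(R))


def test_linear_prediction_can_go_negative(eif_filter, eif_nonlinearity):
    """The linear estimate is not rate-bounded: strong hyperpolarising input
    drives it below zero (the known artifact the nonlinearity repairs)."""
    nl = eif_nonlinearity
    sig = SignalTrace(dt=0.25, values=np.full(4000, -8.0))
    lin = predict_linear(sig, eif_filter, nl.nu0)
    ln = predict_ln(
        sig, CascadeModel(filter=eif_filter, nonlinearity=nl)
    )
    assert lin.min() < 0.0
    assert ln.min() >= 0.0


def test_constant_signal_nonlinear_prediction_is_transfer_function(
    tf_eif, eif_nonlinearity
):
    nl = eif_nonlinearity
    sig = SignalTrace(dt=1.0, values=np.full(100, 1.7))
    pred = predict_nonlinear(sig, nl)
    np.testing.assert_allclose(pred, tf_eif.rate(nl.mu0 + 1.7, nl.sigma0), rtol=1e-5)


def test_ln_to_linear_deviation_scales_quadratically(eif_cascade, eif_filter, eif_nonlinearity):
    """max|LN - linear| shrinks ~4x when sigma_s is halved (Taylor order)."""
    devs = []
    for ss in (0.5, 0.25):
        sig = generate_signal(SignalParams(ss, 10.0), 4000.0, 0.25, seed=3)
        ln = predict_ln(sig, eif_cascade)
        lin = predict_linear(sig, eif_filter, eif_nonlinearity.nu0)
        devs.append(np.max(np.abs(ln - lin)))
    assert devs[0] / devs[1] == pytest.approx(4.0, abs=1.0)


def test_adiabatic_limit_reduces_to_pointwise_nonlinearity(eif_cascade, eif_nonlinearity):
    """For a signal much slower than the filter the cascade tracks the f-I
    curve pointwise: a sinusoid with period 100x the filter e-folding time
    agrees with the pointwise prediction within 2%."""
    tau_fold = 8.4  # e-folding time of the standard-point filter (~tau_eff)
    period = 100.0 * tau_fold
    t = np.arange(0, 3 * period, 0.25)
    sig = SignalTrace(dt=0.25, values=1.0 * np.sin(2 * np.pi * t / period))
    ln = predict_ln(sig, eif_cascade)
    adia = predict_nonlinear(sig, eif_nonlinearity)
    m = t > period
    assert np.max(np.abs(ln[m] - adia[m]) / adia[m]) < 0.02


# ---------------------------------------------------------------------------
# effective timescale and rate models
# ---------------------------------------------------------------------------


def test_effective_timescale_recovers_lorentzian_exactly():
    grid = log_frequency_grid(1.0, 1e4, 30)
    g0, tau = 4.0, 9.0
    resp = _lorentzian(g0, tau, grid)
    assert effective_timescale(resp, g0) == pytest.approx(tau, rel=0.01)
    assert exp_filter_mismatch(resp, tau, g0) < 1e-12


def test_effective_timescale_requires_flat_asymptote():
    grid = log_frequency_grid(0.1, 10.0, 20)  # far below the 1/omega regime
    with pytest.raises(AccuracyError):
        effective_timescale(_lorentzian(4.0, 9.0, grid), 4.0)


def test_tau_eff_decreases_with_rate_and_noise(tf_eif, eif_params):
    """tau_eff falls as either the baseline rate or the noise SD grows."""
    lg = log_frequency_grid(1.0, 1e4, 25)

    def tau_at(nu0, s0):
        mu = mu_for_rate(tf_eif, nu0, s0)
        g0 = transfer_slope(tf_eif, mu, s0)
        return effective_timescale(threshold_response(NoiseParams(mu, s0), eif_params, lg), g0)

    taus = {(nu, s): tau_at(nu, s) for nu in (5.0, 15.0, 45.0) for s in (2.0, 4.0, 6.0)}
    for s in (2.0, 4.0, 6.0):
        assert taus[(5.0, s)] > taus[(15.0, s)] > taus[(45.0, s)]
    for nu in (5.0, 15.0, 45.0):
        assert taus[(nu, 2.0)] > taus[(nu, 4.0)] > taus[(nu, 6.0)]


def test_rate_model_step_response_is_exact_exponential(eif_nonlinearity):
    tau_eff = 7.0
    rm = RateModelParams(tau_eff=tau_eff, nonlinearity=eif_nonlinearity)
    dt = 0.5
    n = 400
    s = np.zeros(n)
    k0 = 100
    s[k0:] = 1.3
    sig = SignalTrace(dt=dt, values=s)
    pred = predict_rate_model(sig, rm)
    # invert the nonlinearity to recover the drive u(t)
    nl = eif_nonlinearity
    t_after = (np.arange(n)[k0:] - k0 + 1) * dt
    u_expected = 1.3 * (1.0 - np.exp(-t_after / tau_eff))
    u_pred = np.array(
        [mu_for_rate(nl.tf, r, nl.sigma0) - nl.mu0 for r in pred[k0 :: 40]]
    )
    np.testing.assert_allclose(u_pred, u_expected[::40], atol=1e-6)


def test_rate_model_equals_exponential_filter_cascade(eif_nonlinearity):
    """The u-variable ODE form is the exponential-filter LN cascade: on a
    fine grid the two differ by < 0.5% everywhere."""
    nl = eif_nonlinearity
    tau_eff = 8.4
    dt = 0.05
    sig = generate_signal(SignalParams(1.5, 10.0), 3000.0, dt, seed=5)
    kexp = exponential_filter(tau_eff, nl.g0, dt, 20 * tau_eff)
    r_ode = predict_rate_model(sig, RateModelParams(tau_eff=tau_eff, nonlinearity=nl))
    r_ln = predict_ln(sig, CascadeModel(filter=kexp, nonlinearity=nl))
    m = np.arange(len(r_ode)) * dt > 5 * tau_eff
    assert np.max(np.abs(r_ode[m] - r_ln[m]) / np.abs(r_ln[m])) < 0.005


@pytest.fixture(scope="module")
def tau_table(tf_eif):
    return TauEffTable.build(tf_eif, 4.0, n_rates=12)


def test_tau_table_is_decreasing_in_rate(tau_table):
    """Faster-firing neurons respond faster: tau_eff(nu) is monotone down."""
    taus = tau_table(np.geomspace(1.0, 100.0, 30))
    assert np.all(np.diff(taus) < 0)


def test_adaptive_model_constant_input_stays_at_baseline(eif_nonlinearity, tau_table):
    sig = SignalTrace(dt=1.0, values=np.zeros(500))
    pred = predict_adaptive(sig, eif_nonlinearity, tau_table)
    np.testing.assert_allclose(pred, eif_nonlinearity.nu0, rtol=1e-4)


def test_adaptive_model_reduces_to_rate_model_for_weak_signals(
    eif_nonlinearity, tau_table
):
    """As sigma_s -> 0 the adaptive timescale stops moving and the model
    converges to the fixed-timescale rate model."""
    nl = eif_nonlinearity
    tau0 = float(tau_table(nl.nu0))
    devs = []
    for ss in (1.0, 0.5):
        sig = generate_signal(SignalParams(ss, 10.0), 3000.0, 1.0, seed=6)
        ra = predict_adaptive(sig, nl, tau_table)
        rr = predict_rate_model(sig, RateModelParams(tau_eff=tau0, nonlinearity=nl))
        devs.append(np.max(np.abs(ra - rr) / np.maximum(rr, 1e-3)))
    assert devs[1] < devs[0] / 2.0  # vanishes faster than linearly


def test_adaptive_model_speeds_up_during_depolarising_transient(
    eif_nonlinearity, tau_table
):
    """A step of drive raises the instantaneous rate, and the adaptive model
    responds faster than the fixed-timescale rate model from then on."""
    nl = eif_nonlinearity
    n, k0 = 300, 50
    s = np.zeros(n)
    s[k0:] = 4.0
    sig = SignalTrace(dt=1.0, values=s)
    ra = predict_adaptive(sig, nl, tau_table)
    r_fixed = predict_rate_model(
        sig, RateModelParams(tau_eff=float(tau_table(nl.nu0)), nonlinearity=nl)
    )
    rise = slice(k0 + 1, k0 + 10)
    assert np.all(ra[rise] >= r_fixed[rise])
    assert float(tau_table(ra[-1])) < float(tau_table(nl.nu0))
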