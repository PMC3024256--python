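"""Transfer functions, linear response, and filter inversion.

The two independent analytic routes (Siegert/bounded-branch ODE for the
LIF; generic threshold integration for both models) are cross-checked
against each other and against closed-form limits.
"""

import numpy as np
import pytest

from lncascade import (
    EIFParams,
    LIFParams,
    NoiseParams,
    FrequencyResponse,
    default_filter_grid,
    eif_transfer,
    filter_from_response,
    lif_response,
    log_frequency_grid,
    mu_for_rate,
    siegert_rate,
    threshold_response,
    transfer_slope,
)
from lncascade.fokker_planck import lif_steady_density


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def test_siegert_refractory_ceiling(lif_params):
    """Far above threshold the rate saturates at the refractory bound."""
    nu = siegert_rate(1e6, 3.0, lif_params)
    assert nu == pytest.approx(1000.0 / lif_params.tau_ref, rel=1e-3)


def test_siegert_small_noise_limit_is_deterministic_period(lif_params):
    mu = 25.0
    period = lif_params.tau_ref + lif_params.tau_m * np.log(
        (mu - lif_params.v_r) / (mu - lif_params.v_th)
    )
    assert siegert_rate(mu, 0.01, lif_params) == pytest.approx(1000.0 / period, rel=1e-2)


def test_siegert_rejects_zero_noise(lif_params):
    with pytest.raises(ValueError):
        siegert_rate(15.0, 0.0, lif_params)


def test_siegert_deep_subthreshold_does_not_overflow(lif_params):
    nu = siegert_rate(-50.0, 4.0, lif_params)
    assert 0.0 <= nu < 1e-100


@pytest.mark.parametrize("mu,sigma", [(12.0, 3.0), (15.0, 4.0), (22.0, 6.0)])
def test_lif_two_routes_agree_on_steady_rate(mu, sigma, lif_params):
    """Siegert quadrature vs threshold-integration scan: independent solvers."""
    dens = lif_steady_density(mu, sigma, lif_params)
    assert dens.nu0 == pytest.approx(siegert_rate(mu, sigma, lif_params), rel=1e-3)


def test_eif_rate_bounded_by_refractory_ceiling(eif_params):
    for mu, sigma in [(5.0, 2.0), (10.0, 4.0), (30.0, 6.0)]:
        nu = eif_transfer(mu, sigma, eif_params)
        assert 0.0 < nu <= 1000.0 / eif_params.tau_ref


def test_eif_approaches_hard_threshold_limit():
    """As delta_t -> 0 the EIF rate climbs monotonically toward the Siegert rate.

    The approach is slow; at delta_t = 0.01 mV a ~4% deficit remains
    (verified against an independent mean-first-passage-time quadrature).
    """
    lif_eq = LIFParams(tau_m=20.0, v_th=10.0, v_r=5.0, tau_ref=2.0)
    target = siegert_rate(8.0, 4.0, lif_eq)
    rates = [
        eif_transfer(8.0, 4.0, EIFParams(delta_t=d, v_t=10.0, v_r=5.0, v_ceiling=40.0), dv=0.002)
        for d in (0.5, 0.1, 0.01)
    ]
    assert rates[0] < rates[1] < rates[2] < target
    assert rates[2] == pytest.approx(target, rel=0.05)


def test_eif_steady_density_normalised(eif_noise, eif_params):
    nu, dens = eif_transfer(
        eif_noise.mu0, eif_noise.sigma0, eif_params, return_density=True
    )
    assert np.all(dens.p0 >= 0)
    mass = np.trapezoid(dens.p0, dens.v_grid) + nu / 1000.0 * eif_params.tau_ref
    assert mass == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# slope and inversion
# ---------------------------------------------------------------------------


def test_transfer_slope_against_fine_grid_oracle(lif_params):
    """Adaptive central difference vs 5-point stencil on a fine mu grid."""
    mu, sigma = 15.0, 4.0
    slope = transfer_slope(lambda m: siegert_rate(m, sigma, lif_params), mu)
    h = 0.02
    f = lambda m: siegert_rate(m, sigma, lif_params)
    stencil = (f(mu - 2 * h) - 8 * f(mu - h) + 8 * f(mu + h) - f(mu + 2 * h)) / (12 * h)
    assert slope == pytest.approx(stencil, rel=1e-3)


def test_transfer_slope_positive_and_saturating(tf_lif):
    s_mid = transfer_slope(tf_lif, 15.0, 4.0)
    s_high = transfer_slope(tf_lif, 2000.0, 4.0)
    assert s_mid > 0
    assert 0 <= s_high < 0.05 * s_mid  # refractory saturation flattens the f-I curve


def test_mu_for_rate_roundtrip_and_monotone(tf_eif):
    mu_star = 9.37
    nu = tf_eif.rate(mu_star, 4.0)
    assert mu_for_rate(tf_eif, nu, 4.0) == pytest.approx(mu_star, abs=1e-4)
    mus = [mu_for_rate(tf_eif, nu, 4.0) for nu in (2.0, 10.0, 40.0)]
    assert mus[0] < mus[1] < mus[2]
    with pytest.raises(ValueError):
        mu_for_rate(tf_eif, -1.0, 4.0)


# ---------------------------------------------------------------------------
# linear response
# ---------------------------------------------------------------------------


def test_response_conjugate_symmetry(lif_resp_uniform):
    r = lif_resp_uniform
    assert r.at(-10.0) == np.conj(r.at(10.0))
    assert np.imag(r.values[0]) == 0.0 and np.real(r.values[0]) > 0


@pytest.mark.parametrize("model", ["lif", "eif"])
def test_zero_frequency_equals_transfer_slope(model, lif_params, eif_params):
    """|R^(omega -> 0)| reaches the slope of the transfer function (to 1%)."""
    p = lif_params if model == "lif" else eif_params
    noise = NoiseParams(15.0 if model == "lif" else 8.0, 4.0)
    if model == "lif":
        slope = transfer_slope(lambda m: siegert_rate(m, noise.sigma0, p), noise.mu0)
        resp = lif_response(noise, p, np.array([0.05]))
    else:
        slope = transfer_slope(lambda m: eif_transfer(m, noise.sigma0, p), noise.mu0)
        resp = threshold_response(noise, p, np.array([0.05]))
    assert abs(resp.values[0]) == pytest.approx(slope, rel=0.01)


def test_high_frequency_decay_laws(lif_noise, lif_params, eif_noise, eif_params):
    """|R^| falls off as 1/sqrt(omega) for the LIF and 1/omega for the EIF."""
    grid = log_frequency_grid(10.0, 1e4, 25)
    s_lif = lif_response(lif_noise, lif_params, grid).loglog_slope()
    s_eif = threshold_response(eif_noise, eif_params, grid).loglog_slope()
    assert s_lif == pytest.approx(-0.5, abs=0.05)
    assert s_eif == pytest.approx(-1.0, abs=0.05)


def test_lif_adjoint_and_threshold_routes_agree(lif_noise, lif_params):
    """Two independent solvers for the same response function (within 2%)."""
    grid = np.array([1.0, 5.0, 20.0, 80.0, 300.0, 1000.0, 2000.0])
    ra = lif_response(lif_noise, lif_params, grid).values
    rt = threshold_response(lif_noise, lif_params, grid).values
    assert np.all(np.abs(ra - rt) <= 0.02 * np.abs(ra))


def test_lif_response_invariant_to_initial_scale(lif_noise, lif_params):
    """The bounded-branch ODE enters only through ratios: rescaling the
    initial condition by 10**+-3 must not change the response."""
    grid = np.array([3.0, 40.0, 400.0])
    base = lif_response(lif_noise, lif_params, grid).values
    up = lif_response(lif_noise, lif_params, grid, init_scale=1e3).values
    down = lif_response(lif_noise, lif_params, grid, init_scale=1e-3).values
    np.testing.assert_allclose(up, base, rtol=1e-9)
    np.testing.assert_allclose(down, base, rtol=1e-9)


def test_low_noise_response_oscillates_at_baseline_rate(tf_lif, lif_params):
    """For weak background noise |R^| peaks within 20% of f = nu0."""
    nu0 = 30.0
    mu = mu_for_rate(tf_lif, nu0, 1.0)
    grid = np.linspace(2.0, 120.0, 60)
    resp = lif_response(NoiseParams(mu, 1.0), lif_params, grid)
    f_peak = grid[np.argmax(np.abs(resp.values))]
    assert abs(f_peak - nu0) <= 0.2 * nu0


def test_low_rate_lif_filter_becomes_membrane_exponential(lif_params):
    """Deep subthreshold, the rate filter is proportional to e^(-t/tau_m).

    Checked by cosine similarity > 0.99 over t in [0, 3 tau_m] with the
    operating point 6 noise SDs below threshold.
    """
    sigma0 = 4.0
    noise = NoiseParams(lif_params.v_th - 6.0 * sigma0, sigma0)
    filt = filter_from_response(
        lif_response(noise, lif_params, default_filter_grid(dt=0.25, df=2.0)), dt=0.25
    )
    m = filt.times <= 3 * lif_params.tau_m
    ref = np.exp(-filt.times[m] / lif_params.tau_m)
    v = filt.values[m]
    cos = v @ ref / np.sqrt((v @ v) * (ref @ ref))
    assert cos > 0.99


# ---------------------------------------------------------------------------
# filter inversion
# ---------------------------------------------------------------------------


def _lorentzian_resp(g0, tau, grid):
    return FrequencyResponse(
        freq_hz=grid, values=g0 / (1 + 2j * np.pi * grid * tau / 1000.0), mu0=0.0, sigma0=1.0
    )


def _triangle_average_exp(t, dt, g0, tau):
    """Closed-form triangular-kernel average of (g0/tau) e^(-t/tau) theta(t)."""
    out = np.empty_like(t)
    for i, tv in enumerate(t):
        u = np.linspace(max(0.0, tv - dt), tv + dt, 801)
        w = np.maximum(0.0, 1.0 - np.abs(u - tv) / dt) / dt
        out[i] = np.trapezoid((g0 / tau) * np.exp(-u / tau) * w, u)
    return out


def test_lorentzian_filter_recovery(uniform_grid):
    """Inverse transform of g/(1+i omega tau) reproduces (g/tau) e^(-t/tau).

    Compared against the closed form seen through the declared triangular
    sampling kernel (and pointwise beyond the kernel width), within 1%.
    """
    g0, tau = 3.0, 12.0
    filt = filter_from_response(_lorentzian_resp(g0, tau, uniform_grid), dt=0.25)
    m = filt.times <= 5 * tau
    truth = _triangle_average_exp(filt.times[m], filt.dt, g0, tau)
    assert np.max(np.abs(filt.values[m] - truth)) < 0.01 * truth.max()
    point = (g0 / tau) * np.exp(-filt.times[m] / tau)
    inner = filt.times[m] >= filt.dt
    assert np.max(np.abs(filt.values[m][inner] - point[inner])) < 0.01 * point.max()
    assert filt.causality_residual < 0.01
    assert filt.integral == pytest.approx(g0, rel=1e-3)


def test_model_filters_are_causal_and_integrate_to_dc(
    lif_filter, lif_resp_uniform, eif_filter, eif_resp_uniform
):
    assert lif_filter.causality_residual < 0.01
    assert eif_filter.causality_residual < 0.01
    assert lif_filter.integral == pytest.approx(abs(lif_resp_uniform.values[0]), rel=0.01)
    assert eif_filter.integral == pytest.approx(abs(eif_resp_uniform.values[0]), rel=0.01)


def test_zero_response_gives_zero_filter(uniform_grid):
    filt = filter_from_response(
        FrequencyResponse(uniform_grid, np.zeros_like(uniform_grid, dtype=complex), 0, 1),
        dt=0.25,
    )
    assert np.all(filt.values == 0.0)
    assert filt.causality_residual == 0.0


def test_filter_inversion_grid_validation(uniform_grid):
    with pytest.raises(ValueError):
        filter_from_response(_lorentzian_resp(1.0, 5.0, np.geomspace(1, 100, 50)), dt=0.25)
    with pytest.raises(ValueError):
        filter_from_response(_lorentzian_resp(1.0, 5.0, uniform_grid), dt=0.33)
    with pytest.raises(ValueError):
        filter_from_response(_lorentzian_resp(1.0, 5.0, uniform_grid), dt=0.25, window=1e6)
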