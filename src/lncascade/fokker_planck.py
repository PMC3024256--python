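"""Steady-state transfer functions and linear rate-response functions.

Both integrate-and-fire models evolve the membrane potential V (mV, relative
to rest) according to

    tau_m dV/dt = -V + psi(V) + mu + sigma * sqrt(tau_m) * eta(t),

with eta unit-variance Gaussian white noise, psi = 0 for the leaky model
(LIF, hard threshold ``v_th``) and psi(V) = delta_t * exp((V - v_t)/delta_t)
for the exponential model (EIF, spike = divergence past ``v_ceiling``).

Two independent analytic routes are implemented:

* the LIF transfer function via the classical mean-first-passage-time
  quadrature (:func:`siegert_rate`) and the LIF rate response via upward
  integration of the bounded branch of the associated complex Hermite-type
  ODE (:func:`lif_response`);
* a generic Fokker-Planck *threshold integration* solver that integrates
  the (steady or modulated) flux/density equations over a voltage grid,
  applicable to both LIF and EIF (:func:`eif_transfer`, :func:`eif_response`,
  :func:`threshold_response`).

Agreement between the two routes, and between each route and direct
stochastic simulation, is part of the test suite.

Units: voltages mV, times ms; rates are returned in Hz and frequency grids
are plain frequencies in Hz (omega = 2 pi f).  Response values are Hz/mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit
from scipy import integrate, optimize
from scipy.interpolate import PchipInterpolator
from scipy.special import erfcx

from .neurons import EIFParams, LIFParams

__all__ = [
    "TransferFunction",
    "FrequencyResponse",
    "FilterTrace",
    "SteadyDensity",
    "siegert_rate",
    "eif_transfer",
    "transfer_slope",
    "mu_for_rate",
    "lif_response",
    "eif_response",
    "threshold_response",
    "filter_from_response",
    "default_filter_grid",
    "log_frequency_grid",
]


class AccuracyError(RuntimeError):
    """A numerical routine failed to reach its accuracy target."""


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def siegert_rate(mu: float, sigma: float, p: LIFParams) -> float:
    """Stationary LIF firing rate (Hz) under white-noise input.

    nu = 1 / ( tau_ref + tau_m * sqrt(pi) * int_{(v_r-mu)/sigma}^{(v_th-mu)/sigma}
               e^{u^2} (1 + erf u) du )

    The integrand equals erfcx(-u), which is numerically stable on the whole
    axis; for deeply subthreshold operating points (upper limit >> 1) the
    integral is evaluated by its leading asymptotics to avoid overflow.
    """
    if sigma <= 0:
        raise ValueError("siegert_rate requires sigma > 0; use the deterministic branch")
    y_th = (p.v_th - mu) / sigma
    y_r = (p.v_r - mu) / sigma
    if y_th > 12.0:
        # int e^{u^2}(1+erf u) du ~ e^{y^2}/y for y >> 1 (Kramers regime);
        # log-space evaluation keeps the tiny rate representable.
        log_int = y_th**2 - np.log(y_th)
        log_denom = np.log(p.tau_m * np.sqrt(np.pi)) + log_int
        return 1000.0 * np.exp(-log_denom)
    val, _ = integrate.quad(lambda u: erfcx(-u), y_r, y_th, limit=200)
    denom = p.tau_ref + p.tau_m * np.sqrt(np.pi) * val
    return 1000.0 / denom


@dataclass
class SteadyDensity:
    """Steady-state membrane-potential density of an IF model.

    ``p0`` is normalised so that int p0 dV + nu0 * tau_ref = 1 (the refractory
    fraction carries the missing mass).  ``j0`` is the probability flux in
    1/ms: nu0/1000 between reset and threshold, 0 below reset.
    """

    v_grid: np.ndarray
    p0: np.ndarray
    j0: np.ndarray
    nu0: float  # Hz


@njit(cache=True)
def _steady_scan(v_grid, drift, v_r_idx, D):
    """Integrate dp/dV = (A(V) p - j)/D downward from the top with unit efflux.

    Exact per-cell update for piecewise-constant A and j (the homogeneous
    solution decays in the downward direction, so the scan is stable).
    Returns the unit-flux density p~ and the flux indicator j.
    """
    n = v_grid.shape[0]
    p = np.zeros(n)
    j = np.zeros(n)
    j[-1] = 1.0
    for k in range(n - 1, 0, -1):
        jk = 1.0 if k > v_r_idx else 0.0
        j[k - 1] = 1.0 if (k - 1) >= v_r_idx else 0.0
        h = v_grid[k] - v_grid[k - 1]
        a = 0.5 * (drift[k] + drift[k - 1]) / D
        x = a * h
        if abs(x) < 1e-12:
            p[k - 1] = p[k] + jk * h / D
        else:
            e = np.exp(-x) if x < 500.0 else 0.0
            p[k - 1] = p[k] * e + (jk / (a * D)) * (1.0 - e)
        # saturate in the deep small-noise regime: a density this large
        # means the rate is zero to double precision, and letting it grow
        # further would overflow the normalisation integral
        if p[k - 1] > 1e280:
            p[k - 1] = 1e280
    return p, j


def _if_drift(v_grid: np.ndarray, mu: float, p) -> np.ndarray:
    """Drift A(V) in mV/ms for LIF or EIF parameters."""
    if isinstance(p, EIFParams):
        expo = np.minimum((v_grid - p.v_t) / p.delta_t, 60.0)
        psi = p.delta_t * np.exp(expo)
    else:
        psi = 0.0
    return (-v_grid + psi + mu) / p.tau_m


def _voltage_grid(mu: float, sigma: float, p, dv: float) -> tuple[np.ndarray, int]:
    # nodes anchored at the top with spacing exactly dv, so the computed
    # rate is a smooth function of mu (a mu-dependent grid would add tiny
    # jumps that break root-finding on the f-I curve)
    v_top = p.v_ceiling if isinstance(p, EIFParams) else p.v_th
    v_lb_raw = min(mu - 8.0 * sigma, p.v_r) - 5.0
    n = int(np.ceil((v_top - v_lb_raw) / dv)) + 1
    v_grid = v_top - dv * np.arange(n - 1, -1, -1)
    v_r_idx = int(np.argmin(np.abs(v_grid - p.v_r)))
    return v_grid, v_r_idx


def eif_transfer(
    mu: float, sigma: float, p: EIFParams, dv: float = 0.01, return_density: bool = False
):
    """Stationary EIF rate (Hz) by threshold integration of the Fokker-Planck system.

    The steady flux/density equations are integrated downward from the
    numerical spike threshold ``v_ceiling`` with unit efflux; the flux drops
    to zero below the reset, and the rate follows from normalisation
    including the refractory mass:  nu0 = 1 / (int p~ dV + tau_ref).
    """
    if sigma <= 0:
        raise ValueError("eif_transfer requires sigma > 0")
    v_grid, v_r_idx = _voltage_grid(mu, sigma, p, dv)
    drift = _if_drift(v_grid, mu, p)
    D = sigma**2 / (2.0 * p.tau_m)
    p_tilde, j = _steady_scan(v_grid, drift, v_r_idx, D)
    mass = np.trapezoid(p_tilde, v_grid)
    nu0_ms = 1.0 / (mass + p.tau_ref)
    nu0 = 1000.0 * nu0_ms
    if not return_density:
        return nu0
    p0 = p_tilde * nu0_ms
    resid = abs(np.trapezoid(p0, v_grid) + nu0_ms * p.tau_ref - 1.0)
    if resid > 1e-4:
        raise AccuracyError(
            f"steady-density normalisation residual {resid:.2e} > 1e-4; refine dv"
        )
    density = SteadyDensity(v_grid=v_grid, p0=p0, j0=j * nu0_ms, nu0=nu0)
    return nu0, density


def lif_steady_density(mu: float, sigma: float, p: LIFParams, dv: float = 0.01) -> SteadyDensity:
    """Steady-state LIF density by the same threshold-integration scan."""
    v_grid, v_r_idx = _voltage_grid(mu, sigma, p, dv)
    drift = _if_drift(v_grid, mu, p)
    D = sigma**2 / (2.0 * p.tau_m)
    p_tilde, j = _steady_scan(v_grid, drift, v_r_idx, D)
    mass = np.trapezoid(p_tilde, v_grid)
    nu0_ms = 1.0 / (mass + p.tau_ref)
    return SteadyDensity(v_grid=v_grid, p0=p_tilde * nu0_ms, j0=j * nu0_ms, nu0=1000.0 * nu0_ms)


# ---------------------------------------------------------------------------
# Transfer-function wrapper
# ---------------------------------------------------------------------------


@dataclass
class TransferFunction:
    """Evaluator of the stationary rate Phi(mu, sigma) for one neuron model.

    Phi is continuous and strictly increasing in mu at fixed sigma > 0,
    bounded by the refractory ceiling 1000/tau_ref Hz.  A monotone (PCHIP)
    interpolation table in mu is cached per sigma for fast vectorised
    evaluation and for inversion.
    """

    kind: str  # "lif" | "eif"
    params: object
    dv: float = 0.01
    _tables: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("lif", "eif"):
            raise ValueError(f"unknown transfer-function kind {self.kind!r}")

    @property
    def ceiling(self) -> float:
        tr = self.params.tau_ref
        return np.inf if tr == 0 else 1000.0 / tr

    def rate(self, mu: float, sigma: float) -> float:
        """Exact (quadrature / threshold-integration) evaluation, scalar."""
        if self.kind == "lif":
            return siegert_rate(mu, sigma, self.params)
        return eif_transfer(mu, sigma, self.params, dv=self.dv)

    __call__ = rate

    def table(self, sigma: float, mu_lo: float, mu_hi: float, n: int = 200):
        """Monotone interpolant of mu -> Phi(mu, sigma) covering [mu_lo, mu_hi]."""
        key = round(float(sigma), 12)
        tab = self._tables.get(key)
        if tab is None or mu_lo < tab[0] or mu_hi > tab[1]:
            lo = mu_lo - 0.1 * (mu_hi - mu_lo) - 1e-9
            hi = mu_hi + 0.1 * (mu_hi - mu_lo) + 1e-9
            grid = np.linspace(lo, hi, n)
            vals = np.array([self.rate(m, sigma) for m in grid])
            vals = np.maximum.accumulate(vals)  # guard against quadrature jitter
            self._tables[key] = (lo, hi, PchipInterpolator(grid, vals))
            tab = self._tables[key]
        return tab[2]

    def rate_interp(self, mu: np.ndarray, sigma: float) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        interp = self.table(sigma, float(mu.min()), float(mu.max()))
        return np.maximum(interp(mu), 0.0)


def transfer_slope(
    tf: TransferFunction | Callable[[float], float],
    mu: float,
    sigma: float | None = None,
    rel_tol: float = 1e-4,
) -> float:
    """Slope dPhi/dmu (Hz/mV) by adaptively-refined central differences.

    The step starts at 0.1 mV and is halved (with 4th-order Richardson
    combination of the two central estimates) until the estimate changes by
    less than ``rel_tol`` relatively.
    """
    if isinstance(tf, TransferFunction):
        f = lambda m: tf.rate(m, sigma)
    else:
        f = tf
    h = 0.1
    prev = (f(mu + h) - f(mu - h)) / (2 * h)
    for _ in range(12):
        h /= 2.0
        cur = (f(mu + h) - f(mu - h)) / (2 * h)
        rich = (4.0 * cur - prev) / 3.0
        if abs(cur - prev) <= rel_tol * max(abs(rich), 1e-12):
            return rich
        prev = cur
    raise AccuracyError("transfer_slope: finite-difference step refinement did not converge")


def mu_for_rate(
    tf: TransferFunction, nu_target: float, sigma: float, rel_tol: float = 1e-6
) -> float:
    """Invert Phi(mu, sigma) = nu_target for mu (Brent bracketing).

    Valid because the f-I curves of all models handled here are continuous
    and strictly increasing in mu.
    """
    if not (0.0 < nu_target < tf.ceiling):
        raise ValueError(f"target rate {nu_target} Hz outside achievable range")
    f = lambda m: tf.rate(m, sigma) - nu_target
    lo, hi = -20.0, 40.0
    while f(hi) < 0 and hi < 400.0:
        hi += 40.0
    while f(lo) > 0 and lo > -400.0:
        lo -= 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"could not bracket rate {nu_target} Hz")
    mu = optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    if abs(tf.rate(mu, sigma) - nu_target) > rel_tol * nu_target:
        raise AccuracyError("mu_for_rate: residual above tolerance")
    return mu


# ---------------------------------------------------------------------------
# Frequency-domain linear response
# ---------------------------------------------------------------------------


@dataclass
class FrequencyResponse:
    """Complex rate response R^(omega) on a frequency grid (Hz -> Hz/mV).

    Stored for f >= 0 only; R^(-omega) = conj(R^(omega)) by reality of the
    time-domain filter.  R^(0) is real and equals the transfer-function
    slope dPhi/dmu.
    """

    freq_hz: np.ndarray
    values: np.ndarray
    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.freq_hz.shape != self.values.shape:
            raise ValueError("freq/value shape mismatch")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies in rad/s."""
        return 2.0 * np.pi * self.freq_hz

    def at(self, f_hz: float) -> complex:
        """Value at one frequency (conjugate symmetry for f < 0)."""
        v = np.interp(abs(f_hz), self.freq_hz, self.values.real) + 1j * np.interp(
            abs(f_hz), self.freq_hz, self.values.imag
        )
        return np.conj(v) if f_hz < 0 else v

    def loglog_slope(self, decades: float = 1.0) -> float:
        """log-log slope of |R^| over the top ``decades`` of the grid."""
        f = self.freq_hz
        mask = (f > 0) & (f >= f[-1] / 10**decades)
        coef = np.polyfit(np.log10(f[mask]), np.log10(np.abs(self.values[mask])), 1)
        return float(coef[0])


@njit(cache=True)
def _psi_scan(y_grid, omega_tau):
    """Upward integration of Psi'' = 2 y Psi' + 2 i w~ Psi from the bounded branch.

    Initialised at y_grid[0] with the algebraically-decaying asymptotic
    solution Psi ~ |y|^(-i w~); fixed-step RK4.  The overall scale is
    irrelevant downstream (the response depends on Psi only through ratios).
    Returns Psi and Psi' on the grid.
    """
    n = y_grid.shape[0]
    psi = np.empty(n, dtype=np.complex128)
    dpsi = np.empty(n, dtype=np.complex128)
    a = -1j * omega_tau
    y0 = y_grid[0]
    b = (a * a - a) / 2.0
    psi[0] = 1.0 + 0.0j
    dpsi[0] = a / y0 + b / y0**3
    u = psi[0]
    v = dpsi[0]
    for k in range(n - 1):
        h = y_grid[k + 1] - y_grid[k]
        y = y_grid[k]
        # RK4 on (u, v): u' = v, v' = 2 y v + 2 i w~ u
        k1u = v
        k1v = 2.0 * y * v + 2j * omega_tau * u
        yh = y + 0.5 * h
        u2 = u + 0.5 * h * k1u
        v2 = v + 0.5 * h * k1v
        k2u = v2
        k2v = 2.0 * yh * v2 + 2j * omega_tau * u2
        u3 = u + 0.5 * h * k2u
        v3 = v + 0.5 * h * k2v
        k3u = v3
        k3v = 2.0 * yh * v3 + 2j * omega_tau * u3
        y4 = y + h
        u4 = u + h * k3u
        v4 = v + h * k3v
        k4u = v4
        k4v = 2.0 * y4 * v4 + 2j * omega_tau * u4
        u = u + (h / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        v = v + (h / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        # renormalise to avoid overflow at large |y| (scale cancels later)
        m = abs(u)
        if m > 1e100:
            u /= m
            v /= m
        psi[k + 1] = u
        dpsi[k + 1] = v
    return psi, dpsi


def lif_response(
    noise,
    p: LIFParams,
    freq_hz: np.ndarray,
    dy: float = 2e-3,
    y_pad: float = 8.0,
    init_scale: float = 1.0,
) -> FrequencyResponse:
    """LIF rate response R^(omega) from the associated complex ODE.

    In the rescaled voltage y = (V - mu0)/sigma0 the frequency-domain
    perturbation problem reduces to a Hermite-type homogeneous ODE whose
    bounded branch Psi(y, omega) is integrated upward from deep below reset.
    The response assembles from boundary ratios (the scale of Psi cancels):

        R^(w) = (nu0/sigma0) / (1 + i w tau_m) *
                (Psi'(y_th) - e^{-i w tau_ref} Psi'(y_r)) /
                (Psi(y_th)  - e^{-i w tau_ref} Psi(y_r))

    with the phase factor expressing that reset re-injection lags threshold
    crossing by exactly the refractory period.  Cross-checked in the test
    suite against the generic threshold-integration solver and against
    sinusoidal stimulation of the simulated neuron.
    """
    mu0, sigma0 = noise.mu0, noise.sigma0
    freq_hz = np.asarray(freq_hz, dtype=float)
    if np.any(freq_hz < 0) or not np.all(np.isfinite(freq_hz)):
        raise ValueError("frequency grid must be finite and non-negative")
    nu0 = siegert_rate(mu0, sigma0, p)
    slope0 = transfer_slope(lambda m: siegert_rate(m, sigma0, p), mu0)
    y_th = (p.v_th - mu0) / sigma0
    y_r = (p.v_r - mu0) / sigma0
    y_min = min(y_r, 0.0) - y_pad
    n = int(np.ceil((y_th - y_min) / dy)) + 1
    y_grid = np.linspace(y_min, y_th, n)
    i_r = int(np.argmin(np.abs(y_grid - y_r)))
    values = np.empty(freq_hz.shape, dtype=complex)
    for i, f in enumerate(freq_hz):
        if f == 0.0:
            values[i] = slope0
            continue
        w_ms = 2.0 * np.pi * f / 1000.0  # rad/ms
        psi, dpsi = _psi_scan(y_grid, w_ms * p.tau_m)
        psi = psi * init_scale
        dpsi = dpsi * init_scale
        phase = np.exp(-1j * w_ms * p.tau_ref)
        num = dpsi[-1] - phase * dpsi[i_r]
        den = psi[-1] - phase * psi[i_r]
        if den == 0:
            raise AccuracyError(f"lif_response: degenerate denominator at f={f} Hz")
        r = (nu0 / sigma0) / (1.0 + 1j * w_ms * p.tau_m) * (num / den)
        values[i] = r
    return FrequencyResponse(freq_hz=freq_hz, values=values, mu0=mu0, sigma0=sigma0)


@njit(cache=True)
def _modulated_scan(v_grid, drift, p0, v_r_idx, D, w_ms, tau_m, tau_ref):
    """One frequency of the modulated threshold-integration problem.

    Downward integration from the absorbing top of two sub-problems:
    (r) unit efflux, reset re-injection with phase lag e^{-i w tau_ref};
    (E) zero efflux, source term p0/tau_m from the mean-input modulation.
    The rate modulation follows from requiring zero total flux at the lower
    boundary:  nu1 = -j_E(v_lb) / j_r(v_lb), in (1/ms)/mV.
    """
    n = v_grid.shape[0]
    jr = 1.0 + 0.0j
    pr = 0.0 + 0.0j
    jE = 0.0 + 0.0j
    pE = 0.0 + 0.0j
    phase = np.exp(-1j * w_ms * tau_ref)
    for k in range(n - 1, 0, -1):
        h = v_grid[k] - v_grid[k - 1]
        a = 0.5 * (drift[k] + drift[k - 1]) / D
        x = a * h
        p0m = 0.5 * (p0[k] + p0[k - 1])
        if abs(x) < 1e-12:
            pr_new = pr + jr * h / D
            pE_new = pE + (jE - p0m / tau_m) * h / D
        else:
            e = np.exp(-x) if x < 500.0 else 0.0
            pr_new = pr * e + (jr / (a * D)) * (1.0 - e)
            pE_new = pE * e + ((jE - p0m / tau_m) / (a * D)) * (1.0 - e)
        jr_new = jr + 1j * w_ms * h * 0.5 * (pr + pr_new)
        jE_new = jE + 1j * w_ms * h * 0.5 * (pE + pE_new)
        if k - 1 == v_r_idx:
            jr_new = jr_new - phase
        pr, jr = pr_new, jr_new
        pE, jE = pE_new, jE_new
    return -jE / jr


def threshold_response(
    noise, p, freq_hz: np.ndarray, dv: float = 0.01
) -> FrequencyResponse:
    """Rate response by threshold integration of the modulated Fokker-Planck system.

    Generic over the IF drift: works for both EIF (the primary use) and LIF
    (where it provides an independent cross-check of :func:`lif_response`).
    The first-order density/flux perturbation is integrated downward over
    the same voltage grid as the steady state, driven by the source term
    p0/tau_m of a unit mean-input modulation; the complex rate modulation
    per mV is read off from the zero-flux condition at the lower boundary.
    """
    mu0, sigma0 = noise.mu0, noise.sigma0
    freq_hz = np.asarray(freq_hz, dtype=float)
    if isinstance(p, EIFParams):
        _, dens = eif_transfer(mu0, sigma0, p, dv=dv, return_density=True)
    else:
        dens = lif_steady_density(mu0, sigma0, p, dv=dv)
    v_grid = dens.v_grid
    v_r_idx = int(np.argmin(np.abs(v_grid - p.v_r)))
    drift = _if_drift(v_grid, mu0, p)
    D = sigma0**2 / (2.0 * p.tau_m)
    values = np.empty(freq_hz.shape, dtype=complex)
    slope0 = None
    for i, f in enumerate(freq_hz):
        if f == 0.0:
            # the omega -> 0 limit is the transfer-function slope (0/0 in
            # the scan itself); evaluate it from the same steady solver
            if slope0 is None:
                if isinstance(p, EIFParams):
                    slope0 = transfer_slope(lambda m: eif_transfer(m, sigma0, p, dv=dv), mu0)
                else:
                    slope0 = transfer_slope(lambda m: siegert_rate(m, sigma0, p), mu0)
            values[i] = slope0
            continue
        w_ms = 2.0 * np.pi * f / 1000.0
        nu1 = _modulated_scan(
            v_grid, drift, dens.p0, v_r_idx, D, w_ms, p.tau_m, p.tau_ref
        )
        values[i] = 1000.0 * nu1  # (1/ms)/mV -> Hz/mV
    return FrequencyResponse(freq_hz=freq_hz, values=values, mu0=mu0, sigma0=sigma0)


def eif_response(noise, p: EIFParams, freq_hz: np.ndarray, dv: float = 0.01) -> FrequencyResponse:
    """EIF rate response R^(omega); see :func:`threshold_response`."""
    if not isinstance(p, EIFParams):
        raise TypeError("eif_response expects EIFParams")
    return threshold_response(noise, p, freq_hz, dv=dv)


# ---------------------------------------------------------------------------
# Frequency -> time conversion
# ---------------------------------------------------------------------------


@dataclass
class FilterTrace:
    """Causal time-domain linear filter K(t), t >= 0, step ``dt`` ms.

    Each sample is the filter locally averaged with a triangular kernel of
    half-width ``dt`` (see :func:`filter_from_response`), so the natural
    quadrature is the plain Riemann sum.  Units Hz/(mV ms): the discrete
    convolution sum_j K_j s(t - t_j) dt is a rate deviation in Hz.
    ``causality_residual`` is max|K(t < 0)| / max|K| over the strictly
    negative sample times of the inverse transform — a quality metric of
    the frequency coverage.
    """

    dt: float
    values: np.ndarray
    causality_residual: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    @property
    def integral(self) -> float:
        """int K dt (Hz/mV); equals R^(0) for a filter built from a response."""
        return float(np.sum(self.values) * self.dt)


def default_filter_grid(dt: float = 0.25, df: float = 2.0, oversample: int = 5) -> np.ndarray:
    """Uniform grid 0..f_max for inversion at time step ``dt`` (ms).

    The grid extends ``oversample`` times beyond the output Nyquist
    frequency 500/dt Hz, so that the smoothing kernel of the inversion has
    decayed strongly at the truncation edge; 1/df is the total (two-sided)
    time window in seconds.
    """
    f_max = oversample * 500.0 / dt
    n = int(round(f_max / df))
    return np.linspace(0.0, f_max, n + 1)


def log_frequency_grid(f_lo: float = 0.1, f_hi: float = 1e4, n: int = 41) -> np.ndarray:
    """Log-spaced grid for asymptote estimation (no zero entry)."""
    return np.logspace(np.log10(f_lo), np.log10(f_hi), n)


def filter_from_response(
    resp: FrequencyResponse,
    dt: float = 0.25,
    window: float | None = None,
    causality_tol: float = 1e-2,
) -> FilterTrace:
    """Inverse Fourier transform of R^(omega) onto a causal time grid.

    Requires a uniform frequency grid starting at 0; the negative-frequency
    half is supplied by conjugate symmetry (irfft).  A raw truncated
    transform of these responses rings at the t = 0 edge (|R^| decays only
    algebraically), so the spectrum is multiplied by sinc^2(f dt) before
    inversion: each returned sample is then the exact triangular-kernel
    average of K over [t - dt, t + dt], which a frequency grid extending a
    few times past the output Nyquist represents to fractional accuracy
    ~1e-4.  This is also precisely the discretisation under which the
    convolution with a linearly-interpolated signal is exact.

    Samples that wrap to strictly negative times measure the residual
    acausal leakage and are reported, not returned.
    """
    f = resp.freq_hz
    df = f[1] - f[0]
    if not np.allclose(np.diff(f), df, rtol=1e-8) or f[0] != 0.0:
        raise ValueError("filter inversion needs a uniform frequency grid starting at 0")
    m = 2 * (len(f) - 1)
    dt_fine = 1000.0 / (m * df)  # ms
    stride = int(round(dt / dt_fine))
    if stride < 1 or abs(stride * dt_fine - dt) > 1e-9 * dt:
        raise ValueError(
            f"grid implies a fine step of {dt_fine:.6g} ms; dt={dt} ms must be an "
            "integer multiple of it"
        )
    if window is not None and window * df > 1000.0:
        raise ValueError("window exceeds the resolution of the frequency grid")
    kernel = np.sinc(f / 1000.0 * dt) ** 2
    # K(t) = int R^ e^{2 pi i f t} df; discretised as df * irfft * m, in Hz/mV/ms
    k_fine = np.fft.irfft(resp.values * kernel, n=m) * m * df / 1000.0
    half = m // 2
    causal = k_fine[:half:stride]
    # wrapped samples at t = -dt, -2dt, ... (skip |t| < dt where the
    # triangular kernel of a causal K legitimately overlaps t=0)
    acausal = k_fine[m - stride : half : -stride]
    peak = np.max(np.abs(k_fine))
    residual = 0.0 if peak == 0 else float(np.max(np.abs(acausal)) / peak)
    if residual > causality_tol:
        raise AccuracyError(
            f"acausal residual {residual:.3g} exceeds {causality_tol}; widen the frequency range"
        )
    if window is not None:
        n_keep = min(int(round(window / dt)), len(causal))
        causal = causal[:n_keep]
    return FilterTrace(dt=dt, values=causal.copy(), causality_residual=residual)
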