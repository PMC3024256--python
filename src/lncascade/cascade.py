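"""Linear-nonlinear cascade and firing-rate reductions of spiking models.

The cascade estimates the trial-averaged firing rate as

    r(t) = F( (K * s)(t) ),

where both elements are fixed by the neuron's Fokker-Planck theory, with no
parameter fitted to the PSTH being predicted:

* the linear filter K(t) is the inverse Fourier transform of the rate
  response function R^(omega) evaluated at the operating point
  (mu0, sigma0), so that int K dt = dPhi/dmu = g0;
* the static nonlinearity is the rescaled transfer function
  F(x) = Phi(mu0 + x/g0, sigma0), so F(0) is the baseline rate nu0 and
  F'(0) = 1.

This normalisation is the unique split consistent with both exactly-solvable
limits: for vanishing signal amplitude the cascade linearises to
nu0 + (K*s)(t), and for signal correlation times much longer than the
filter width it reduces to the adiabatic rate Phi(mu0 + s(t), sigma0).

Because |R^| of the exponential integrate-and-fire model decays as 1/omega
at high frequency and tends to g0 at zero frequency, the filter is well
approximated by a single exponential of time constant tau_eff = g0/C, with
C the high-frequency asymptote of omega*|R^|.  The cascade then collapses
to a one-variable rate model, and letting tau_eff track the instantaneous
rate gives the adaptive-timescale rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fokker_planck import (
    AccuracyError,
    FilterTrace,
    FrequencyResponse,
    TransferFunction,
    eif_response,
    log_frequency_grid,
    mu_for_rate,
    transfer_slope,
)
from .stimulus import SignalTrace

__all__ = [
    "StaticNonlinearity",
    "CascadeModel",
    "RateModelParams",
    "TauEffTable",
    "build_nonlinearity",
    "predict_linear",
    "predict_nonlinear",
    "predict_ln",
    "predict_rate_model",
    "predict_adaptive",
    "effective_timescale",
    "exp_filter_mismatch",
    "exponential_filter",
]


@dataclass
class StaticNonlinearity:
    """F(x) = Phi(mu0 + x/g0, sigma0): baseline rate at the origin, unit slope."""

    tf: TransferFunction
    mu0: float
    sigma0: float
    g0: float  # Hz/mV
    nu0: float  # Hz

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.tf.rate_interp(self.mu0 + x / self.g0, self.sigma0)

    def exact(self, x: float) -> float:
        """Non-interpolated evaluation at a single point."""
        return self.tf.rate(self.mu0 + x / self.g0, self.sigma0)


def build_nonlinearity(tf: TransferFunction, mu0: float, sigma0: float) -> StaticNonlinearity:
    """Rescale the transfer function into the cascade's static nonlinearity."""
    g0 = transfer_slope(tf, mu0, sigma0)
    if g0 <= 0:
        raise RuntimeError(f"transfer-function slope {g0} must be positive")
    nu0 = tf.rate(mu0, sigma0)
    return StaticNonlinearity(tf=tf, mu0=mu0, sigma0=sigma0, g0=g0, nu0=nu0)


@dataclass
class CascadeModel:
    """Linear filter + static nonlinearity + baseline rate: the LN predictor."""

    filter: FilterTrace
    nonlinearity: StaticNonlinearity

    @property
    def nu0(self) -> float:
        return self.nonlinearity.nu0

    def __post_init__(self) -> None:
        g0 = self.nonlinearity.g0
        if abs(self.filter.integral - g0) > 0.02 * abs(g0):
            raise ValueError(
                f"filter integral {self.filter.integral:.4g} deviates from the "
                f"transfer slope {g0:.4g} by more than 2%"
            )


def _convolve(signal: SignalTrace, filt: FilterTrace) -> np.ndarray:
    """Causal discrete convolution (K * s)(t) in Hz.

    Filter samples are kernel-averaged (see ``FilterTrace``), so the plain
    Riemann sum is the consistent quadrature — for a linearly-interpolated
    signal it reproduces the continuous convolution exactly.
    """
    if abs(signal.dt - filt.dt) > 1e-9 * filt.dt:
        raise ValueError(
            f"signal dt {signal.dt} != filter dt {filt.dt}; resample the signal first"
        )
    from scipy.signal import fftconvolve

    full = fftconvolve(signal.values, filt.values * filt.dt)
    return full[: len(signal.values)]


def predict_linear(signal: SignalTrace, filt: FilterTrace, nu0: float) -> np.ndarray:
    """Linear estimate nu0 + (K*s)(t).  May go negative for strong signals."""
    return nu0 + _convolve(signal, filt)


def predict_nonlinear(signal: SignalTrace, nl: StaticNonlinearity) -> np.ndarray:
    """Adiabatic estimate Phi(mu0 + s(t), sigma0), valid for slow signals."""
    return nl(nl.g0 * signal.values)


def predict_ln(signal: SignalTrace, model: CascadeModel) -> np.ndarray:
    """Full cascade estimate F((K*s)(t)); nonnegative by construction of F."""
    drive = _convolve(signal, model.filter)
    return model.nonlinearity(drive)


# ---------------------------------------------------------------------------
# Single-timescale (rate) model
# ---------------------------------------------------------------------------


def effective_timescale(
    resp: FrequencyResponse, g0: float, decades: float = 1.0, flat_tol: float = 0.05
) -> float:
    """Effective exponential-filter timescale tau_eff = g0 / C (ms).

    C is the high-frequency asymptote of omega*|R^(omega)| (rad/s * Hz/mV),
    estimated by averaging over the top ``decades`` of the grid after
    checking that omega|R^| has levelled off (relative drift below
    ``flat_tol``).  Matching a Lorentzian g0/(1 + i omega tau) at both ends
    of the spectrum gives exactly tau.
    """
    f = resp.freq_hz
    mask = (f > 0) & (f >= f[-1] / 10**decades)
    if mask.sum() < 4:
        raise ValueError("frequency grid too short for asymptote estimation")
    wr = resp.omega[mask] * np.abs(resp.values[mask])
    drift = abs(wr[-1] - wr[0]) / np.mean(wr)
    if drift > flat_tol:
        raise AccuracyError(
            f"omega*|R| drifts by {drift:.3f} over the top decade; extend the grid"
        )
    c = float(np.mean(wr))
    return 1000.0 * g0 / c  # s -> ms


def exp_filter_mismatch(resp: FrequencyResponse, tau_eff: float, g0: float) -> float:
    """RMS of |R^(omega) - g0/(1 + i omega tau_eff)| over the grid (Hz/mV)."""
    lor = g0 / (1.0 + 1j * resp.omega * tau_eff / 1000.0)
    return float(np.sqrt(np.mean(np.abs(resp.values - lor) ** 2)))


def exponential_filter(tau_eff: float, g0: float, dt: float, window: float) -> FilterTrace:
    """The single-timescale filter K(t) = (g0/tau_eff) e^{-t/tau_eff} as a trace.

    Samples are bin averages over [t, t+dt] (matching the kernel-averaged
    semantics of ``FilterTrace``), which makes the discrete convolution with
    a piecewise-constant signal identical to the exact exponential update of
    the equivalent rate-model ODE.
    """
    t = np.arange(int(round(window / dt))) * dt
    alpha = np.exp(-dt / tau_eff)
    vals = (g0 / dt) * (1.0 - alpha) * np.exp(-t / tau_eff)
    return FilterTrace(dt=dt, values=vals)


@dataclass
class RateModelParams:
    """Single-timescale rate model: tau_eff (ms) plus the static nonlinearity."""

    tau_eff: float
    nonlinearity: StaticNonlinearity

    def __post_init__(self) -> None:
        if self.tau_eff <= 0:
            raise ValueError("tau_eff must be > 0")


def predict_rate_model(signal: SignalTrace, rm: RateModelParams) -> np.ndarray:
    """Integrate tau_eff du/dt = -u + s(t); r(t) = Phi(mu0 + u(t), sigma0).

    The drive u is updated with the exact exponential (zero-order-hold)
    rule, so the integration is unconditionally stable and dt-exact for a
    piecewise-constant signal.  Equivalent to the LN cascade with the
    exponential filter (checked to high accuracy in the tests).
    """
    from scipy.signal import lfilter

    nl = rm.nonlinearity
    alpha = np.exp(-signal.dt / rm.tau_eff)
    u = lfilter([1.0 - alpha], [1.0, -alpha], signal.values)
    # u(t) lags s by one step in this recursion: u_k depends on s_k with
    # weight (1-alpha), matching u' = (s - u)/tau integrated over the step.
    return nl(nl.g0 * u)


@dataclass
class TauEffTable:
    """Monotone interpolation of nu -> tau_eff(nu) along the f-I curve.

    Built by sweeping baseline rates: for each nu the operating mean mu(nu)
    is recovered by inverting the transfer function at fixed sigma0, the
    rate response is solved there, and tau_eff extracted from its
    asymptotics.  Rates outside the tabulated range are clamped.
    """

    rates: np.ndarray
    tau: np.ndarray
    _interp: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        from scipy.interpolate import PchipInterpolator

        order = np.argsort(self.rates)
        self.rates = np.asarray(self.rates, dtype=float)[order]
        self.tau = np.asarray(self.tau, dtype=float)[order]
        self._interp = PchipInterpolator(np.log(self.rates), self.tau)

    def __call__(self, nu) -> np.ndarray:
        nu = np.clip(nu, self.rates[0], self.rates[-1])
        return self._interp(np.log(nu))

    @classmethod
    def build(
        cls,
        tf: TransferFunction,
        sigma0: float,
        n_rates: int = 30,
        nu_lo: float = 0.5,
        nu_hi_frac: float = 0.9,
        freq_grid: np.ndarray | None = None,
        dv: float = 0.01,
    ) -> "TauEffTable":
        from .stimulus import NoiseParams

        if freq_grid is None:
            freq_grid = log_frequency_grid(1.0, 1e4, 25)
        # the achievable ceiling of an EIF-type model is set by the f-I
        # curve itself (reset-to-threshold transit adds to tau_ref), so
        # probe it rather than trusting the refractory bound
        ceiling = tf.rate(50.0, sigma0)
        rates = np.geomspace(nu_lo, nu_hi_frac * ceiling, n_rates)
        taus = np.empty_like(rates)
        for i, nu in enumerate(rates):
            mu = mu_for_rate(tf, nu, sigma0)
            g0 = transfer_slope(tf, mu, sigma0)
            resp = eif_response(NoiseParams(mu0=mu, sigma0=sigma0), tf.params, freq_grid, dv=dv)
            taus[i] = effective_timescale(resp, g0)
        return cls(rates=rates, tau=taus)


def predict_adaptive(
    signal: SignalTrace, nl: StaticNonlinearity, tau_table: TauEffTable
) -> np.ndarray:
    """Adaptive-timescale rate model.

    Per step the filter timescale is re-evaluated at the instantaneous
    firing rate — the rate estimated at the previous step — so responses
    are faster when the neuron fires faster; only the timescale adapts, the
    nonlinearity and gain stay at their baseline construction.
    """
    dt = signal.dt
    s = signal.values
    n = len(s)
    rates = np.empty(n)
    u = 0.0
    nu_prev = nl.nu0
    interp = nl.tf.table(
        nl.sigma0, float(nl.mu0 + min(s.min(), 0) - 1.0), float(nl.mu0 + s.max() + 1.0)
    )
    for k in range(n):
        tau_now = float(tau_table(nu_prev))
        a = np.exp(-dt / tau_now)
        u = a * u + (1.0 - a) * s[k]
        nu_prev = max(float(interp(nl.mu0 + u)), 0.0)
        rates[k] = nu_prev
    return rates
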