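"""Stochastic simulation of LIF, EIF and Wang-Buzsáki neurons over trials.

All three models receive the same total input current, expressed in mV:

    I(t) = mu0 + s(t) + sigma0 * sqrt(tau_m) * eta(t),

with s(t) the shared signal trace and eta unit white noise drawn
independently per trial.  Discretely, the noise enters the membrane
potential as an additive Gaussian increment of SD sigma0*sqrt(dt/tau_m) per
step — the unique convention under which the classical mean-first-passage
formula with bounds (v_th - mu)/sigma and (v_r - mu)/sigma gives the LIF
stationary rate (cross-checked against simulation in the tests).  For the
conductance-based model the mV-scale parameters are converted to current
density through the leak conductance, with tau_m = C_m/g_L.

The deterministic part of each step is advanced with Heun's method (RK2);
the noise increment is added Euler-Maruyama style, the appropriate
treatment for additive white noise.  Trial t uses seed base_seed + t, so
the full trial ensemble is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .stimulus import NoiseParams, SignalTrace

__all__ = [
    "LIFParams",
    "EIFParams",
    "WBParams",
    "SimConfig",
    "SpikeTrainSet",
    "PSTH",
    "simulate_lif",
    "simulate_eif",
    "simulate_wb",
    "compute_psth",
    "wb_resting_state",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """The membrane-potential integration produced a non-finite state."""


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire. Voltages in mV relative to rest, times in ms."""

    tau_m: float = 20.0
    v_th: float = 20.0
    v_r: float = 10.0
    tau_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")
        if self.v_r >= self.v_th:
            raise ValueError("reset must lie below threshold")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be >= 0")


@dataclass(frozen=True)
class EIFParams:
    """Exponential integrate-and-fire.

    The spike-generating current delta_t*exp((V - v_t)/delta_t) makes V
    diverge in finite time once well past v_t; the divergence is detected at
    ``v_ceiling`` and stands for the action potential.
    """

    tau_m: float = 20.0
    v_t: float = 10.0
    delta_t: float = 1.5
    v_r: float = 5.0
    tau_ref: float = 2.0
    v_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if not (self.v_r < self.v_t < self.v_ceiling):
            raise ValueError("require v_r < v_t < v_ceiling")


@dataclass(frozen=True)
class WBParams:
    """Wang-Buzsáki conductance-based interneuron model (canonical constants).

    Conductances in mS/cm^2, capacitance in uF/cm^2, potentials in mV
    (absolute).  Sodium activation is instantaneous (m = m_inf(V)); the h
    and n kinetics are scaled by phi.  A spike is an upward crossing of
    ``v_spike``, with a 2 ms minimum interval to suppress double detection.
    """

    c_m: float = 1.0
    g_l: float = 0.1
    g_na: float = 35.0
    g_k: float = 9.0
    e_l: float = -65.0
    e_na: float = 55.0
    e_k: float = -90.0
    phi: float = 5.0
    v_spike: float = 0.0

    def __post_init__(self) -> None:
        if min(self.g_l, self.g_na, self.g_k) < 0:
            raise ValueError("conductances must be >= 0")
        if not (self.e_k < self.e_l < self.e_na):
            raise ValueError("require e_k < e_l < e_na")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m/g_L (ms)."""
        return self.c_m / self.g_l


@dataclass(frozen=True)
class SimConfig:
    dt_sim: float = 0.01
    n_trials: int = 400
    duration: float = 10_000.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class SpikeTrainSet:
    """Per-trial ordered spike times (ms) from a repeated-trial experiment."""

    spike_times: list
    n_trials: int
    duration: float

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(s, dtype=float) for s in self.spike_times]

    @property
    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))

    def mean_rate(self, t_start: float = 0.0) -> float:
        """Trial-averaged stationary rate in Hz over [t_start, duration]."""
        span = self.duration - t_start
        count = sum(int(np.sum(s >= t_start)) for s in self.spike_times)
        return 1000.0 * count / (self.n_trials * span)

    def mean_rate_se(self, t_start: float = 0.0) -> float:
        """Standard error of :meth:`mean_rate` from the trial-to-trial spread."""
        span = self.duration - t_start
        counts = np.array([np.sum(s >= t_start) for s in self.spike_times], dtype=float)
        if self.n_trials < 2:
            return 1000.0 * np.sqrt(max(counts.sum(), 1.0)) / span
        return 1000.0 * counts.std(ddof=1) / (np.sqrt(self.n_trials) * span)


@dataclass
class PSTH:
    """Trial-averaged, binned firing rate r(t) in Hz."""

    bin_dt: float
    rates: np.ndarray
    n_trials: int

    @property
    def times(self) -> np.ndarray:
        """Bin centres (ms)."""
        return (np.arange(len(self.rates)) + 0.5) * self.bin_dt


# ---------------------------------------------------------------------------
# Per-trial kernels (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _if_trial(
    xi, sig, dt, tau_m, v_th, v_r, tau_ref, mu0, sigma0, v0, is_eif, v_t, delta_t
):
    """One integrate-and-fire trial; LIF (is_eif=0) or EIF (is_eif=1).

    ``sig`` is the signal already sampled at dt (zero-order hold per step).
    LIF spike times are linearly interpolated at the threshold crossing; EIF
    spikes are recorded at the first step at/above the ceiling (v_th plays
    the role of v_ceiling), where the super-exponential divergence makes the
    timing error negligible.  For the LIF the detection threshold is lowered
    by the standard absorbing-boundary shift 0.5826 * sigma0 * sqrt(dt/tau_m)
    (|zeta(1/2)|/sqrt(2*pi) times the per-step noise SD), compensating the
    sub-step threshold excursions a discrete scheme cannot see; without it
    the stationary rate carries an O(sqrt(dt)) downward bias.  The
    refractory hold ends mid-step: the
    remainder of that step is integrated from the reset with the shortened
    step, so deterministic inter-spike intervals are O(dt^2)-accurate.
    Returns (spike_times, failure_step) with failure_step = -1 on success.
    """
    n_steps = xi.shape[0]
    spikes = np.empty(256, dtype=np.float64)
    n_sp = 0
    v = v0
    t_free = -1.0
    if is_eif == 0:
        v_det = v_th - 0.5826 * sigma0 * np.sqrt(dt / tau_m)
    else:
        v_det = v_th
    for k in range(n_steps):
        t = k * dt
        t_next = t + dt
        if t_next <= t_free:
            continue
        if t < t_free:
            h = t_next - t_free
            v = v_r
        else:
            h = dt
        i0 = mu0 + sig[k]
        if is_eif == 1:
            e1 = (v - v_t) / delta_t
            psi1 = delta_t * np.exp(min(e1, 40.0))
            k1 = (-v + psi1 + i0) / tau_m
            vp = v + h * k1
            e2 = (vp - v_t) / delta_t
            psi2 = delta_t * np.exp(min(e2, 40.0))
            k2 = (-vp + psi2 + i0) / tau_m
        else:
            k1 = (-v + i0) / tau_m
            vp = v + h * k1
            k2 = (-vp + i0) / tau_m
        v_new = v + 0.5 * h * (k1 + k2) + sigma0 * np.sqrt(h / tau_m) * xi[k]
        if not np.isfinite(v_new):
            if is_eif == 1:
                v_new = v_th + 1.0  # overflow of the divergence = a spike
            else:
                return spikes[:n_sp], k
        if v_new >= v_det:
            if is_eif == 1:
                t_sp = t_next
            else:
                frac = (v_det - v) / (v_new - v) if v_new > v_det and v_new > v else 1.0
                frac = min(max(frac, 0.0), 1.0)
                t_sp = t_next - h + frac * h
            if n_sp >= spikes.shape[0]:
                grown = np.empty(spikes.shape[0] * 2, dtype=np.float64)
                grown[: spikes.shape[0]] = spikes
                spikes = grown
            spikes[n_sp] = t_sp
            n_sp += 1
            t_free = t_sp + tau_ref
            v = v_r
        else:
            v = v_new
    return spikes[:n_sp], -1


@njit(cache=True)
def _wb_trial(xi, sig, dt, p_arr, mu0, sigma0, v0, h0, n0):
    """One Wang-Buzsáki trial.

    p_arr = (c_m, g_l, g_na, g_k, e_l, e_na, e_k, phi, v_spike).
    Input current density is g_l*(mu0 + s(t)) uA/cm^2 plus a white-noise
    increment of SD sigma0*sqrt(dt/tau_m) directly on V (tau_m = c_m/g_l).
    Returns (spike_times, gating_violation, failure_step).
    """
    c_m, g_l, g_na, g_k, e_l, e_na, e_k, phi, v_spike = (
        p_arr[0], p_arr[1], p_arr[2], p_arr[3], p_arr[4], p_arr[5], p_arr[6], p_arr[7], p_arr[8],
    )
    tau_m = c_m / g_l
    n_steps = xi.shape[0]
    spikes = np.empty(256, dtype=np.float64)
    n_sp = 0
    v, hh, nn = v0, h0, n0
    above = v >= v_spike
    worst_gate = 0.0
    noise_sd = sigma0 * np.sqrt(dt / tau_m)
    for k in range(n_steps):
        i_in = g_l * (mu0 + sig[k])
        # stage 1
        dv1, dh1, dn1 = _wb_derivs(v, hh, nn, i_in, c_m, g_l, g_na, g_k, e_l, e_na, e_k, phi)
        v1 = v + dt * dv1
        h1 = hh + dt * dh1
        n1 = nn + dt * dn1
        dv2, dh2, dn2 = _wb_derivs(v1, h1, n1, i_in, c_m, g_l, g_na, g_k, e_l, e_na, e_k, phi)
        v_new = v + 0.5 * dt * (dv1 + dv2) + noise_sd * xi[k]
        h_new = hh + 0.5 * dt * (dh1 + dh2)
        n_new = nn + 0.5 * dt * (dn1 + dn2)
        if not (np.isfinite(v_new) and np.isfinite(h_new) and np.isfinite(n_new)):
            return spikes[:n_sp], worst_gate, k
        for val in (h_new, n_new):
            ex = max(0.0 - val, val - 1.0)
            if ex > worst_gate:
                worst_gate = ex
        h_new = min(max(h_new, 0.0), 1.0)
        n_new = min(max(n_new, 0.0), 1.0)
        t_next = (k + 1) * dt
        if (not above) and v_new >= v_spike:
            if n_sp == 0 or t_next - spikes[n_sp - 1] >= 2.0:
                if n_sp >= spikes.shape[0]:
                    grown = np.empty(spikes.shape[0] * 2, dtype=np.float64)
                    grown[: spikes.shape[0]] = spikes
                    spikes = grown
                spikes[n_sp] = t_next
                n_sp += 1
        above = v_new >= v_spike
        v, hh, nn = v_new, h_new, n_new
    return spikes[:n_sp], worst_gate, -1


@njit(cache=True, inline="always")
def _wb_derivs(v, hh, nn, i_in, c_m, g_l, g_na, g_k, e_l, e_na, e_k, phi):
    # gating rate functions of the Wang-Buzsáki interneuron model (1/ms, mV)
    x = v + 35.0
    if abs(x) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    b_m = 4.0 * np.exp(-(v + 60.0) / 18.0)
    m_inf = a_m / (a_m + b_m)
    a_h = 0.07 * np.exp(-(v + 58.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    x = v + 34.0
    if abs(x) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * x / (1.0 - np.exp(-x / 10.0))
    b_n = 0.125 * np.exp(-(v + 44.0) / 80.0)
    i_na = g_na * m_inf**3 * hh * (v - e_na)
    i_k = g_k * nn**4 * (v - e_k)
    i_l = g_l * (v - e_l)
    dv = (-i_l - i_na - i_k + i_in) / c_m
    dh = phi * (a_h * (1.0 - hh) - b_h * hh)
    dn = phi * (a_n * (1.0 - nn) - b_n * nn)
    return dv, dh, dn


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def _signal_on_sim_grid(signal: SignalTrace, dt_sim: float, n_steps: int) -> np.ndarray:
    """Signal value per integration step (zero-order hold on the signal grid)."""
    ratio = signal.dt / dt_sim
    if abs(ratio - round(ratio)) > 1e-6 * max(ratio, 1.0):
        raise ValueError(
            f"signal dt {signal.dt} ms must be an integer multiple of dt_sim {dt_sim} ms"
        )
    idx = np.minimum(
        (np.arange(n_steps) * dt_sim / signal.dt).astype(np.int64),
        len(signal.values) - 1,
    )
    return signal.values[idx]


def _run_if(
    p, noise: NoiseParams, signal: SignalTrace, cfg: SimConfig, is_eif: bool, v0: float
) -> SpikeTrainSet:
    n_steps = int(round(cfg.duration / cfg.dt_sim))
    sig = _signal_on_sim_grid(signal, cfg.dt_sim, n_steps)
    v_stop = p.v_ceiling if is_eif else p.v_th
    v_t = p.v_t if is_eif else 0.0
    delta_t = p.delta_t if is_eif else 1.0
    trains = []
    for t in range(cfg.n_trials):
        rng = np.random.default_rng(cfg.base_seed + t)
        xi = rng.standard_normal(n_steps)
        spikes, fail = _if_trial(
            xi, sig, cfg.dt_sim, p.tau_m, v_stop, p.v_r, p.tau_ref,
            noise.mu0, noise.sigma0, v0, 1 if is_eif else 0, v_t, delta_t,
        )
        if fail >= 0:
            raise IntegrationError(
                f"non-finite membrane potential in trial {t} at t={fail * cfg.dt_sim:.3f} ms"
            )
        trains.append(spikes)
    return SpikeTrainSet(spike_times=trains, n_trials=cfg.n_trials, duration=cfg.duration)


def simulate_lif(
    p: LIFParams, noise: NoiseParams, signal: SignalTrace, cfg: SimConfig
) -> SpikeTrainSet:
    """Simulate LIF trials sharing ``signal`` with independent background noise."""
    return _run_if(p, noise, signal, cfg, is_eif=False, v0=p.v_r)


def simulate_eif(
    p: EIFParams, noise: NoiseParams, signal: SignalTrace, cfg: SimConfig
) -> SpikeTrainSet:
    """Simulate EIF trials; a spike is recorded when V reaches ``v_ceiling``."""
    return _run_if(p, noise, signal, cfg, is_eif=True, v0=p.v_r)


def wb_resting_state(p: WBParams, i_const: float = 0.0) -> tuple[float, float, float]:
    """Noise-free resting equilibrium (V, h, n) of the Wang-Buzsáki model.

    Found by root-finding the steady-state current balance with h = h_inf(V)
    and n = n_inf(V).
    """

    def balance(v):
        h_inf, n_inf = _wb_inf(v)
        dv, _, _ = _wb_derivs(
            v, h_inf, n_inf, i_const, p.c_m, p.g_l, p.g_na, p.g_k, p.e_l, p.e_na, p.e_k, p.phi
        )
        return dv

    # scan upward for the first sign change: the resting fixed point (the
    # balance crosses zero again near spike threshold)
    vs = np.arange(-90.0, -45.0, 0.5)
    vals = [balance(v) for v in vs]
    for a, b, fa, fb in zip(vs[:-1], vs[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            return a, *_wb_inf(a)
        if fa * fb < 0:
            lo, hi = a, b
            break
    else:
        raise ValueError("no resting equilibrium found in [-90, -45] mV")
    v_rest = brentq(balance, lo, hi, xtol=1e-10)
    h_inf, n_inf = _wb_inf(v_rest)
    return v_rest, h_inf, n_inf


def _wb_inf(v: float) -> tuple[float, float]:
    a_h = 0.07 * np.exp(-(v + 58.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    x = v + 34.0
    a_n = 0.1 if abs(x) < 1e-7 else 0.01 * x / (1.0 - np.exp(-x / 10.0))
    b_n = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return a_h / (a_h + b_h), a_n / (a_n + b_n)


def simulate_wb(
    p: WBParams,
    noise: NoiseParams,
    signal: SignalTrace,
    cfg: SimConfig,
    gate_tol: float = 0.05,
) -> SpikeTrainSet:
    """Simulate Wang-Buzsáki trials from the noise-free resting equilibrium.

    mV-scale input parameters are converted to current density via g_L; the
    noise convention matches the integrate-and-fire models with
    tau_m = C_m/g_L.
    """
    n_steps = int(round(cfg.duration / cfg.dt_sim))
    sig = _signal_on_sim_grid(signal, cfg.dt_sim, n_steps)
    v0, h0, n0 = wb_resting_state(p)
    p_arr = np.array(
        [p.c_m, p.g_l, p.g_na, p.g_k, p.e_l, p.e_na, p.e_k, p.phi, p.v_spike]
    )
    trains = []
    for t in range(cfg.n_trials):
        rng = np.random.default_rng(cfg.base_seed + t)
        xi = rng.standard_normal(n_steps)
        spikes, worst_gate, fail = _wb_trial(
            xi, sig, cfg.dt_sim, p_arr, noise.mu0, noise.sigma0, v0, h0, n0
        )
        if fail >= 0:
            raise IntegrationError(
                f"non-finite state in trial {t} at t={fail * cfg.dt_sim:.3f} ms"
            )
        if worst_gate > gate_tol:
            raise IntegrationError(
                f"gating variable left [0,1] by {worst_gate:.3g} in trial {t}; reduce dt_sim"
            )
        trains.append(spikes)
    return SpikeTrainSet(spike_times=trains, n_trials=cfg.n_trials, duration=cfg.duration)


def compute_psth(spikes: SpikeTrainSet, bin_dt: float) -> PSTH:
    """Trial-averaged firing rate: counts per bin / (n_trials * bin_dt), in Hz."""
    if bin_dt <= 0:
        raise ValueError("bin_dt must be > 0")
    if bin_dt > spikes.duration:
        raise ValueError("bin_dt exceeds the trial duration")
    n_bins = int(round(spikes.duration / bin_dt))
    edges = np.arange(n_bins + 1) * bin_dt
    counts = np.zeros(n_bins)
    for train in spikes.spike_times:
        if len(train):
            c, _ = np.histogram(train, bins=edges)
            counts += c
    rates = 1000.0 * counts / (spikes.n_trials * bin_dt)
    return PSTH(bin_dt=bin_dt, rates=rates, n_trials=spikes.n_trials)
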