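"""Input signal and background-noise descriptions.

The stimulation paradigm is a repeated-trial experiment: a single *signal*
current s(t), identical across trials, rides on top of *background noise*
that is drawn independently on every trial.  The signal is a zero-mean
Gaussian Ornstein-Uhlenbeck (OU) process with standard deviation ``sigma_s``
(mV) and correlation time ``tau_s`` (ms); the background noise is Gaussian
white noise with mean ``mu0`` and standard deviation ``sigma0`` (both mV).

Only the signal is materialised as a trace.  White background noise has no
dt-independent sample-path representation, so it is drawn inside the neuron
integrators as Gaussian increments (see :mod:`lncascade.neurons`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalParams",
    "NoiseParams",
    "SignalTrace",
    "generate_signal",
    "write_signal",
    "read_signal",
]


@dataclass(frozen=True)
class SignalParams:
    """OU signal parameters: amplitude ``sigma_s`` (mV), correlation time ``tau_s`` (ms)."""

    sigma_s: float
    tau_s: float

    def __post_init__(self) -> None:
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")
        if self.tau_s <= 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")


@dataclass(frozen=True)
class NoiseParams:
    """Background-noise parameters: mean input ``mu0`` (mV), noise SD ``sigma0`` (mV)."""

    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError(f"sigma0 must be >= 0, got {self.sigma0}")


@dataclass(frozen=True)
class SignalTrace:
    """A sampled signal s(t) on a uniform grid of step ``dt`` (ms)."""

    dt: float
    values: np.ndarray
    seed: int | None = None
    params: SignalParams | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal trace contains non-finite values")

    @property
    def duration(self) -> float:
        return self.dt * len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def resample(self, dt_new: float) -> "SignalTrace":
        """Resample onto a new uniform grid by linear interpolation.

        Decimation to an integer multiple of ``dt`` picks exact sample
        points, which preserves the OU statistics exactly (the OU process
        restricted to a coarser grid is the OU process on that grid).
        """
        if dt_new <= 0:
            raise ValueError("dt_new must be > 0")
        n_new = int(round(self.duration / dt_new))
        t_new = np.arange(n_new) * dt_new
        vals = np.interp(t_new, self.times, self.values)
        return SignalTrace(dt=dt_new, values=vals, seed=self.seed, params=self.params)


def generate_signal(
    params: SignalParams, duration: float, dt: float, seed: int
) -> SignalTrace:
    """Generate a stationary OU signal trace.

    Uses the exact OU transition density rather than an Euler scheme, so the
    sample statistics are independent of ``dt``:

        s(t + dt) | s(t)  ~  N( s(t) e^(-dt/tau_s),  sigma_s^2 (1 - e^(-2 dt/tau_s)) )

    The initial value is drawn from the stationary distribution
    N(0, sigma_s^2), avoiding any burn-in transient.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be > 0")
    if duration < dt:
        raise ValueError("duration must be >= dt")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    if params.sigma_s == 0.0:
        return SignalTrace(dt=dt, values=np.zeros(n), seed=seed, params=params)
    decay = np.exp(-dt / params.tau_s)
    innov_sd = params.sigma_s * np.sqrt(-np.expm1(-2.0 * dt / params.tau_s))
    xi = rng.standard_normal(n)
    # AR(1) scan with the exact one-step transition; scipy.signal.lfilter
    # implements exactly this recursion and handles long traces in C.
    from scipy.signal import lfilter

    innov = innov_sd * xi
    innov[0] = params.sigma_s * xi[0]
    values = lfilter([1.0], [1.0, -decay], innov)
    return SignalTrace(dt=dt, values=values, seed=seed, params=params)


def write_signal(path, trace: SignalTrace) -> None:
    """Write a trace as two-column text (time_ms, signal_mV) with a '#' header."""
    header = [f"dt_ms = {trace.dt!r}", f"seed = {trace.seed!r}"]
    if trace.params is not None:
        header.append(f"sigma_s = {trace.params.sigma_s!r}")
        header.append(f"tau_s = {trace.params.tau_s!r}")
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, header="\n".join(header), fmt="%.9g")


def _parse_header(path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                val = val.strip()
                if val == "None":
                    continue
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
    return meta


def read_signal(path) -> SignalTrace:
    """Read a trace written by :func:`write_signal`."""
    meta = _parse_header(path)
    data = np.atleast_2d(np.loadtxt(path))
    times, values = data[:, 0], data[:, 1]
    dt = float(meta.get("dt_ms", times[1] - times[0] if len(times) > 1 else 1.0))
    params = None
    if "sigma_s" in meta and "tau_s" in meta:
        params = SignalParams(sigma_s=meta["sigma_s"], tau_s=meta["tau_s"])
    seed = meta.get("seed")
    return SignalTrace(
        dt=dt, values=values, seed=None if seed is None else int(seed), params=params
    )
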