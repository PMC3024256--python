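"""Reverse-correlation estimation of the cascade elements from spike data.

These estimators recover the linear filter (via the spike-triggered
average) and the static nonlinearity directly from simulated spike trains,
providing a data-driven validation of the analytic, parameter-free
construction in :mod:`lncascade.cascade`.

For an Ornstein-Uhlenbeck signal of variance sigma_s^2 and correlation time
tau_s the exact identity is

    STA(lag) * nu_bar = (K ⊛ C_ss)(lag),   C_ss(d) = sigma_s^2 e^{-|d|/tau_s},

so for tau_s much shorter than the filter width the signal acts as white
noise of intensity 2 sigma_s^2 tau_s and

    K(lag) ~= STA(lag) * nu_bar / (2 sigma_s^2 tau_s).

No deconvolution by the signal autocorrelation is attempted; the estimator
is therefore biased (smoothed on the scale tau_s) when tau_s is not small
compared to the filter width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neurons import PSTH, SpikeTrainSet
from .stimulus import SignalTrace

__all__ = ["STAResult", "NonlinearityEstimate", "spike_triggered_average", "estimate_nonlinearity"]


class EmptyResultError(RuntimeError):
    """No spikes available for the requested estimate."""


@dataclass
class STAResult:
    """Mean signal preceding spikes, on a lag grid in [0, window] ms."""

    lags: np.ndarray
    sta: np.ndarray
    n_spikes: int
    filter_estimate: np.ndarray | None = None  # Hz/(mV ms), white-signal identity


def spike_triggered_average(
    spikes: SpikeTrainSet, signal: SignalTrace, window: float
) -> STAResult:
    """Average of s(t_spike - lag) over all spikes, lag in [0, window].

    Spikes earlier than ``window`` are dropped (their lag window is not
    fully covered by the signal).  When the signal carries OU parameters,
    the white-signal normalisation nu_bar/(2 sigma_s^2 tau_s) is applied to
    produce ``filter_estimate`` for direct comparison with the analytic
    filter.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    dt = signal.dt
    n_lags = int(round(window / dt)) + 1
    lags = np.arange(n_lags) * dt
    acc = np.zeros(n_lags)
    count = 0
    s = signal.values
    for train in spikes.spike_times:
        if len(train) == 0:
            continue
        idx = np.round(train / dt).astype(np.int64)
        idx = idx[(idx >= n_lags - 1) & (idx < len(s))]
        for i in idx:
            acc += s[i - n_lags + 1 : i + 1][::-1]
        count += len(idx)
    if count == 0:
        raise EmptyResultError("no spikes in the valid window; cannot form an STA")
    sta = acc / count
    filt_est = None
    if signal.params is not None and signal.params.sigma_s > 0:
        nu_bar = spikes.total_spikes / (spikes.n_trials * spikes.duration) * 1000.0
        norm = nu_bar / (2.0 * signal.params.sigma_s**2 * signal.params.tau_s)
        filt_est = sta * norm
    return STAResult(lags=lags, sta=sta, n_spikes=count, filter_estimate=filt_est)


@dataclass
class NonlinearityEstimate:
    """Observed PSTH rate conditioned on the linear rate estimate.

    ``centers`` are mean linear-estimate values per quantile bin; ``mean``
    and ``sd`` summarise the distribution of simultaneous PSTH values.  The
    spread measures output variability that a static function of the linear
    drive cannot capture.
    """

    centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    counts: np.ndarray


def estimate_nonlinearity(
    linear_rate: np.ndarray, psth: PSTH, n_bins: int = 40, min_count: int = 20
) -> NonlinearityEstimate:
    """Quantile-bin the linear estimate; report the conditional PSTH mean and SD.

    Equal-count binning stabilises the per-bin standard deviation compared
    to equal-width bins.  Bins with fewer than ``min_count`` samples are
    dropped.
    """
    linear_rate = np.asarray(linear_rate, dtype=float)
    rates = np.asarray(psth.rates, dtype=float)
    if linear_rate.shape != rates.shape:
        raise ValueError("linear estimate and PSTH must share the time grid")
    edges = np.quantile(linear_rate, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # constant linear estimate: a single degenerate bin
        edges = np.array([edges[0], edges[0] + 1.0])
    which = np.clip(np.searchsorted(edges, linear_rate, side="right") - 1, 0, len(edges) - 2)
    centers, mean, sd, counts = [], [], [], []
    for b in range(len(edges) - 1):
        mask = which == b
        n = int(mask.sum())
        if n < min_count:
            continue
        centers.append(linear_rate[mask].mean())
        mean.append(rates[mask].mean())
        sd.append(rates[mask].std(ddof=1) if n > 1 else 0.0)
        counts.append(n)
    return NonlinearityEstimate(
        centers=np.array(centers), mean=np.array(mean), sd=np.array(sd), counts=np.array(counts)
    )
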