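"""Quantitative comparison between predicted rate traces and PSTHs.

Two complementary measures: the Pearson correlation rho, which scores only
the temporal covariation (it is invariant to affine rescaling of either
trace), and the RMS distance D in Hz, which additionally penalises offsets
in mean and scale.  For two traces standardised to equal mean and variance
sigma^2 the two are tied by D = sigma * sqrt(2 (1 - rho)).

The sampling floor of D is set by the finite trial count: a PSTH bin at
rate r estimated from N trials of width dt carries a Poisson counting error
of sqrt(r / (N dt)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ComparisonResult", "pearson", "rms_distance", "psth_sampling_error"]


@dataclass(frozen=True)
class ComparisonResult:
    rho: float
    d_rms: float
    n_bins: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")
        if self.d_rms < 0:
            raise ValueError("d_rms must be >= 0")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation over time bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("traces must have equal length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    va = np.dot(da, da)
    vb = np.dot(db, db)
    if va == 0.0 or vb == 0.0:
        raise ValueError("Pearson correlation undefined for a constant trace")
    return float(np.dot(da, db) / np.sqrt(va * vb))


def rms_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square distance between two rate traces (Hz)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def compare(a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    """Bundle rho and D for one prediction/PSTH pair."""
    return ComparisonResult(rho=pearson(a, b), d_rms=rms_distance(a, b), n_bins=len(a))


def psth_sampling_error(rate: float, n_trials: int, bin_dt: float) -> float:
    """Poisson counting error (Hz) of a PSTH bin at instantaneous rate ``rate`` Hz.

    sqrt(rate / (n_trials * bin_dt)), with bin_dt in ms converted so the
    result is in Hz.
    """
    if n_trials <= 0 or bin_dt <= 0:
        raise ValueError("n_trials and bin_dt must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float(np.sqrt(rate * 1000.0 / (n_trials * bin_dt)))
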