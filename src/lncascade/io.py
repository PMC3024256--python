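"""Plain-text writers/readers for the package's data objects.

Everything is delimited text with '#'-prefixed header metadata, so results
remain diffable and readable without the package.
"""

from __future__ import annotations

import numpy as np

from .fokker_planck import FilterTrace, FrequencyResponse
from .neurons import PSTH, SpikeTrainSet

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_psth",
    "read_psth",
    "write_response",
    "read_response",
    "write_filter",
    "read_filter",
    "write_rate_traces",
]


def write_spikes(path, spikes: SpikeTrainSet) -> None:
    """Columns (trial_index, spike_time_ms)."""
    rows = [
        (t, s) for t, train in enumerate(spikes.spike_times) for s in train
    ]
    header = f"n_trials = {spikes.n_trials}\nduration_ms = {spikes.duration!r}"
    arr = np.array(rows, dtype=float).reshape(-1, 2)
    np.savetxt(path, arr, header=header, fmt=["%d", "%.6f"])


def read_spikes(path) -> SpikeTrainSet:
    meta = _header(path)
    n_trials = int(meta["n_trials"])
    duration = float(meta["duration_ms"])
    arr = np.loadtxt(path, ndmin=2)
    trains = [[] for _ in range(n_trials)]
    for trial, t in arr:
        trains[int(trial)].append(t)
    return SpikeTrainSet(spike_times=trains, n_trials=n_trials, duration=duration)


def write_psth(path, psth: PSTH) -> None:
    """Columns (time_ms, rate_hz); times are bin centres."""
    header = f"bin_dt_ms = {psth.bin_dt!r}\nn_trials = {psth.n_trials}"
    np.savetxt(path, np.column_stack([psth.times, psth.rates]), header=header, fmt="%.6f")


def read_psth(path) -> PSTH:
    meta = _header(path)
    arr = np.loadtxt(path, ndmin=2)
    return PSTH(bin_dt=float(meta["bin_dt_ms"]), rates=arr[:, 1], n_trials=int(meta["n_trials"]))


def write_response(path, resp: FrequencyResponse) -> None:
    """Columns (freq_hz, re_hz_per_mv, im_hz_per_mv)."""
    header = f"mu0_mv = {resp.mu0!r}\nsigma0_mv = {resp.sigma0!r}"
    np.savetxt(
        path,
        np.column_stack([resp.freq_hz, resp.values.real, resp.values.imag]),
        header=header, fmt="%.9g",
    )


def read_response(path) -> FrequencyResponse:
    meta = _header(path)
    arr = np.loadtxt(path, ndmin=2)
    return FrequencyResponse(
        freq_hz=arr[:, 0], values=arr[:, 1] + 1j * arr[:, 2],
        mu0=float(meta.get("mu0_mv", np.nan)), sigma0=float(meta.get("sigma0_mv", np.nan)),
    )


def write_filter(path, filt: FilterTrace) -> None:
    """Columns (time_ms, k_hz_per_mv_ms)."""
    header = f"dt_ms = {filt.dt!r}\ncausality_residual = {filt.causality_residual!r}"
    np.savetxt(path, np.column_stack([filt.times, filt.values]), header=header, fmt="%.9g")


def read_filter(path) -> FilterTrace:
    meta = _header(path)
    arr = np.loadtxt(path, ndmin=2)
    return FilterTrace(
        dt=float(meta["dt_ms"]), values=arr[:, 1],
        causality_residual=float(meta.get("causality_residual", 0.0)),
    )


def write_rate_traces(path, times: np.ndarray, traces: dict) -> None:
    """One time column plus one rate column per model."""
    names = list(traces)
    header = "columns = time_ms " + " ".join(names)
    data = np.column_stack([times] + [np.asarray(traces[n]) for n in names])
    np.savetxt(path, data, header=header, fmt="%.6f")


def _header(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    return meta
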