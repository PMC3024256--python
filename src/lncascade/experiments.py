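"""Config-driven comparison experiments tying all modules together.

An experiment point is specified by four input parameters: the signal
amplitude sigma_s and correlation time tau_s, and the background noise
described by (nu0, sigma0) — the baseline firing rate and noise SD — with
the mean input mu0 recovered internally by inverting the transfer function.
Parametrising by the baseline rate rather than mu0 makes operating points
comparable across neuron models, and is well defined because every model
handled here has a continuous, monotonically increasing f-I curve.

For each point the workflow is: simulate the trial ensemble and its PSTH;
build the cascade elements from (nu0, sigma0) alone (nothing is fitted to
the PSTH); evaluate the requested predictors; report Pearson rho and RMS
distance per model, alongside the PSTH sampling error.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import (
    CascadeModel,
    RateModelParams,
    TauEffTable,
    build_nonlinearity,
    effective_timescale,
    predict_adaptive,
    predict_linear,
    predict_ln,
    predict_nonlinear,
    predict_rate_model,
)
from .fokker_planck import (
    TransferFunction,
    default_filter_grid,
    filter_from_response,
    lif_response,
    log_frequency_grid,
    mu_for_rate,
    threshold_response,
)
from .metrics import compare, psth_sampling_error
from .neurons import (
    EIFParams,
    LIFParams,
    SimConfig,
    WBParams,
    compute_psth,
    simulate_eif,
    simulate_lif,
    simulate_wb,
)
from .stimulus import NoiseParams, SignalParams, generate_signal

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "WB_EIF_SURROGATE",
    "build_cascade",
    "run_comparison",
    "wb_cascade_from_eif",
    "fit_eif_surrogate",
    "sinusoidal_response_probe",
]

#: EIF parameters whose transfer function reproduces the Wang-Buzsáki
#: stationary rates (voltages relative to the WB resting potential,
#: tau_m = C_m/g_L).  Calibrated once with :func:`fit_eif_surrogate` against
#: simulated WB rates on a 6 x 3 grid of (mu0, sigma0); agreement is within
#: the simulation standard errors across the grid.
WB_EIF_SURROGATE = EIFParams(
    tau_m=10.0, v_t=4.73, delta_t=3.10, v_r=-2.97, tau_ref=2.10, v_ceiling=34.73
)

_MODELS = ("linear", "nonlinear", "ln", "rate", "adaptive")


@dataclass
class ExperimentConfig:
    """One comparison experiment (possibly a sweep over parameter lists)."""

    neuron: str = "eif"  # lif | eif | wb
    params: object | None = None
    nu0: float = 10.0
    sigma0: float = 4.0
    sigma_s: float = 1.0
    tau_s: float = 10.0
    duration: float = 10_000.0
    n_trials: int = 100
    dt_sim: float = 0.01
    bin_dt: float = 1.0
    seed: int = 0
    models: tuple = _MODELS
    filter_dt: float = 0.25
    filter_df: float = 2.0
    dv: float = 0.01
    wb_surrogate: EIFParams = field(default_factory=lambda: WB_EIF_SURROGATE)

    def __post_init__(self) -> None:
        if self.neuron not in ("lif", "eif", "wb"):
            raise ValueError(f"unknown neuron kind {self.neuron!r}")
        if self.params is None:
            self.params = {"lif": LIFParams(), "eif": EIFParams(), "wb": WBParams()}[
                self.neuron
            ]
        if self.neuron == "lif" and self.models == _MODELS:
            # the rate-model reductions need the 1/omega response decay of
            # the EIF family; trim them from the default list for the LIF
            self.models = ("linear", "nonlinear", "ln")
        bad = set(self.models) - set(_MODELS)
        if bad:
            raise ValueError(f"unknown model(s) {sorted(bad)}")


def _transfer_for(cfg: ExperimentConfig) -> tuple[TransferFunction, object]:
    """Transfer function and response-function parameter set for a config.

    For the Wang-Buzsáki neuron both are those of the calibrated EIF
    surrogate: its transfer and linear-response functions stand in for the
    (analytically unavailable) WB ones.
    """
    if cfg.neuron == "lif":
        return TransferFunction("lif", cfg.params, dv=cfg.dv), cfg.params
    if cfg.neuron == "eif":
        return TransferFunction("eif", cfg.params, dv=cfg.dv), cfg.params
    return TransferFunction("eif", cfg.wb_surrogate, dv=cfg.dv), cfg.wb_surrogate


def build_cascade(cfg: ExperimentConfig) -> dict:
    """Construct every reduced model for one operating point (nu0, sigma0).

    Returns a dict with the noise parameters, cascade, rate-model and
    adaptive-model ingredients; nothing in it depends on the signal.
    """
    tf, rp = _transfer_for(cfg)
    mu0 = mu_for_rate(tf, cfg.nu0, cfg.sigma0)
    noise = NoiseParams(mu0=mu0, sigma0=cfg.sigma0)
    nl = build_nonlinearity(tf, mu0, cfg.sigma0)
    grid = default_filter_grid(dt=cfg.filter_dt, df=cfg.filter_df)
    if isinstance(rp, LIFParams):
        resp = lif_response(noise, rp, grid)
    else:
        resp = threshold_response(noise, rp, grid, dv=cfg.dv)
    filt = filter_from_response(resp, dt=cfg.filter_dt)
    cascade = CascadeModel(filter=filt, nonlinearity=nl)
    out = {"tf": tf, "noise": noise, "nonlinearity": nl, "response": resp, "cascade": cascade}
    if {"rate", "adaptive"} & set(cfg.models):
        lg = log_frequency_grid(1.0, 1e4, 25)
        if isinstance(rp, LIFParams):
            resp_lg = lif_response(noise, rp, lg)
        else:
            resp_lg = threshold_response(noise, rp, lg, dv=cfg.dv)
        tau_eff = effective_timescale(resp_lg, nl.g0)
        out["tau_eff"] = tau_eff
        out["rate_model"] = RateModelParams(tau_eff=tau_eff, nonlinearity=nl)
    if "adaptive" in cfg.models:
        if isinstance(rp, LIFParams):
            raise ValueError(
                "the adaptive-timescale model needs the 1/omega response decay of "
                "the EIF family; the LIF response decays as 1/sqrt(omega)"
            )
        out["tau_table"] = TauEffTable.build(tf, cfg.sigma0, dv=cfg.dv)
    return out


def _simulate(cfg: ExperimentConfig, noise: NoiseParams, signal):
    sim = SimConfig(
        dt_sim=cfg.dt_sim, n_trials=cfg.n_trials, duration=cfg.duration,
        base_seed=cfg.seed + 1000,
    )
    if cfg.neuron == "lif":
        return simulate_lif(cfg.params, noise, signal, sim)
    if cfg.neuron == "eif":
        return simulate_eif(cfg.params, noise, signal, sim)
    return simulate_wb(cfg.params, noise, signal, sim)


def run_comparison(cfg: ExperimentConfig, built: dict | None = None) -> pd.DataFrame:
    """Simulate one parameter point and score every requested predictor.

    Returns a tidy table with one row per model (plus a ``psth`` row with
    the sampling statistics); identical configs give identical tables.
    """
    t0 = time.time()
    if built is None:
        built = build_cascade(cfg)
    noise, nl = built["noise"], built["nonlinearity"]
    sig_fine = generate_signal(
        SignalParams(cfg.sigma_s, cfg.tau_s), cfg.duration, cfg.dt_sim, cfg.seed
    )
    spikes = _simulate(cfg, noise, sig_fine)
    psth = compute_psth(spikes, cfg.bin_dt)
    logger.info(
        "simulated %s: %d trials, %d spikes, %.1f s",
        cfg.neuron, cfg.n_trials, spikes.total_spikes, time.time() - t0,
    )
    sig_filt = sig_fine.resample(cfg.filter_dt)
    sig_bin = sig_fine.resample(cfg.bin_dt)
    n_bins = len(psth.rates)

    def to_bins(x: np.ndarray, dt: float) -> np.ndarray:
        step = int(round(cfg.bin_dt / dt))
        if step == 1:
            return x[:n_bins]
        # average prediction samples within each PSTH bin
        x = x[: n_bins * step]
        return x.reshape(-1, step).mean(axis=1)

    base = {
        "neuron": cfg.neuron, "nu0": cfg.nu0, "sigma0": cfg.sigma0,
        "sigma_s": cfg.sigma_s, "tau_s": cfg.tau_s, "seed": cfg.seed,
        "n_trials": cfg.n_trials,
    }
    rows = []
    err = psth_sampling_error(float(psth.rates.mean()), cfg.n_trials, cfg.bin_dt)
    rows.append(
        base | {
            "model": "psth", "rho": np.nan, "d_rms": np.nan,
            "psth_mean": float(psth.rates.mean()), "psth_error": err,
        }
    )
    preds = {}
    for model in cfg.models:
        if model == "linear":
            preds[model] = to_bins(
                predict_linear(sig_filt, built["cascade"].filter, nl.nu0), cfg.filter_dt
            )
        elif model == "nonlinear":
            preds[model] = to_bins(predict_nonlinear(sig_bin, nl), cfg.bin_dt)
        elif model == "ln":
            preds[model] = to_bins(predict_ln(sig_filt, built["cascade"]), cfg.filter_dt)
        elif model == "rate":
            preds[model] = to_bins(predict_rate_model(sig_bin, built["rate_model"]), cfg.bin_dt)
        elif model == "adaptive":
            preds[model] = to_bins(
                predict_adaptive(sig_bin, nl, built["tau_table"]), cfg.bin_dt
            )
    for model, pred in preds.items():
        res = compare(pred, psth.rates)
        rows.append(
            base | {
                "model": model, "rho": res.rho, "d_rms": res.d_rms,
                "psth_mean": float(psth.rates.mean()), "psth_error": err,
            }
        )
    return pd.DataFrame(rows)


def wb_cascade_from_eif(
    wb: WBParams,
    eif_equiv: EIFParams,
    noise: NoiseParams,
    filter_dt: float = 0.25,
    filter_df: float = 2.0,
    dv: float = 0.01,
) -> CascadeModel:
    """LN cascade for the Wang-Buzsáki model built from its EIF surrogate.

    The WB transfer and linear-response functions are not known in closed
    form, but an EIF with matched threshold, sharpness, reset and refractory
    period reproduces them closely; the cascade is therefore assembled
    entirely from the surrogate's Fokker-Planck solutions at the WB
    operating point.
    """
    if eif_equiv is None:
        raise ValueError("an EIF surrogate parameter set is required")
    tf = TransferFunction("eif", eif_equiv, dv=dv)
    nl = build_nonlinearity(tf, noise.mu0, noise.sigma0)
    grid = default_filter_grid(dt=filter_dt, df=filter_df)
    resp = threshold_response(noise, eif_equiv, grid, dv=dv)
    filt = filter_from_response(resp, dt=filter_dt)
    return CascadeModel(filter=filt, nonlinearity=nl)


def fit_eif_surrogate(
    wb: WBParams,
    mu_grid=(1.0, 2.0, 3.0, 5.0, 7.0, 9.0),
    sigma_grid=(2.0, 4.0, 6.0),
    n_trials: int = 24,
    duration: float = 4000.0,
    seed: int = 5,
    x0=(2.0, 3.0, -2.0, 1.5),
) -> EIFParams:
    """Least-squares fit of (v_t, delta_t, v_r, tau_ref) to the WB f-I surface.

    Simulates the WB stationary rate on the (mu, sigma) grid once, then
    adjusts the EIF transfer function to it.  This is a calibration helper,
    not part of the parameter-free cascade construction: the surrogate is
    fitted to stationary rates only, never to any PSTH it later predicts.
    """
    from scipy.optimize import least_squares

    sig0 = generate_signal(SignalParams(0.0, 10.0), duration, 0.01, seed)
    cfg = SimConfig(dt_sim=0.01, n_trials=n_trials, duration=duration, base_seed=seed)
    pts, rates = [], []
    for mu in mu_grid:
        for s0 in sigma_grid:
            spk = simulate_wb(wb, NoiseParams(mu, s0), sig0, cfg)
            pts.append((mu, s0))
            rates.append(spk.mean_rate(200.0))
    tau_m = wb.tau_m

    def resid(x):
        v_t, delta_t, v_r, tau_ref = x
        try:
            e = EIFParams(
                tau_m=tau_m, v_t=v_t, delta_t=delta_t, v_r=v_r,
                tau_ref=tau_ref, v_ceiling=v_t + 30.0,
            )
        except ValueError:
            return np.full(len(pts), 1e3)
        from .fokker_planck import eif_transfer

        return np.array(
            [eif_transfer(mu, s0, e, dv=0.02) - r for (mu, s0), r in zip(pts, rates)]
        )

    fit = least_squares(
        resid, x0=np.asarray(x0, dtype=float),
        bounds=([0.0, 0.5, -15.0, 0.0], [8.0, 8.0, 4.0, 5.0]), diff_step=0.05,
    )
    v_t, delta_t, v_r, tau_ref = fit.x
    return EIFParams(
        tau_m=tau_m, v_t=v_t, delta_t=delta_t, v_r=v_r,
        tau_ref=tau_ref, v_ceiling=v_t + 30.0,
    )


def sinusoidal_response_probe(
    p: LIFParams,
    noise: NoiseParams,
    f_hz: float,
    amplitude: float,
    duration: float = 10_000.0,
    n_trials: int = 100,
    dt_sim: float = 0.01,
    bin_dt: float = 1.0,
    base_seed: int = 0,
    n_groups: int = 8,
) -> tuple[complex, float]:
    """Complex PSTH component at ``f_hz`` under s(t) = A cos(2 pi f t).

    Returns (c, se) where c estimates A * R^(f): the PSTH is projected onto
    e^{-i omega t} over an integer number of periods, and the standard error
    comes from the spread over ``n_groups`` disjoint trial groups.  The
    direct simulation oracle for the analytic response function.
    """
    from .neurons import compute_psth as _psth
    from .stimulus import SignalTrace

    period = 1000.0 / f_hz
    n_per = max(int(duration // period), 1)
    t_used = n_per * period
    n_steps = int(round(duration / dt_sim))
    t = np.arange(n_steps) * dt_sim
    sig = SignalTrace(dt=dt_sim, values=amplitude * np.cos(2 * np.pi * f_hz * t / 1000.0))
    cfg = SimConfig(dt_sim=dt_sim, n_trials=n_trials, duration=duration, base_seed=base_seed)
    spikes = simulate_lif(p, noise, sig, cfg)
    psth_full = _psth(spikes, bin_dt)
    tb = psth_full.times
    mask = tb < t_used
    phase = np.exp(-2j * np.pi * f_hz * tb[mask] / 1000.0)

    def project(rates):
        return 2.0 * np.mean(rates[mask] * phase)

    groups = np.array_split(np.arange(n_trials), n_groups)
    comps = []
    for g in groups:
        sub = spikes.spike_times
        counts = np.zeros(mask.sum())
        edges = np.arange(len(psth_full.rates) + 1) * bin_dt
        acc = np.zeros(len(psth_full.rates))
        for i in g:
            c, _ = np.histogram(sub[i], bins=edges)
            acc += c
        rates_g = 1000.0 * acc / (len(g) * bin_dt)
        comps.append(project(rates_g))
    comps = np.array(comps)
    c_mean = project(psth_full.rates)
    se = float(np.std(comps, ddof=1) / np.sqrt(n_groups))
    return complex(c_mean), se
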