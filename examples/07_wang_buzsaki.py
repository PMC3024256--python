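"""Reduce a conductance-based neuron through its integrate-and-fire surrogate.

The Wang-Buzsáki model has no analytic transfer or response function, but
an exponential integrate-and-fire neuron with matched threshold, sharpness,
reset and refractory period reproduces both.  The cascade built from that
surrogate predicts the firing rate of the full conductance-based model.
"""

from lncascade import (
    ExperimentConfig,
    NoiseParams,
    SignalParams,
    SimConfig,
    WBParams,
    WB_EIF_SURROGATE,
    eif_transfer,
    generate_signal,
    run_comparison,
    simulate_wb,
    wb_resting_state,
)

wb = WBParams()
v_rest, h_rest, n_rest = wb_resting_state(wb)
print(f"WB resting state:  V = {v_rest:.2f} mV, h = {h_rest:.3f}, n = {n_rest:.3f}")

# stationary-rate check of the surrogate at one noise point
noise = NoiseParams(4.0, 4.0)
sig0 = generate_signal(SignalParams(0.0, 10.0), 4000.0, 0.01, seed=1)
spk = simulate_wb(wb, noise, sig0, SimConfig(0.01, 24, 4000.0, base_seed=5))
print(f"WB simulated rate: {spk.mean_rate(200.0):.2f} ± {spk.mean_rate_se(200.0):.2f} Hz")
print(f"EIF surrogate:     {eif_transfer(noise.mu0, noise.sigma0, WB_EIF_SURROGATE):.2f} Hz")

# full PSTH prediction with the surrogate cascade and rate models
cfg = ExperimentConfig(
    neuron="wb", nu0=20.0, sigma0=4.0, sigma_s=2.0, tau_s=10.0,
    duration=8_000.0, n_trials=100, seed=5, models=("ln", "adaptive"),
)
table = run_comparison(cfg)
print(table[["model", "rho", "d_rms", "psth_error"]].to_string(index=False))
# Everything in the 'ln' and 'adaptive' rows was computed from the EIF
# surrogate's Fokker-Planck solutions; the spiking data are pure WB.
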