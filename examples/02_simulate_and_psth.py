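"""Simulate a repeated-trial experiment and average the spikes into a PSTH.

An exponential integrate-and-fire neuron receives the same signal in every
trial plus background white noise that is drawn independently per trial;
the PSTH (1 ms bins, trial-averaged rate in Hz) is the quantity every
reduced model in this package tries to predict.
"""

from lncascade import (
    EIFParams,
    NoiseParams,
    SignalParams,
    SimConfig,
    compute_psth,
    eif_transfer,
    generate_signal,
    simulate_eif,
)

eif = EIFParams()
noise = NoiseParams(mu0=8.0, sigma0=4.0)
signal = generate_signal(SignalParams(sigma_s=1.5, tau_s=10.0), 5_000.0, 0.01, seed=7)
cfg = SimConfig(dt_sim=0.01, n_trials=100, duration=5_000.0, base_seed=0)

spikes = simulate_eif(eif, noise, signal, cfg)
psth = compute_psth(spikes, bin_dt=1.0)

print(f"trials:              {cfg.n_trials}, duration {cfg.duration/1000:.0f} s each")
print(f"total spikes:        {spikes.total_spikes}")
print(f"mean rate:           {spikes.mean_rate():.2f} Hz")
print(f"theory (no signal):  {eif_transfer(noise.mu0, noise.sigma0, eif):.2f} Hz")
print(f"PSTH bins:           {len(psth.rates)} x {psth.bin_dt} ms, peak {psth.rates.max():.0f} Hz")
# The signal modulates the rate around the stationary value; the mean rate
# sits close to the zero-signal transfer function because the signal is
# zero-mean and the modulation is roughly symmetric at this amplitude.
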