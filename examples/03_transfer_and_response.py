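"""The two Fokker-Planck building blocks of the cascade.

For an operating point set by the baseline rate nu0 and noise SD sigma0:
the transfer function Phi(mu, sigma) gives the static nonlinearity, and the
rate response function R^(omega) gives the linear filter.  Both come from
the model's Fokker-Planck equation — nothing is fitted to data.
"""

from lncascade import (
    EIFParams,
    NoiseParams,
    TransferFunction,
    default_filter_grid,
    effective_timescale,
    filter_from_response,
    log_frequency_grid,
    mu_for_rate,
    threshold_response,
    transfer_slope,
)

eif = EIFParams()
tf = TransferFunction("eif", eif)
nu0, sigma0 = 15.0, 4.0

mu0 = mu_for_rate(tf, nu0, sigma0)        # invert the f-I curve
g0 = transfer_slope(tf, mu0, sigma0)      # gain = filter integral
print(f"operating point: mu0 = {mu0:.3f} mV gives nu0 = {tf.rate(mu0, sigma0):.2f} Hz")
print(f"gain dPhi/dmu:   {g0:.3f} Hz/mV")

noise = NoiseParams(mu0, sigma0)
resp = threshold_response(noise, eif, default_filter_grid(dt=0.25, df=2.0))
filt = filter_from_response(resp, dt=0.25)
print(f"|R(0)|:          {abs(resp.values[0]):.3f} Hz/mV  (equals the gain)")
print(f"filter integral: {filt.integral:.3f} Hz/mV, acausal residual {filt.causality_residual:.1e}")

lg = log_frequency_grid(1.0, 1e4, 25)
tau_eff = effective_timescale(threshold_response(noise, eif, lg), g0)
print(f"high-freq decay: log-log slope {threshold_response(noise, eif, lg).loglog_slope():.3f} (EIF: -1)")
print(f"tau_eff:         {tau_eff:.2f} ms  (single-exponential filter matched at both ends)")
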