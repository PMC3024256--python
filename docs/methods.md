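# Methods

## Models and input statistics

All membrane-potential models are driven by the same decomposition of the
synaptic current (expressed in mV):

    I(t) = mu0 + s(t) + sigma0 * sqrt(tau_m) * eta(t)

where s(t) is the *signal* — a zero-mean Ornstein-Uhlenbeck (OU) process
with SD `sigma_s` and correlation time `tau_s`, identical across trials —
and the remainder is *background noise*: white, Gaussian, independent
across trials, parametrised by its mean `mu0` and SD `sigma0`.  Under this
convention the stationary LIF rate is the Siegert expression with
integration bounds `(v_th - mu)/sigma` and `(v_r - mu)/sigma`; the
simulation/theory cross-checks in the test suite pin the convention down.

* **LIF**: `tau_m dV/dt = -V + I(t)`; spike and reset at a hard threshold,
  refractory period `tau_ref`.
* **EIF**: adds the spike-generating current
  `delta_t * exp((V - v_t)/delta_t)`; the upward divergence is detected at
  `v_ceiling` and stands for the action potential.
* **Wang-Buzsáki (WB)**: single-compartment Hodgkin-Huxley-type
  interneuron model with instantaneous sodium activation (m = m_inf(V)),
  gating kinetics scaled by phi = 5, and the canonical constants
  (g_Na = 35, g_K = 9, g_L = 0.1 mS/cm^2, E_Na = 55, E_K = -90,
  E_L = -65 mV, C_m = 1 uF/cm^2).  mV-scale inputs are converted to
  current density through g_L, with tau_m = C_m/g_L = 10 ms.

Default LIF/EIF constants (tau_m = 20 ms, v_th = 20, v_r = 10 mV for the
LIF; v_t = 10, delta_t = 1.5, v_r = 5 mV for the EIF; tau_ref = 2 ms) are
representative cortical values; every one is a plain dataclass field and
freely overridable.

## Signal generation

The OU trace uses the exact transition density

    s(t+dt) | s(t) ~ N( s e^(-dt/tau_s), sigma_s^2 (1 - e^(-2dt/tau_s)) )

with the initial value drawn from the stationary law, so the statistics
are independent of the sampling step and no burn-in is needed.  White
background noise is never materialised as a trace (it has no
dt-independent sample path); it enters the integrators as Gaussian
increments of SD `sigma0 sqrt(dt/tau_m)` per step.

## Stochastic integration

The deterministic part of each step is advanced by Heun's method (RK2) at
`dt_sim = 0.01 ms` by default; the noise increment is added
Euler-Maruyama-style, which is the correct strong-order treatment for
additive white noise.  Three details matter for accuracy:

* **LIF threshold crossing.** A discrete scheme misses excursions above
  threshold that begin and end within one step, biasing the rate downward
  by O(sqrt(dt)).  The simulator compensates with the standard
  absorbing-boundary shift: spikes are detected at
  `v_th - 0.5826 * sigma0 * sqrt(dt/tau_m)`
  (0.5826 = |zeta(1/2)|/sqrt(2 pi) times the per-step noise SD), and the
  crossing time is linearly interpolated.  Measured against the Siegert
  rate, this removes a ~1% deficit at dt = 0.01 ms.
* **Refractory bookkeeping.** The hold ends mid-step; the remainder of
  that step is integrated from the reset with a shortened step, so
  noise-free inter-spike intervals are accurate to O(dt^2) (checked to 4
  significant digits against the closed form).
* **EIF/WB spike detection.** EIF spikes are recorded at the first step at
  or above `v_ceiling`; the divergence is super-exponential, so the timing
  error is far below dt.  WB spikes are upward crossings of 0 mV with a
  2 ms minimum separation to suppress double detection.

Trial t uses seed `base_seed + t`, making any subset of the ensemble
bit-reproducible.

## Steady-state Fokker-Planck solutions

`siegert_rate` evaluates the LIF mean-first-passage quadrature with the
integrand written as `erfcx(-u)` (stable on the whole axis); operating
points more than ~12 SDs below threshold switch to the leading Kramers
asymptotics in log space.

`eif_transfer` integrates the steady flux/density system downward from the
absorbing top of a voltage grid (spacing 0.01 mV, nodes anchored at the
top so the computed rate is smooth in mu — a mu-dependent grid would break
root-finding on the f-I curve).  Each cell uses the exact update for
piecewise-constant drift, the flux drops to zero below the reset, and the
rate follows from normalisation including the refractory mass.  Densities
are saturated at 1e280 in the extreme small-noise regime
(sigma0 below ~0.7 mV at moderate rates), where the Kramers factor exceeds
double precision; rates there are returned as 0 rather than overflowing.
This bounds the usable noise range of the solver and is the reason the
exponential-filter-mismatch scan (below) starts at sigma0 = 1 mV.

The same scan applied to the LIF provides a second, independent route to
the Siegert rate (they agree to ~1e-4 relative in the tests).

## Linear response functions

Two independent solvers compute the rate response R^(omega) — the complex
gain from a small mean-input modulation to the rate modulation:

* **LIF, bounded-branch ODE.**  In the rescaled voltage
  `y = (V - mu0)/sigma0` the frequency-domain perturbation problem reduces
  to the Hermite-type equation `Psi'' = 2 y Psi' + 2 i omega tau_m Psi`.
  The branch that stays bounded as y -> -infinity is integrated upward
  (fixed-step RK4, initialised from its algebraic asymptotics), and the
  response assembles from boundary ratios at the rescaled reset and
  threshold, with the phase factor `e^(-i omega tau_ref)` expressing the
  delayed re-injection of the reset flux.  The overall scale of Psi
  cancels (asserted by invariance under rescaling the initial condition by
  10^±3).
* **Threshold integration (LIF and EIF).**  The linearised density/flux
  system is integrated downward over the steady-state grid at each
  frequency, driven by the source term p0/tau_m of a unit mean modulation;
  the rate modulation follows from the zero-flux condition at the lower
  boundary.  At omega = 0 the scan is 0/0; that limit equals the
  transfer-function slope and is returned as such.

The two routes agree within 2% at all tested frequencies up to 5 kHz, and
both satisfy the exact checks |R^(0)| = dPhi/dmu (to 0.001%) and the
high-frequency laws |R^| ~ omega^(-1/2) (LIF) and omega^(-1) (EIF).  The
sinusoidal-stimulation oracle — driving the simulated LIF with a small
cosine and reading the complex PSTH component — confirms amplitude and
phase within Monte-Carlo error, which also fixes the sign conventions
end-to-end.

## Filter inversion

|R^| decays only algebraically, so a raw truncated inverse FFT rings at
the causal edge (for a Lorentzian test spectrum: 8% acausal residual, and
the t = 0 sample lands at the Gibbs midpoint, 50% low).  The inversion
therefore multiplies the spectrum by `sinc^2(f dt)` before the transform:
each returned sample is the exact triangular-kernel average of K over
[t - dt, t + dt], which a frequency grid extending five times past the
output Nyquist (default 0-10 kHz at 2 Hz for dt = 0.25 ms) represents to
~2e-4 of the peak.  This is also precisely the discretisation under which
the discrete convolution with a linearly-interpolated signal is exact, so
filter samples are combined with plain Riemann weights.  The residual at
strictly negative sample times ("causality residual") is reported on every
filter and stays below 0.3% of peak for both models at the standard
operating point.

## Cascade normalisation and the reduced models

The split between K and F is fixed by requiring both exact limits at once:
K carries physical units (integral = dPhi/dmu, Hz/mV), and F has unit
slope at the origin, `F(x) = Phi(mu0 + x/g0, sigma0)`.  F is evaluated
through a monotone PCHIP table of Phi(mu) per sigma (200 nodes, extended
on demand; interpolation error ~1e-9 relative), so trace-length
predictions cost interpolation, not quadrature.

The **rate model** keeps the drive u in input units,
`tau_eff du/dt = -u + s(t)`, r = Phi(mu0 + u), advanced by the exact
exponential update.  With the exponential filter stored as bin averages
this is *identical* to the LN cascade with that filter (agreement at
float precision in the tests), which is why the u-form was chosen over an
ODE on the rate itself — the two differ at strong nonlinearity, and only
the u-form is exactly the exponential-filter cascade.

`tau_eff = g0 / C`, with C the high-frequency asymptote of omega*|R^|,
estimated by averaging over the top decade of a log grid after checking
flatness (<5% drift).  The **adaptive-timescale model** re-evaluates
tau_eff each step at the rate predicted one step earlier, via a
30-point log-spaced table of tau_eff(nu) built along the f-I curve
(mu(nu) by inversion at fixed sigma0, monotone cubic interpolation,
clamped outside).  Only the timescale adapts; gain and nonlinearity stay
at their baseline construction.  The table's upper rate is 90% of
Phi(mu = 50 mV, sigma0) — the achievable ceiling of an EIF-type model is
set by the f-I curve, since the reset-to-ceiling transit adds to the
refractory period.

The tau_eff(nu) table is evaluated self-consistently along the f-I curve,
so at nu = nu0 it reduces exactly to the baseline tau_eff; whether the
gain inside tau_eff should instead track the instantaneous operating
point is a genuinely open modelling choice, and the along-the-curve form
was adopted as the one that collapses to the non-adaptive model in the
weak-signal limit (verified by the continuity test).

## Wang-Buzsáki surrogate

The WB transfer and response functions are not known analytically.  An
EIF with matched threshold, sharpness, reset and refractory period
(`WB_EIF_SURROGATE`: v_t = 4.73, delta_t = 3.10, v_r = -2.97 mV relative
to rest, tau_ref = 2.10 ms, tau_m = 10 ms) stands in for them.  These
values were calibrated once with `fit_eif_surrogate` — least squares of
the EIF transfer function against simulated WB stationary rates on a
6 x 3 grid of (mu, sigma) — and reproduce the WB rates within the
simulation standard errors at all 18 grid points.  The surrogate is fitted
to stationary rates only, never to any PSTH it later predicts, so the
cascade built from it remains parameter-free with respect to the data
being predicted.

## Reverse correlation

For an OU signal the exact identity is
`STA(lag) * nu_bar = (K ⊛ C_ss)(lag)` with
`C_ss(d) = sigma_s^2 e^(-|d|/tau_s)`; for tau_s far below the filter width
this gives `K ≈ STA * nu_bar / (2 sigma_s^2 tau_s)`.  No deconvolution by
the signal autocorrelation is attempted, so the estimator is smoothed on
the scale tau_s — a bias that matters once tau_s is not small against the
filter width.  The error floor of the estimate is set by the *signal
duration*, not the trial count: spikes cluster at the same signal features
across trials, so adding trials stops helping once the per-feature
sampling saturates.  The validation run uses a 60 s signal at
tau_s = 0.5 ms and reaches a normalised RMS of 0.05-0.09 against the
analytic filter, with no fitted parameters.

The nonlinearity estimate conditions the PSTH on the linear drive in
equal-count (quantile) bins — 40 by default, at least 20 samples each —
which stabilises the per-bin SD relative to equal-width binning.

## Comparison metrics

Pearson rho scores temporal covariation only (affine-invariant); the RMS
distance D (Hz) additionally penalises mean/scale errors, and for traces
standardised to equal mean and variance the identity
`D = sigma sqrt(2 (1 - rho))` holds exactly.  The sampling floor of D is
the Poisson counting error `sqrt(r/(N dt))` of a PSTH bin, which the
Monte-Carlo test reproduces within 10%.

## What the synthetic data do and do not show

All validation data are generated by the package's own simulators under
the same diffusion-input assumptions the theory makes: current-based
white background noise, OU signal, no adaptation currents, no synaptic
conductance dynamics or filtering, no trial-to-trial nonstationarity.
Passing tests therefore demonstrate the internal correctness of the
reduction — that the Fokker-Planck cascade predicts the spiking models it
was derived for — not that real neurons are this well described.  In
particular, colored background noise changes the high-frequency response
laws, and conductance (multiplicative) input would rescale the effective
membrane time constant; both are outside scope.

## Known limitations

* The steady-state scan saturates below sigma0 ≈ 0.7 mV at moderate rates
  (float64 dynamic range); the weak-noise oscillatory regime is reachable
  for the response function but not arbitrarily deep for the f-I curve.
* The LIF filter's t^(-1/2) short-time growth is represented only through
  its triangular-kernel averages; pointwise values within one sample of
  t = 0 are not meaningful.
* The adiabatic limit is approached pointwise only as fast as the signal
  is smooth: for OU signals the sup-norm gap between the cascade and the
  pointwise f-I prediction decays as ~1/sqrt(tau_s) because the OU
  roughness is amplified by the steep low-rate tail of Phi; deep-trough
  relative errors remain tens of percent even at tau_s = 5 s, while
  smooth slow signals converge at first order.
* Simulation-vs-theory comparisons in the tests run at reduced problem
  sizes (tens of trials, 5-60 s of biological time) chosen so that
  Monte-Carlo standard errors, not compute, dominate the comparison;
  3-SE tolerances are used throughout.
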