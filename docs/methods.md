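# Methods

## Model and operating point

The network is a threshold-linear Wilson–Cowan-type system: one E and one I
population per area, local weights `w_EE, w_EI, w_IE, w_II`, long-range
weights `mu_EE FLN` (onto E) and `mu_IE FLN` (onto I), and a rectified gain
`f(x) = beta [x]_+`. The same FLN matrix drives both target populations —
tracer data do not resolve the transmitter identity of targets — with the
two global scalars `mu_EE` and `mu_IE` setting their relative efficacy.
The composite excitation gradient `h_i` multiplies every excitatory input
of target area *i* through the factors `(1 + eta_E h_i)` on the E equations
and `(1 + eta_I h_i)` on the I equations. Units are fixed: time in ms,
rates in Hz, currents in pA; `beta` in Hz/pA and weights in pA/Hz, so
`beta * w` is dimensionless.

Parameter defaults are the calibrated set
`tau_E = 20 ms, tau_I = 10 ms, beta_E = 0.066, beta_I = 0.351,
eta_E = 0.685, eta_I = 0.76, w_EE = 24.4, w_EI = 19.7, w_IE = 11.66,
w_II = 12.5, mu_EE = 67.4, mu_IE = 49.81`.

The operating point is the fixed point of the rectified system under
constant drive, solved exactly by active-set iteration: populations with a
positive bracket argument are "linear", silenced populations sit at zero;
the linear subsystem is solved and the active set updated until
self-consistent (residual below 1e-10 Hz, cycles reported as instability).
The baseline currents are not part of the published parameter set; the
package defaults to `I_E = 10 pA, I_I = 0 pA` per area, which keeps an
isolated area in the linear regime at (1.75, 1.33) Hz, and to white current
noise of 0.5 pA·√ms on both populations for resting-state runs. All three
are configurable and recorded in every manifest.

### Stability structure

Stability is read off the spectral abscissa (largest eigenvalue real part)
of the 2N×2N Jacobian assembled at the fixed point; silenced populations
contribute only their leak. Two non-obvious facts shape the sweeps:

- The stable region in `mu_EE` is a **window**, not a half-line. With
  strong `mu_IE`, a weakly E–E-coupled network destabilizes through a
  mutual-disinhibition (competition) mode: area A excites area B's
  interneurons, which suppress B, and vice versa — a positive feedback loop
  through two inhibitory links. `critical_coupling` therefore brackets the
  *upper* edge of the window, starting from a stable operating point (or
  locating the window by coarse scan when the starting point is unstable).
  On the default synthetic fixture the window's upper edges for
  `mu_IE = 24.91, 37.36, 49.81` are ≈ 35.7, 52.0, 68.4 pA/Hz.
- A gradient value `h` large enough to push the *local* effective E→E
  weight `(1 + eta_E h) w_EE` past its critical value 30.12 pA/Hz
  (determinant condition of the 2×2 block) does **not** destabilize a lone
  area, because `eta_I h` raises the E→I drive in step. The quoted
  "critical h ≈ 0.342" is the inversion of the E-side factor alone and is
  reported as such; the sign flip is exact when `eta_I = 0`.

### Integration

Forward Euler (Euler–Maruyama with noise, per-step noise scaled by
`1/sqrt(dt)`), default `dt = 0.05 ms` for oracle-grade runs and 0.25–0.5 ms
for property runs; the precondition `dt ≤ tau_I/20` keeps the rectified
non-smooth dynamics well resolved and observed convergence is first order.
Delays use per-pair circular history buffers; `tau_ij = d_ij / v_ax`
(mm / (m/s) = ms) rounded to the nearest step with ties up, local terms
delayed by `local_delay` (2 ms by default; a value of 0 is allowed and
makes the delayed code path reproduce the undelayed scheme exactly, which
is how the ODE-limit equivalence is tested — a one-step local delay can
only converge at O(dt) and is tested at that rate instead). History before
t = 0 equals the initial state.

## Timescale estimation

Welch PSD with Hamming windows and 50% overlap; channels mapped to the
same area are averaged. The aperiodic component `A/(k + f^chi)` is fitted
in log10 power against linear frequency with a Huber loss; residual peaks
above 2.5 residual SDs are fitted as Gaussians and their bands (±3 fitted
widths) are *masked* during the aperiodic refit — masking rather than
subtracting keeps imperfect peak shapes from biasing the knee. Residuals
are weighted by `f^-0.25`: on a linear frequency grid the knee region holds
few bins but all the timescale information. Initialization: `chi = 2`, `k`
from the half-power frequency; `tau = 1/(2 pi k^(1/chi))` is always derived,
never stored. The knee is declared undefined when it falls outside the fit
range and the area's `tau` is reported missing rather than dropped.

Two configurations are used: the standard one (1-s windows, 0.5–80 Hz) for
resting-state runs whose knees sit at a few Hz, and a calibration
configuration (4-s windows, 0.25–80 Hz) when slow channels down to
`tau = 400 ms` (knee 0.4 Hz) must be resolved — a 1-s window's 1-Hz
resolution cannot see such a knee. Calibration on exact OU ladders
(25–400 ms, 60 s at 1 kHz) gives per-level median errors within 10% and
exact rank order of the medians; the fitted exponent clusters at 2, as an
OU spectrum implies.

## Gradient estimation

`L(h) = Corr(tau_exp, 1/(1-h)) + lambda Corr(h_exp, h)` with `lambda = 1`,
maximized by L-BFGS-B over `[0, h_max]^N` (default `h_max = 0.9`, the
optimization bound being our choice) from one rank-informed start plus
random restarts. Because both terms are correlations the solution is only
weakly identified up to monotone rescalings; the default `minmax` anchor
rescales to `[0, h_max]` for reproducibility, but only when the rescaling
is objective-neutral (the timescale term is not exactly affine-invariant),
otherwise the raw optimum is returned. Extrapolation to unmeasured areas
uses weights `exp(-|h_i,exp - h_j,exp|^2 / sigma^2)`, `sigma = 0.05`,
normalized by default (a weighted average); the unnormalized literal sum
is exposed as an option since both conventions are defensible.

## Localization metrics

`IPR = Σ|v_j|^4` on the unit-normalized moduli of the E-entries of each
eigenvector (the per-area displays and all downstream analyses use E
rates; an option folds in I entries by root-sum-of-squares). Conjugate
pairs share moduli and are collapsed to the member with `Im ≥ 0`. `theta`
weights concentration by proximity with kernel scale `d̄`, the mean
*off-diagonal* distance — including the zero diagonal would bias the scale
down. Note `theta ≤ IPR²`, with equality only when a mode's support is
mutually at zero distance, so `theta` conflates concentration and
proximity; the spatial part alone is `theta/IPR²`.

## FC–SC comparison

FC is the Pearson correlation of E rates: empirically after discarding the
transient, or analytically as the correlation form of the E-block of the
stationary covariance solving `J S + S J' + Q = 0` with
`Q = diag((beta_X sigma_X / tau_X)^2)` — the same noise convention the
simulator uses, so the two routes agree (max-abs ≤ 0.05 on a 3-area fixture
against a 600-s simulation). For the global dissimilarity SC is the
symmetrized `(FLN + FLN')/2` (FC is symmetric, FLN is not; neither
convention is canonical and the choice is recorded in the report); per-area
dissimilarity uses each target's directed incoming row. The default
comparison is against raw FLN, with a log option that excludes absent
connections.

## Synthetic data

The generator is the package's study population, not a caricature of one
dataset. Its defaults define the conditions under which all properties are
tested:

- 30 areas in an 18-mm box, grouped around 5 cluster centers with 1.2 mm
  scatter — cortical areas come in lobes, and clustered geometry is what
  gives the proximity kernel in `theta` its contrast;
- EDR decay length 5 mm with lognormal log-weight noise of SD 0.8, rows
  normalized per target, as tracer-derived FLN matrices are;
- hierarchy ranks follow a noisy spatial axis (sensory at one end),
  mirroring the spatial organization of real cortical hierarchies; SLN is
  a logistic function of the hierarchy difference (steepness 6) — an
  invented but conventional rule, documented as such and never used as
  ground truth for SLN-specific claims;
- the ground-truth gradient rises linearly in hierarchy rank to 0.6,
  placing the full network at the printed couplings in the stable,
  near-critical regime (spectral abscissa ≈ −0.009/ms at `gamma = 1`).

A `strong_edr` preset (55 areas, EDR length 2 mm, weight noise 0.6,
gradient to 0.4) is used for the connectivity-shuffling experiment, where
modes must be carried by groups of physically proximal areas for spatial
localization to be measurable: with the steep default gradient most modes
collapse onto single areas and shuffling can even *increase* raw `theta`
through the concentration term, so the flatter-gradient strong-EDR fixture
is the appropriate test bed for the spatial claim. Shuffle comparisons are
made against the mean over several shuffles per fixture (the distribution
view), not single draws.

Activity surrogates are exact discrete OU processes
(`x_{t+1} = a x_t + sqrt(1-a²) xi`, `a = exp(-dt/tau)`, stationary start,
unit variance), so estimator tests are not confounded by integrator bias;
optional oscillatory peaks are complex-OU resonators with Lorentzian lines
of chosen center, relative power and bandwidth.

What the generator does **not** emulate: the marmoset's actual FLN value
distribution beyond EDR + lognormal noise, electrode-level measurement
noise, volume conduction, line noise, or non-stationarity. Passing tests
therefore demonstrate the pipeline's correctness and the model's
qualitative mechanisms under realistic statistical structure — not that
any particular empirical dataset would yield the same numbers.

## Problem sizes and numerical choices

Property tests use 20 seeds of the 30-area fixture (55 for shuffling) with
sign tests at p < 0.05; oracle equivalences use `dt = 0.02–0.25 ms` and a
600-s FC simulation at three areas; resting-state runs are 60 s at an
effective 1 kHz. Bisection tolerance for critical couplings is 1e-6
relative; fixed-point residual 1e-10 Hz; eigen-solves use dense LAPACK
(networks here are ≤ 110-dimensional). Degenerate inputs (constant
timescales, absent SLN, unstable baselines, empty windows) raise typed
errors rather than propagating silently; unstable sweep points are flagged
rows, not aborts.

## Known limitations

- The delayed integrator is O(N²) memory in the history window and is
  intended for ≤ 100-area networks.
- `fit_aperiodic` assumes a single knee; spectra with two aperiodic
  regimes (e.g., an additional low-frequency plateau) will fit the
  dominant one.
- Analytic FC ignores rectification: it is exact only while no population
  crosses its threshold, which holds at the default operating point but
  not arbitrarily close to criticality with large noise.
- The mutual-disinhibition lower stability edge means "reduce `mu_EE`" is
  not a safe fallback for stabilizing a network; move toward the window.
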