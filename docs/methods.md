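# Methods

This note records the models implemented in `neuroloop`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coupling biomarker

### Envelope pipeline

The high-frequency content of a single-channel recording is isolated with a
zero-phase four-pole Butterworth band-pass (200-300 Hz, or 300-500 Hz where
the recording bandwidth allows), full-wave rectified, mean subtracted and
resampled to exactly 1 kHz with a polyphase anti-aliasing resampler.  The
rectifier also produces a line at twice the carrier frequency; content at
the output Nyquist edge is an artifact of rectification, not demodulated
signal, and consumers should ignore it.

### Complex-valued filter

The beta-band filter is parametrized in the frequency domain: complex gains
on the DFT bins of a 256-tap grid restricted to 13-30 Hz (4-5 bins at
1 kHz), zero elsewhere including negative frequencies, so the output is an
analytic beta-band signal.  The gains minimize the relative variance q^2 of
the output magnitude, optimized by L-BFGS-B from a fixed Gabor-atom
initializer centered at 21.5 Hz; the design is deterministic given the
input, and q^2 never exceeds the initializer's value.  A Blackman taper on
the impulse response suppresses the -13 dB truncation sidelobes that a
rectangular cut would leak across the spectrum, so the realized
(linear-convolution) response honors the band restriction; the filter
output is normalized to unit RMS before the log so that none of the 0-1
test's (EV)^2 terms depend on recording units.

The achieved q^2 itself is strongly informative: a coherent beta-band
envelope line (coupling) lets the optimizer make |z| nearly constant
(q^2 ~ 1e-3), while for Gaussian envelope noise no linear filter can push
the population q^2 below 1, and the empirical value stays above ~0.5.

### 0-1 test for chaos

Implemented exactly as stated in the package API: N_c = 100 frequencies
drawn uniformly on (0, pi) from a seeded generator, translation variables
over n_max = 1000 samples, mean squared displacement estimated for
n <= n_cut = n_max/10 by a time average over a fixed window of
n_max - n_cut start indices, the oscillatory term subtracted, and a damping
term h (EV)^2 sin(2n) added.  The damping argument `2n` follows the primary
description; a `sqrt2` switch provides the sin(sqrt(2) n) variant known
from the noise-robust-test literature, because the printed argument is
plausibly a typographical contraction of it.  The damping constant defaults
to h = 1 for Parkinson's-disease mode and h = 0 for OCD mode.  Constant
input has no displacement dynamics; the test returns K_t = 0 with a
degenerate-input flag.  The decision threshold is K_t < 0.1 for regular
dynamics (= significant coupling).

The log transform floors its argument at 1e-12 of the maximum magnitude to
avoid -inf.

### Comparators

The modulation index uses 18 phase bins (the convention of the method it
follows), zero-phase Butterworth band-passes and the analytic signal, and
normalizes the Kullback-Leibler distance to the uniform profile by
log(n_bins) so it lies in [0, 1].  Empty phase bins are merged into their
neighbours with a warning.  Phase-slip counting thresholds the
instantaneous angular frequency at the band-pass limits; roughly three
low-band-edge cycles at each boundary are excluded because zero-phase
filtering rings there.

### Firing-pattern gate

Bursting is declared when the ISI distribution is positively skewed
(skewness > 1) with a short mean ISI (mu_ISI < 0.05 s).  The thresholds are
chosen so that a group with mu_ISI ~ 0.024 s passes and a group with
mu_ISI ~ 0.107 s fails, reflecting the bursting/non-bursting site
statistics that motivate the gate.

## Stochastic phase model

The phase phi in [0, 1) of a bursting neuron follows an Ito SDE with:
natural burst-cycle frequency omega; mean-field coupling
K r sin(2 pi (psi - phi + a)) with fixed phase shift a = 1/4 (partially
synchronous surround, 0 < r < 1); colored common noise entering through its
effective drift v_C and diffusion amplitude D_C; independent white noise
with phase sensitivity R_I; and PRC jumps Delta(phi, beta) at Poisson-timed
impulses.

* The printed Ito-correction coefficient is read as
  (sigma_I/2) R_I'(phi) (sigma_I R_I(phi) + D_C) — the standard (1/2) g g'
  correction for the diffusion g = sigma_I R_I + D_C; an `ito_literal`
  switch preserves the alternative sigma_I^2 reading.
* v_C and D_C are double integrals of the common-noise sensitivity against
  the noise autocorrelation C(s).  The inner phase integral is evaluated
  exactly through the Fourier series of the tabulated curve; the outer time
  integral uses adaptive quadrature over ~60 autocorrelation timescales.
  For R_C = sin(2 pi phi) and C(s) = exp(-|s|/tau) the implementation
  matches the closed forms to 1e-6 relative (tested).
* Impulse trains: inter-impulse intervals are X/(f lambda) with
  X ~ Poisson(lambda), zeros redrawn, making f the exact mean rate and
  1/sqrt(lambda) the IPI coefficient of variation; lambda -> inf is the
  regular (conventional-DBS) surrogate.
* Integration is Euler-Maruyama with default dt = 1e-4 s and step splitting
  at impulse times, so a noise-free rotation is exact to machine precision
  and each jump equals the PRC value at the pre-impulse phase.  A
  vectorized ensemble integrator serves Monte-Carlo uses.

### Bundled curves are synthetic stand-ins

The phase sensitivity functions (R_I = 1 + 0.5 sin 2 pi phi,
R_C = sin 2 pi phi), the exponential autocorrelation (tau = 20 ms) and the
biphasic type-II-like PRC table are smooth placeholders with the
qualitative shape such curves take for bursting neurons; deriving them from
a full conductance-based reduction is out of scope, and all are overridable
by user-supplied tables.

The PRC table is referenced to a *strong* perturbation,
beta_ref = 0.42 (= w I0 / C for a 210 us, 2 mA pulse), and scaled linearly
in beta/beta_ref.  Referencing the table to a weak pulse would make the
linear scaling extrapolate the table by an order of magnitude at the upper
corner of the stimulation box, where the resulting giant jumps act as an
artificial phase-concentrating map; with the strong-perturbation reference
the scaling interpolates over the whole admissible range.  Linearity of the
scaling itself is an assumption.

### Parameter estimation

The estimation procedures are deliberately simple, documented summaries of
what a full pipeline would do: omega is the burst-cycle rate (bursts are
split at ISI gaps above 2.5x the median ISI); (r, psi) is the circular mean
of beta-band LFP phases at burst onsets; sigma_I follows from burst-cycle
interval dispersion through the phase-diffusion relation
Var(T) = sigma^2/omega^3; sigma_C scales with the square root of relative
beta-band LFP power; K is a configurable multiple of r.  Recordings that
fail the bursting gate are refused — the model is a bursting-oscillator
abstraction.  On paired synthetic recordings the estimators recover omega
within 10% and r within 0.1 (tested).

## Transfer operator and cost

The stimulus-to-stimulus phase map is discretized into m bins (500 by
default; tests and the acceptance runs use m = 100 with 200 Monte-Carlo
samples per bin, a scale at which one cost evaluation takes tens of
milliseconds).  Each row launches samples from the bin center, integrates
one sampled inter-impulse interval (dt = 1e-3 s here; the constraint
dt <= 0.1/omega holds with margin for all archetypes) and applies the
terminal impulse's PRC jump, so the matrix depends on the stimulation
settings, as the cost requires.  Separate child random streams drive IPIs
and diffusion noise so that evaluations at different settings share random
numbers (common random numbers); the optimizer therefore sees an
effectively deterministic objective for a fixed seed.

The invariant density is the dominant left eigenvector (unit eigenvalue,
checked to 1e-6; degenerate multiplicity raises), polished by power
iteration to a fixed-point residual below 1e-8, clipped to non-negative and
normalized to sum 1.  Its element variance sigma^2_pst = (1/m)||p - mu 1||^2
is the desynchronization measure (lower = flatter = more desynchronized);
the Monte-Carlo estimate of sigma^2_pst carries a positive sampling floor
of order 1e-6 at the test scale, which bounds the resolvable differences.
The cost adds the power penalty g P with g = 0.25, P = I0^2 w f R and
R = 1000 ohm (pulse width converted to seconds), making the two terms
commensurate over the admissible box.

## SID-PSM optimizer

The bound-constrained direct search works in the unit box (affine scaling
of the physical bounds — pulse width in tens of microseconds and current in
milliamperes would otherwise give degenerate poll geometry) with
coordinate directions +-e_i as the positive generating set.

* **Search step** (once d+1 cached evaluations exist): a quadratic model is
  built from cached points — determined interpolation at exactly
  q = (d+1)(d+2)/2 - 1 displacements, minimum-Frobenius-norm (KKT system in
  a scaled monomial basis whose coefficient norm equals the Hessian
  Frobenius norm) below that, least-squares regression above — and
  minimized exactly over a ball of radius sigma_k alpha_{k-1} max||d||
  (sigma_k = 2 after a success, else 1) via an eigendecomposition-based
  trust-region solve, then clipped to the box.  Model points are the 80%
  nearest / 20% farthest of the cache, restricted to a locality radius of
  8x the search radius so stale distant points cannot corrupt the model.
  An accepted search candidate is given one expansion trial at twice the
  step.  A successful search step skips polling.
* **Poll step**: feasible points x_k + alpha_k d, ordered by the angle each
  direction makes with the negative simplex gradient when the gradient's
  sample set is Lambda-poised (Lambda = 100, 1/sigma_min of the scaled
  displacement matrix); infeasible poll points are discarded; acceptance is
  opportunistic.
* **Step size**: halved on failure, doubled on success (capped at the
  initial value); stop when alpha < 1e-6 in scaled units or the evaluation
  budget (default 2000) is spent.  Objective exceptions count as +inf
  evaluations.  Disabling the search step and poll ordering reduces the
  method to a plain generalized pattern search, which serves as the
  comparison baseline.

Restarts use seeded Latin-hypercube initial points; the cost seed is held
fixed within each restart (common random numbers) and varies across
restarts.

## Synthetic data: what it does and does not emulate

* **Hindmarsh-Rose**: canonical bursting coefficients (a=1, b=3, c=1, d=5,
  s=4, x_rest=-1.6, r=0.001, I=2), fixed-step RK4.  A `time_scale`
  parameter (default 800 per second, i.e. one model time unit = 1.25 ms)
  maps the dimensionless equations to wall-clock seconds so the intraburst
  ISI lands near 0.02 s, matching pathological subthalamic bursting.  The
  integrator agrees with a tight-tolerance adaptive reference solution and
  its spike count is stable under step halving (tested).
* **Coupled LFP surrogate**: a beta-band sinusoid plus a constant-modulus
  high-frequency carrier whose phase diffuses (Lorentzian linewidth 10 Hz —
  real high-frequency band activity has finite coherence, and an infinitely
  coherent tone would hand the q^2 optimizer an artificial rectification
  harmonic to lock onto), amplitude-modulated by the beta phase with the
  requested depth, plus white Gaussian measurement noise at the requested
  SNR (measured SNR within 1 dB, tested).  The surrogate is stationary and
  Gaussian-noise-driven; it does not emulate nonstationary artifacts,
  spiking transients leaking into the high-frequency band, or 1/f
  background.  One consequence, verified in the suite and recorded here as
  a limit on what passing tests show about real data: the conventional
  modulation index remains discriminative on these surrogates even at 0 dB
  SNR (its real failure mode involves phase-slip-corrupted estimates on
  short, nonstationary segments).
* **Spike trains**: regular, Poisson (exponential ISIs), and bursting
  (exponential interburst intervals, 1 + Poisson burst sizes, exponential
  intraburst ISIs) patterns; generator statistics recover the specification
  within sampling error (tested).
* **Archetype parameter sets**: `pd_bursting`, `ocd_high_rate` and
  `ocd_low_rate` draw omega from disjoint ranges (6-8, 7-9, 2-4 bursts/s)
  and noise intensities reflecting the relative ISI dispersion of the
  corresponding site groups (high-rate sites: high dispersion); r is drawn
  inside (0, 1) and a = 1/4 always.

## Acceptance scale

`scripts/acceptance.py` evaluates the coupling detector on the 10 s
surrogate exactly as specified above, and runs the optimizer at m = 100
bins, 200 samples per bin, 250-evaluation budget and five restarts —
the scale at which the cost landscape is resolved well beyond its
Monte-Carlo floor while a full run completes in minutes.

## Known limitations

* The K_t statistic is one-sided on these surrogates: coupled signals are
  classified as regular with high reliability (all battery seeds at the
  default configuration, including the 0 dB PD-mode battery), but the
  *absence* of coupling is not reliably flagged.  The log magnitude of a
  strictly beta-band-confined noise process decorrelates over ~60 ms, and
  over a 1000-sample window at 1 kHz its 0-1 statistic exceeds the 0.1
  threshold for only about 40% of realizations even in the ideal
  band-limited-Gaussian limit (narrower bands read more regular, wider
  leakage destroys the coupled side's robustness instead).  When a negative
  verdict matters, use the achieved filter q^2, which separates the classes
  with a wide margin on these surrogates, or the modulation index at
  adequate SNR.
* sigma^2_pst comparisons finer than the Monte-Carlo floor (~1e-6 at test
  scale) are not resolvable; increase the per-bin sample count for finer
  contrasts.
* K, sigma_I and sigma_C estimation are heuristic summaries; absolute
  values should not be over-interpreted, and K in particular is only
  determined up to the configured scale.
* No voltage-to-current conversion is asserted for post-operative reference
  settings; the reference arm uses the midpoint of the current bound by
  convention.
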