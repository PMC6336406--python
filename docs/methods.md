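# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `pausekit`, and what the shipped tests do and do not
establish about real data.

## Kinetic schemes and the deterministic solver

A pause mechanism is a continuous-time Markov chain over labelled states.
The generator matrix `K` collects first-order rate constants (s⁻¹);
substrate-dependent steps store a second-order constant (µM⁻¹s⁻¹) that is
multiplied by the named concentration (µM) at build time, so the network is
always purely first-order after folding. Schemes are immutable; re-binding
substrate concentrations creates a new scheme. Zero-rate transitions are
pruned; isolated states are allowed with a warning. Units are seconds and
µM throughout.

`solve_scheme` integrates `dp/dt = K p` with LSODA (switching to implicit
BDF on stiff problems) and the exact constant Jacobian `K`, at relative
tolerance 1e-8 and absolute tolerance 1e-10. Conservation (row sums = 1
within 1e-9) is asserted on every solve and a violation raises with the
scheme's stiffness ratio in the message. The independent accuracy oracle in
the tests is the matrix exponential `expm(K t) p₀`; agreement is required
to 1e-7 max-abs on random networks with rates spanning 1e-3–1e3 s⁻¹.

The Gillespie simulator exploits that a first-order network decouples over
molecules: all molecules advance in vectorized rounds of jumps. Randomness
comes from a counter-based Philox generator with an explicit seed in every
public call; there is no global random state. The dwell time at a state
*set* is the total residence before the first exit out of the set, which is
the "pause lifetime" notion of the assays (hopping between pause substates
does not end a pause; extension does).

## The consensus preset

The study conditions emulated by the generator are the published
phenomenology of the consensus elemental pause at 37 °C: ~80% of ECs are
captured by the pause with an apparent escape lifetime of ~5 s, a slow
subpopulation of ~15% with lifetime ~100 s, and ~20% bypass with lifetime
~0.1 s. These printed fractions sum to more than one; the preset reconciles
them by treating the slow species as part of the captured fraction, giving
apparent biexponential amplitudes a = 0.65, b = 0.15 and bypass = 0.20.

The microscopic rates that realize this are illustrative (no global-fit
rate table exists to adopt): arrival (G16→C17) at 10 s⁻¹ partitioned
0.8/0.2 between pause entry and bypass, bypass extension at 12 s⁻¹,
pause escape plus slow-branch entry totalling 0.2 s⁻¹ with the branch
chosen so the asymptotic slow amplitude is 0.15, and slow escape at
0.01 s⁻¹. Because arrival (10 s⁻¹) is only 50× faster than fast escape
(0.2 s⁻¹), the convolution of arrival with escape inflates the
extrapolated t→0 amplitudes slightly; the generator therefore stores as
ground truth the *exact* modal coefficients of the observable (a = 0.663,
b = 0.150, bypass = 0.187), obtained by eigendecomposition of `K`, rather
than the nominal design values. Fits are compared against these.

## Noise model

Gel quantification noise is modelled as additive Gaussian on the measured
fraction, SD 0.02, independent across time points, species and replicates
(default three replicates). Truncation of noisy fractions to [0, 1] is
available but **off** by default: band quantification with background
subtraction produces small negative fraction estimates, not censored ones,
and censoring at zero would bias every near-zero point upward — enough to
make even a correctly specified mechanism's residuals look systematic. A
generator configured to truncate refuses to run if more than half the
points would clip (a sign the noise model is misconfigured). The optional
"chase" step appends a final time point at which remaining pause RNA has
been chased to product (fraction 0).

What the generator does *not* emulate: correlated lane-to-lane gel errors,
radiolabel saturation, loading-normalization drift, and RNAP-preparation
variability in the slow fraction. Passing recovery tests therefore show
calibration under independent Gaussian noise, not robustness to structured
experimental error.

## Exponential fitting

Pause decays are fit by weighted nonlinear least squares to one or two
exponentials. Replicates sharing a time grid are averaged; the weights use
per-point SDs of the mean when at least six replicates are available, and a
pooled (RMS) SD with three to five — per-point SDs estimated from three
replicates are χ²₂-noisy and weighting by their inverse demonstrably
miscalibrates the confidence intervals. With fewer than three replicates
the fit is unweighted. Covariances are scaled by the reduced χ², and 95%
intervals use Student-t critical values at the residual degrees of freedom.

The decay fit starts one grid point past the curve maximum: the rise is the
arrival transient, and the peak point itself still carries measurable
transient curvature. Amplitudes are the extrapolated t→0 intercepts of the
decay phases, so bypass = 1 − (a + b). Rates are constrained positive,
amplitudes to [0, 1.05] (absorbing quantification noise); multistart uses a
log-spaced rate grid (≥10 starts) and the ordering convention
k_p,app ≥ k_sp,app is enforced by a post-hoc swap, so initialization order
never changes which rate is reported as the fast one. Rates within 3× of
each other are flagged as weakly identifiable. Model selection between one
and two exponentials is an F-test on weighted RSS at α = 0.05.

Two amplitude conventions exist in the literature (fractions of total RNA
vs of the captured fraction); `pause_metrics` implements both and names the
convention in its output. Pause strength `PS = E·τ` uses the lifetime of
the major species; its SE comes from the delta method on the fit
covariance.

The binding fitter adds a pragmatic guard to the "no binding evident"
verdict: besides an F_max CI containing zero, an amplitude below twice the
residual RMS is also called no-binding, because the linearized F_max SE is
far too optimistic when K_d is unidentifiable at F_max ≈ 0.

## Mechanism discrimination

Arrival rates are fit first from the pre-pause decay and then frozen — the
same frozen values are shared by every mechanism fit in a comparison.
Each mechanism template exposes named free rates with bounds; fitting is
weighted least squares over all replicate points of all measured species
(pre-pause, pause RNA, at-or-beyond product), in log-parameter space, with
8 log-uniform multistarts (seeded). Starts run in order — a mid-bounds
heuristic first — and stop early once a start reaches reduced χ² ≤ 2, so
well-posed fits cost a single start. Species weights are the pooled
replicate SD (floored at 0.005, the quantification noise floor). When the
simple mechanism is nested in the complex one, the complex fit is
warm-started from the embedded simple optimum if it would otherwise end up
worse, guaranteeing the nested-RSS inequality up to solver tolerance.

Rejection follows the residual-structure logic: the simpler mechanism is
rejected only if its residuals are flagged *systematic* while the complex
mechanism's are not; nothing is ever concluded in favour of the complex
mechanism. The flag is computed on the replicate-averaged, time-ordered
residuals (concatenated across species) as:

- Wald–Wolfowitz runs test, one-sided toward *too few* runs (clustering);
- lag-1 autocorrelation against the *upper* 95-type permutation bound
  (1000 seeded permutations);

with the two tests Bonferroni-split so the flag has family-wise level 5%.
Both one-sidedness and the split matter: least-squares fitting leaves mild
*anti*-correlation in the residuals of the *true* mechanism, and a
two-sided OR of two 5% tests flags the generating mechanism about 10% of
the time — enough to break the documented ≥90/100 discrimination
calibration. Misfit of a wrong mechanism produces the opposite signature
(long same-sign waves, strongly positive lag-1) and is unaffected. The
two-sided, unsplit variant is still computed and reported as `non_random`
for users who want a pure exchangeability test (it fires on alternation as
well). This decision rule is this package's operationalization of a
criterion that is applied visually in practice.

The tandem-pause test is symmetric: fixed-subpopulation and
dynamic-partitioning templates are both fit (arrival and inter-site transit
rates frozen — they are design constants of the tandem assay), and
whichever hypothesis shows systematic residuals while the other does not is
rejected.

## Pause-signal additivity

Reduction factors are ratios of pause strengths, with SEs propagated on the
log scale from the fit covariances. The combined prediction is the product
of single-element factors; its 95% bracket uses the delta method on
log-factors by default, with a parametric lognormal bootstrap as an
alternative (both named in the output; they agree within a few percent at
the SE magnitudes of interest). Reported factors are rounded to two
significant figures, full precision retained internally. Note that the
product of *already-rounded* factors can disagree with a published combined
value in the last digit (1.4 × 3.7 = 5.18); the additivity verdict is
therefore made against the confidence bracket, not against rounded digits.

## Multistate dwell model

With registers in fast pre-equilibrium and escape possible only from the
half-translocated register, mean dwell is `1/(f_half·k_escape)`; the
lengthening factor relative to a baseline complex is `baseline/f_half`,
baseline defaulting to 0.95 (a complex that is half-translocated >95% of
the time). For occupancies 0.50 / 0.25 / 0.10 this gives 1.9 / 3.8 / 9.5 —
about 2-fold, 4-fold and 9.5-fold. (Published round-number factors of "~3"
for 25% occupancy are not reproducible from any single baseline choice;
this package reports the computed values and does not force agreement.)
The explicit register-hopping scheme uses hop rates `κ·π_dest` with
`κ = speed·k_escape`, which satisfies detailed balance with stationary law
π; the rapid-equilibrium prediction is attained as speed → ∞ with relative
error shrinking like 1/speed, and deviates measurably at speed ≈ 1.

The NTP partition model treats bypass as the competition
`k_esc(c)/(k_esc(c)+k_pause)` with a hyperbolic, saturating
`k_esc(c) = k_max·c/(K+c)` — the minimal form consistent with a bypass
plateau at high NTP. Two (concentration, bypass) observations determine
`K` and `k_max/k_pause` in closed form; the absolute rate scale is not
identified by bypass data and is supplied by the user.

## Problem sizes and determinism

Calibration-style tests run 200 seeded fit-recovery datasets, 100 seeded
discrimination trials per direction, 50 random schemes for the solver
oracle, and 5×10⁴ molecules for stochastic/deterministic agreement —
sizes at which the binomial and coverage bounds quoted in the tests are
meaningful while the full suite stays in the tens of minutes on one CPU.
Every stochastic routine takes an explicit seed; identical inputs
reproduce identical outputs bit-for-bit, and CLI runs record their seeds
in a manifest.

## Known limitations

- Only pseudo-first-order networks: true bimolecular kinetics (e.g.
  explicit NTP binding/release) must be folded at fixed concentrations.
- The rejection rule's calibration is established under the generator's
  independent Gaussian noise; strongly correlated residual noise in real
  data would inflate false "systematic" flags for all mechanisms at once
  (the AND-structure of the verdict offers partial protection).
- Amplitude SEs near the [0, 1.05] box bounds are linearized and can be
  optimistic; coverage was verified in the identifiable regime (rates ≥10×
  apart, amplitudes well inside the box).
- The multistate dwell factor assumes escape from exactly one register;
  mechanisms with several escape-competent registers need an explicit
  scheme instead.
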