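# Methods

## Scope and design

`cavclamp` couples a mechanistic generator of whole-cell Cav1.3 currents to
the standard empirical analysis pipeline used to characterize voltage-gated
Ca²⁺-channel gating. The generator is deliberately the *smallest* gate model
whose output the pipeline can invert: the published characterization of a
channel variant consists entirely of fitted curve parameters (Boltzmann
midpoints and slopes, exponential amplitudes and time constants, a Hill
IC50, a linear run-down slope), so a model with one activation gate, two
amplitude-weighted inactivation gates plus a non-inactivating fraction,
linear ohmic driving force, linear leak, and multiplicative run-down/block
is sufficient for every quantity the pipeline measures. No claim of
mechanistic realism beyond that is intended (no Ca²⁺-dependent inactivation,
no GHK rectification, no Markov single-channel structure, no temperature
dependence).

## Gating model

States evolve by first-order relaxation toward voltage-dependent targets;
within each constant-voltage protocol segment the relaxation is propagated
analytically sample-by-sample, so traces carry no ODE-solver error and are
bit-reproducible given the seed.

* **Activation.** `m∞(V)` is a Boltzmann with midpoint `V0.5,act` and slope
  `k_act`. τ_m(V) is a Gaussian bell (default peak 2 ms at −20 mV, floor
  0.3 ms, width 30 mV) crossing over below ≈ −60 mV to a deactivation
  branch `τ_deact_ref · exp((V+69)/25)` anchored at −69 mV. The recordings
  being emulated constrain activation only to be fast relative to the 25-ms
  test pulse; the bell parameters are a modelling choice. The crossover is
  placed below the activation range of both variants so that test-pulse
  kinetics stay quasi-steady while repolarization tails deactivate with the
  reference time constant (WT 0.9 ms, mutant 4 ms at −69 mV — chosen to
  reproduce the several-fold slower mutant deactivation; no numeric τ is
  published).
* **Inactivation.** Two gates share the availability steady state
  `s∞(V) = 1/(1+exp((V−V0.5,inact)/k_inact))`; the current weights them as
  `f_ni + A_f·h_f + A_s·h_s` with `A_f + A_s + f_ni = 1`. Gate time
  constants interpolate logistically (center −50 mV, width 5 mV) between
  the depolarized decay values and the hyperpolarized recovery values —
  the two regimes are characterized separately by experiment and the
  transition is a modelling choice. The mutant inactivates
  mono-exponentially but recovers bi-exponentially; the model reconciles
  this by giving both mutant gates the same decay τ while keeping distinct
  recovery τ.
* **Preset amplitudes.** Fitted decay amplitudes plus plateau sum to ~96%,
  not 100% (free-amplitude fits); the simulator renormalizes the fast:slow
  ratio into `1 − f_ni`, with `f_ni` taken from the steady-state
  inactivation plateau. The verbatim fitted decay and recovery parameter
  sets are shipped alongside and used directly for closed-form fixtures.
  Recovery parameters were measured with β3; β2a presets reuse the matching
  variant's values.
* **Hook.** An optional blocked-open pool (occupied during depolarization,
  re-entering the open state with τ_unblock ≈ 1.5 ms on repolarization)
  produces the delayed tail-current peak seen in the mutant. The underlying
  mechanism is unresolved experimentally, so the feature is off by default.
* **Cell and drug.** Ohmic leak with 0 mV reversal; additive white Gaussian
  current noise; linear run-down in percent of the initial peak per minute
  (units are a convention choice — the published slopes are unitless);
  Hill-type block with slope 1 and first-order equilibration (default
  τ = 15 s) toward `c/(c+IC50)`.

## Protocols

Six families, all from a −89 mV holding potential (all voltages are liquid-
junction-corrected; a `jp_corrected` flag prevents double correction):
25-ms I–V steps in 5-mV increments (default grid −84…+61 mV, spanning both
variants' activation ranges); two-pulse SSI with 5-s conditioning in 10-mV
increments (default ladder −109…+21 mV, extending ~60 mV beyond the
inactivation midpoint so the plateau is well-sampled) at 30-s sweep starts;
5-s depolarizations to Vmax; two-pulse recovery (2-s prepulse, 15
log-spaced gaps over 0.001–20 s, 10 kHz); 10-ms step to Vrev followed by
20-ms repolarizations (10-mV steps, including −69 and −49 mV); and 100-ms
pulses at 0.1 Hz for pharmacology. Default sampling is 50 kHz (10 kHz for
recovery; SSI analysis is rate-insensitive and simulated at 10 kHz).

## Analysis pipeline

* **Leak subtraction.** P/4 (four −¼-amplitude sub-sweeps summed after
  per-sweep baseline removal) for I–V and tail families — exact for linear
  leak; offline baseline subtraction for 5-s, SSI and pharmacology sweeps.
  The P/4 builder accepts one contiguous excursion block so the two-level
  tail waveform can be subtracted online; multi-pulse protocols are
  rejected.
* **Peak extraction.** Inward peaks are negative; densities are pA/pF. The
  I–V path takes the extremum by magnitude because test potentials beyond
  reversal carry small outward peaks that an inward-only rule would zero
  out, corrupting the fitted reversal potential. SSI and recovery peak
  windows begin 8 ms into each pulse, mirroring cursor placement after the
  settling phase: after depolarized conditioning (or at millisecond
  recovery gaps) the activation gate is still open at pulse onset and an
  instantaneous peak overstates availability.
* **Fits.** All fits are bounded nonlinear least squares (scipy) with
  documented initialization (midpoints from interpolated half-max
  crossings, k = 6 mV, τ from log-linear regression), bounds k ∈ (0.5, 30)
  mV and τ ∈ (1, 60 000) ms, and standard errors from the Jacobian. The SSI
  equation is the standard single-plateau modified Boltzmann. Decay model
  selection (mono vs bi) uses the extra sum-of-squares F-test at α = 0.05;
  two numerical guards precede it — if the mono fit's relative residual is
  below 1e−10 the F ratio is machine noise and mono is kept, and a bi fit
  whose time constants collapse (ratio > 0.8) is refit as mono. The
  recovery fit's instantaneous offset is free on [0, 0.95]: a conditioning
  prepulse short relative to slow inactivation leaves a large
  un-inactivated fraction (up to ~0.66 for the β2a mutant), and a tight
  offset bound forces a spurious 1-ms "fast" component. The dose–response
  fit has one free parameter (log IC50; bottom/top fixed at 0/100, Hill
  slope 1) with an asymptotic 95% CI exponentiated from the log scale.
  Steady-state inhibition per concentration is the mean of the last three
  sweeps (no canonical rule exists; configurable).
* **Statistics.** Mean ± SEM (sample SD/√n); unpaired two-sided t-tests;
  one-way ANOVA with Bonferroni post-hoc (raw p × number of pairs, capped
  at 1); extra sum-of-squares F-test for nested curve models.

## What the synthetic data do and do not show

The generator reproduces the *structure* of whole-cell recordings —
voltage-dependent sigmoidal activation, bi/mono-exponential inactivation
with a plateau, deactivation tails, double-exponential recovery, linear
run-down, Hill-type block, ohmic leak, Gaussian noise — and passing
round-trip tests shows the pipeline is an unbiased inverse of that
structure under study conditions. It does not emulate capacitive
transients, series-resistance error, Ca²⁺-dependent inactivation,
endogenous currents, or cell-to-cell parameter scatter, so the tests say
nothing about robustness to those features of real data.

Two systematic effects of the protocols themselves are faithfully
reproduced and worth noting. (1) Inactivation accrued while the activation
gate settles biases 25-ms peak I–V fits by a few tenths of a millivolt;
the integer-mV activation-shift computation therefore uses fast activation
kinetics (bell peak 0.5 ms) where the default bell would tip a rounding
boundary. (2) A 5-s conditioning step cannot equilibrate inactivation whose
slow time constant is ~2 s: the fitted non-inactivating fraction of the
β2a presets overshoots the generating value by ~3–6 points (β3 presets stay
within 3), the same truncation visible when comparing published SSI
plateaus with published decay plateaus.

## Problem sizes

Noise-free study conditions: 30-sweep I–V families, 14-sweep SSI families,
15-gap recovery ladders, single 5-s decays per preset, 30-sweep control
runs and 42-sweep drug runs (12 sweeps per concentration at 0.1 Hz,
equilibration τ 15 s), 20 pF cells with 0–1.5 nS leak. The complete test
suite and the acceptance script each run in seconds on one CPU.
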