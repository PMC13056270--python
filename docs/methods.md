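# Methods

This note documents the models, estimators and design choices behind
`rhythmforge`: what is simulated, with which defaults and why, what the
synthetic inputs do and do not emulate, and where the genuinely open choices
were made.

## Units and conventions

Time is in milliseconds everywhere; rates and frequencies are in Hz and
converted internally (neuron constants are conventionally quoted in ms/pA/mV).
Event sequences are strictly increasing timestamp arrays tagged `stimulus`,
`spike` or `chirp`. Relative tempo is the dimensionless frequency ratio
`f_input / (f_input + f_model)`; its inverse (`input_rate_for_ratio`) is used
to build sweep grids, so a grid from 1/6 to 5/6 spans input:model tempo
relations from 1:5 to 5:1.

## Input generators

Two stimulus classes drive the models:

* **Poisson trains** — cumulative sums of i.i.d. exponential gaps with mean
  `1000/rate` ms (exact construction, no thinning). Their defining property
  for this package: the rhythm ratios of i.i.d. exponential intervals are
  exactly Uniform(0,1), so Poisson input is rhythmically maximally random
  (differential entropy ≈ 0 nats). This was verified by Monte Carlo before
  being frozen into the tests.
* **Isochronous trains** — exactly periodic events, the most ordered input
  (all ratios 0.5, entropy −∞).

Sequence length is specified by interval count, not duration, so the
≥100-interval analysis floor holds in every sweep cell; per-cell inputs are
additionally sized to cover the simulated output duration with margin. The
generators emulate only the timing statistics of the study conditions; they do
not model event amplitudes, acoustic structure, or any non-Poisson stochastic
process (renewal, Hawkes, jittered-periodic), so conclusions from the sweeps
concern timing structure only.

## The LIF neuron

Subthreshold dynamics: `C_m dV/dt = −(C_m/τ_m)(V − E_L) + I_e + I_syn(t)`,
with `I_syn` a sum of alpha kernels `w·e·(t/τ_syn)·exp(−t/τ_syn)` from past
input events — `w` is the kernel's peak amplitude in pA, which is the only
convention under which connection weights of 500–10,000 are dimensionally
sensible. At `V ≥ V_th` the neuron spikes, resets to `V_reset`, and is clamped
there for `t_ref`; synaptic state keeps evolving (and incoming events keep
accumulating) during refractoriness. Forcing is excitatory only, making this a
Type I oscillator: input can only advance the next spike (a tested property).

**Integration.** The membrane + alpha-current system is linear between
events, so it is propagated exactly (exponential propagators) on a fixed grid
of step `dt`; input events snap to the nearest grid point and spikes are
reported at the grid point where threshold is crossed, with no sub-step
interpolation. Timing accuracy is therefore O(dt) per spike, and free-run
inter-spike intervals match the closed-form period

```
T = t_ref + τ_m · ln((V∞ − V_reset)/(V∞ − V_th)),   V∞ = E_L + τ_m I_e / C_m
```

within 2·dt (tested over 50 random supra-rheobase parameter sets). Spike-time
differences under dt-halving grow at most one step per reset, i.e. the k-th
spike moves by < k·dt — grid quantization accumulates linearly in unlocked
regimes, which is why the convergence test bounds per-spike error rather than
whole-train error. `current_for_rate` inverts the period formula analytically;
near rheobase (rates of a few Hz with the default constants) the inversion
loses precision to cancellation, so its round-trip contract (1e−9 ms) is
guaranteed for rates ≳10 Hz.

**Defaults.** `C_m=250 pF, τ_m=10 ms, E_L=V_reset=−70 mV, V_th=−55 mV,
t_ref=2 ms, τ_syn=2 ms, dt=0.1 ms` — the standard defaults of the simulator
family this model follows; all overridable via `LIFParams` or the YAML config.
The default connection weight is `w=500 pA`, the lower of the two weights the
connection-strength experiment compares (500 vs 8000); under it the
random-input experiment's monotone isochrony bias is robust. Note that `w`
moves the dynamics across qualitatively different regimes: around 1000 pA and
above, a single input spike can trigger an immediate spike *and* its tail can
re-excite the neuron after the refractory period (doublets), which is exactly
the mechanism behind the non-1:1 categories of the connection-strength
experiment.

## The cricket

The cricket chirps with natural period `T0` and adjusts the ongoing cycle
multiplicatively: a stimulus at phase `φ = (t_stim − t_lastchirp)/T_cur`
rescales the cycle to `T_cur·(1 + Δ(φ))`. Later stimuli in the same cycle
recompute the period from `T_cur` (most-recent-stimulus rule — responses do
not compound within a cycle). A perturbed period is carried forward, and at
every chirp the carried period relaxes by `T_cur ← T_cur + ρ(T0 − T_cur)`.
This placement of the relaxation step is deliberate: it is the only reading
under which both printed semantics hold exactly — `ρ=1` restores `T0`
immediately after a perturbed interval, and `ρ=0.2` moves each unperturbed
interval 20% closer to `T0` (deviations decay geometrically with factor
`1−ρ`, an exactly tested invariant).

**PRC.** The empirical phase response curve this mechanism abstracts is known
only graphically, so the package ships a parameterized stand-in with the
qualitative Type II structure — delay early, advance late: a triangular curve
rising 0→`a` on `[0, φ*/2]`, falling back through 0 at the breakpoint `φ*`,
and descending to `−b` as `φ→1` (defaults `a=b=0.5`, `φ*=0.6`), plus a
sinusoidal alternative with the same zero crossings. All PRC-dependent results
are therefore qualitative, not curve-exact. Optional Gaussian noise of
standard deviation `noise_sd` is added per evaluation (truncated at
`Δ > −0.95` so periods stay positive); sweeps default to noise off.
Edge rules: a stimulus exactly at a chirp belongs to the new cycle (`φ=0`,
where `Δ=0`); a phase ≥1 (possible when an earlier stimulus lengthened the
cycle) is clamped just below 1; if an advance would schedule the chirp before
the stimulus that caused it, the chirp is emitted immediately after the
stimulus (causality guard, 1e−6·T0). Because perturbations multiply the
*current* period, sustained late-phase forcing at low `ρ` can drive intervals
below `T0·(1−b)` — interval bounds hold per cycle relative to that cycle's
base period, not globally.

`T0` defaults to 2000 ms (the order of magnitude of slow insect chirping);
all sweep results are expressed in dimensionless frequency ratios, so the
absolute scale is immaterial.

## Rhythm metrics

* **KDE**: `scipy.stats.gaussian_kde` with Scott's-rule bandwidth (the
  conventional default). Zero-variance samples raise a dedicated error.
* **On-integer fractions**: for the seven targets (0.25, 1/3, 0.4, 0.5, 0.6,
  2/3, 0.75), adjacent targets split at their midpoint; each target's on-bin
  is the central half of its segment (half-width = ¼ of the distance to each
  neighbor, outermost targets mirroring their inner side), the remainder is
  off-bin. The reported fraction is `W_on/(W_on + W_off)` with each class
  weighted by the inverse of its total width — under that weighting a uniform
  sample scores exactly 0.5, an all-on-target sample 1. Ratios outside the
  tiled support `[0.25 − 1/24, 0.75 + 1/24]` fall in no bin; if all three
  bins of a target are empty the fraction is undefined (NaN), never silently
  zero. Inverse categories (1:2 vs 2:1) are kept separate. The bin geometry
  is isolated behind `IntegerRatioBins`, so alternative constructions are
  pluggable without touching the headline fraction.
* **Differential entropy**: the Ebrahimi spacing estimator
  (`scipy.stats.differential_entropy`) with window `m = ⌊√n⌋`. A sample in
  which more than half of the m-spacings are ≤1e−12 (e.g. the ratios of an
  isochronous sequence, up to float jitter) is reported as −∞ rather than an
  arbitrarily large negative number — matching how degenerate cells are
  grouped in the heatmaps, whose color floor is the minimum finite value.
  Estimator calibration (tested): Uniform(0,1) at n=10⁴ within ±0.05 of
  0 nats; Uniform(0,0.5) within ±0.05 of ln 0.5.

## Experiments

Sweeps run on reduced grids by default (CLI default 21×21; the test suite
uses 11×11 and 11×7 with 150 analyzed intervals per cell and 3 seeds where
input is stochastic — sizes chosen to keep a full run at desk scale while
leaving the qualitative structure clearly resolved). Per-cell seeds derive
deterministically from (sweep seed, grid indices), so any cell can be re-run
in isolation and sweeps are embarrassingly parallel. Failed cells (e.g. an
unattainable firing rate) carry an explicit status string; they never abort a
sweep and never masquerade as NaN metrics.

Isochronous inputs start at half an input period by default, so forcing at
matched frequencies is non-trivial (a zero offset makes stimuli coincide with
events, which the phase-0 rules render inert). The first 20 output intervals
can be discarded as lock-in transient (`discard`); this is off by default and
switched on for the locking analyses, where the attractor — not the approach
to it — is the object of interest.

Two empirical regime notes, both consequences of the models rather than
implementation choices. First, the neuron's 1:1 locked region is asymmetric:
purely excitatory forcing entrains only from input frequencies at and above
unison (frequency ratios ≳0.5–0.65 at moderate weight), because added charge
can only shorten cycles. Second, the simple-ratio-versus-midpoint entropy
comparison of the isochronous-input experiment is well-posed only at moderate
intrinsic rates (≈30–45 Hz at weight 1000): at lower rates the tongues are so
wide that even the higher-order tongues at the (rational) midpoint cells
capture them, and at higher rates the simple-ratio tongues narrow below the
grid spacing.

## Known limitations

* The PRC is a qualitative stand-in; cricket results characterize the
  mechanism class, not a fitted animal.
* Spike/chirp times are grid- (neuron) or event-exact (cricket) model
  outputs; no measurement noise, motor jitter, or detection error is
  modeled, so −∞-entropy cells are idealizations real recordings would not
  produce.
* One-way forcing only: a single forced unit, no mutual coupling, no
  inhibition, no plasticity, no networks.
* The entropy estimator's small negative bias at finite n means absolute
  entropy values carry ~0.05-nat uncertainty; comparisons within a sweep are
  unaffected.
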