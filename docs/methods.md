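# Methods

This note documents the models implemented in `gridmind`, the assumptions
behind them, the synthetic data they are trained and evaluated on, and the
numerical and design choices that were genuinely open.

## The system being modelled

Grid cells (GCs) in medial entorhinal cortex fire on a triangular lattice
and form modules sharing a spatial period and orientation; a module's
population state is equivalent to a phase on a 2-torus.  Spatially
modulated cells (SMCs) carry sensory signals.  Hippocampal place cells
(HPCs) fire at single locations.  The package implements a system-level
account of how these populations cooperate: a single recurrent network in
which SMC units autoencode masked, noisy sensory input, GC units
path-integrate self-motion, and an unsupervised hidden population links
the two codes by autoassociation, so that (i) a sensory cue can recall the
grid pattern of the cued place, (ii) navigation can be planned directly on
the grid-phase manifold, and (iii) intermediate grid states along a
planned route can reconstruct the expected sensory experience.

## Synthetic environment

All data are simulated; there is no external dataset.

* **Arena** — rectangular, default 1.5 m x 1.5 m, origin lower-left,
  half-open bins (1 cm for geometry measurements, 2 cm for training).
* **Trajectories** — correlated random walk at dt = 0.05 s (so a 5-s
  trajectory is 100 timesteps).  Heading is a wrapped AR(1) walk with
  per-step turn s.d. `(1 - persistence) * pi * sqrt(dt)` (persistence 0.7);
  per-step speed is a Rayleigh draw rescaled to mean 20 cm/s with
  fluctuation s.d. 10 cm/s, clipped at 0; walls reflect, mirroring the
  heading.  These are generic rodent-foraging statistics chosen once; no
  published trajectory parameters were available to match.
* **Self-motion code** — head-direction ring of 24 cells with tuning
  `exp((cos(theta - theta_pref) - 1)/w^2)` (w = 0.5 rad; strictly positive,
  peak 1, population activity on a 1-D ring) and 8 linear-gain speed cells
  with gains in [0.02, 0.06] (response O(1) at typical speeds).
* **Grid tuning** — module periods form a geometric hierarchy
  `l_i = l0 * s**i`, s = sqrt(e) in 2-D (e in 1-D analyses), smallest
  period 30 cm, six modules by default.  Each cell is a sum of Gaussian
  blobs (sigma = l/(4 * 3.26), i.e. spacing / field diameter = 3.26 with
  field size read at two standard deviations) on the module lattice,
  shifted per cell by a uniform phase offset and peak-normalized over the
  arena.
* **Sensory (SMC) tuning** — per-cell smoothed white noise: Gaussian blur
  chosen so the pre-rectification autocorrelation falls to 0.5 at one
  correlation length, rectified at zero, peak-scaled.  Default correlation
  length 10 cm: the stand-in emulates fine-grained visual-feature
  embeddings, which carry spatial detail at least as fine as the smallest
  grid fields; much smoother fields make the sensory-to-grid association
  information-poor in a way real visual input is not.
* **Masking** — per trajectory an effective fraction f ~ Uniform(0,
  r_mask) is drawn and independent Bernoulli(f) entries over (time x cell)
  are zeroed, applied to head-direction, speed and SMC inputs and to the
  grid-cell initial state.  Masks are resampled every trajectory.

What the generator does *not* emulate: visual occlusion structure,
landmark geometry, boundary cells, non-rectangular arenas, or realistic
sensor noise spectra.  Passing tests therefore show that the mechanisms
work under clean, controlled statistics, not that they survive real
sensory pipelines.

## Network model

One recurrent state vector is partitioned into GC, SMC, SPD, DIR, HIDDEN
and (optionally) PLANNER blocks, updated as

    z[t+1] = alpha ⊙ z[t] + (1 - alpha) ⊙ (inject(u[t]) + W f(z[t]))

* `inject` writes raw external input into input-node coordinates (SMC,
  SPD, DIR, planner goal); there is **no learnable input or output
  projection** — the relevant sub-blocks of the full recurrent matrix act
  as surrogate projections, and supervision applies directly to output
  coordinates (GC, SMC).
* `alpha` is a per-unit leak, learned through a sigmoid so it stays in
  [0, 1]; initialized at 0.9.
* `f` is rectification at zero (rates are non-negative); `tanh` and
  identity are available through configuration.
* W is randomly initialized (scale `1/sqrt(dim)`), with no block structure
  imposed.

Grid coordinates receive external values only through the initial state at
t = 0; thereafter the network must carry position by integrating the
self-motion inputs.  Hidden units receive and produce only recurrent
input; they are the place-cell candidates.

Training is first-order stochastic gradient descent (Adam, learning rate
1e-3 to 2e-3) on mean-squared error: grid coordinates against the
ground-truth grid rates and, for the full loop, SMC coordinates against
the *clean, unmasked* sensory pattern.  Gradients come from full
backpropagation through time, implemented in NumPy (float32) along with
the optimizer, so the package has no deep-learning framework dependency.

**Horizon and masking curriculum.** Training from scratch directly on
100-step rollouts stalls near the predict-the-mean baseline: the
velocity-conditioned update is a second-order effect per step and
long-horizon credit assignment cannot find it.  Likewise, heavy masking
applied from the start blocks the sensory-grid association before it
exists.  `fit()` therefore trains the same operator on short, unmasked
rollouts first and ramps both the horizon and the masking ratio —
path integrator: 20%/50%/100% of the target duration for 35%/25%/40% of
the steps; full loop: 20%/40%/50% of the duration for 20%/20%/60% of the
steps — with the masking ratio at 0%/50%/100% of its target and the
learning rate halved at each stage.  The transition operator learned on
short horizons transfers to long rollouts because it is the same
recurrent map.

**Decoding.** Positions are decoded from population activity by exact
nearest-neighbour search against the flattened ground-truth (or
aggregated) ratemap; ties resolve to the lowest flattened bin index.  With
only two grid modules (desk-scale default) the combined code has genuine
in-arena aliases: periods 30 and 30*sqrt(e) cm nearly coincide at
~148 cm, so a correctly tracking network occasionally decodes to the
alias.  Decode-error distributions are therefore heavy-tailed and the
package reports the median alongside the mean; the paper-scale six-module
code has no in-arena alias.

**Place-cell identification.** Hidden units count as place-cell-like when
their occupancy-weighted mean activation exceeds 0.01 and their Skaggs
spatial information (bits per sample) exceeds 3.0 — a compact-field
criterion (activity concentrated in roughly an eighth of the arena).
The information threshold is calibrated to model activation units —
reported thresholds for spike-count information do not transfer to
activations, and permissive thresholds saturate (nearly every recurrent
unit carries some spatial information).  What the package tests is the
*trend*: whether more place-cell-like units emerge at higher masking
ratios.  At desk scale this trend is within seed noise (see Limitations).

## Analytic planning on the grid manifold

* **Phase algebra.** `phi = 2*pi*frac(B^-1 p)` with B the module's lattice
  basis (columns at 60 degrees).  Displacement decoding wraps the phase
  difference per lattice axis into (-pi, pi] — the antipodal tie resolves
  to +pi, the positive lattice direction — and maps through B; each
  component is bounded by half the period.
* **Multi-scale combination** averages the per-module decoded
  displacements.  Scales whose half-period exceeds the remaining distance
  ("decodable") contribute the true displacement; undercovered scales
  contribute wrapped pseudo-displacements `d - l_i * round(d / l_i)`.
* **Contraction condition.**  The quoted sufficient condition for the
  average to reduce the remaining distance is `m > k + (1 - s^-k)/(s - 1)`
  (margin < 1 for s = e in 1-D, hence "m > k"; slightly above 1 for
  s = sqrt(e) in 2-D, hence "m > k + 1").  The source inequality is
  typographically corrupted and this reconstruction, while matching the
  quoted corollaries, is *not* sufficient in the worst case: with exactly
  one decodable scale the deterministic wraps can cancel the decodable
  contribution entirely, producing stable spurious fixed points (e.g.,
  m = 6, s = e: the remaining distance stalls near 940 cm), and in 2-D the
  k = m - 2 band shows occasional non-monotone steps.  The bound that
  matches both the worst-case algebra (bounding each wrap by l_i/2 with
  d >= l_k/2) and the observed behaviour is the alternative parse
  `m > k + (1 - s^-k)/(1 - s^-1)` — one module stricter:  two decodable
  scales guarantee monotone contraction in 1-D, three in 2-D.
  `contraction_margin(..., worst_case=True)` returns this corrected
  margin, a dedicated test exhibits the single-decodable-scale fixed
  point, and the contraction test suites sample within the guaranteed
  bands.
* **Sequential (Markov) planning.**  Phase space is discretized into
  `N_phi**n` toroidal bins with a row-stochastic transition matrix (ideal:
  uniform over self + ring/8-neighbour torus adjacency; or counted from
  binned phase trajectories with add-one smoothing on that support).  The
  plan vector starts with equal mass on start and target and diffuses
  through T with renormalization.  Three mechanics details are inferred
  (the source describes them only narratively) and configurable:
  1. the target bin is re-clamped *above* the running maximum
     (`(1 + source_boost) * max(v)`, boost 1.0) — the matrix is doubly
     stochastic, so renormalized diffusion flattens to uniform and a clamp
     exactly at the maximum stops feeding the field;
  2. a diffusion burn-in (5 x the state count) precedes the first move so
     the walker reads the settled target gradient rather than the
     transient blob around the start;
  3. the walker advances to the highest-valued unvisited neighbour, waits
     when the best neighbours tie within tolerance (the gradient has not
     arrived, or the configuration is symmetric), and breaks a tie that
     survives a full mixing period toward the positive direction.
  With these choices planned paths equal graph geodesics for all pairs on
  rings (N up to 32) and 8-neighbour tori (N up to 8).
* **Greedy vector navigation** iterates: decode all phases at the current
  position, average across scales, move by `step_fraction` times the
  estimate (1.0 in 1-D, 0.5 in 2-D, trading speed for path straightness).
  It stops when the decoded estimate drops below tolerance; this equals
  true arrival whenever all scales are decodable, but at a spurious fixed
  point (see above) the estimate vanishes away from the target, so
  `converged` means phase-consistency, not proximity.

## Learned planner

`PlannerModel` extends a pre-trained, frozen network with a planner block.
Each step the planner's coordinates receive `W_in g*` (goal grid pattern
through a learned projection) as external input; trainable blocks are the
planner recurrence, grid-to-planner, and planner-to-speed/direction —
the planner acts on the world model only by driving the self-motion input
coordinates.  Projections from SMC and hidden units into the planner are
pinned to exactly zero (verified bitwise after training).  Start/target
pairs are endpoints of short random trajectories (1 s), drawn once as a
fixed pool of 128 pairs; the loss is the MSE between the current and goal
grid patterns over all rollout steps.  Generalization is evaluated on
pairs from much longer held-out trajectories.

## Recall protocol

A query clamps the ground-truth SMC pattern of a chosen location on the
SMC inputs of a zero-initialized network for T_q = 100 steps (5 s); all
other inputs are zero.  Per step, each subpopulation's state is decoded on
its ratemap and the Euclidean distance to the cued location recorded.  An
untrained network is the negative control.  PCA recall visualization
projects the flattened ratemap (bins x cells) to three components and maps
the recall trace through the same linear basis.

## Problem sizes and defaults

Desk-scale defaults keep every training run on one CPU core in minutes:
2 grid modules x 64 cells (path integrator; hidden pool 128), 2 x 32 GC
with 64 SMC and 192 hidden units for the full loop, six modules x
16 cells for planner pretraining, batch 16, and 4k-9k optimizer steps
per network in the test suite (up to ~15k when run standalone).
Ratemaps for training use 2-cm bins; geometry measurements 1-cm bins.
The full-scale configuration of the original system (six modules, 512
hidden units, masking-ratio sweep 0.1-0.9) is reachable through
configuration but is not what the test suite exercises.

## Known limitations

* No boundary or obstacle handling; planning is valid only up to half the
  largest grid period.
* The two-module desk-scale grid code has in-arena aliases (above).
* The SMC stand-in is a stationary random field; conclusions about
  sensory reconstruction concern this surrogate, not images.
* Sequential-planner mechanics beyond the documented defaults (clamp
  boost, burn-in, tie handling) change path optimality; the defaults were
  selected for exact geodesic recovery on ideal topologies.
* At desk scale three network-level effects do not reach their
  paper-scale strength, and the corresponding end-to-end tests document
  this by failing at their stated targets: (i) cue-triggered recall
  completes reliably in the hidden and sensory populations (green
  tests), but the grid population often settles into a self-consistent
  grid state of a nearby wrong location, so grid-decoded recall accuracy
  stays below its target; (ii) the place-cell-count increase with
  masking ratio is smaller than seed-to-seed noise; (iii) the learned
  planner reaches distant goals but does not hold them to the evaluation
  horizon reliably enough to meet its success-rate target.  All three
  mechanisms are exercised and their achievable desk-scale behaviour is
  pinned by green companion tests.
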