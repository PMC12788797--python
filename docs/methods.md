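# Methods

## Observation model for single-molecule tracking

A fluorophore-tagged molecule in state k diffuses with coefficient D_k
(µm²/s). Over one frame interval Δt its true displacement per axis is
Gaussian with variance 2·D_k·Δt; each localized position additionally
carries Gaussian localization error σ per coordinate. The observed 2-D
jump length r is then Rayleigh with scale s, s² = 2(D_k·Δt + σ²). The
defaults — Δt = 7.48 ms, σ = 0.03 µm, axial detection slab 0.7 µm
(full thickness), camera pixel 0.16 µm — describe fast HILO SMT of
nuclear proteins. σ = 0.03 µm is a conventional figure for bright
rhodamine dyes at these frame rates, not a measured property of any
particular instrument, and is configurable everywhere it enters.

Trajectories are the unit of molecular identity but not of inference:
they are split into segments of at most `splitsize` jumps (3 by
default; 8 is a coarser convention some analyses prefer) so that no
single long trajectory dominates, and each segment is modeled as drawn
from one state on a fixed grid of 100 log-spaced coefficients over
[0.01, 100] µm²/s. Mixture occupations are estimated by EM from a
uniform start (making inference deterministic), stopping when the
relative log-likelihood gain drops below 1e-8 or after 1000
iterations. The log-likelihood is non-decreasing by construction and
asserted to be so in tests. Occupations are reported on a per-jump
basis: each segment's posterior responsibility is weighted by its jump
count. This is a deliberate simplification of full state-array
inference — we fix σ rather than marginalizing over a grid of
localization errors, and use per-jump Rayleigh factors rather than a
full correlated trajectory likelihood — which is adequate for the
summary statistic this package centers on, the bound fraction.

**Bound fraction.** Molecules with D < 0.1 µm²/s are operationally
immobile and read as chromatin-associated; the bound fraction is the
posterior mass strictly below that threshold. On the default grid, 25
of 100 points lie below 0.1 µm²/s.

## Defocalization correction

Fast molecules wander out of the detection slab and are
under-observed, biasing raw occupations toward slow states. Two
corrections are provided:

* **Observation-model weights (default).** The expected number of
  observed jumps per molecule of coefficient D is computed exactly for
  the acquisition model: a molecule starts uniformly distributed in
  the slab, survives photobleaching with a geometric lifetime (mean
  `bleach_mean_frames`, default 8 frames ≈ 60 ms — a typical effective
  track length under continuous illumination), and contributes a jump
  whenever its axial position lies inside the slab on two consecutive
  frames. Because a tracker that forbids gaps simply starts a new
  trajectory when a molecule re-enters, no absorbing boundary applies,
  and the two-endpoint slab probability is a one-dimensional
  quadrature against the analytic uniform⊛Gaussian marginal. An
  optional field-of-view factor applies the same logic to x and y.
  Dividing jump-level occupations by these weights and renormalizing
  gives molecule-level fractions. The quadrature is validated against
  an independent Monte-Carlo of the observation process in the test
  suite.
* **Absorbing-slab retention (variant).** The classic Fourier series
  for the probability that a Brownian particle starting uniform in the
  slab has not touched either boundary after the segment duration
  (splitsize·Δt), truncated at terms below 1e-10 and clipped to
  [1e-6, 1]. This ignores re-entry and photobleaching and
  over-corrects on simulated data with realistic track lengths (it
  recovers ≈0.23 when the truth is 0.30 under the default two-state
  conditions), which is why it is not the default; it remains
  available both as `correction="retention"` and as the standalone
  `defocalization_retention`, and is validated against a brute-force
  walker simulation with Brownian-bridge boundary-crossing corrections
  (agreement within 0.005 across four decades of D).

The kinetic two-state fit of the empirical jump-length CDF (bound +
free Rayleigh components, multi-start least squares) serves as an
independent cross-check of the grid spectrum; its apparent weight is
corrected with the same observation-model weights. D_bound is poorly
identified when D_bound·Δt ≪ σ² — the bound component's scale is set
almost entirely by localization error — so only the weight and D_free
should be interpreted quantitatively.

## Trajectory quality control

The filter chain reproduces standard post-hoc SMT curation: (1)
trajectories must lie entirely within exactly one nuclear mask
(labeled image; straddlers and strays are dropped); (2) if any frame
of a cell holds more than six localizations, frames are truncated
strictly from the beginning of the movie until every remaining frame
has at most six — a prefix rule, so one late dense frame removes
everything before it; (3) cells with fewer than 100 displacements
(counted after the first two filters) are excluded. The chain is
idempotent, and jumps never bridge a truncation cut because jump
construction requires consecutive frames. Greedy nearest-neighbor
linking (search radius 1 µm, no gap tolerance) is provided for
synthetic data; distance ties break to the lowest localization index
for determinism. It is not intended to replace production trackers on
real movies, which normally arrive already linked.

## Resampling

Cell-wise bootstrap: for n cells, each of 96 trials draws n cells with
replacement, pools their data (a cell drawn twice counts twice, as an
independent pseudo-cell), recomputes the statistic, and the 2.5/97.5
percentiles give the 95% CI. For the bound fraction a batched
implementation runs all trials' EM updates as matrix products over one
shared segment-likelihood matrix — numerically identical to the
generic path (same draws per seed, verified in tests) and roughly two
orders of magnitude faster. Coverage of the bootstrap CI is verified
on replicate simulated experiments.

Variance decomposition: n jumps are drawn 1000 times per scheme —
(1) from the entire pool, (2) from one uniformly chosen cell,
(3) from one uniformly chosen day — and the s.d. of the trial
statistic is recorded per n. The subsampled statistic is injectable
and defaults to the mean jump length, a model-free summary that tracks
the bound/free composition; the procedure is agnostic to the choice,
and any scalar jump summary slots in unchanged. The pool curve falls as n^(−1/2); the within-cell
and within-day curves plateau at the between-cell and between-day
variance floors. Draws use replacement, so n may exceed a group's
jump count.

## PAPA quantification

The acquisition interleaves unsaved shelving (639 nm) and reactivation
pulses (violet 405 nm: proximity-independent; green 561 nm:
proximity-dependent) with four saved 30-frame readout blocks per cycle
(spontaneous 1, violet, spontaneous 2, green), five cycles → 600 saved
frames. A reactivated molecule is a new trajectory, tallied to the
phase of its first localization (a localization-level tally is
available behind a flag; the choice is a convention, and at the
counts involved the two differ only by a per-cell scale that the ratio
cancels). The corrected ratio (green − spont2)/(violet − spont1)
floors both excesses at zero and is flagged missing when the floored
denominator is zero. Day-matched normalization divides each cell's
corrected ratio by the *pooled-counts* aggregate ratio of that day's
non-interacting control — pooling counts rather than averaging
per-cell ratios keeps low-count control cells from injecting noise.
The condition-level estimate pools counts day-wise, normalizes by the
day's control aggregate, and combines days weighted by pooled violet
excess (the quantity that sets each day's information content); its
96-trial bootstrap resamples condition cells only, holding control
aggregates fixed, matching the convention that every condition is
normalized to its own day's control. Consequence: the CI reflects
condition sampling noise only, and is honest when the control is
measured much more deeply than the condition (coverage verified at a
10:1 control:condition cell ratio); with shallow controls the CI
understates total uncertainty.

The PAPA count generator is a Poisson model per cell: both spontaneous
blocks at rate `spont_rate`, violet at `spont_rate + violet_rate`, and
green at `spont_rate + control_ratio·violet_rate +
interaction·green_rate`, so the expected corrected ratio is
`control_ratio + interaction·green_rate/violet_rate` — a
non-interacting condition sits exactly at the control baseline and the
interaction term adds linearly. Defaults (spont 20, violet 80, green
80 molecules per cell per acquisition, control baseline 0.26) give
count depths and a control ratio typical of the assay. An optional
lognormal per-cell expression factor scales all four means together,
leaving the expected ratio unchanged while spreading per-cell counts.

## FRAP analysis

Steps, in order (fits refuse unbinned curves so the order cannot be
silently skipped): (1) nuclear mask from the per-frame z-normalized
sum projection — Gaussian blur σ = 2 px, isodata (intermeans)
threshold, hole filling, largest connected component; (2) per-frame
background subtraction using the median of non-nuclear pixels;
(3) two-anchor photobleach correction — pre-bleach frames scaled to
the in-mask sum of the last pre-bleach frame, post-bleach frames to
the first post-bleach frame, which flattens observational
photobleaching while leaving the intentional bleach untouched (valid
because recovery conserves total nuclear fluorescence); (4) FRAP(t) =
mean spot intensity / mean pre-bleach spot intensity, times
re-referenced to the first post-bleach frame; (5) up to 100 log-spaced
bins from 0.01 s to the last time point, each non-empty bin
contributing the arithmetic means of its times and values, so the long
tail does not outweigh the fast phase; (6) the gradient-smoothing
test: radial mean-intensity profiles (1 px annuli) of the first
post-bleach frames, each min-max normalized; recovery is flagged
diffusion-coupled when successive normalized profiles differ by more
than 0.1 anywhere (in practice this check is often done by eye; the 0.1
max-difference criterion is this package's quantitative stand-in,
configurable). The companion scale r²/(4D) — 70 ms for a
0.75 µm spot at D = 2 µm²/s — explains why diffusion is invisible at
a 250 ms first post-bleach delay. (7) Constrained fits of the
fractional recovery of the bleached amount, rec(t) =
(FRAP(t) − F0)/(1 − F0) with F0 the first post-bleach value:
A(1 − e^{−t/τ}) or the double-exponential sum, amplitudes in [0, 1]
with A1 + A2 ≤ 1 enforced by the reparameterization A1 = p·q,
A2 = p(1 − q); no additive offset is fitted — the "implicit constant"
is the bleach floor already removed in rec(t), and the amplitude
constraint caps the plateau at full recovery. τ is fitted on a log
scale with multi-start (τ ∈ {0.1, 1, 10, 100} s × amplitude splits);
double fits report τ1 ≤ τ2.

The FRAP generator renders a disk nucleus (photons-per-pixel floats;
no camera gain/offset model), bleaches a 0.75 µm spot between the
pre and post phases, and recovers it along the ground-truth
double-exponential, with the recovered intensity drawn from the rest
of the nucleus so total fluorescence is conserved — the property the
two-anchor correction relies on. The recovery clock starts at the
first post-bleach frame, making generator→analyzer round trips exact
(verified to 1e-3 in tests; the sub-frame offset this introduces is
far below fit precision). Observational photobleaching multiplies the
nuclear signal by e^{−rate·frame}; background and Gaussian noise are
added per pixel. A diffusion mode replaces the uniform spot recovery
with a relaxing Gaussian hole (variance σ0² + 2Dt) to exercise the
gradient-smoothing test's positive branch.

## SMT generator

Molecules draw a state once (weights configurable per cell via a
Dirichlet concentration, for studies of cell-to-cell variability),
perform 3-D Brownian motion, and are observed with localization noise
only while inside the slab and field of view; any gap starts a new
trajectory id, matching gap-free tracking. Fluorophores activate at
uniformly random frames (continuous photoactivation), keeping
per-frame density sparse and stationary; an all-at-frame-zero burst
mode exists but interacts destructively with the dense-frame
truncation filter (the burst itself gets truncated), so it is not the
default. Lifetimes are geometric with mean `bleach_mean_frames`.
Defaults (2 days × 10 cells × ~60 molecules, 20 µm field) give a few
hundred displacements per cell, comparable to a filtered fast-SMT
acquisition. An optional per-frame state-switching rate exists purely
to stress the fixed-state assumption of the inference model.

What the generator does not emulate: detection/localization from
pixel data (it emits localizations directly, so detection false
positives/negatives and intensity-dependent precision are absent),
anomalous or confined diffusion, state switching under the default
settings, chromatin context, and camera noise. Passing
parameter-recovery tests therefore demonstrates correctness of the
inference chain under its own model assumptions — not robustness to
every artifact of real movies.

## Numerical choices and problem sizes

EM: uniform initialization, no prior, tolerance 1e-8 (relative), cap
1000 iterations. Defocalization series: term cutoff 1e-10, clip floor
1e-6. Observation-weight quadrature: 201 trapezoid nodes, lifetime
tail truncated below 1e-9 relative weight. Monte-Carlo retention
oracle: 10⁶ walkers, 100 substeps, Brownian-bridge crossing
corrections per boundary. Parameter-recovery runs use 220 simulated
cells (~8×10⁴ jumps); bootstrap-coverage runs use 100 replicate
20-cell experiments with 96 trials each (batched EM); FRAP recovery
uses 100 replicate 64×64 movies (16 pre + 120 post frames at 0.5 s).
These sizes keep every stage's sampling error comfortably below the
tolerances being asserted while remaining single-core friendly.

## Known limitations

* Fixed σ: localization error is not marginalized; a badly wrong σ
  biases the slow end of the spectrum.
* The observation-weight correction needs the mean fluorophore
  lifetime in frames; on real data estimate it from the track-length
  distribution of immobile molecules (slab losses are negligible for
  them) before correcting.
* The two-state CDF fit's D_bound is only weakly identified below
  σ²/Δt.
* PAPA bootstrap CIs exclude control-measurement noise by design (see
  above).
* The FRAP gradient-smoothing threshold (0.1) is a heuristic; borderline
  diffusion coupling should be judged from the returned profiles, not
  the flag alone.
* Movies with axial drift must be excluded upstream; the CLI honors a
  manual exclude list but detects nothing itself.
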