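# Methods

This note documents the model, the estimators, the numerical choices and
the limitations of `wormswarm`.  Units are millimetres and seconds
throughout; areal densities are mm⁻²; analysis outputs use the µm and
µm/min conventions of multi-worm tracking.

## Agent model

Worms are chains of M nodes (default 18) with total length L = 1 mm,
moving in a periodic square arena (default side 8 mm, so 40 worms of
width ≈ 0.08 mm cover ≈ 5% of the arena, matching the area fraction of
the tracking experiments).  The leading node is self-propelled at the
speed of the current motility state and its heading θ performs a
persistent random walk:

    θ(t+dt) = angle( u(θ) + dt · T ) + √(2 D_θ dt) ξ,   ξ ~ N(0, 1)

where u(θ) is the unit persistence vector and T is the taxis drive (see
below).  Trailing nodes follow: each node is placed at exactly the rest
spacing L/(M−1) along the line towards its already-updated anterior
neighbour.  This is the stiff-spring (constraint-projection) limit of
harmonic bonds; chain length is conserved to machine precision, which
satisfies the ±5% non-extensibility requirement trivially and is stable
at any dt.  Worms may overlap; there is no volume exclusion.  Body
undulations are omitted — aggregation in this class of models is robust
to their presence, and they only add a faster length-scale to resolve.

Worm positions are integrated unwrapped and re-centred by whole-arena
shifts, so intra-worm geometry never crosses a wrap seam; all inter-worm
distances use the minimum-image convention.

### Density sensing

Each worm senses the local density ρ as the k-nearest-neighbour density
k/(π d_k²) of all worms' head-region centroids with k = 6 ≈ √N — the
same estimator applied to tracking data, so model and analysis are
internally consistent.  Whether the original agents sense density by
neighbour counts or k-NN is not observable at our scale; k-NN was chosen
for this consistency.

### Reversals

Contact is registered when any node of another worm lies within
r_contact = 0.1 mm of one of the first or last ⌈0.1 M⌉ = 2 nodes.  A
forward worm with contact at exactly one end — the signature of leaving
a cluster — starts a reversal with probability 1 − exp(−r′ ρ dt); no
contact or both-end contact never triggers one, and the rate at zero
density is zero (spontaneous reversals are ignored).  During a reversal
the tail node becomes the leader and the worm retraces its body; the
heading variable tracks the leading end and is re-derived from the body
axis at each switch.  Reversal durations are exponential with mean 2 s.

### Speed switching

Worms switch between v_slow = 0.035 and v_fast = 0.35 mm/s with Poisson
rates k_slow = k_s0 + k_s′ρ and k_fast = k_f0·exp(−k_f′ρ).  The
zero-density rates default to k_s0 = 1/240 s⁻¹ and k_f0 = 1/60 s⁻¹
(single-worm roaming/dwelling scale; config-overridable package
defaults, not measured values).  Where food is absent, k_slow is set to
zero while k_fast is unchanged, so worms on depleted ground end up fast.

### Taxis

The drive towards neighbours is T = f_t Σ_j û_j / r_j over neighbours
with r_min < r_j ≤ L (û_j the unit vector towards neighbour j).  Two
numerical choices matter here:

1. **Turn-rate form.** The heading update adds dt·T to the unit
   persistence vector, so for small drives the taxis turns the heading
   at rate |T| rad/s independently of the integration step.  Blending T
   without the dt factor makes the effective taxis strength scale as
   1/dt — the model would change with the step size.  A drive much
   larger than 1/dt still aligns the heading in a single step.
2. **Short-range cutoff.** The 1/r kernel is cut off below
   r_min = taxis_softening (default L/4).  Without it, overlapping
   worms — overlap is allowed — experience a diverging mutual pull and
   every cluster collapses to a point-like absorbing state.  With the
   cutoff, clusters equilibrate at a finite ~0.3–0.5 mm scale.  The
   public `taxis_drive` keeps r_min = 0 by default; the simulation loop
   passes the softening value.

Taxis acts on the head only (head-led sensing) and is disabled while a
worm reverses.

### Update order

Per step: density sensing → taxis → reversal update → speed-state
update → heading update → body advance → food depletion.  All random
draws come from one seeded generator in a fixed order (reversal
uniforms, reversal durations, switching uniforms, heading normals), so
runs are bit-reproducible given the seed.

### Reference parameter sets

The posterior parameter values behind the published strain fits are not
printed, so the package ships its own reference sets, calibrated once so
that the npr-1-like set reproduces the qualitative structure of the
fitted model: strong aggregation (S1 short-range excess ≫ 1); removing
taxis (f_t = 0) or speed switching (k_s′ = k_f′ = 0) disrupts
aggregation; removing reversals (r′ = 0) measurably changes the summary
statistics; and with food depletion, clusters swarm at order-100 µm/min.

    npr1_reference: r′ = 0.2,  k_s′ = 0.015, k_f′ = 0.2, f_t = 0.1
    n2_reference:   r′ = 0.02, k_s′ = 0.005, k_f′ = 0.2, f_t = 0.02

The narrow k_s′ scale follows from the background density: 40 worms in
64 mm² give ρ ≈ 0.6 mm⁻², and slowing must stay below k_fast there
(else the population freezes uniformly) while dominating at in-cluster
densities ρ ≳ 5.

## Food field and swarming

Food is a periodic grid of relative concentration in [0, 1] (cell
0.2 mm ≈ L/5), initially uniform.  Each step, the cell under each
worm's head loses feed_rate·dt per occupant, floored at zero — only the
head feeds (the pharynx is the feeding organ).  A cell counts as
food-free below 5% of the initial concentration.  Feeding rates are
swept over (0.005, 0.01, 0.02, 0.05) per worm per second: across this
range a cluster-occupied cell empties in minutes to tens of minutes
while the full lawn lasts from about an hour to many hours, bracketing
the thin-to-thick lawn conditions of swarming experiments.  Cluster
migration speed rises with feeding rate, as expected when clusters must
re-form on neighbouring food more often.

Cluster speed is measured exactly as for time-lapse videos: sample
frames every 30 s, rasterise all worm nodes onto a 0.1 mm occupancy
grid, label 8-connected blobs (merged across the periodic boundary),
keep blobs above an area threshold (default: the raster footprint of 3
worms), link blob centroids across frames (nearest centroid within
1 mm), smooth each centroid track with a 10-min moving average, and
report speeds in µm/min.

## Summary statistics

- **S1, pair correlation**: observed pair counts per 0.1 mm distance
  bin divided by the analytic expectation for uniform points on the
  square torus (the covered-area formula handles r beyond side/2); for
  bounded experimental-style data the expectation comes from a seeded
  Monte-Carlo uniform reference of ≥10⁴ points.  Ratios are averaged
  over frames.
- **S2, branch lengths**: the n−1 single-linkage merge distances per
  frame (SciPy agglomerative clustering), pooled and histogrammed
  (0.2 mm bins, normalised to sum 1).
- **S3/S4**: per-axis standard deviation and Pearson kurtosis
  (Gaussian = 3; the convention is not fixed by the source analyses),
  averaged over the two axes and then over frames.
- Simulated datasets are summarised over the final 10% of the run
  (quasi-steady state), at one frame per 30 s.

S3/S4 are computed on wrapped coordinates; a cluster sitting on the
periodic seam inflates S3 slightly.  This affects simulated data only
and equally across compared conditions.

## Track analysis

Signed speed is the centroid speed signed by the dot product of the
pharynx skeleton vector with the velocity, smoothed over 0.5 s; missing
frames are linearly interpolated.  Reversal events are maximal runs of
negative signed speed starting at a positive-to-negative change, kept
when the backward path is ≥ 50 µm and the mean displacement in the
0.5 s windows before and after is ≥ 0.5 px/frame (10 µm/px calibration
by default; real data must supply theirs).  Reversal rates per density
bin are events divided by forward time, with dispersion from a
100-sample worm-frame bootstrap.

## Inference

Rejection ABC over (r′, k_s′, k_f′, f_t): uniform priors (defaults
r′ ∈ [0,1], k_s′ ∈ [0,1], k_f′ ∈ [0,2], f_t ∈ [0,2]) with a feasibility
cap r′·ρ_max ≤ 2 s⁻¹ at ρ_max = 8 mm⁻² excluding unrealistically high
reversal rates; infeasible draws are rejected and resampled.  The
distance is d = Σᵢ dᵢ/σᵢ with Euclidean distances between S1 and S2
curves and absolute differences of S3 and S4 — the four statistics
equally weighted after dividing by σᵢ, the RMS component distance to
the ensemble mean across the simulation bank (self-normalising; no
external scale is specified for "equal weighting").  The accepted set
is the fraction with smallest distance (default 1%; the recovery tests
use 5% of a 500-simulation bank).  Ties at the boundary break by sample
order.

The two-parameter phase portrait fixes f_t = 0 and k_s′ = k_f′ = k′ and
sweeps (r′, k′); aggregation without taxis is present but weak,
consistent with the observation that reversals and speed switching
alone produce some but not compact aggregation.

## Problem sizes used by the tests and the acceptance script

Full-scale runs use N = 40, dt = 0.05 s.  The validation suite uses
dt = 0.1 s for the long food-depletion and phase-portrait runs (the
constraint-projection body, exact exponential switching probabilities
and rate-form taxis make the dynamics nearly step-independent),
one simulated hour for swarming, 30 simulated minutes for ablations,
and a reduced configuration (N = 15, M = 6, 4.9 mm arena, 300 s, k = 4)
for the 500-simulation ABC recovery study.

## What the synthetic data does and does not cover

The fixture generators emulate the statistical structure the analyses
assume — uniform vs clustered point patterns, sign-changing scripted
tracks, rigidly translating blobs, density-dependent speed mixtures —
with known ground truth.  They do not emulate segmentation noise,
identity switches, lost tracks inside dense clusters, larval
contamination or intensity-dependent detection, so passing tests
validate the estimators on clean input, not robustness to tracking
artefacts.  The generic blob pre-filters (minimum intensity, maximum
area) exposed for imported tracking tables are identity operations on
simulated data and are untested against real tracker output.

## Known limitations

- No volume exclusion: in-cluster densities are higher than physically
  possible for real worms, so the absolute S1 amplitude of simulated
  clusters exceeds experimental values; comparisons between conditions
  are unaffected.
- The taxis softening scale (L/4) is a regularisation choice; the true
  short-range behaviour of the attraction is unidentified.
- k_s0, k_f0, r_contact, the 2 s reversal duration and D_θ = 0.1 rad²/s
  are package defaults at physiologically plausible scales, not fitted
  values; all are config-overridable.
- The S1 seed-to-seed variability of strongly aggregated runs is large
  (clusters are few and history-dependent), so quantitative S1 levels
  should be averaged over seeds.
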