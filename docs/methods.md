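# Methods

This note documents the models, parameter choices, and numerical
conventions behind `motionsync`, and what the synthetic cohorts do and do
not establish about real sensor data.

## Data model and preprocessing

A cohort indexes one univariate joint-angle trace (degrees) per
(participant-side, movement, angle).  Stroke patients contribute their
paretic side only; controls contribute both sides, each as its own
participant-side record.  Every movement is performed once, so durations
vary across recordings; all angles of one recording share a duration
(they come from one synchronized sensor take).

Before any comparison, traces are mapped to a common length `m_max`
(default 1500 samples) by an interpolating spline over the affinely
normalized index: cubic for inputs of length ≥ 4, linear for 2–3 points
where a cubic is under-determined.  Over-long traces pass through the same
spline (down-sampling); the stored `original_length` is retained so
"Proportional" summaries can restore real time extents.  Resampling is
idempotent at the target length and preserves endpoints exactly.

## Dissimilarity

For equal-length traces the dissimilarity is Z = w1·z1 + w2·z2 + w3·z3
with default weights (1, 1, 1):

* z1 — squared Euclidean distance (synchrony);
* z2 — 2 if either trace is null (max |value| ≤ 1e-8; exact-zero tests
  are fragile after spline interpolation), else 0;
* z3 — exp(−TV(t_i)) + exp(−TV(t_j)); near-constant traces have total
  variation ≈ 0 and are penalized by ≈ 2, busy traces contribute ≈ 0.

**Scale of the synchrony term.** Raw joint-angle curves give z1 of order
1e5–1e7 deg² over 1500 samples, which makes the fixed-size penalties
z2 = 2 and z3 ≤ 2 numerically invisible — null channels would then look
*similar* to each other (z1 = 0) and attract strong edges, the opposite of
the penalties' purpose.  The network-building pipeline therefore computes
z1 on mean-centered, unit-L2-norm curves: z1 = 2(1 − ρ) with ρ the Pearson
correlation, capped at 4, scale- and offset-invariant.  A motionless curve
(zero vector after centering: null or constant) has no defined correlation
with anything and is assigned the maximal z1 = 4 against every partner —
it synchronizes with nothing, including other motionless curves.  z2 and
z3 always see the raw curves.  The audit-level functions
(`pair_dissimilarity`, `dissimilarity_matrix` by default) keep raw
semantics so individual values remain interpretable in deg².

## Graph learning

Per recording we minimize, over symmetric non-negative zero-diagonal W,

    F(W) = ½ Σ W_ij Z_ij − α Σ_i log(Σ_j W_ij) + γ ||W||_F².

The problem is convex; on the upper-triangular vector w with the linear
degree operator S (d = Sw) it reads
min_{w≥0} 2 z·w − α 1ᵀlog(Sw) + 2γ||w||².

**Solver.** Condat–Vũ primal–dual splitting: a forward step on the smooth
2γ||w||² term, the proximal map of the linear-plus-positivity part
(max(0, x − 2τz)), and a dual step on the barrier through S, whose
proximal map is closed-form ((x ± √(x² + 4tα))/2).  With σ = τ the scheme
converges when 1/τ − τ·2(n−1) ≥ 2γ; τ solves the equality with a 0.99
margin.  Iterations stop when the relative objective change drops below
`tolerance` (default 1e-6; tests that compare against an independent
bound-constrained quasi-Newton solution use 1e-13 and match it to better
than 1e-6 relative in objective).  Identical inputs give bit-identical
output; networks are independent across recordings.

**Parameters.** α (barrier) = 1 fixes the degree scale.  γ controls
where connection stops: at an optimum a pair carries weight only if
2 Z_ij < α(1/d_i + 1/d_j), and a vertex holding one strong partner has
d ≈ √(α/2γ), so γ = 0.125 places the cutoff at Z ≈ 0.7 — on the
correlation-distance scale that admits only pairs with ρ ≳ 0.65.  Because
the pipeline's Z is already O(1), no solver-side rescaling is applied by
default (`z_scaling="none"`); mean-normalization remains available for
externally supplied Z on other scales.

**Edges.** The log barrier leaves *every* vertex a strictly positive
degree; for motionless channels this residual is spread thinly over many
partners at ≈ 1% of the maximum weight (analytically d ≈ α/(2 Z_motionless)
split over n−1 partners).  An entry counts as an edge iff
W_ij > 0.05 · max(W): above the barrier floor, well below genuine edge
weights (≥ ~0.3 of max in all tested regimes).  A purely positivity-based
edge rule cannot work under a degree barrier.

## Filtering

All networks share the vertex set, so edges pool into a provenance-tagged
multiset E_U.  Filters restrict by group/side token (strokeL, strokeR,
ctrlL, ctrlR), movement, and optionally individual.  Edge support counts
distinct (participant, movement) networks — one unit per network even when
several movements are selected.  Top-K ranking breaks ties
lexicographically on (smaller id, larger id).  Group difference compares
presence (support ≥ 1) per domain, not magnitudes; intersection returns
the shared pairs.

## Descriptors and projections

* Per-series measures: arithmetic mean; energy = Σ x²; entropy =
  natural-log Shannon entropy of the 100-bin histogram over the series'
  own [min, max] (constant series → 0).  Measures use raw resampled
  values.
* Group summaries: pointwise mean and population SD across participants;
  `display_length` is the mean original duration (Proportional) or the
  common length (SameLength).
* Network features: per vertex [weighted degree | closeness |
  eigencentrality | clustering], 4·N_A values per movement, N_M·4·N_A
  concatenated.  Closeness uses 1/weight distances; eigencentrality is the
  non-negative L2-normalized leading eigenvector per connected component;
  clustering is the weighted (geometric-mean) coefficient; isolated
  vertices score 0 in all blocks.
* PCA: mean-centered, full SVD, deterministic signs (largest-|loading|
  coordinate positive).  Motion-curve PCA z-scores each trace first.
* MDS: classical Torgerson double-centering with the top eigenpairs;
  all-identical input collapses to the origin with a warning.

## Autoencoder embedding

A 1-D convolutional autoencoder implemented directly on NumPy (im2col
convolutions, manual backprop, Adam 1e-3, β = (0.9, 0.999)).  Encoder:
six conv layers, kernel 3, unit padding — one stride-1 layer lifting 1 → 4
channels at length 1500, then five stride-2 layers at 4 channels giving
lengths 750, 375, 188, 94, 47; the flattened 4×47 = 188 activations are
the embedding.  ReLU in the encoder only; the decoder mirrors with
transposed convolutions and no activation, with per-layer output lengths
fixed so shapes invert exactly.  This schedule keeps the channel width at
4 throughout: halving the channel count five times from 4 is impossible,
and this is the simple schedule consistent with a 188-dimensional
bottleneck.  Inputs are standardized by one global SD fit on the training
data.  Training data are all selected traces plus every trace reversed in
time (a doubling augmentation that preserves the kinematic vocabulary);
training minimizes mean squared reconstruction error and is a pure
function of (inputs, seed, schedule).  Defaults: 200 epochs, batch 32; the
pipeline's AE-MDS projection trains 30–60 epochs on preset-sized cohorts,
which is already well past the reconstruction-loss knee at these data
sizes.  Weight init is He-scaled Gaussian from the seeded generator.

## Synthetic cohorts

The generator emulates the statistical shape of single-execution IMU
kinematics: smooth band-limited curves (2–4 sinusoids ≤ 3 cycles plus
linear drift, amplitudes 10–90°), durations uniform on [600, 1500]
samples shared across a recording's channels, group metadata with
plausible Fugl–Meyer totals, optional null (all-zero) and constant
channels, and planted couplings.

Couplings are declared per group (or per individual, to plant outliers) as
(angle pair, movement) entries.  Channels of one coupled component share a
single latent curve drawn per (group, movement, component) — shared across
the group's participants, with a per-participant amplitude factor
(0.9–1.1) and additive Gaussian noise (default SD 1°).  Group-level
sharing is what gives projections a group signal to find; couplings alone
would otherwise not shift any marginal distribution.  Component latents of
one (group, movement) are drawn from component-specific frequency bands
and Gram–Schmidt decorrelated on the master grid, because random smooth
low-frequency curves correlate up to |ρ| ≈ 0.75 by chance, which would
blur the planted structure.  Uncoupled channels get independent
per-participant curves.

Presets:

* `flexor-synergy-like` — one movement, 7 stroke-L + 5 controls per side,
  11 angles; both groups fully paired but with different pairings, one
  all-zero wrist channel everywhere, and individual "stroke_7" carrying an
  extra truncal coupling that merges the trunk components (the planted
  outlier).  Exercises projection-based group separation and null-channel
  handling.
* `shoulder-flexion-like` — one movement, 6 stroke-L + 5 controls per
  side, 9 angles; four normal synergies shared by all, controls hold
  shoulder abduction constant, stroke individuals couple abduction into
  the flexion/elbow synergy.  The Differences filter recovers exactly the
  two planted stroke-only pairs and nothing control-only.
* Presets use amplitudes 20–90° so the default 1° noise stays ≤ 5% of the
  smallest latent amplitude.

**What passing tests show — and don't.** The synthetic curves are
noise-perturbed shared latents: within-group homogeneity is far higher
and channel cross-talk far lower than in real kinematics, recovery there
does not bound sensitivity on clinical data, and the exact-count filter
results depend on the generator's decorrelated construction.  What the
tests do establish is that each pipeline stage implements its definition
correctly (solver vs. independent convex oracle, filter algebra vs. brute
force, projections vs. closed-form cases) and that the end-to-end
mechanism — dissimilarity, barrier, thresholding, set algebra — extracts
exactly the planted group structure when one exists.

## Degenerate inputs and conventions

Series shorter than 2 samples, non-finite values, length mismatches, and
negative weights raise typed errors.  Movements and angles are 0-based
internally and rendered 1-based ("M1"…).  All-zero weight matrices yield
empty edge sets; the objective is +∞ whenever any row sum is 0.  Renderers
are pure functions of their inputs (fixed SVG hash salt, no timestamps);
arc thickness is affine in support; projection marker radius decreases
affinely in the Fugl–Meyer total over the cohort's observed range, with a
default radius and a warning when a score is missing.

## Problem sizes used in checks

The full study-scale structural check generates 87 participant-sides × 13
movements × 20 angles (22,620 series) and learns all 1,131 networks
(~15 s total on one CPU).  Solver–oracle equivalence uses 50 random
instances with n ∈ {3…6}; recovery and filter-exactness checks run the
presets over 5 and 11 seeds respectively; the AE-MDS separation property
averages 3 seeds at 30 training epochs.
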