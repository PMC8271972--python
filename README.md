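# motionsync

Joint-angle **synchronization networks** from wearable-sensor recordings of
upper-extremity movement.

Stroke survivors often lose the normal coordination between body segments:
pairs of joints that usually move together stop doing so (impairment),
while other segments start moving together that normally would not
(compensation, e.g. trunk flexion standing in for shoulder flexion).
`motionsync` turns a cohort of joint-angle time series — one trace per
(participant-side, movement, anatomical angle) — into one weighted
undirected network per recording, whose edges mark the angle pairs that
genuinely co-varied during that movement.  Set-algebra filters over the
pooled edge sets then expose group-level patterns (edges present only in
the stroke group, most prevalent relations, shared structure), and three
projection schemes place individuals in 2-D for comparison against their
group.  It is written for movement scientists and rehabilitation
researchers working with IMU-derived kinematics.

## The model

For the traces T = {t_1, ..., t_n} of one recording (n angles, common
length m after spline resampling) a pairwise dissimilarity is built from
three terms:

    z1(i,j) = ||t_i - t_j||^2          synchrony (squared Euclidean)
    z2(i,j) = 2 if t_i or t_j is identically zero, else 0
    z3(i,j) = exp(-TV(t_i)) + exp(-TV(t_j)),   TV = total variation

    Z_ij = w1 z1 + w2 z2 + w3 z3,      default weights (1, 1, 1)

z2 and z3 penalize motionless (null / near-constant) channels, which record
no movement and must not attract edges.  Inside the network-building
pipeline z1 is computed on mean-centered, unit-norm curves, i.e.
z1 = 2(1 − ρ) with ρ the Pearson correlation, so all three terms share one
O(1) scale (see `docs/methods.md`).

The adjacency matrix W ≥ 0 (symmetric, zero diagonal) is the minimizer of

    F(W) = ½ Σ_ij W_ij Z_ij  −  α Σ_i log(Σ_j W_ij)  +  γ ||W||_F²

solved by a primal–dual (Condat–Vũ) splitting on the upper-triangular
weight vector.  The Dirichlet term rewards weight on synchronized pairs,
the log-degree barrier (α > 0) forbids isolated vertices, and the
Frobenius term (γ) controls density.  Edges are the entries above
`edge_threshold_rel · max(W)`.

Downstream, the union edge multiset E_U over all networks supports
declarative filters Λ (groups × sides × movements × individuals), edge
support counts `fcount`, top-K prevalence ranking, and group
difference/intersection queries; projections are network-feature PCA
(degree, closeness, eigencentrality, clustering per vertex), motion-curve
PCA, and classical MDS of a 188-dimensional convolutional-autoencoder
embedding of each trace.

## Worked example

Since clinical recordings are rarely shareable, the package ships a
synthetic-cohort generator with planted ground truth.  The
`shoulder-flexion-like` scenario emulates an arm-raise task: everyone
shares four normal synergies, controls keep shoulder abduction still, and
stroke individuals show an intrusive flexor synergy that couples abduction
with shoulder flexion and with elbow flexion:

```
motionsync simulate --out demo/cohort --preset shoulder-flexion-like --seed 7
motionsync build-networks --cohort demo/cohort --out demo/nets
motionsync filter --cohort demo/cohort --networks demo/nets \
    --groups strokeL,ctrlL,ctrlR --movements M1 --mode differences \
    --out demo/edges.json
```

`demo/edges.json` then contains (abridged):

```json
{
 "stroke_only": [
  [[0, 1], ["Shoulder Abduction LT, deg", "Shoulder Flexion LT, deg"]],
  [[0, 2], ["Shoulder Abduction LT, deg", "Elbow Flexion LT, deg"]]
 ],
 "control_only": [],
 "shared": [
  [[1, 2], ["Shoulder Flexion LT, deg", "Elbow Flexion LT, deg"]],
  [[3, 4], ["Shoulder Rotation LT, deg", "Shoulder Total Flexion LT, deg"]],
  [[5, 6], ["Wrist Flexion LT, deg", "Forearm Pronation LT, deg"]],
  [[7, 8], ["Thoracic Flexion, deg", "Lumbar Flexion, deg"]]
 ]
}
```

Reading: the Differences filter found exactly two edges unique to the
stroke group — abduction synchronizing with shoulder flexion and with
elbow flexion, the planted compensation pattern — no control-only edges,
and the four normal synergies shared by both groups.  `render-arcs` draws
this as an arc diagram (stroke-only red, control-only green, shared gray);
`project --method ae-mds` followed by `render-projection` gives the 2-D
individual map with marker size encoding impairment (lower Fugl–Meyer
total → larger circle).

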