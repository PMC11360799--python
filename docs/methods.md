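# Methods

## The Halfwave reduction

A sampled signal is first compressed to its level-1 representation: the
ordered, strictly alternating sequence of local minima and maxima. For
sampled data, extrema need not be isolated, so a plateau run of equal
samples is represented by its first sample; the first and last samples are
appended by default (kinds chosen to preserve alternation) so the
piecewise-linear reconstruction spans the whole window and the absolute
min/max features see the window edges.

Each further level deletes *trivial* half-waves. With extremal values
y₀…yₙ and successive differences Δᵢ = yᵢ₊₁ − yᵢ, the deletion set D holds
interior indices i ∈ [1, n−2] with |Δᵢ| ≤ |Δᵢ₊₁| and |Δᵢ| ≤ |Δᵢ₋₁|; the
points xᵢ, xᵢ₊₁ of every admitted segment are removed, i.e. the survivors
are {xᵢ : i ∉ D, i−1 ∉ D}. Two numerical choices make this well defined on
real data:

* **Ties.** Under strict inequalities, admitted indices can never be
  adjacent; with ties (flat or symmetric excursions) they can. A greedy
  left-to-right scan that skips the successor of an admitted index enforces
  non-adjacency by construction, keeping deletions in disjoint adjacent
  pairs — which is exactly what preserves the min/max alternation and, by
  the ordering |Δᵢ| ≤ min(|Δᵢ₋₁|, |Δᵢ₊₁|), alternation in value as well.
* **The trailing index.** A literal reading of the deletion-set definition
  also admits the final index n unconditionally, which removes the last
  extremal point on *every* pass — the iteration then erodes any signal to
  a single point and a meaningful fixed point never exists, contradicting
  the method's own convergence property. The default therefore preserves
  the endpoint (`preserve_endpoints=True`); the literal variant is kept as
  an explicit mode for fidelity, and still terminates (the point count
  strictly decreases until ≤ 1).

Convergence: the point count is non-increasing and strictly decreases on
any non-fixed pass, so the complete Halfwave is reached in at most the
initial point count of passes; the fixed point is idempotent under further
passes. One property one might expect does **not** hold: the maximum
reconstruction error of the piecewise-linear interpolant is not pairwise
monotone across levels — deleting a pair occasionally moves the interpolant
closer to the signal locally. What does hold (checked on random signals) is
that no deeper level reconstructs better than level 1, which interpolates
through every extremum.

## Features

The pipeline reduces each 30-s epoch to level 2 — one deletion pass —
because deeper levels oversimplify low-amplitude sleep EEG (epochs can
collapse to a single extremum). Six scalars per epoch:

| feature | definition | units |
|---|---|---|
| E | surviving extremal-point count | – |
| S_mean_abs | mean of segment slopes \|yᵢ₊₁−yᵢ\|/(xᵢ₊₁−xᵢ) | value/sample |
| S_max | maximum signed segment slope | value/sample |
| Ē | mean of extremal values | value |
| y_min, y_max | min/max of extremal values | value |

The slope set is variable-length; it is summarized by the mean absolute
slope (a signed-mean option exists) so the feature vector is a fixed six
scalars. Amplitude statistics are computed on the reduced extremal values
(raw-window mode available). Slopes use sample indices as abscissa — per-Hz
bookkeeping stays out of the features; multiply by fs for per-second units.
Degenerate epochs (reduction below 2 points, e.g. constant input) fall back
to zero slopes and raw-window statistics. Features are standardized (zero
mean, unit variance on training statistics) before KNN, which is
scale-sensitive; the flag is in the config and echoed in provenance.

## Distances and KNN

Both distance routes produce squared Euclidean distances between feature
columns: the naive expansion (2dn² MACs, a d×n×n intermediate) and the
Gram-matrix form D = diag[G] + diag[G]ᵀ − 2G (n²(d+2) MACs, n×n
intermediates). The Gram form can leave −ε entries by cancellation; they
are clamped to zero and the diagonal is set exactly to zero. KNN ranks by
squared distance (monotone-equivalent to the rooted metric, no sqrt).
Determinism under K = 2, where vote ties are routine: distance ties break
toward the lower training index, vote ties toward the label of the single
nearest neighbour among the tied classes — the classifier degrades
gracefully to 1-NN. A self-match exclusion option exists for
resubstitution-style evaluation; the default protocol uses disjoint splits
and never needs it. Operation tallies (MACs, storage) are attached to every
distance matrix and follow the closed forms above exactly.

## Class balancing

Sleep-stage data are heavily imbalanced, so before classification every
training class is oversampled up to the largest class count. SMOTE
interpolates uniformly on segments between a seed and one of its k = 5
same-class nearest neighbours. ADASYN allocates each class's budget over
its samples proportionally to rᵢ — the fraction of other-class samples
among the sample's k nearest neighbours over the whole training set
(largest-remainder rounding; uniform fallback with a warning if a class
sees no foreign neighbours at all) — then perturbs each interpolated point
with zero-mean Gaussian jitter of per-feature scale σ·sd(feature),
σ = 0.01, clipped at 3σ so synthetic points provably stay within the class
bounding box inflated by 3σ·sd. Balancing runs **after** the 60–40 split
and only on the training partition — oversampling first would leak
synthetic copies of test neighbourhoods into training; a literal pre-split
mode exists for replication attempts. All draws come from one seeded
generator: runs are bit-reproducible.

## Evaluation

The headline metrics pool one-vs-rest counts over the C×C confusion
matrix: TP = trace, FP = FN = total − trace, TN = Σ_c (total − row_c −
col_c + diag_c), reported as sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/(TP+TN+FP+FN), in percent. For C = 2 the
pooled accuracy equals trace/total; for larger C it is an optimistic
aggregate (TN-heavy), so macro-averaged per-class values and the plain
accuracy trace/total are always reported alongside. Class order is fixed
(S1–S4, then W, R, M) so matrices are comparable across runs. Zero
denominators report NaN with a warning, never a silent 0.

## Synthetic data

The generator emulates what the staging problem needs and nothing more:
per-stage band structure and amplitude. Each epoch is a sum of sinusoids
(2 per nonzero band, frequencies uniform within delta 0.5–4, theta 4–8,
alpha 8–12, beta 12–30 Hz, random phases) whose band amplitudes realize a
target RMS split by the stage's band weights, plus white Gaussian noise.
Defaults (RMS in arbitrary µV-like units): W alpha/beta-dominant at 30;
S1 theta at 45; S2 theta at 60 plus a fixed 13 Hz, amplitude-15
spindle-like tone; S3/S4 delta-dominant at 110/150; R mixed theta/beta at
18 — textbook band structure and the amplitude progression of deepening
sleep. The default dataset is 5 stages (W, S1, S2, S3, R) × 40 epochs; an
imbalance preset draws multinomial counts from the empirical slpdb stage
proportions (17.79/38.28/4.76/1.78/6.89/30.5% for S1/S2/S3/S4/R/W).

What passing on this harness shows — and does not. The stages are
separable by construction (distinct dominant bands and RMS levels), so
end-to-end recovery near 100% validates the plumbing: reduction, features,
split hygiene, balancing, distance algebra, vote determinism. It says
nothing about scorer-grade performance on real polysomnography, which has
1/f background, artifacts, stage transitions inside epochs and
inter-subject variability, none of which are modelled (a 1/f option was
considered and deliberately left out to keep SNR controllable).

## Problem sizes

The shipped checks run on sizes chosen to exercise every code path while
staying quick: the exhaustive reduction oracle enumerates all ~797k
signals of length ≤ 12 over {−1,0,1} (deduplicated to ~150k unique
extremal sequences for the level battery), the random-signal battery uses
1000 signals of length ≤ 500, distance equivalence 200 random matrices up
to 50×200, and the end-to-end run 200 epochs of 7500 samples.

## Known limitations

* The generator's separability makes the end-to-end accuracy a plumbing
  check, not a clinical claim (see above).
* The pooled TN-heavy aggregation inflates specificity/accuracy for many
  classes; macro values are reported but not headline.
* The WFDB reader covers the slpdb subset only: format 16, single EEG
  channel by header description, stage symbols {1,2,3,4,W,R,M(T)}; 20-s
  scored records are rejected rather than adapted. No EDF path.
* Level-2 reduction is wired as the default everywhere; no per-record
  level selection is attempted.
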