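# Methods

This note documents the model behind `psamnmf`, its parameter defaults, the
numerical choices, what the synthetic cohorts do and do not emulate, and the
package's known limitations.

## Problem setting

Post-stroke motor impairment of the upper limb is scored clinically with the
Fugl-Meyer Assessment (FMA-UE, 0–66; lower = more impaired).  The package
asks how far severity classes can be recovered *unsupervised* from reaching
kinematics: trials are clustered on frequency-domain features, the clusters
are ranked by compensatory trunk displacement (a well-documented motor
compensation: the more the trunk leans into the reach, the more impaired the
arm), and the resulting labels are validated against FMA-UE bands.  FMA
scores enter only the evaluation, never the clustering.

## Signal path

- **Filtering.**  Second-order Butterworth low-pass, applied
  forward-backward (`scipy.signal.filtfilt`).  Zero-phase filtering is
  chosen so that no phase lag corrupts the timing of trunk displacement
  relative to the reach; the consequence is that the single-pass −3 dB point
  becomes a gain of 0.5 at the cutoff (verified in the tests to ±0.02).
  Defaults: 10 Hz (wearable, 60 Hz sampling), 20 Hz (camera, 200 Hz).
- **Acceleration.**  Central second differences scaled by fs², one-sided at
  the endpoints; exact for quadratics.  No smoothing beyond the low-pass.
- **3-D → 1-D.**  Per-sample Euclidean norm √(X²+Y²+Z²) of the acceleration,
  making the series independent of sensor mounting orientation (rotation
  invariance is property-tested to 1e−9).
- **Spectral features.**  Magnitude of the one-sided DFT of the
  mean-removed series, collapsed into `n_freq_bins` (default 16) contiguous
  bands by root-sum-of-squares, unit-normalized per channel; a constant
  series maps to the zero vector.  The bands cover only the filter passband
  (cutoff/Nyquist fraction of the spectrum): after low-pass filtering the
  upper spectrum is empty, and spending all bins on the passband is what
  gives the bands enough resolution to separate movement dynamics.  Band
  aggregation by RSS keeps a pure tone in a single output bin and makes
  band energies additive (Parseval is tested to 1e−6).
- **Feature spaces.**  `position_freq` — per-axis position spectra of the
  feature channels (wearable: 5 segments × 3 axes; camera: 9 markers × 3,
  the 4 trunk markers feed labeling only); `accel_freq` — spectra of the
  per-channel acceleration magnitude plus that series' trial mean (the one
  amplitude-bearing column); `merged` (default) — their concatenation.
  Unequal trial lengths are handled by the fixed number of bands.

Because unit-norm spectra and physical-unit columns coexist, every baseline
partitioner scales feature columns to unit variance (without centering, so
nonnegativity is preserved) before clustering; otherwise the physical-unit
columns dominate all distances.

## Baseline ensemble

Eight partitioners behind one contract (hard labels in [0, k), deterministic
given the seed): K-means, Gaussian mixture (full covariance, hardened by
posterior argmax), Ward hierarchical, spectral (Gaussian affinity with
median-distance bandwidth), DBSCAN, OPTICS, fuzzy C-means (fuzziness m = 2,
hardened by maximum membership) and a 1×k self-organizing map (online,
exponentially decaying learning rate and Gaussian neighborhood).  Fuzzy
C-means and the SOM are small native implementations; the rest wrap
scikit-learn.  DBSCAN/OPTICS do not take k: eps is scanned over a geometric
grid of pairwise-distance quantiles (MinPts = 5) until k non-noise clusters
appear; noise points join the nearest cluster centroid, surplus clusters are
merged into the k largest, missing ones are created by splitting the largest
cluster with seeded 2-means.  On 10σ-separated blobs all eight repaired
methods recover the ground truth exactly (tested).

## Consensus

Each member partition induces a binary connectivity matrix; their mean is
the consensus matrix CM̃ with entries on {0, 1/T, …, 1} and dispersion
ΔCM² = (1/T) Σₜ Σᵢⱼ (CMᵢⱼ(bᵗ) − CM̃ᵢⱼ)², zero iff the members agree as
co-associations.

**MNMF solver.**  min_{N,L≥0} ‖CM̃ − N L Nᵀ‖² by alternating multiplicative
updates.  The L step multiplies by (Nᵀ CM̃ N) ⊘ (NᵀN L NᵀN) — the exact
multiplicative rule for the quadratic subproblem.  The N step multiplies by
the ratio given by the sign split of the exact gradient,
(CM̃ N (L+Lᵀ)) ⊘ (N L NᵀN Lᵀ + N Lᵀ NᵀN L), whose fixed points are the KKT
points; the looser surrogate denominator N Nᵀ CM̃ N L sometimes quoted for
this scheme coincides with it only under the derivation's own working
assumptions (CM̃ = N L Nᵀ, near-orthogonal N) and is not monotone in
practice, whereas the gradient-consistent form shows no objective increase
above 1e−9 per step across all tested seeds.  L is not constrained to be
diagonal.  Safeguards: denominator floor 1e−12; convergence at relative
objective change < 1e−7 or 500 iterations; CM̃ is internally divided by its
mean diagonal (a no-op for co-association matrices), which makes the entire
trajectory — and hence the hardened partition — exactly invariant to
positive rescaling of the input.

**Hardening and restarts.**  `harden` is the row-wise argmax of N (ties to
the lowest column; empty clusters repaired by the weakest-margin instance).
The solver path runs 5 restarts cycling three initializations — absolute
leading eigenvectors of CM̃ (an NNDSVD-style seed), Uniform(0.1, 1.1), and
random hard indicators plus a small offset — because identically
distributed random inits tend to fall into the same basin.  Each restart
yields two candidates (argmax, and k-means on the normalized rows of
N(L+Lᵀ)/2 — the factor rows are the instances' consensus-centroid
coordinates), each polished by *consensus reassignment*: coordinate descent
on ‖CM̃ − NNᵀ‖² over hard labels, i.e. each instance moves to the cluster
maximizing its summed co-association penalized by cluster size, until
stable.  The candidate with the smallest hard-partition residual wins.  On
small ensembles (n ≤ 8) this matches the exhaustively enumerated optimum in
≥ 95 % of cases (tested); plain argmax alone reaches only ~75–85 %.

**Comparison solvers.**  CSPA: average-linkage agglomeration on 1 − CM̃ cut
at k.  MCLA: member clusters become hyperedges (binary indicator columns,
canonically sorted so all hyperedge solvers are invariant to member order
and relabeling); hyperedges are grouped into k meta-clusters by spectral
partitioning of their Jaccard-similarity graph, collapsed by averaging, and
each instance joins the meta-cluster of strongest participation.  HBGF:
spectral co-clustering of the instance × cluster bipartite incidence (degree
normalization, k leading singular-vector pairs, joint k-means).  HGPA is
approximate ("hgpa-approx" in outputs): star-expansion spectral embedding
with hyperedges down-weighted by size, followed by balance-constrained local
moves minimizing the number of broken hyperedges (minimum part size
⌊n/2k⌋); the CSPA solution is used as an additional start when it meets the
balance floor, so the returned cut never exceeds CSPA's in that regime.  All
ties break toward the lowest index; every solver is deterministic given the
ensemble.

**ANMI.**  Mean over members of NMI(candidate, member), computed from the
contingency table with natural logs and arithmetic-mean normalization
2 I/(H₁+H₂); a zero-entropy side defines NMI = 0.

## Severity labeling and evaluation

Trunk displacement per trial: per trunk channel, subtract the per-axis mean
of the first 10 samples (the pre-movement baseline), then TDₜ =
|TDx|+|TDy|+|TDz|.  The literal signed sum is available (`signed_sum`) but
cancels for oscillatory sway, so the absolute convention is the default;
severity ranking needs a nonnegative displacement magnitude.  Camera
profile: the four trunk markers' series are averaged.  Clusters are ranked
by mean member displacement — lowest = least severe; ties rank the lower
cluster id as less severe.  Ground truth: severe iff FMA-UE < 29; for k = 3
the default bands are [0, 29) severe, [29, 43) mild, [43, 66] non-severe
(half-open, configurable; the mild/non-severe edge follows the standard FMA
banding since only the severe edge is pinned down clinically).  Each trial
inherits its subject's class.  Metrics: confusion matrix plus class-support-
weighted precision/recall/F1 and accuracy; weighted recall equals accuracy
identically (property-tested), and classes never predicted score 0.

## Exhaustive combination search

All method subsets of size ≥ 2 (247 for 8 methods) are scored per run
through the full consensus + labeling + F-score path; baselines and
factorization are re-randomized each run from a fresh run seed.  The top-m
(default 10) subsets per run are tallied over n_runs (default 100) and the
most frequent subset wins, ties broken by higher mean F-score.  Singleton
subsets are excluded — the consensus of one partition is that partition.

## Synthetic cohorts

The generator produces what the pipeline assumes about real reaching data:
4 grasping tasks × 3 repetitions per subject; limb channels follow a
minimum-jerk reach–hold–return profile (10t³−15t⁴+6t⁵); the trunk adds a
forward-lean bump (sin² window starting after the baseline window) whose
peak is Normal(class mean, 10 % CV) truncated at 0.  Severity affects three
clinically documented aspects of the movement: trunk-lean amplitude
(defaults 5 / 20 / 40 mm for non-severe / mild / severe), temporal jitter —
jerkiness — (0.02 / 0.08 / 0.15 as a low-frequency time-warp fraction), and
movement slowness and reduced range (reach time × 1.0 / 1.3 / 1.6, reach
amplitude 300 / 240 / 180 mm).  Isotropic Gaussian position noise
(default σ = 1 mm) is added everywhere.  FMA-UE scores are drawn uniformly
inside each class's band, so generated ground truth is consistent with the
severity thresholds by construction.  Trials last 3 s at the device rate.

What this does **not** emulate: marker occlusion and gap filling, soft-
tissue artifact, sensor-fusion drift, task-specific movement differences,
orientation (quaternion) channels, inter-subject anatomical variation, and
healthy-control asymmetries.  Passing the end-to-end tests therefore shows
that the pipeline recovers severity when the assumed class structure is
present at realistic amplitudes and noise — not that it will reach the same
accuracy on any particular clinical recording.

A separate toy-ensemble generator plants a partition and re-labels each
instance uniformly with probability 1 − agreement, giving closed-form
expectations for member corruption; it drives the consensus-solver tests.

## Problem sizes in the verification suite

The test suite and `scripts/acceptance.py` use: 200 random ensembles with
n ≤ 8 instances for the enumeration-oracle comparison (31 / 3280
bipartitions/tripartitions enumerated per case); 50 × 500 iterations for
monotonicity; 100 unanimous ensembles with n up to 200 for unanimity
recovery; 10 cohorts of 40 subjects (480 trials each) for end-to-end
accuracy; 20 repeated searches of 20 runs for the search behavior.  These
sizes keep the whole suite in the minutes range on one CPU while leaving
each property statistically meaningful.

## Known limitations

- The MNMF consensus is a local method; the enumeration-oracle match rate
  is ~95–98 %, not 100 %, and degrades if restarts are reduced.
- HGPA is a spectral approximation with local refinement, not an exact
  hypergraph min-cut; it is labeled "hgpa-approx" accordingly.
- Density-based members (DBSCAN/OPTICS) are forced to exactly k clusters by
  repair; on data without density structure their contribution is close to
  a nearest-centroid quantization.
- The evaluation assumes every subject's trials share one severity class;
  within-subject variability across tasks is not modeled.
- Native Xsens MVNX / Vicon C3D parsing is out of scope; data enter through
  the documented CSV/HDF5 schema.
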