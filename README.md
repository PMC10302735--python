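# psamnmf — post-stroke severity assessment by consensus clustering

`psamnmf` assesses upper-limb motor impairment after stroke from motion
recordings alone.  It is aimed at movement-analysis researchers who have
per-trial 3-D position time series — from a wearable IMU suit (5 upper-limb
segments at 60 Hz, sternum sensor T8) or a marker-based camera system
(9 feature markers + 4 trunk markers at 200 Hz) — and clinician-scored
Fugl-Meyer Assessment (FMA-UE, 0–66) scores to validate against.

## Method

For each trial the pipeline extracts frequency-domain kinematic features:
zero-phase 2nd-order Butterworth low-pass (10 Hz wearable / 20 Hz camera),
linear acceleration by central second differences, the orientation-free
magnitude √(X²+Y²+Z²), and banded magnitude spectra of position and
acceleration.  Eight baseline partitioners (fuzzy C-means, K-means, SOM,
Gaussian mixture, DBSCAN, Ward hierarchical, spectral, OPTICS) cluster the
trials into k ∈ {2, 3} groups.  The ensemble is fused through its
co-association matrix

    CM̃ = (1/T) Σₜ CM(bᵗ),   CMᵢⱼ(bᵗ) = 1 iff i, j share a cluster in bᵗ,

which a modified symmetric nonnegative matrix factorization solves for the
consensus partition:

    min_{N,L ≥ 0} ‖CM̃ − N L Nᵀ‖²_F

by alternating multiplicative updates (best of several restarts, hardened by
row-wise argmax plus consensus reassignment).  Four classical hypergraph
consensus solvers (CSPA, MCLA, HBGF, an approximate HGPA) are provided for
comparison, with averaged normalized mutual information (ANMI) as the
model-selection diagnostic.  Clusters are then labeled by compensatory
**trunk displacement** — per-step |TDx|+|TDy|+|TDz| of the trunk sensor
relative to a 10-sample baseline; the cluster with the largest mean
displacement is the most severe — and scored against FMA-UE-derived classes
(severe iff FMA-UE < 29; for k = 3, [29, 43) is mild).  An exhaustive search
over all 247 method subsets, repeated over re-randomized runs, selects the
combination that most often reaches the top-10 by F-score.

A synthetic-cohort generator emulates both device profiles (4 grasping
tasks × 3 repetitions per subject, minimum-jerk reaches, severity-dependent
trunk lean / slowness / jerkiness, FMA scores consistent with the class
bands), so the full pipeline is testable without any data download.

## Worked example

```python
from psamnmf import CohortSpec, PipelineConfig, generate_cohort, run_pipeline

records = generate_cohort(CohortSpec(n_subjects=40, seed=7))
result = run_pipeline(records, PipelineConfig(k_clusters=2), seed=7)
print(f"accuracy {result.metrics.accuracy:.3f}  f-score {result.metrics.f_score:.3f}")
print("cluster mean trunk displacement (mm):", result.labeling.cluster_means)
```

prints

```
accuracy 0.965  f-score 0.964
cluster mean trunk displacement (mm): {0: 15.41, 1: 22.86}
```

480 trials (40 subjects × 4 tasks × 3 repetitions) are clustered into two
groups; the cluster with the larger mean trunk displacement (≈ 23 mm — the
reported means include the sensor-noise and passive-drift floor common to
both classes) is labeled severe and the other non-severe, matching the
FMA-derived ground truth on 96.5 % of trials.  Exact values vary with the
seed.

The same steps are available from a shell:

```sh
psamnmf simulate --n-subjects 40 --seed 7 --out cohort/
psamnmf evaluate --cohort cohort/ --seed 7
psamnmf search --cohort cohort/ --out report.json   # exhaustive subset search
```

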