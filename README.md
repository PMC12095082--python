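# bmiphase

Timing-based clustering of childhood BMI trajectories.

Children traverse the characteristic BMI course — infancy peak near 9
months, decline to the adiposity-rebound minimum, pubertal rise — on
different schedules. `bmiphase` groups children by that schedule
(*maturational age*) rather than by BMI level: sparse height/weight visit
records are screened and spline-interpolated onto a standard 34-point age
grid (3 months–16 years), pairwise **elastic phase distances** are computed
between the BMI curves, and **k-medoids (PAM)** with average-silhouette
model selection partitions the cohort into timing types. Per-trajectory
timing features (age at infancy peak, age at adiposity rebound, infancy and
childhood slopes, peak counts) summarize the clusters.

The phase distance between curves f₁, f₂ is computed in the square-root
slope function (SRSF) framework, q = sign(f′)√|f′|: a dynamic program finds
the boundary-fixed monotone warp γ minimizing ‖q₁ − (q₂∘γ)√γ′‖², and

    d(f₁, f₂) = arccos( ∫₀¹ √γ′(t) dt )  ∈  [0, π/2]

is the arc-length on the unit sphere between the SRSF of γ and that of the
identity warp. d is invariant to affine amplitude changes — it measures
timing only.

Because cohort data of this kind are access-restricted, the package ships a
synthetic-cohort generator (`bmiphase.cohort_synth`) that emulates the data
structure — dense infancy/sparser school-age visit schedules, three latent
timing types including a mid-childhood-bump type, individual random time
warps, measurement noise — with known ground-truth labels and warps, so the
whole pipeline is testable end to end. See `docs/methods.md` for the model,
parameter defaults, and what the synthetic validation does and does not
establish.

Intended users: epidemiologists and biostatisticians analysing longitudinal
growth records, and methodologists working on elastic functional data
analysis of sparse trajectories.

## Worked example

```bash
bmiphase simulate --seed 1 --out results
bmiphase run-all --input results/measurements.csv --seed 1 --out results
```

or equivalently in Python:

```python
import bmiphase as bp

cfg = bp.SimConfig(n_per_cluster=20, sex_mode="female", seed=1)
cohort = bp.simulate_cohort(cfg)                      # 60 children, 3 types
bmi, report, qc = bp.preprocess_cohort(cohort.records)
D = bp.pairwise_distance_matrix(bmi)                  # 60x60, radians
assignment, table = bp.select_k(D, 2, 10)
print(assignment.k, assignment.avg_silhouette)
```

The pipeline prints per stratum the selected number of clusters, the
average silhouette width and the cluster sizes; a run of the above (seed 1)
reports

```
synthetic run (seed 1): kept 60/60, k*=3, sizes [20, 20, 20], avg silhouette 0.624
cluster 1 median age at first peak: 0.50 y (n=20)
```

i.e. all 60 simulated children pass the selection rules, and
silhouette-based model selection recovers the three planted timing types at
their exact sizes — on the synthetic defaults the separation between timing
types is deliberately large relative to phase noise, hence the high
silhouette. The grid quantizes infancy-peak ages to 0.25/0.5/0.75/1.0 y,
and spline smoothing of the sparse infancy visits rounds the peak slightly
earlier, so the detected median lands on the 0.5 y grid point (the
noise-free template itself peaks at 0.75 y — asserted in the tests).
Output tables (`labels_*.csv`, `distances_*.csv`, `silhouette_by_k_*.csv`,
`cluster_summary_*.csv`, `peak_counts_*.csv`, `aligned_means_*.csv`, a run
manifest) are written to the output directory. `bmiphase agreement a.csv
b.csv` compares two labelings (e.g. B-spline vs linear-interpolation
preprocessing) by optimal label matching and adjusted Rand index.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a live run of the package: the size of the standard age
grid built from its construction rule, the sample-total and largest-cluster
share implied by the published cluster sizes, and then executes the full
synthetic pipeline (simulate → selection/QC → spline BMI grid → pairwise
phase distances → PAM with silhouette selection) printing the selected k,
cluster sizes and feature summaries. Results are written as JSON to
`--out`.
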