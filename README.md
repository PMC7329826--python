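# neurodyad

Dyadic analysis of inter-subject resting-state connectome similarity in
school social networks.

## The problem

Do friends have more similar resting-state functional connectomes than
students who are socially distant ("neural homophily at rest")?  Answering
this requires joining two very different data modalities per school-year
cohort:

* a **sociometric roster**: every student rates, on a five-point Likert
  scale (1 = "None" … 5 = "Most"), how much time they spend with each peer;
  ratings thresholded at 4 ("more than some") and kept when reciprocated
  define a friendship graph, whose geodesics give dyadic **social
  distance** d_ij and whose Louvain modules give **community affiliation**;
* per-subject **parcellated BOLD time series** (T×P): Pearson correlation
  across parcels gives each subject a P×P connectome; after Fisher
  transformation (z = atanh r, diagonal removed) the similarity of a dyad
  is the Pearson correlation of the two vectorised upper triangles,
  standardised within cohort.

Because every student appears in many dyads, similarity outcomes are not
independent and OLS inflates type-I error.  The core model is a linear
mixed-effects model with **crossed random member effects**,

```
y_ij = β0 + β1·x_ij + u_i + u_j + ε_ij,   u ~ N(0, σ²_u),  ε ~ N(0, σ²_ε)
```

where x_ij is social distance (or community match) and the two members of
an unordered dyad share a single random-intercept variance.  The fit is
REML, profiled to a one-dimensional optimisation over λ = σ²_u/σ²_ε via an
eigendecomposition of the dyad–member incidence Gram matrix.  Per-cohort
slopes are pooled with a random-effects meta-analysis (REML τ²,
inverse-variance weights 1/(SE² + τ²)).

The package also provides signed graph metrics of each connectome (nodal
strength, nodal diversity, signed modularity Q*) with dyadic similarity
outcomes, an elastic-net model predicting social distance from edgewise
similarity features with subject-grouped nested cross-validation and a
permutation test, and a **synthetic-cohort generator** that plants a
controllable homophily effect θ so that every stage has a
parameter-recovery and calibration test.

## Worked example

Simulate a three-cohort study (23, 17 and 28 students; 40 parcels; planted
homophily θ = 0.3) and run the full pipeline:

```python
import dataclasses, json
from neurodyad.workbench import simulate_study, run_pipeline

cfg = simulate_study("demo_study", sizes=(23, 17, 28), group_counts=(4, 3, 4),
                     theta=0.3, n_parcels=40, seed=11)
cfg = dataclasses.replace(cfg, scopes=("whole-brain", "DMN"),
                          predictors=("distance", "community"))
manifest = run_pipeline(cfg)          # 12 LME fits, 4 meta-analyses
meta = json.load(open("demo_study/results/meta_whole-brain_distance.json"))
```

This prints/stores, for the whole-brain × distance analysis:

```
pooled beta = -0.918   95% CI [-1.206, -0.630]   tau2 = 0.0618   p = 3.9e-10
cohort1 beta = -1.207  SE = 0.058  sigma2_u = 0.107  sigma2_eps = 0.239
```

The pooled slope is negative — connectome similarity falls with social
distance — and its confidence interval excludes zero, exactly what a
planted θ = 0.3 should produce.  Rerunning with `theta=0` gives a pooled
CI that covers zero.  (Small synthetic cohorts can disconnect; unreachable
dyads are kept in the table with an undefined distance and excluded from
distance models with a logged count.)

The same pipeline is scriptable from a shell:

```bash
neurodyad simulate --out demo_study --seed 11 --theta 0.3
neurodyad run --config demo_study/study.yaml
neurodyad power --theta 0.0,0.5 --replicates 200 --out power.csv
```

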