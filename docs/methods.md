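# Methods

## The dyadic model

The unit of analysis is the unordered pair (dyad) of students within one
school-year cohort.  For dyad (i, j) the outcome y_ij is the similarity of
the two students' resting-state connectomes (or of a graph-metric summary
of them), standardised within cohort and analysis scope; the predictor
x_ij is either the social distance d_ij (entered as a continuous numeric
variable — it takes small integer values 1–4 in connected school networks)
or the binary community match.  Because each student belongs to n−1 dyads,
outcomes sharing a member are correlated; the model is

y_ij = β0 + β1·x_ij (+ covariates) + u_i + u_j + ε_ij,
u_i ~ N(0, σ²_u) i.i.d., ε_ij ~ N(0, σ²_ε),

with a **single** member variance σ²_u shared by both members: dyads are
unordered, so separate variances for "member 1" and "member 2" are not
identifiable.  Assumptions: member effects additive and Gaussian,
homoscedastic residuals, and exchangeability of the two members — the
implementation is invariant (to 1e−10) under relabelling (i, j)→(j, i),
which the tests assert.

### Estimation

Writing Z for the m×n dyad–member incidence matrix (two ones per row), the
marginal covariance is V = σ²_ε (I + λ Z Zᵀ) with λ = σ²_u/σ²_ε.  The
restricted likelihood is profiled: one eigendecomposition of Z Zᵀ
diagonalises V for every λ, σ²_ε has a closed form given λ, and REML
reduces to a bounded scalar minimisation over log λ ∈ [log 1e−8, log 1e5]
(scipy bounded Brent, xatol 1e−10).  The λ = 0 boundary is evaluated
explicitly; when it is at least as good as the interior optimum the fit is
reported as singular with σ²_u pinned at exactly 0, in which case the fixed
effects coincide with OLS (asserted to 1e−6).  REML rather than ML because
the variance components are estimated from a few dozen subjects.

Inference on coefficients uses a normal approximation by default — the
dyad counts in view are in the hundreds (253/136/378) — with a
residual-degrees-of-freedom t reference available via
`df_method="residual"` for small tables.  A full Satterthwaite
approximation was considered and not implemented: for these sample sizes
it differs negligibly from the normal reference, and the residual-df
option brackets it from the conservative side.  Covariates (ethnicity
match, boarding match, head motion) enter as fixed effects; match
variables are coded 1 = same, and motion enters as the dyad mean and
absolute difference so the design respects member exchangeability.
Unreachable dyads (infinite geodesic) stay in the dyad table with an
undefined distance and are excluded from distance models with a logged
count; community models use all dyads.

### Meta-analysis

Per-cohort slopes β̂_k with squared standard errors v_k are pooled under
the random-effects model β̂_k ~ N(β̄, v_k + τ²).  τ² is estimated by
restricted maximum likelihood (bounded scalar minimisation, boundary at 0
checked explicitly; agreement with a grid-search maximiser to 1e−6 and
with R metafor to ~1e−5 is asserted in tests); DerSimonian–Laird and
fixed-effect pooling are available as options — DL is the documented
fallback if the k = 3 restricted likelihood is too flat, though in
practice the bounded optimiser has not needed it.  Weights are
1/(v_k + τ²), the pooled standard error is (Σ weights)^−1/2 and the CI is
Wald.  Scopes (whole-brain, DMN, salience, lFPN, rFPN) are tested
separately without multiplicity correction, mirroring per-network
reporting; `adjust_pvalues` provides a Bonferroni switch over the scopes
actually tested.

## The synthetic cohort generator

The generator is the package's study-conditions definition: everything the
calibration and power results claim is relative to it.

**Roster.**  Students are split into `n_groups` near-equal planted groups.
Each directed rating is drawn independently (reciprocity is emergent): a
rating is tie-level (5) with probability `p_in` within groups and `p_out`
between, otherwise 1; each rating is then jittered ±1 with probability
`likert_noise` (default 0.1) and clipped to [1, 5], populating the middle
response options.  Defaults p_in = 0.9, p_out = 0.2 were chosen so that
cohorts of 17–28 students with 3–4 groups produce connected reciprocal
graphs with density ≈ 0.2, reciprocity ≈ 0.6 and diameter ≤ 4 — the
regime school-year friendship networks occupy.  Smaller p_out makes the
reciprocal graph fragment into group components (cross-group reciprocal
ties appear with probability p_out²), which small cohorts occasionally do
anyway; fragmentations are handled by the unreachable-dyad rule, not
hidden.

**Connectomes.**  Random correlation templates are built from rank-5
factor loadings (Σ = AAᵀ + D rescaled to unit diagonal), giving low-rank
structure resembling empirical connectomes.  Subject s in group g receives
R_s = nearest_correlation(η·C_global + θ·C_g + (1−η−θ)·E_s) with
subject-unique noise E_s.  θ ("homophily effect") is the weight of the
shared-group template and η (default 0.3) the cohort-global weight; the
convex mixture of correlation matrices is itself a correlation matrix, so
the Higham projection acts as a cheap validity guard (fixed point on valid
input).  θ = 0 is the null condition.

**BOLD.**  T×P zero-mean Gaussian series with the target correlation via
an eigenfactorisation (valid for PSD-singular matrices), T = 250 by
default (≈ a 10-minute scan at ordinary repetition times); samples are
i.i.d. in time — only large-sample correlation stability matters
downstream, so no autocorrelation, haemodynamics, drift or motion is
simulated.  Covariates are synthetic demographics (ethnicity proportions
typical of a UK single-school cohort, ~1/3 boarders) and log-normal motion
summaries.

**Seeding.**  One root seed; every stream (roster, templates, per-subject
noise, BOLD, covariates) is a labelled `SeedSequence` child, so adding a
subject or cohort never perturbs existing draws, and identical seeds give
bit-identical outputs.

**What passing tests do and do not show.**  The generator realises the
modelled data-generating process (Gaussian member effects, exchangeable
dyads, independent-in-time BOLD).  Calibration and recovery results
therefore validate the estimation machinery, not robustness to
autocorrelated scanner noise, non-Gaussian social structure, or rating
biases in real rosters.

## Graph machinery

* Social Louvain: igraph multi-level optimisation, resolution γ = 1,
  best of 100 seeded restarts by Q, ties broken by first occurrence in
  seeded order.  Deterministic given the seed.
* Eigenvector centrality: principal eigenvector of the symmetric adjacency
  by dense eigendecomposition, max-normalised to 1 (ARPACK's random starts
  would break byte-reproducibility of pipeline reruns).
* Signed brain modularity: the asymmetric objective
  Q* = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻ (positive weights dominate; the symmetric
  variant is an option) optimised by greedy single-node moves plus greedy
  community merges from singleton starts, restarted under a seeded RNG.
  Partition-invariant diagonal null-model terms are added back so that
  with no negative weights Q* equals ordinary weighted modularity (checked
  against igraph).  On random 6-node matrices the optimiser attains the
  exhaustive-search optimum; at P = 272 it is a heuristic like any Louvain.
* Nodal diversity uses each subject's own signed-modularity partition, and
  dyadic strength/diversity similarity correlates the concatenated
  positive+negative vectors (sign-separated variants are options).

## Elastic net and permutation inference

Features are per-edge similarities, by default −|z_i(p,q) − z_j(p,q)|
(edge-product and edge-mean variants are options).  Cross-validation is
grouped by subject at both levels: any dyad touching a held-out subject
leaves the training set, because dyads sharing a member are dependent and
plain k-fold leaks.  A dyad touching two different folds' subjects is
predicted in each and its out-of-fold predictions averaged.
Standardisation statistics come from training rows only, per fold, and are
hashed so reruns can be audited for leakage.  The λ path is log-spaced
over 4 decades down from λ_max (the smallest λ zeroing all coefficients);
the default mixing grid is {0.1, 0.25, 0.5, 0.75, 1.0}.

The permutation test relabels **subject identities**
(y′_(i,j) = y_(π(i),π(j))) rather than shuffling targets across dyads.
Social distance has strong subject-level structure — a peripheral student
is distant from everyone — and dyad-wise shuffling destroys it, producing
a permutation distribution that is too narrow and shifted relative to the
observed statistic: measured on null cohorts, dyad-wise shuffling gave
p ≤ 0.05 in 5/20 seeds where the nominal rate is 1/20, while subject
relabelling is calibrated (19/20).  Relabelling preserves the dyadic
dependence and the subject-grouped folds; dyads whose relabelled
counterpart was unreachable are dropped for that draw, mirroring the
observed analysis.  Dyad-wise shuffling remains available
(`scheme="dyads"`) for comparison.

## Numerical choices

* Fisher transform clip: r is clipped to ±(1 − 1e−7) before atanh
  (synthetic duplicates can produce r = ±1); diagonal removed.
* Upper-triangle vectorisation: row-major over p < q — correlation is
  order-invariant but the fixed order makes intermediate files comparable.
* Standardisation of the similarity outcome: per cohort and per scope
  (sample SD, ddof = 1); zero variance is a loud error, never a silent NaN.
* nearest_correlation: Higham alternating projections with Dykstra
  correction, relative Frobenius tolerance 1e−8, max 500 iterations;
  non-convergence raises with the iteration count.
* Direct-tie proximity between two scanned students aggregates the two
  directed ratings by their mean (min and max exposed as options).
* CSV floats at 17 significant digits; loaders use round-trip float
  parsing where byte-level reproducibility is asserted.

## Problem sizes used by the test-suite studies

Calibration and recovery studies are run at desk scale: 40 parcels
(T = 250) instead of the 272-parcel study parcellation, 200 replicates for
the type-I and slope-recovery checks, 20 replicate cohorts × 19
permutations (reduced hyperparameter grid: mixing 0.5, 20-λ path, 4 outer /
2 inner folds) for the prediction null, and 150/60 replicates in the
acceptance script's type-I/power entries.  Parcel count affects only the
feature dimension, not the dyadic dependence structure the calibration
targets.

## Known limitations

* The normal-approximation test on β1 is mildly anti-conservative in
  principle for very small cohorts; measured type-I over the full pipeline
  at (23, 17, 28) is ≈ 0.03–0.07, inside the nominal band.
* With k = 3 cohorts, τ² is weakly identified; pooled CIs ignore τ²
  estimation uncertainty (as does the standard Wald random-effects CI).
* The signed-modularity optimiser is a restart heuristic; global optima
  are verified only exhaustively at small P.
* The generator plants homophily through shared correlation templates;
  real neural homophily, if any, need not be low-rank or
  template-structured.
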