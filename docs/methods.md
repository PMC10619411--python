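# Methods

`memnet` analyses weighted structural brain connectomes: it builds
per-subject connectivity matrices from probabilistic-tractography streamline
tallies, computes whole-brain weighted graph metrics, tests
covariate-adjusted sex differences, and quantifies how much of the
sex→episodic-memory association is mediated by weighted transitivity.  This
note documents the models, the synthetic cohort generator, the numerical
choices, and what the validation suite does and does not establish.

## Connectome construction

Each of R parcellated brain regions (default R = 82: 68 cortical
Desikan-Killiany regions plus 14 subcortical structures; R = 162 with the
finer Destrieux parcellation) is a node.  Probabilistic tractography yields
directed streamline counts `N[i, j]` and per-seed totals `waytotal[i]`
(default 5000 streamlines per seed voxel in the emulated acquisition).  The
directed connection probability is `P[i, j] = N[i, j] / waytotal[i]` and the
undirected edge weight is the average of the two directions,
`C[i, j] = (P[i, j] + P[j, i]) / 2`, giving a symmetric matrix with zero
diagonal and weights in [0, 1].

Spurious connections are removed with a population-level criterion so every
subject keeps the same edge set: edge (i, j) is excluded from all subjects
when `mean_s(C_ij) + k_sd * sd_s(C_ij) < theta`, with `theta = 0.01` and
`k_sd = 2` by default.  Two readings were fixed deliberately:

* the across-subject standard deviation is the *sample* (n−1) SD, the
  default of the statistical environments this criterion is usually
  computed in;
* "below the threshold" is read strictly, so an edge sitting exactly at
  `theta` is retained.

## Graph metrics

All metrics are computed from first principles on the dense weight matrix;
graph libraries appear only as oracles in the test suite.

* **Strength** `s_i = Σ_j C_ij`; reported globally as the mean over nodes so
  the scale is comparable between the 82- and 162-node parcellations.
* **Shortest paths** use the edge length `l_ij = 1/C_ij` — the standard
  mapping in the weighted-network toolbox literature (strong connections are
  short).  Distances come from Dijkstra's algorithm per source; unreachable
  pairs are `inf`.
* **Characteristic path length** is the mean distance over *finite* ordered
  pairs; a disconnected matrix sets a `connected = False` flag instead of
  erroring, because population masking can in principle disconnect a graph.
* **Global efficiency** is the mean of `1/d_ij` with `1/inf = 0`.
* **Weighted transitivity** uses the geometric-mean (Onnela-style) triangle
  intensity with max-weight normalization: with `w = C / max(C)`,
  `t_i = ½ Σ_{j,h} (w_ij w_ih w_jh)^{1/3}`, local clustering
  `C_i = 2 t_i / (k_i (k_i − 1))` (0 when the degree `k_i < 2`), and global
  `T = Σ 2 t_i / Σ k_i (k_i − 1)`.  Several weighted clustering variants
  exist (e.g. Barrat's arithmetic-mean form); the choice is isolated inside
  `weighted_clustering` so an alternative can be swapped in one place.

## Statistical models

Sex is coded female = 0 / male = 1 everywhere, so positive d means
male-higher.  F tests use Type-II sums of squares (the convention of the
`car` package family): the test of a term compares the model with every term
not containing it against that model plus the term, with the full-model
residual mean square in the denominator.

Cohen's d is reconstructed from the model t value,
`d = t (n1 + n2) / (√(n1 n2) √df)`, rather than from raw means and SDs, so
d inherits every covariate adjustment in the model.  ICV (intracranial
volume) is the critical covariate: it is strongly sex-associated, and all
sex-difference models include it together with age.  Models involving
memory additionally include the recall-room batch covariate.

The valence × sex memory model is a random-intercept linear mixed model on
the long (subject × valence) table, estimated by profiled REML: for a fixed
variance ratio γ = σ²_subject/σ²_resid the GLS fit has closed form after
per-subject whitening (`v → v − c·mean_subject(v)` with
`c = 1 − (1+Jγ)^{-1/2}` for J observations per subject), and the REML
criterion is minimized over γ by bounded 1-D search with the γ = 0 boundary
checked explicitly.  Denominator degrees of freedom follow the inner/outer
(between/within-subject) convention: between-subject terms are tested
against `n_subjects − rank(between design)` and within-subject terms
against `n_obs − n_subjects − rank(within columns)`.  For the default
layout (sex, age, batch between; valence and sex × valence within; n = 655)
this gives F(1, 651) and F(2, 1306).  Satterthwaite or Kenward-Roger
corrections are out of scope.

The node-level scan refits `clustering_i ~ sex + age + ICV` per node and
Bonferroni-corrects at `0.05 / R`.  Whole-brain results use the analysis
threshold α = 0.0125 (0.05 corrected for the four connectome measures).

## Mediation

Mediation of sex → recall by weighted transitivity removes age, batch and
ICV from all three variables once, by least-squares residualization on the
full sample, then standardizes, so the paths live on the correlation scale:
a (sex→mediator, a point-biserial-type correlation), b (mediator→outcome
given sex), c (total), c′ (direct).  The indirect effect is a·b, the
mediation strength (a·b)/c′ (numerically unstable and flagged when
|c′| < 0.01).

Inference uses the bias-corrected and accelerated bootstrap (default
B = 10 000 draws): subjects are resampled with replacement, paths are
recomputed per draw with per-draw standardization, z₀ = Φ⁻¹ of the fraction
of bootstrap statistics below the point estimate (clamped with a warning at
0 or 1), and the acceleration comes from the jackknife skewness formula
(leave-one-out statistics are computed in closed form from running sums).
Significance at levels 95/99/99.5% means the indirect-effect interval
excludes zero.  Re-residualizing inside every draw is available as a switch
(`residualize_per_draw`); the default residualizes once, matching a
residual-based analysis pipeline.

## Synthetic cohort generator

The generator exists to validate the pipeline by parameter recovery.  It
emulates a cohort of n = 655 healthy young adults (60% female; ages 18–35,
means ≈ 22.6/23.3 years by sex; ICV means 15.14/17.64 with the printed
within-group spreads rescaled ≈ 1% so the sex-ICV point-biserial correlation
is exactly the configured −0.69; hormonal-contraceptive and menstrual-cycle
labels at their observed frequencies among females, not-applicable for
males; a recall-room batch with a configurable additive benefit of the
quieter room, default +0.4 pictures per valence).

**Networks.** A block-modular template `W0` (7 modules, within/between
weight levels 0.5/0.10, log-normal edge jitter sd 0.15) is paired with a
triangle-enriched companion `T0 = sqrt(W0 ∘ (W0·W0))` rescaled to max 1 —
the elementwise geometric mean of the template and its two-step walk
(triangle-support) matrix, which smooths the weight profile and up-weights
edges embedded in strong triangles.  A subject's expected network is
`mix(α_i) = (1−α_i) W0 + α_i T0` clipped to [0, 1]; weighted transitivity
is strictly increasing in the dial α (asserted numerically), so a single
latent scalar carries the clustering effects:

    α_i = 0.4 + β_sex·male_i + β_age·z(age_i) + ε_i,  ε ~ N(0, 0.015).

Multiplicative log-normal edge noise (sd 0.10) and binomial streamline
sampling `N_ij ~ Binomial(waytotal, W_i[i,j])` per ordered pair supply
measurement noise.  Sex and age act *only* through the global dial — the
paper-level effect this emulates is a whole-brain transitivity difference,
and no node-level localization is modeled.  Consequently the node scan on
synthetic cohorts flags essentially *all* nodes at full power; the scan's
machinery is validated separately with injected node-specific effects.

**Memory.** Recall counts per valence are Binomial(24, p) with a
logit-linear predictor: a valence-specific baseline (expected counts
8.2/5.6/8.0 of 24 for negative/neutral/positive — negative and positive
better recalled than neutral, in the ~25–35% recall range typical of free
recall of 72 pictures), a mean-zero female-advantage interaction pattern
largest for positive pictures (−0.05/−0.20/+0.25 counts), the batch
benefit, a direct sex term, a standardized-latent-transitivity term, and a
subject random intercept (sd 0.35 logits) that induces the within-subject
correlation the mixed model estimates.

**Calibration.** Targets are effect sizes: the ICV-adjusted sex difference
in transitivity d = 0.42 (male-higher), age-transitivity r = −0.23,
transitivity-memory partial r = −0.12, and a residual direct sex→memory
effect c′ = −0.06 on the correlation scale (female advantage; this default
makes the implied total sex→memory effect d ≈ −0.17, a small effect).  The
implied indirect effect is a·b with `a = d√(pq)/√(1+d²pq)` and
`b = r_tm − a·c′`, ≈ −0.022 at the defaults.

The dial coefficients (β_sex, β_age) are solved in closed form from the
implied joint covariance of (T, sex, age, ICV).  Two quantities of that
covariance are estimated from a 1000-subject pilot: the *effective* dial
slope dT/dα — computed as a paired difference quotient with the same
edge-noise draw on both sides, because edge noise shrinks the transitivity
response by ~25% relative to the noiseless template slope — and the
measurement-noise variance (edge-noise and binomial components separately).
The memory coefficients (transitivity slope, direct sex term), which act
through the nonlinear logit link, are calibrated by secant iteration on
100 000-subject pilot simulations with common random numbers; pilots
simulate transitivity from its locally linear response rather than full
networks, which the recovery tests justify a posteriori.  Exact-zero targets
short-circuit to exactly-zero coefficients, and infeasible targets (dial
range escaping the template's monotone mixing region, non-convergent
secant) raise a `CalibrationError` carrying the iteration trace.

**What the generator does not emulate.** Absolute metric levels (template
transitivity ≈ 0.24, not the ~0.77 of real tractography connectomes at
these parameters), node-level anatomical localization of sex effects,
hormonal effects on networks (labels are carried as factors only), edge-set
sparsity (the default template leaves no edge below the population mask
threshold), and any item-level recall structure.  Passing recovery tests
therefore shows that the *estimators* are unbiased and correctly calibrated
under a realistic noise budget — not that real connectomes follow a
two-matrix mixture model.

## Validation suite and problem sizes

* Worked effect-size example: F = 27.11 with 264/391 and df 651 → d = 0.42
  (exact arithmetic).
* Type-I error: 5000 replicate null cohorts (sex effect switched off) at
  n = 64, R = 12, waytotal = 500 — sizes chosen so the run finishes in
  ~1.5 minutes; the rejection rate of the α = 0.0125 sex test is checked
  within 3 binomial MC SEs of nominal.
* Oracle equivalence: Dijkstra vs Floyd-Warshall and triangle vectorization
  vs exhaustive triple loops, 100 random graphs, agreement ≤ 1e-10.
* Parameter recovery: 50 replicate cohorts at the full study scale
  (n = 655, R = 82); the mean recovered d, age r, memory r, sex-ICV r and
  indirect effect must each sit within 2 MC SEs of the configured targets.
* BCa coverage: 200 replicates of a linear mediation model with known paths
  (a = 0.2, b = −0.11, c′ = −0.06), B = 2000, n = 400; 95% coverage within
  ±3 points.
* Mask arithmetic: the {0.001, 0.003} edge is excluded and a constant 0.01
  edge retained, exactly.

Independent implementations are used as oracles throughout the unit tests:
statsmodels (Type-II ANOVA, REML MixedLM), pingouin (partial correlations),
scipy (Floyd-Warshall, BCa bootstrap), plus brute-force enumeration and
normal-equation solvers.

## Numerical choices and degenerate inputs

Treatment (first-level-reference) coding for factors; rank-deficient
designs are rejected with the collinear columns named (pivoted QR).  A
perfectly fitted response (zero residual variance) reports F = 0 rather
than 0/0.  Partial correlations and residualization reject residuals whose
SD falls below 1e-10 of the variable's scale.  The REML search runs on
log γ in [e⁻¹², e⁸] with an explicit γ = 0 boundary comparison.  Bootstrap
draws are chunked (2000 at a time) to bound memory; the bootstrap, the
generator and every pipeline stage draw from seed-derived independent
substreams, so runs are bit-reproducible for a fixed seed and every output
directory records the seed in its manifest.

## Known limitations

Only the random-intercept mixed model is implemented (no random slopes);
denominator df follow a single within stratum, whereas some software
prints per-term within df; the mediation model has a single mediator and no
exposure-mediator interaction; real-data mode expects pre-built
connectivity matrices (tractography itself is upstream of this package).
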