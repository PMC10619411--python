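# memnet

Weighted structural connectome metrics and sex-difference mediation
analysis.

Females typically outperform males on episodic memory tasks, while
diffusion-imaging studies find sex differences in the structural wiring of
the brain.  `memnet` implements the full analysis chain needed to connect
the two in a cohort of healthy young adults: it turns probabilistic
tractography output into weighted brain networks, computes whole-brain
graph metrics, tests covariate-adjusted sex differences, and asks how much
of the sex difference in free-recall performance is statistically mediated
by a network property — weighted transitivity, a measure of local
clustering / segregation.

It is aimed at network-neuroscience researchers who have per-subject
node-to-node connectivity matrices (or streamline tallies) plus a covariate
table, and at methodologists who want a fully synthetic, effect-calibrated
cohort generator to validate this kind of pipeline end to end.

## The model in brief

For R parcellated brain regions, directed streamline counts are converted
to connection probabilities `P_ij = N_ij / waytotal_i` and symmetrized,
`C_ij = (P_ij + P_ji)/2`.  Edges whose population distribution satisfies
`mean(C_ij) + 2 sd(C_ij) < 0.01` are removed in all subjects.  Four
whole-brain measures are computed per subject: graph strength `s_i = Σ_j
C_ij`, characteristic path length and global efficiency on shortest paths
with edge length `1/C_ij`, and weighted transitivity

    T = Σ_i 2 t_i / Σ_i k_i (k_i − 1),
    t_i = ½ Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3},   ŵ = C / max C.

Sex differences are tested with linear models adjusted for age and
intracranial volume; Cohen's d is reconstructed from the model t value,
`d = t (n1+n2) / (√(n1 n2) √df)`, so it inherits the covariate adjustment
(male = 1, so positive d means male-higher).  Memory models are
random-intercept mixed models (profiled REML) on the subject × valence
long table.  Mediation of sex → recall by transitivity reports paths a, b,
c, c′ on the correlation scale after residualizing age, recall-room batch
and ICV, with bias-corrected-and-accelerated (BCa) bootstrap intervals for
the indirect effect a·b and the mediation strength (a·b)/c′.

A synthetic cohort generator (`memnet.synthetic`) emulates the study
conditions — n = 655 subjects (60% female), 82-node parcellation, 5000
streamlines per seed, sex-ICV correlation −0.69, and calibrated effect
targets d = 0.42 (sex → transitivity), r = −0.23 (age → transitivity),
r = −0.12 (transitivity → recall), plus a residual direct sex → recall
effect — so every stage can be validated by parameter recovery.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from memnet import CohortConfig, generate_cohort, cohort_to_frame
from memnet import tally_to_probability, symmetrize, build_population_mask, apply_mask
from memnet import compute_metrics, fit_ols, run_mediation

cfg = CohortConfig(n_subjects=120, n_nodes=16, n_blocks=4, waytotal=1000, seed=42)
subjects, tallies = generate_cohort(cfg)

mats = [symmetrize(tally_to_probability(t)) for t in tallies]
mask = build_population_mask(mats, threshold=0.01, k_sd=2.0)
masked = [apply_mask(m, mask) for m in mats]

df = cohort_to_frame(subjects)
df["transitivity"] = [compute_metrics(m)[0].weighted_transitivity for m in masked]

res = fit_ols(df, "transitivity", ["male", "age", "icv"])
tt = res["male"]
print(f"sex difference: F(1,{tt.df2}) = {tt.f:.2f}, p = {tt.p:.4f}, d = {tt.cohens_d:+.2f}")

med = run_mediation(df, df["transitivity"], outcome="all", b_boot=2000, rng=0)
lo, hi = med.ci_indirect[95.0]
print(f"indirect effect a*b = {med.indirect:+.4f}  95% BCa CI [{lo:+.4f}, {hi:+.4f}]")
```

prints

```
sex difference: F(1,116) = 2.78, p = 0.0984, d = +0.32
indirect effect a*b = -0.0158  95% BCa CI [-0.0778, +0.0039]
```

At this demonstration size (120 subjects, 16 nodes) the configured
male-higher transitivity difference (d ≈ 0.3–0.4 here, target 0.42) is
visible but not significant, and the indirect effect is negative — males
have higher transitivity, higher transitivity predicts *worse* recall, so
the network path works against the male direction — with a confidence
interval that still includes zero.  At the full study scale (n = 655,
R = 82) the same quantities stabilize near their targets; run the
acceptance script below to reproduce them.

The same chain is available from the shell:

```
memnet simulate --out cohort/ --seed 1
memnet metrics  --cohort cohort/ --out tables/
memnet mediate  --cohort cohort/cohort.csv --metrics tables/metrics.csv --out mediation.csv
memnet run-all  --seed 1 --out run/        # full pipeline + figures + summary
```

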