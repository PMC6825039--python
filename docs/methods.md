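# Methods

## The experimental template

The package is built around a full factorial timed-arrival design: an
exotic focal species sown into a native grassland community that is
either grasses only (`G`) or grasses plus legumes (`GL`), under four
arrival treatments — `Early` (exotic at the first sowing event, natives
three weeks later), `Late` (the reverse), and two synchronous controls
`Sync1` / `Sync2` sown entirely at the first or second event — with five
replicate pots per cell (40 pots). The two synchronous controls exist so
that each timed arrival can be compared against plants of the same age
at harvest: `Sync1` plants match the first sowing's growth duration,
`Sync2` plants the second's. Arrival codes always refer to the exotic
species' timing.

## Priority-effect indices

All indices share the relative interaction kernel RI(a, b) =
(a − b)/(a + b), which is antisymmetric, invariant to rescaling both
arguments, and bounded in [−1, +1]; ±1 are attained exactly when one
member of the pair is zero. Each index pairs a group's response under a
timed arrival with its age-matched synchronous control:
B_E = RI(Y_E^Early, Y_E^Sync1), B_N = RI(Y_N^Late, Y_N^Sync1),
P_E = RI(Y_E^Late, Y_E^Sync2), P_N = RI(Y_N^Early, Y_N^Sync2), where the
native response Y_N is the within-pot sum of grass and legume values.
Negative values are inhibitory priority effects, positive values
facilitative.

Three conventions are deliberate design choices:

* **Replicate pairing.** Indices are computed per replicate, pairing
  replicate *r* of the treatment with replicate *r* of its control
  within composition. This is deterministic and independent of row
  order; a seeded random-permutation policy is available for sensitivity
  analysis of the convention. Any other pairing of pots across
  treatments is equally defensible — the data carry no physical link
  between pots — so the default is documented as a convention.
* **Zero–zero pairs are missing, not zero.** A pair summing to zero
  carries no information; an index of 0 must mean "no effect", never
  "no data". Undefined pairs are dropped from group means and *n* is
  reported.
* **Group means are arithmetic means of per-replicate indices**, not the
  index of treatment means. This matches the per-observation display and
  the ANOVA carried out on index values. The two estimators differ under
  noise (see *Recovery* below).

The percent-change equivalent g = 100·2b/(1 − b) inverts the kernel at a
unit reference, translating an index b into the familiar ±% language;
reported percent changes of raw responses always use the age-matched
synchronous group mean as reference.

Shoot N content is defined as an amount: dry weight × %N/100, in grams
per pot. The alternative reading (the concentration %N itself) is
available by analysing `n_percent` directly; the amount convention was
chosen because N content scales with biomass and is analysed separately
from concentration.

## Bootstrap confidence intervals

Group-mean CIs use the percentile bootstrap: 1000 resamples (with
replacement) of the per-replicate index values, the mean of each
resample, and the α/2 and 1−α/2 empirical quantiles at 95% coverage.
Quantiles interpolate linearly between order statistics — one of several
defensible conventions, fixed here for reproducibility and pinned by an
exhaustive-enumeration test at n = 3. The resample index stream is drawn
once per call, independent of the coverage level, so nested levels give
nested intervals for a fixed seed. Per-group seeds derive from a single
root seed and the group labels via SHA-256, making results invariant to
the order in which groups are processed. A group mean differs
significantly from zero exactly when its closed interval excludes zero
(an endpoint at zero counts as inclusion — the conservative reading).
With n = 5 the percentile bootstrap undercovers (≈ 0.82–0.85 empirically
at nominal 0.95 in the recovery study); that is a property of the
method at this sample size, not of the implementation, and the recovery
study quantifies it.

## Gamma GLM, ANOVA and contrasts

Biomass is analysed with Gamma GLMs under a log link, fitted by IRLS
implemented directly: for this link the working weights are identically
one, so each iteration is a least-squares solve on the working response
η + (y − μ)/μ, started from the least-squares fit to log y, with
step-halving whenever a step would increase the deviance (which makes
the deviance non-increasing across iterations) and convergence when the
relative deviance change falls below 10⁻⁸ (at most 100 iterations).
Dispersion is the Pearson statistic over residual degrees of freedom.
Term tests are deviance-based F statistics,
F = ΔD/(Δdf·φ̂_full), on (Δdf, df_resid) degrees of freedom. The
interaction term is dropped automatically when it fails this test at
α = 0.05, and the additive model is refitted; the decision is recorded
in the output. The covariate check (number of established exotic
individuals) compares models with and without the covariate by the same
F test plus a full-likelihood AIC with the Gamma shape profiled out by
maximum likelihood.

Index values are analysed with fixed-effects ANOVA using Type-II sums of
squares — each term tested against the model containing the other terms
— because a lost replicate makes the design unbalanced, and Type II
reduces to the classical decomposition when balance holds (verified
numerically). Post-hoc general linear hypotheses use single-step
adjustment: the adjusted p of contrast i is P(max_j |T_j| ≥ |t_i|) under
a multivariate t (least-squares fits, on the residual df) or normal
(GLM z statistics) with the contrasts' correlation matrix, evaluated by
seeded Monte Carlo with 10⁵ draws by default (MC noise ≈ ±0.002 on a
p-value near 0.05). With a single contrast the exact two-sided tail is
used, so adjusted and raw p coincide; MC adjusted values are floored at
the raw p so p_adj ≥ p_raw holds deterministically.

## δ15N diagnostics

δ15N = (R_sample/R_standard − 1)×1000, with atmospheric N2 as standard
(R = 0.0036765 by convention, configurable — analyses that start from
δ15N values never touch it). Three directional checks are reported, each
with direction, magnitude and a test outcome, and no verdict beyond the
stated rule: legume fixation (legume mean δ15N below the non-legume
mean and near zero — reported as a distance, not thresholded, since only
comparative conclusions are warranted), N transfer (non-legume δ15N
lower in `GL` than `G`, tested by one-way ANOVA per non-legume group),
and N sparing (non-legume %N higher in `GL` than `G`). Group means pool
all arrival treatments within a species group. Missing measurements make
a check "not assessable" rather than raising.

## Synthetic data and what it does (not) emulate

The generator draws each species group's biomass from a Gamma
distribution whose mean is a composition-specific baseline times a
positive arrival multiplier, with shape 10 by default (CV ≈ 0.32,
matching the right-skewed, strictly positive character of pot biomass
and the family the analysis fits). %N is Gaussian, truncated to (0, 100)
by resampling rather than clipping so the distribution stays smooth;
legume δ15N follows two-pool mixing p_fix·0 + (1 − p_fix)·soil with
p_fix = 0.8 and soil δ15N = 4‰; non-legume δ15N sits at the soil value,
optionally lowered in `GL` by a transfer offset (0 by default — the
no-transfer case). Established exotic individual counts are Poisson(25)
and independent of biomass. The `paper_like_spec` preset encodes
realistic effect *directions* — strong exotic benefit from early
arrival (larger with legumes), near-exclusion of the exotic when late,
moderate native benefit from arriving first, native suppression by an
early exotic that legumes mitigate, and a 0.35 Sync2/Sync1 baseline
ratio for the shorter growth period — with invented magnitudes; it is a
preset for testing, not a measurement.

The generator does not emulate: pot-to-pot environmental heterogeneity
or spatial effects, correlations between the biomass of groups sharing a
pot (competition is baked into the means, not the noise), germination
failure beyond Poisson count variation, or measurement error structure
in the C/N and IR-MS instruments. Passing recovery tests therefore show
that the pipeline recovers known truth under the stated noise model —
not that any particular greenhouse dataset satisfies that model.

## Recovery study and estimator bias

`recovery_study` simulates experiments, runs the complete index +
bootstrap pipeline, and scores two estimators against the analytic index
of the generating means: the pipeline's mean of per-replicate indices,
and the index of treatment means. Under Gamma noise the former carries a
mean-of-ratios vs ratio-of-means gap (≈ −0.02 at shape 10 for an index
near 0.4) that does not shrink with replication; the latter is
consistent, its bias falling roughly as 1/n (from ≈ 3×10⁻³ at n = 5 to
≈ 5×10⁻⁵ at n = 500 in the shipped configuration). Both are reported
with Monte-Carlo standard errors. The default study sizes — 500
simulations at 5 replicates, 60 at 500 replicates in the consistency
check — keep Monte-Carlo error well below the effects being measured.

## Numerical and degenerate-input conventions

Rank deficiency in any design matrix raises an error naming the first
aliased column. Strictly non-positive responses are rejected by the
Gamma GLM. A perfect ANOVA fit (zero residual MS) reports F = 0, p = 1
for terms with zero sum of squares and F = ∞, p = 0 otherwise. All
randomness — bootstrap, post-hoc Monte Carlo, simulation — flows from a
single root seed through named SHA-256 substreams, so outputs are
invariant to processing order and reruns are byte-identical.

## Known limitations

Inference on index group means with n = 5 is fragile regardless of
implementation; the bootstrap undercoverage above is the visible
symptom. The Gamma GLM reports z-based contrasts (large-sample), while
ANOVA contrasts are exact-t; at these sample sizes the GLM p-values are
approximate. The single-step adjustment is Monte-Carlo, not quadrature:
p-values carry ≈ 10⁻³-scale simulation noise (seeded, hence
reproducible). The isotope checks are directional contrasts, not a
mixing-model quantification of the fraction of N derived from the
atmosphere.
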