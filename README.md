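# priorityfx

Quantifying priority effects — how the *order* in which species arrive
shapes their performance — in timed-arrival community-assembly
experiments.

The package targets the classic greenhouse design in which an exotic
focal species is sown earlier than, later than, or synchronously with a
native plant community (grasses only, or grasses plus legumes), with two
synchronous controls so that every timed arrival can be compared with
plants of exactly the same age at harvest. It provides:

* **Bounded interaction indices.** The benefit of arriving early (*B*)
  and the cost of arriving late (*P*), built on the relative interaction
  kernel

  ```
  RI(a, b) = (a − b) / (a + b)  ∈  [−1, +1]
  ```

  applied to a response *Y* (shoot dry weight or shoot N content) under a
  timed arrival versus its age-matched synchronous control:

  | index | group  | treatment               | control |
  |-------|--------|-------------------------|---------|
  | B_E   | exotic | exotic sown early       | Sync1   |
  | B_N   | native | exotic sown late        | Sync1   |
  | P_E   | exotic | exotic sown late        | Sync2   |
  | P_N   | native | exotic sown early       | Sync2   |

  (Arrival labels always refer to the exotic species, so when the exotic
  arrives late it is the *natives* that arrived early — hence the crossed
  mapping.) Negative values are inhibitory priority effects, positive
  values facilitative; unlike log response ratios the indices are
  symmetric around zero and bounded, so experiments are directly
  comparable.

* **Inference.** Percentile-bootstrap confidence intervals (1000
  iterations) for index group means with the include-zero significance
  rule; Gamma log-link GLMs fitted by IRLS with deviance F tests and an
  automated interaction-dropping rule; Type-II fixed-effects ANOVA;
  Tukey-style simultaneous contrasts with single-step adjusted p-values;
  covariate model comparison and Pearson correlation.

* **δ15N nitrogen diagnostics.** Natural-abundance δ15N = (R_sample /
  R_standard − 1) × 1000 against atmospheric N2, with the three standard
  checks for legume-mediated facilitation: active N2 fixation (legume
  δ15N near zero), belowground N transfer (non-legume δ15N lower with
  legumes present) and N sparing (non-legume %N higher with legumes
  present).

* **A synthetic-data generator.** Full factorial 2 compositions × 4
  arrival treatments × 5 replicates with multiplicative treatment
  effects, Gamma biomass noise, truncated-Gaussian %N and two-pool
  isotope mixing — with closed-form index truth for end-to-end recovery
  studies.

## Worked example

```python
from priorityfx import (
    paper_like_spec, generate_experiment, aggregate_performance,
    compute_all_indices,
)
from priorityfx.io import RunConfig, summarize_indices

spec = paper_like_spec()                      # preset effect structure
frame = generate_experiment(spec, seed=1)     # 40 pots, tidy records
matrix = aggregate_performance(frame, "shoot_dry_weight")
tidy = compute_all_indices(matrix)            # per-replicate B and P
print(summarize_indices(tidy, RunConfig(seed=1)).round(3).to_string(index=False))
```

```
kind origin composition   mean  ci_low  ci_high  n  differs_from_zero  percent_equivalent
   B      E           G  0.221   0.092    0.344  5               True              56.710
   B      E          GL  0.485   0.300    0.628  5               True             188.692
   B      N           G  0.057  -0.179    0.244  5              False              12.028
   B      N          GL  0.168   0.009    0.383  5               True              40.465
   P      E           G -0.911  -0.929   -0.889  5               True             -95.330
   P      E          GL -0.881  -0.904   -0.851  5               True             -93.653
   P      N           G -0.641  -0.731   -0.527  5               True             -78.113
   P      N          GL -0.351  -0.464   -0.270  5               True             -51.952
```

Reading the first row: in grasses-only communities the exotic species
gained from sowing three weeks ahead of the natives (mean B_E = 0.221,
equivalent to +57% biomass relative to its age-matched synchronous
control), and the bootstrap interval excludes zero, so the benefit is
significant at the 95% level. The strongly negative P_E rows say that
arriving late nearly excluded the exotic (−95% / −94%), while the cost of
arriving late for natives was mitigated by legumes (P_N: −0.641 in G vs
−0.351 in GL).

The same pipeline runs from the shell:

```sh
priorityfx simulate --seed 1 --out exp.csv
priorityfx validate exp.csv
priorityfx report --input exp.csv --seed 1 --out results/
```

`report` (alias `all`) writes per-replicate indices, bootstrap
summaries, percent-change tables, index ANOVA with post-hoc contrasts,
Gamma-GLM analyses of deviance, the isotope report, and a `manifest.json`
recording versions, seeds and the config hash so the run can be
reproduced bit-identically.

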