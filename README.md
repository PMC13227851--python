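# boutcog

Day-of-week varying associations between the *distribution* of daily
activity bouts and ambulatory cognitive performance in older adults.

Modern thigh-worn accelerometers (e.g. activPAL) export event streams from
which contiguous sedentary (SED), light (LPA), and moderate-to-vigorous
(MVPA) activity bouts of at least one minute can be built. Two indices
summarise how a day's bouts of one class are distributed:

- **alpha index** — the Pareto density exponent fitted to the bout lengths,

  `alpha = 1 + 1 / M`,  `M = (1/n) * sum_i log(x_i / x_min)`,

  where `x_min` is the shortest recordable bout (1 min). Higher alpha:
  short bouts dominate; lower alpha: activity consolidates into long bouts.

- **Gini index** — half the relative mean absolute difference,

  `G = sum_ij |x_i - x_j| / (2 n sum_i x_i)`  in `[0, 1)`,

  0 for perfectly even bout lengths, near 1 when a few long bouts coexist
  with many short ones.

Cognitive outcomes come from smartphone EMA: four prompts per day of an
18-trial symbol-search task, summarised per day as the median response time
(RT) of accurate trials and the mean number of correct trials. With a
14-day protocol each subject contributes two copies of every day of week
`d` (1 = Sunday .. 7 = Saturday), and the model

```
Y_i(d) = b0(d) + alpha_i(d) b1(d) + G_i(d) b2(d) + N_i(d) b3(d)
         + Age_i b4(d) + Sex_i b5(d) + Edu_i b6(d) + u_i + e_i(d)
```

lets every coefficient vary smoothly over the weekly circle. Curves are
expanded in K cyclic B-splines with circulant difference penalties, a
scalar random intercept `u_i` absorbs within-subject correlation, REML
picks the smoothing and variance parameters, pointwise bands come from the
Bayesian coefficient covariance, and each whole curve gets an
effective-rank Wald test of `b_j(.) = 0`.

The package is a complete, testable pipeline around that model:

| module        | role                                                        |
| ------------- | ----------------------------------------------------------- |
| `simulate`    | synthetic cohort generator (events, EMA trials, demographics, planted ground-truth effect curves) |
| `bouts`       | event classification (MET cut-points: SED < 1.25 seated, LPA 1.25–2.99, MVPA >= 3), bout merging, wear time |
| `cognition`   | trial -> session -> day aggregation of symbol-search outcomes |
| `indices`     | alpha / Gini / bout-count indices per (subject, day-of-week, class) |
| `qc`          | valid-day rules (>= 10 h wear and >= 1 complete session), analysis-table assembly |
| `functional`  | the day-of-week varying-coefficient model                    |
| `power`       | Monte-Carlo power for the days-nested-in-subjects random-intercept design |
| `pipeline`/`cli` | one-config orchestration and the `boutcog` command        |

## Worked example

Simulate a 150-subject cohort at the day level (the generator plants a
Gini effect on RT for MVPA bouts that is zero on Sunday, −600 ms per unit
Gini on weekdays and −300 on Saturday) and fit the MVPA/RT model:

```python
>>> import numpy as np
>>> import boutcog as bc
>>> bc.gini_index([1, 4]), bc.alpha_index([1.0, np.e**2, 1.0])
(0.3, 2.5)
>>> tab, truth = bc.simulate_dow_table(bc.SimConfig(n_subjects=150), seed=1,
...                                    aggregation="per_day_mean")
>>> fit = bc.fit_model(tab, bc.ModelSpec(outcome="median_rt", bout_class="MVPA"))
>>> fit.curves["gini"].values.round(1)
array([ -103.5,  -386.8,  -791. , -1041.9,  -994.7,  -632.8,  -227.7])
>>> round(fit.curves["gini"].wald_p, 11), round(fit.curves["alpha"].wald_p, 3)
(1.76e-09, 0.02)
>>> round(fit.adjusted_r2, 3)
0.677
```

Reading: the fitted Gini curve is negative through the week with its
largest magnitudes midweek — days on which a subject's MVPA bout lengths
were more unequal (higher Gini) were days with faster processing speed —
while the Sunday value is small and its pointwise 95% band covers zero.
The curve-level Wald test rejects a flat-zero Gini effect (p ≈ 2e-9).
`mean_abs_effect(fit.curves["gini"])` summarises the curve as the mean
absolute effect over the seven days (597 ms per unit Gini here).

The same analysis runs end to end from the shell, starting from raw event
and trial CSVs:

```sh
boutcog run --config config.yaml --out results/
boutcog power --out power.csv --seed 1
```

`run` writes every intermediate table (bouts, day summaries, day-level
cognition, valid days, indices, the analysis table), six model fits
(2 outcomes x 3 bout classes), and a manifest with row counts, exclusion
percentages, and a reproducibility hash.

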