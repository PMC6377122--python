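# vmrnorm

Model-based normalization and comparison of plate-based zebrafish
visual-motor-response (VMR) data.

High-throughput behavioural assays record the swimming activity of
zebrafish larvae arrayed in 96-well plates before and after an abrupt
light change. The per-second activity measure, *Burst Duration* (the
fraction of video frames within one second in which a larva moved), is
bounded in [0, 1] and contaminated by systematic, non-biological
variation: wells at the plate centre receive more stimulus light than
edge wells, independent biological replicates (batches) shift activity
additively, and groups differ in pre-stimulus baseline activity. Left
uncorrected, these effects distort comparisons of the stimulus response
between strains or developmental stages.

`vmrnorm` removes each effect with a per-group linear model and keeps the
residuals:

- **light**: `activity_ij = β0_j + β1_j · light.intensity_ij + ε_ij`,
  ordinary least squares per group *j* (strain × stage × stimulus);
- **batch**: `activity_ij = β0_j + β_kj · I(batch k) + ε_ij` with the
  sum-to-zero constraint `Σ_k β_kj = 0`, so `β0_j` is the unweighted grand
  mean of batch means;
- **baseline**: an intercept-only model on the pre-stimulus window; the
  factor `β̂_j = ave(dark_activity_j) − target` shifts every group's
  baseline mean to a common grand-mean target.

Since residuals can be negative while activity is non-negative, an offset
`μ_offset` (default 0.06) is added after subtraction. The integrated
pipeline chains light → batch → baseline, each step fitted on the previous
step's residuals, with the offset applied once at the final step.

Downstream, groups are compared with the two-sample **Hotelling's T²**
test on short multivariate windows (one vector of per-second activities
per larva),

    T² = (n_a n_b / (n_a + n_b)) · d̄ᵀ S_pooled⁻¹ d̄,
    F = T² (n_a + n_b − p − 1) / ((n_a + n_b − 2) p) ~ F(p, n_a + n_b − p − 1),

and the normalization is evaluated with PCA (variance structure preserved)
and t-SNE (group clustering revealed). A synthetic-data generator emulates
every systematic effect with known ground truth.

## Worked example

```python
from vmrnorm import (SimConfig, simulate_experiment, fit_light_model,
                     integrated_normalize, hotelling_t2)

table, lights, truth = simulate_experiment(SimConfig(seed=1))

(fit3, fit6, fit9) = fit_light_model(table, lights)
print(fit6.group, fit6.coefficients)

normalized, report = integrated_normalize(table, lights, offset=0.06)

for label, data in (("raw", table), ("normalized", normalized)):
    r = hotelling_t2(data[data.stage_dpf == 6], data[data.stage_dpf == 9],
                     (1, 3), group_a=(6,), group_b=(9,))
    print(f"{label}: T2 = {r.t2:.1f}, p = {r.p_value:.3g}")
```

prints

```
('TL', 6, 'LightOn') {'beta0': 0.022279..., 'beta_light': -0.00019361...}
raw: T2 = 958061.5, p = 0
normalized: T2 = 2168519.9, p = 0
```

The simulated experiment holds 288 larvae (three stages × two replicates ×
48 larvae) recorded for 61 seconds around light onset. The fitted light
slope −1.94×10⁻⁴ recovers the generating value −2×10⁻⁴ well within one
standard error. The Hotelling comparison of the 6 vs 9 dpf response in the
three seconds after light onset is already overwhelming on raw data; after
the integrated normalization the statistic more than doubles, because the
nuisance variation that inflated the pooled covariance is gone.

The same pipeline is scriptable from the shell:

```sh
vmrnorm simulate --out sim --seed 1
vmrnorm normalize integrated --activity sim/activity.csv \
    --lights sim/light_map.csv --offset 0.06 --out norm
vmrnorm test --activity norm/normalized.csv --out ht --normalized-input
vmrnorm evaluate --raw sim/activity.csv --normalized norm/normalized.csv \
    --seed 1 --out emb
```

Each command writes a JSON manifest (inputs, digests, seed, version) next
to its outputs.

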