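# slnet

Functional-network analysis of multichannel resting-state EEG for two-group
diagnostic classification. Interictal EEG read visually is often normal in
the very patients one wants to identify, and no single spectral or network
summary separates groups reliably; `slnet` implements the multivariable
alternative: estimate a weighted functional network per subject with the
synchronization likelihood, summarize it as 18 graph-theoretical features,
and evaluate a random-forest classifier with bootstrap internal validation
so that reported accuracy is not same-data optimism.

## What it computes

**Synchronization likelihood (SL).** For channels x and y, both
delay-embedded, SL is the probability that y is recurrent at a time pair
(i, j) given that x is, with per-reference critical distances calibrated so
a fixed fraction p_ref of eligible neighbours (Theiler window w1 <
|i−j| ≤ w2) is recurrent:

    SL(x, y) ∈ [0, 1],   SL ≈ p_ref  for independent channels,
    SL = 1               for identical channels.

Per-epoch SL matrices are averaged into one symmetric weight matrix W per
subject (w_ii = 0).

**Network features.** On the weighted complete graph W, with edge length
1/w for path metrics: strength s_i = Σ_j w_ij; average shortest path L_i;
closeness cc_i = (N−1)/Σ_j d_ij; betweenness (shortest-path transit counts,
1e-12 tie tolerance); eigenvector centrality (unit-norm Perron vector);
Onnela weighted clustering C_i; and the continuous-MLE power-law index
α = 1 + n/Σ ln(d_i/d_min) of the strength distribution. Min/mean/max per
family (mean/max for betweenness) give 18 features per subject.

**Validated classification.** A random forest (mtry = 5 features per split)
is refit on B group-stratified bootstrap resamples and scored on each
replicate's out-of-bag subjects; the report carries bootstrap-corrected
AUC, sensitivity, specificity, PPV and NPV (Youden operating point) with
percentile 95% CIs, and a vertically averaged ROC curve.

**Synthetic cohorts.** A generator of two-group EEG cohorts (AR(2)
alpha-band oscillators, shared latent drivers, planted coupling increment on
a focal channel block) reproduces the target recording protocol — 35+35
subjects, 17 channels, four 8-s epochs at 512 Hz — so the whole chain runs
and is tested without clinical data. See `docs/methods.md`.

## Worked example

```python
from slnet import (CohortSpec, features_from_spec, bootstrap_validate,
                   per_feature_ttest)

spec = CohortSpec(n_per_group=20, n_channels=8, fs=256.0, epoch_seconds=4.0,
                  n_epochs=2, base_coupling=0.3, effect_size=0.65, seed=101)
ds = features_from_spec(spec)            # SL networks -> 18 features/subject
rep = bootstrap_validate(ds, B=200, n_trees=100, seed=7)
print(f"AUC  {rep.auc:.3f}  [{rep.auc_ci[0]:.3f}, {rep.auc_ci[1]:.3f}]")
print(f"sens {rep.sensitivity:.3f}  spec {rep.specificity:.3f}")
n_sig = sum(c.p < 0.05 for c in per_feature_ttest(ds))
print(f"{n_sig}/18 features individually significant at p<0.05")
```

prints

```
AUC  0.950  [0.819, 1.000]
sens 0.923  spec 0.922
14/18 features individually significant at p<0.05
```

A planted focal-coupling increment of 0.65 is recovered with excellent
discrimination (bootstrap-corrected AUC ≈ 0.95): the out-of-bag estimate,
not the optimistic same-data one. With `effect_size=0` the same pipeline
returns AUC ≈ 0.5 — the validation is calibrated. The same stages are
available from the shell: `slnet simulate | features | validate | report`.

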