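# clpntraj

Tools for studying how anxiety and depression co-develop in multi-wave
symptom panels: comorbidity descriptives, parallel-process latent-class
growth trajectories, and cross-lagged panel networks (CLPN) with
bootstrap accuracy, case-dropping stability and cross-phase
replicability. The package targets the common three-wave GAD-7 / PHQ-9
design (16 items scored 0–3 per wave) used in large longitudinal mental
health cohorts, and ships a synthetic-data module that generates panels
with known ground truth so every stage can be validated end to end.

## What it computes

**Descriptives.** Subjects are flagged clinical at a scale sum ≥ 7.
Per-wave prevalence trends are tested with a Pearson χ² on the
waves × {flagged, not} table, with effect size η = √(χ²/N); comorbidity
rates are P(anxious at wave s | depressed at wave t).

**Trajectories.** On wave-level mean scores (time scores 0, 1, 2), a
parallel-process latent growth curve model

y_i ~ MVN(Λμ, ΛΨΛᵀ + Θ)

estimates the joint distribution of the four growth factors (α_A, β_A,
α_D, β_D) — the Ψ correlations quantify co-development — and latent-class
growth analysis (class-specific growth means, zero within-class
growth-factor variance) fitted by EM enumerates K = 1..K_max classes on
AIC/BIC/aBIC, relative entropy E_K = 1 + Σ p_ik ln p_ik /(n ln K), and a
parametric bootstrap likelihood-ratio test (BLRT).

**Networks.** For binarized symptoms (presence = score ≥ 1), the CLPN for
a wave pair (t, t+1) fits, per outcome j, an L1-penalized logistic
regression

logit P(X_j^{t+1} = 1) = b_j + Σ_i B[i,j] X_i^t + γ_jᵀ c,

with cross-validated penalties and unpenalized covariates, giving a
16 × 16 directed edge matrix (diagonal = autoregressive effects) reported
as odds ratios exp(B). Node importance is expected influence: out-EI_i =
Σ_{j≠i} B[i,j], in-EI analogous, standardized across nodes; nodes with
standardized out-EI > 1 are flagged influential. Subject-bootstrap
percentile CIs, edge/centrality difference tests, the case-dropping
correlation-stability (CS) coefficient, and a replicability report
comparing two wave pairs (edge-weight correlations, % edges replicated,
centrality correlations) complete the pipeline.

## Worked example

```python
from clpntraj import (GrowthMixtureConfig, generate_growth_mixture, score_panel,
                      prevalence, trend_chi_square, enumerate_classes, growth_matrix,
                      binarize, fit_clpn, density, expected_influence)

cfg = GrowthMixtureConfig(n_subjects=2000, seed=7)   # 3 latent trajectory classes
panel, truth = generate_growth_mixture(cfg)
scores = score_panel(panel, cutoff=7)

prev = prevalence(scores, "anxiety")
trend = trend_chi_square(prev["count"].to_numpy(), panel.n_subjects)
table, fits = enumerate_classes(growth_matrix(scores), k_max=3, n_restarts=4, seed=7)
net = fit_clpn(binarize(panel), wave_pair=(1, 2), seed=7)
```

prints (via the obvious `print` statements):

```
anxiety prevalence by wave (%): [5.1, 12.8, 24.4]
trend chi2 = 312.3 (df=2), eta = 0.228
        BIC  entropy        proportions
K
1  12214.06      NaN              1.000
2   2065.48      1.0        0.695/0.305
3  -2894.15      1.0  0.695/0.274/0.031
T1->T2 network: 255 edges (239 cross-lagged), density 0.996
most influential symptom: GAD3 (standardized out-EI = 2.63)
```

Reading it: prevalence rises across waves (the generator's middle class
grows), the 3-class solution recovers the configured proportions
(0.698/0.272/0.030) with perfectly crisp assignment (entropy 1.0), and
the network fitted on the *pooled* cohort is nearly saturated — class
membership confounds every symptom pair, which is exactly why the
pipeline fits networks within trajectory classes
(`run_pipeline` / the `pipeline` CLI command do this, skipping classes
below a 200-subject floor where lagged networks are too unstable to
interpret).

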