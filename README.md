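# survfuse

Multi-omics survival prediction with **dually fused** graphs and features: a
graph-convolutional Cox model that integrates paired gene-expression and
microRNA-expression profiles of a patient cohort to predict right-censored
survival.

## The problem and the model

Given two sample-aligned expression matrices `X⁽¹⁾` (genes) and `X⁽²⁾`
(microRNAs) and outcomes `(Oᵢ, Δᵢ)` — observed time `Oᵢ = min(Tᵢ, Cᵢ)` and
event indicator `Δᵢ` — the model learns a per-patient risk score whose
ordering predicts survival:

1. **Highway encoders.** Each omics view is projected to width `l` and passed
   through three gated blocks `x_out = H(x)·T(x) + x·(1 − T(x))`, giving
   encodings `Z⁽¹⁾, Z⁽²⁾ ∈ ℝⁿˣˡ`.
2. **Factorized bilinear fusion (FBM).** Cross-omics features
   `Z⁽ᶜ⁾[i, j] = z⁽¹⁾ᵢᵀ Uⱼ Vⱼᵀ z⁽²⁾ᵢ` with rank-`d` factors `Uⱼ, Vⱼ ∈ ℝˡˣᵈ`
   capture multiplicative gene × microRNA interactions. The fused features are
   `Z = (Z⁽¹⁾ + Z⁽²⁾) ⊕ Z⁽ᶜ⁾`.
3. **Graph fusion.** Per-omics patient-similarity graphs
   `A(i,j) = exp(−ρ²(xᵢ,xⱼ)/(μδ²))` over k-nearest neighbours (δ² = median
   pairwise squared distance; μ = 0.3 genes, 0.2 microRNAs) are averaged and
   normalised to `Â = D̃^{−1/2}(A + I)D̃^{−1/2}`.
4. **GCN + Cox head.** `Z_h = σ(tanh(Â Z W₁) W₂)`, risk `= βᵀZ_h`, trained by
   full-batch Adam on the negative Cox partial log-likelihood
   `−Σ_{i:Δᵢ=1} [βᵀzᵢʰ − log Σ_{j:Oⱼ≥Oᵢ} exp(βᵀzⱼʰ)]`. The baseline hazard is
   recovered afterwards with the Breslow estimator.

Evaluation follows the standard protocol: repeated random 80/20 holdout,
Harrell's concordance index and the event-time-cumulative AUC on the test
part, Kaplan–Meier curves of the median-risk split with a log-rank test, and
ablations that remove the FBM, the graph, or the GCN. A seeded synthetic-cohort
generator plants additive and cross-omics risk in two correlated views, so the
whole pipeline is exercisable without any data download.

## Worked example

```python
from survfuse import (GraphFusionSurvival, SimConfig, simulate_cohort,
                      stratify_by_median, logrank_test,
                      repeated_holdout, SplitScheme)

cfg = SimConfig(n_samples=300, beta_additive=2.0, beta_cross=1.0,
                target_censoring=0.4, seed=1)
dataset, truth = simulate_cohort(cfg)

report = repeated_holdout(dataset, variant="FULL",
                          scheme=SplitScheme(train_frac=0.8, n_repeats=5,
                                             seeds=[0, 1, 2, 3, 4]))
print("held-out:", report.summary())

model = GraphFusionSurvival(variant="FULL", random_state=0).fit(dataset)
groups = stratify_by_median(model.risk_scores_)
chi2, p = logrank_test(groups, dataset.outcome)
print(f"median-risk stratification: log-rank chi2={chi2:.1f}, p={p:.2e}")
```

prints

```
held-out: C-index 0.840 +/- 0.019, AUC 0.918 +/- 0.015 (5 repeats)
median-risk stratification: log-rank chi2=304.4, p=3.67e-68
```

The C-index is the probability that, of two comparable patients, the one who
dies earlier received the higher predicted risk (0.5 = chance); the AUC is the
analogous ranking score accumulated over event times. The log-rank p-value
says the survival curves of the predicted high- and low-risk halves of the
cohort are very different — the model has found the planted hazard structure.

The same workflows are available from the shell: `survfuse simulate`,
`survfuse preprocess`, `survfuse train`, `survfuse evaluate`,
`survfuse ablate`, `survfuse sweep-k` (see `--help` of each).

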