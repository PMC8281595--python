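# omicsurv

Ensemble multi-omics survival subtyping: discover survival-ordered
molecular subtypes from several omics layers plus censored survival data,
and classify new samples — even with partial omics coverage — into those
subtypes.

## Who this is for

Computational biologists with a cohort measured on one or more omics
platforms (bulk RNA-seq, miRNA-seq, DNA methylation, ...) as
feature-by-sample TSV matrices, plus per-sample follow-up time and
vital-status data, who want prognosis-driven patient stratification rather
than purely unsupervised clustering — and who then need to place *new*
patients (possibly measured on a different platform, a subset of features,
or a single omic) into the discovered strata.

## The method in brief

For each omic layer, samples are re-described by rank-normalized
correlation distances to the training cohort (top-100 variance features,
within-sample ranks, d = 1 − Pearson r, per-sample rank rescale to [0, 1]),
compressed by a one-hidden-layer autoencoder
f(v) = tanh(W′·s(W·v + b) + b′) with bottleneck h = 100, and each latent
feature is screened with a univariate Cox proportional-hazards model
(likelihood-ratio p < 0.01). The retained latent features of all omics form
Z, which a diagonal-covariance Gaussian mixture (best of 100
initializations) clusters into K subtypes, relabeled so subtype 0 has the
lowest Kaplan–Meier median survival. A Kruskal–Wallis-selected, Platt-
calibrated SVM then predicts the subtype of new samples. The whole model is
a bagging ensemble: 10 such members fit on random 80% subsamples, members
without survival-associated features or labels (log-rank p > 0.05)
eliminated, probabilities averaged on the survival-ordered label index.
P(subtype 0) is the sample's risk score. See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from omicsurv import (SyntheticCohortSpec, generate_cohort, fit_ensemble,
                      predict_ensemble)
from omicsurv.subtyping import adjusted_rand_index

# 200 samples, 2 planted subtypes, RNA + miRNA + methylation layers,
# hazard ratio 3 between subtypes, 20% censoring
cohort = generate_cohort(SyntheticCohortSpec(n_samples=200, seed=1))
ensemble = fit_ensemble(cohort.dataset, n_models=10, K=2, seed=3)
print({k: round(v, 4) if isinstance(v, float) else v
       for k, v in ensemble.metrics.to_dict().items()})

pred = predict_ensemble(ensemble, cohort.dataset)
print("recovery ARI:", adjusted_rand_index(pred.labels, cohort.subtypes))
print("risk score range:", pred.risk_score.min().round(3),
      pred.risk_score.max().round(3))
```

prints

```
{'logrank_p': 0.0, 'c_index': 0.6192, 'silhouette': 0.2786,
 'stability_ari': 0.955, 'K': 2, 'n_retained_models': 10,
 'mean_model_c_index': 0.6302, 'mean_model_logrank_p': 0.0125,
 'n_oob_samples': 174}
recovery ARI: 1.0
risk score range: 0.0 1.0
```

Reading the numbers: all 10 ensemble members survived the survival-
association filter; the pooled out-of-bag predictions stratify survival
decisively (log-rank p ≈ 2×10⁻¹², printed as 0.0 after rounding) and reach
a hold-out C-index of 0.62 — essentially the information ceiling for a
binary subtype risk at hazard ratio 3 (see `docs/methods.md`); the
predicted labels recover the planted subtypes exactly (ARI 1.0); label 0
(highest risk score) is the worst-survival group.

The same workflow from the shell:

```bash
omicsurv simulate --n-samples 200 --seed 1 --out cohort/
omicsurv fit --omic RNA=cohort/RNA.tsv --omic MIR=cohort/MIR.tsv \
             --omic METH=cohort/METH.tsv --survival cohort/survival.tsv \
             --k 2 --n-models 10 --seed 3 --out model.bin
omicsurv predict --model model.bin --omic RNA=cohort/RNA.tsv --out pred.tsv
omicsurv evaluate --model model.bin --omic RNA=cohort/RNA.tsv \
                  --survival cohort/survival.tsv
```

(omit `--k` to select K over {2,3,4,5} by silhouette; `predict` with only
the RNA layer exercises the reduced-classifier path.)

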