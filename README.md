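# tnbcsig

Prognostic gene-signature discovery and validation for triple-negative
breast cancer (TNBC) from pooled microarray expression cohorts.

Triple-negative tumors lack ER, PgR and HER2 expression, and the common
proliferation-driven prognostic signatures carry little information in this
subtype. A route to TNBC-specific markers is to pool every available
expression dataset, harmonize it aggressively (keep only mutually comparable
datasets, drop probesets whose expression depends on dataset of origin),
and run a supervised survival screen on the pooled finding cohort. This
package implements that pipeline end to end, together with a synthetic-data
generator that plants known batch bias, co-expression factors, prognostic
effects and response outcomes, so that every stage can be checked against
ground truth.

## What it computes

**Cohort harmonization.** Each array is log2-transformed, median-centred
and scaled to unit magnitude (sum of squared values = 1). Datasets are
ranked by a comparability metric

&nbsp;&nbsp;&nbsp;&nbsp;C_d = (1/G) Σ_g ((μ_gd − μ_g)/σ_g)²

(per-dataset gene means vs pooled means in pooled-SD units; lower is
better), and the best datasets form the finding cohort. Dataset-biased
probesets are scored by the Kruskal–Wallis H of their expression across
dataset labels and filtered at cutoffs 75 / 150. Triple-negative status can
be called from bimodal receptor mRNA via two-component Gaussian mixtures.

**Supervised discovery (SAM survival mode).** For each probeset, a Cox
score statistic is computed from the risk sets at the distinct event times
(Breslow tie handling):

&nbsp;&nbsp;&nbsp;&nbsp;r = Σ_k [ Σ_{i∈D_k} x_i − d_k·x̄(R_k) ],&nbsp;&nbsp;
s = √( Σ_k (d_k/|R_k|) Σ_{i∈R_k} (x_i − x̄(R_k))² )

moderated as d = r/(s + s0), where the fudge factor s0 is chosen by the
coefficient-of-variation criterion over the s-distribution percentiles. For
a binary tie-free covariate, r/s is exactly the log-rank Z. A permutation
null (shuffling the survival pairs against the expression columns) gives
expected order statistics; the monotone band rule at half-width delta
defines the called set, and the median permuted count beyond the cuts,
scaled by the null-proportion estimate pi0, gives the median FDR.

**Risk scoring and validation.** A signature's compound-covariate score is
Σ_j d_j·x_j; cohorts are dichotomized at their top score quartile and
validated by Kaplan–Meier curves, the log-rank test, and a multivariate Cox
proportional-hazards model (Newton–Raphson on the Breslow partial
likelihood; Wald hazard ratios and 95% CIs) against nodal status, age,
tumor size and grade. RFS and DMFS endpoints are coalesced into event-free
survival, administratively censored at 120 months.

**Interpretation.** Signature probesets are correlated against metagene
scores (mean member expression) and assigned to the best-correlated
metagene at |r| ≥ 0.2 (0.3 stringent); score vectors are clustered by
average linkage on 1 − |Pearson r|. Response to neoadjuvant chemotherapy is
assessed by ROC/AUC of an immune metagene, the (negated) risk signature,
and their z-score combination.

## Worked example

```python
from tnbcsig.pipeline import RunConfig, run_pipeline

cfg = RunConfig(simulate=True, partition_top_k=3, deltas=[0.3, 0.5],
                sam_B=50, seed=7)
report = run_pipeline(cfg)
```

The simulated scenario is 5 datasets × 80 samples, 2000 probesets, a
50-probeset prognostic co-expression program (log-HR 0.8 per unit of its
mean expression), 50 batch-biased probesets and ~45% events. The run
partitions 3 finding / 2 validation datasets, discovers the signature on
the finding cohort and validates it on the held-out datasets. The delta
table of the discovery stage prints

```
delta 0.3: 57 POOR, 0 GOOD, median FDR 0.193
delta 0.5: 50 POOR, 0 GOOD, median FDR 0.040
```

i.e. a lenient and a stringent signature, both essentially recovering the
50 planted prognostic probesets (recovery report: sensitivity 1.0,
specificity 0.996). Validating the stringent signature on the held-out
cohort (`report["validation"]["delta0.5"]["validation"]`):

```
logrank_chi2 42.48   (p = 7.1e-11, n = 160)
multivariate HR (high vs low risk) 4.80, 95% CI 2.85-8.08, p = 3.4e-09
```

High-risk (top score quartile) samples have about a five-fold event hazard
— the synthetic analogue of the strong dichotomized hazard ratios such a
signature is designed to detect.

The same stages are scriptable from the shell (`tnbcsig simulate`,
`assemble`, `bias`, `sam`, `score`, `metagenes`, `validate`,
`predict-pcr`, `run --config run.yaml`).

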