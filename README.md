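# methicc

Reliability assessment of array-based DNA methylation measurements from
technical replicates, and its consequences for epigenome-wide association
studies (EWAS).

Methylation arrays (e.g. Illumina Infinium HM450) report a β value per CpG
probe and sample — the fraction of methylated signal, in [0, 1]. Probe-level
measurement quality varies enormously: at some CpGs technical noise and chip
(batch) effects swamp any biological signal. When a study includes technical
replicates — the same DNA measured two or three times, ideally on different
chips — each probe's reliability can be quantified by the intraclass
correlation coefficient of a one-way random-effects model

    y_ij = μ + τ_j + ε_ij,        ICC = σ²_τ / (σ²_τ + σ²_ε),

where j indexes replicate sets (biological samples), σ²_τ is between-sample
variance, and σ²_ε within-set technical variance. ICC = 1 means perfectly
reproducible; ICC = 0 means replicate noise dominates. The method-of-moments
(ANOVA) estimator truncates negative between-variance estimates to zero,
producing a point mass of probes at ICC = 0.

`methicc` implements the full analysis:

- **synthetic**: a generator of complete synthetic methylation studies
  (β matrix, detection p-values, sample sheet with chip layout, probe
  annotation, ground truth) under the random-effects model with chip
  batches, plus a direct sampler from the ICC mixture distribution;
- **qc**: detection-p pass-rate filters for samples and probes, and the
  SNP-within-50-bp probe mask;
- **icc**: per-probe ICC with the unbalanced-design k₀ coefficient, chip-wise
  ICC (share of variance due to chip), per-probe SD, and a LOWESS trend of
  ICC against SD;
- **mixture**: two-component models for the ICC distribution — a censored
  normal mixture, and a zero-inflated truncated-normal/normal mixture —
  fitted by EM, compared by maximized log likelihood, with posterior-based
  classification of probes into **zero / low / high** reliability clusters;
- **ewas**: per-probe association of methylation with a binary phenotype
  (chip as random intercept, or plain OLS), hit summaries by reliability
  cluster, and closed-form Bonferroni power calculations;
- **report/cli**: readers/writers, stratified summaries, and an end-to-end
  pipeline with a `methicc` command-line entry point.

## Worked example

```python
import numpy as np
from methicc import (
    SimulationConfig, simulate_methylation_study, apply_pass_rate_filters,
    icc_table, fit_truncated_mixture, classify_sites,
    icc_threshold_for_posterior, EwasConfig, run_ewas, summarize_by_cluster,
)

cfg = SimulationConfig(seed=2024)   # 2,000 probes; 130 replicate sets
beta, detp, sheet, ann, truth = simulate_methylation_study(cfg)
beta, qc = apply_pass_rate_filters(beta, detp)

table = icc_table(beta, sheet)
print(f"median ICC {table.icc.median():.2f}, "
      f"{(table.icc == 0).mean():.1%} at exactly 0")

fit = fit_truncated_mixture(table.icc.dropna().to_numpy(), seed=0)
thr = icc_threshold_for_posterior(fit, pi_cutoff=0.01)
labels = classify_sites(table, fit, pi_cutoff=0.01)
print(f"posterior 0.01 ~ ICC {thr:.2f}; clusters: {labels.attrs['counts']}")

res = run_ewas(beta, sheet, ann, EwasConfig())
summary = summarize_by_cluster(res, labels)
print(f"{int(res.significant.sum())} genome-wide hits, "
      f"{summary.attrs['fraction_high']:.0%} in the high-reliability cluster")
```

Typical output (seed 2024):

```
median ICC 0.47, 8.0% at exactly 0
posterior 0.01 ~ ICC 0.35; clusters: {'high': 1074, 'low': 767, 'zero': 159}
30 genome-wide hits, 100% in the high-reliability cluster
```

The median ICC and the zero-ICC share describe how reproducible the simulated
probes are; the posterior threshold is the ICC above which a probe is called
high-reliability at the 0.01 posterior cutoff; and the final line shows that
the probes carrying real phenotype signal are almost entirely recovered from
the high-reliability cluster.

The same analysis runs from the shell:

```sh
methicc run --outdir results_demo --seed 2024
```

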