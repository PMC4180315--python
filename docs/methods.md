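# Methods

## Measurement model and ICC estimation

Each probe's β value is modeled by the one-way random-effects ANOVA
y_ij = μ + τ_j + ε_ij over replicate sets j, with reliability
ICC = σ²_τ/(σ²_τ + σ²_ε). We estimate components by method of moments:
σ̂²_ε = MSW (pooled within-set mean square), σ̂²_τ = (MSB − MSW)/k₀ with the
unbalanced-design coefficient k₀ = (N − Σn_j²/N)/(J − 1), truncating negative
σ̂²_τ to zero. This is the classic ICC(1,1) estimator. We use it rather than
REML deliberately: truncation of negative moment estimates produces an exact
point mass at ICC = 0, which is the empirically observed feature the zero
cluster models; REML approaches the boundary differently and would smear that
mass. The raw (untruncated) between-variance is retained for diagnostics.

Probes are estimable only with ≥ 2 usable sets of size ≥ 2; missing entries
are dropped pairwise and a set shrinking below size 2 is dropped from that
probe's ANOVA. Unestimable probes carry NaN and are reported, never silently
zeroed.

The same estimator with chip as the grouping factor gives ICC_chip, the share
of measurement variance attributable to chip (batch) differences. It is
computed on replicate samples by default, the same data as the replicate ICC,
for comparability (`replicates_only=False` switches to all samples).
Per-probe SD is computed across distinct subjects — the first sample of each
replicate set — so replicate sets are not double-counted; this convention is
ours, as is the fixed sample-then-probe filtering order in QC (the order
matters because probe pass rates are recomputed on retained samples).

A caveat on QC idempotence: because sample pass rates are defined with
respect to the supplied matrix, re-filtering an already-filtered matrix can,
in principle, exclude further samples whose rates shift when probes are
removed. With realistic detection-failure rates (well below 1%) and the 99%
thresholds, the filter is a fixed point in practice.

## Mixture models for the ICC distribution

Two models accommodate the boundary at 0.

**Censored normal mixture.** Two normal components (low/high reliability);
an observation at 0 is a censored draw (latent value ≤ 0), contributing
Φ(−μ_k/σ_k) instead of the density. We censor both components — a single
coherent likelihood — although at fitted scales the high component's sub-zero
mass (≈ Φ(−0.67/0.14) ~ 10⁻⁶) makes this numerically indistinguishable from
censoring only the low component. EM treats the censored points by expected
sufficient statistics of the normal truncated above 0: with α = −μ/σ and
λ = φ(α)/Φ(α), E[X|X≤0] = μ − σλ and Var[X|X≤0] = σ²(1 − λ(λ + α)).

**Truncated normal mixture.** Exact zeros form their own cluster with weight
p0 estimated by the sample proportion; non-zero values follow
p·f_TN(x; μ1, σ1) + (1−p)·φ((x−μ2)/σ2)/σ2, where f_TN is the normal density
truncated below at 0. For model comparison the log likelihood is extended to
the full data: n0·log p0 + Σ log[p1 f_TN + p2 φ₂], p1 = p(1−p0),
p2 = (1−p)(1−p0) (the zero term is omitted when n0 = 0). The truncated
component has no closed-form M-step; we maximize its weighted log likelihood
numerically. The objective depends on the data only through Σw, Σwx, Σwx², so
each inner evaluation is O(1); the update is accepted only when it improves
the conditional objective, so the generalized-EM ascent property is
preserved and asserted in tests. No upper truncation at 1 is applied — the
high component's mass above 1 is negligible at fitted scales.

The likelihood forms above are reconstructions from the model definitions;
the primary description of these models that we follow did not include
machine-readable formulas.

**Conventions and numerical choices.** The mixing proportion `p` is stored as
the component-1 (low-reliability) share of the modeled observations; the
opposite caption convention exists in the literature, so serialized fits also
report `p_high_reading = 1 − p`. Initialization places the component means at
the 25th/75th percentiles of the non-zero values with σ at half the IQR and
p = 0.5, plus seeded jittered restarts (default 5), keeping the best log
likelihood. Convergence: relative log-likelihood change < 10⁻⁸ or 2,000
iterations. Component collapse (σ < 10⁻⁴) aborts a start. Degenerate input
(all zeros) yields p0 = 1 with the fit flagged degenerate. Three-component
mixtures are deliberately not implemented.

**Classification.** Non-zero probes are assigned by the posterior
π(x) = p2 g2(x)/(p1 g1(x) + p2 g2(x)); the zero-ICC probes are their own
cluster regardless of the fit. The default cutoff π ≥ 0.01 is intentionally
permissive, maximizing the high-reliability cluster; the boundary is assigned
to high. The ICC value corresponding to a cutoff is found by bracketed root
finding (tolerance 10⁻⁶) after verifying a single sign change of π − cutoff
on (0, 1). Model choice follows the larger maximized full-data log
likelihood, with ties broken toward the truncated model.

## Association demonstration and power

The EWAS stage regresses each probe's β on a binary phenotype plus covariates
(age, sex, BMI, alcohol, ancestry PCs, visit, chip row), with the chip as a
random intercept (statsmodels MixedLM, REML) and a Wald normal test for the
phenotype coefficient; the genome-wide significance threshold is p < 10⁻⁷.
Replicates are collapsed to one sample per subject. A non-convergent mixed
fit falls back to OLS and is flagged. The plain-OLS mode exists as the naive
comparator: with chip-level correlation in the residuals it understates
standard errors and inflates hit counts.

Power for a single regressor explaining r² of variance at per-test level
α/m uses the noncentral distribution of the t statistic with noncentrality
√(n·r²/(1−r²)). We evaluate it through the equivalent noncentral-F form
(T² ~ F(1, n−2; ncp²)) because scipy's noncentral-t CDF is numerically
unstable at df ≈ 2,500 in the versions we target. The power gain from probe
filtering compares per-test levels α/m and α/(m(1−f)) over an effect-size
grid and reports the maximum; the "maximum over the grid" reading of the
gain is an interpretation, the grid r² ∈ [0.002, 0.03] covering effects that
are neither undetectable nor saturated at n = 2,500.

## The synthetic-data generator

The generator runs the measurement model forward:
y = clamp(μ_p + τ_j + b_l(ij) + effect·smoker_j + e_ij, 0, 1), with τ a
subject effect, b a chip effect, and e residual noise, so the true
reliability of probe p is σ²_b/(σ²_b + σ²_chip + σ²_e) — chip variation acts
as within-set noise because replicates of a set are placed on different
chips (except a configurable 2 same-chip pairs, mirroring real replicate
layouts). Default design: 500 subjects, 125 duplicate + 5 triplicate
replicate sets (265 replicate measurements in 130 sets), 12-sample chips
(6 rows × 2 columns), 2,000 probes.

Per-probe parameters: means from a tri-modal Beta mixture (modes near 0.05,
0.5, 0.95 — unmethylated, hemi-methylated, methylated CpGs); true non-zero
ICC from a two-mode Beta mixture (modes 0.10 and 0.75, high-mode weight
0.55); a fraction 0.076 of probes with exactly zero between-subject variance
(the zero-ICC mass); total within-set SD log-normal around 0.015 split
40%/60% between chip and residual. All component SDs are scaled by
clip(2·min(μ, 1−μ), 0.1, 1) so that near-boundary probes have compressed
variance — both realistic for β values and necessary to keep clamping rare
(≈ 0.1% of entries at defaults; clamping was chosen over logit-scale
simulation for transparency). Phenotype prevalence 0.256, age N(56.7, 5.9²),
63.4% female, echoing a large replication cohort; 30 effect probes with mean
β difference 0.05 placed on high-ICC probes by default. Detection p-values
exceed 0.01 independently per entry with probability 0.002. Cross-reactive
and Infinium-I annotations are drawn with weights decreasing in true ICC,
reproducing the empirical enrichment of such probes at low reliability; the
SNP flag is independent.

What the generator does **not** emulate: fluorescence intensities and color
channels, cell-type composition, ancestry structure in methylation itself,
spatial within-chip gradients, or probe-sequence effects. Passing tests
therefore demonstrate the statistical machinery (estimator calibration,
mixture recovery, cluster enrichment, error control), not robustness to
those real-data complications.

## Problem sizes used in tests

The reference end-to-end check uses the default design (2,000 probes, 130
replicate sets, 500 subjects); mixture recovery uses 20 replicates of
n = 50,000 ICC draws; EM-versus-direct-optimization checks use n = 500 with
ten optimizer restarts; the family-wise-error check uses 200 null studies of
12 probes × 96 samples. These sizes make every stochastic check stable under
its stated tolerance while the whole suite remains quick to run.

## Known limitations

- ICC estimates at 130 replicate sets carry substantial sampling error
  (visible as spread in the estimated-vs-true comparison); the package does
  not propagate that uncertainty into the mixture fit (no weighting).
- The normal high-reliability component cannot capture left-skew near
  ICC = 1; moderate-ICC probes may receive small posteriors as a result.
- The mixed-model Wald test relies on a normal approximation; with very few
  chips its p-values can be mildly anti-conservative.
- `p0` is estimated by the sample proportion, not jointly by maximum
  likelihood, matching the procedure it implements.
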