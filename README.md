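# mrsmeta

Random-effects meta-analysis of study-level magnetic resonance spectroscopy
(MRS) metabolite summaries, with a moving-window procedure that locates the
measurement-quality level beyond which a patient–control difference becomes
evident.

## The problem

MRS studies of psychiatric disorders report, per study, group means and SDs
of metabolite levels (NAA, choline, creatine) in a brain region, for a
patient and a control group. Meta-analysis pools these into a standardized
mean difference, but metabolite quantification quality varies enormously
across sites; noisy measurements dilute real group differences. `mrsmeta`
implements the full analytic pipeline for this setting:

- **Effect sizes**: Hedges' *g* per dataset, with the small-sample
  correction *J* = 1 − 3/(4m − 1), m = n₁ + n₂ − 2, and sampling variance
  v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)); plus the sample-size-weighted mean
  percent difference Σᵢ[(x̄ᵖᵗᵢ − x̄ᶜᵒⁿᵢ)/x̄ᶜᵒⁿᵢ](Nᵖᵗᵢ+Nᶜᵒⁿᵢ) / Σᵢ(Nᵖᵗᵢ+Nᶜᵒⁿᵢ).
- **Pooling**: inverse-variance-weighted random-effects model with τ²
  estimated by restricted maximum likelihood; Wald omnibus test (df = 1),
  Cochran's Q heterogeneity, I².
- **Moderators**: mixed-effects meta-regression (ln TE, age, % male,
  % medicated) and subgroup comparisons (field strength at 3 T,
  normalization method, illness duration at 36 months, TE at 35 ms).
- **Bias & robustness**: Egger weighted regression for small-study bias
  with a single-study removal rule; leave-one-out robustness; CI-overlap
  outlier detection with a "report when significance flips or the effect
  changes by ≥ 1/3" rule.
- **Quality thresholds** (the centerpiece): rank datasets by a quality
  metric (COV of reported values, CRLB, linewidth FWHM as mean + 2 SD, or
  SNR as mean − 2 SD), pool a sliding window of k′ = max(7, ⌈k/5⌉)
  consecutive ranks, fit a 4-parameter logistic
  y(i) = d + (a − d)/(1 + e^{b(i−c)}) to the window series, and — when the
  fit is significant with an in-range inflection — map the inflection to
  metric units to split the corpus into low- and high-quality subgroups,
  which are then compared formally. The stratification requires ≥ 14
  reporting datasets.
- **Synthetic corpora**: a seeded generator of study-level summaries with a
  true percent difference, subject-level biological spread, a per-site
  measurement-quality axis that can attenuate the observable difference
  through a sigmoid switch, and optional moderator couplings — so every
  pipeline stage is testable without real data.

## Worked example

```python
from mrsmeta import (SyntheticCorpusConfig, SigmoidAttenuation, generate_corpus,
                     RegionalCollection, Region, Metabolite,
                     hedges_g, pool_random_effects, weighted_percent_difference,
                     quality_threshold_scan, QualityMetric)

corpus = generate_corpus(SyntheticCorpusConfig(seed=3, attenuation=SigmoidAttenuation()))
coll = RegionalCollection(Region.MPFC, Metabolite.CHO, corpus)

res = pool_random_effects([hedges_g(d) for d in coll])
print(f"k={res.k}  g={res.pooled_g:+.3f}  p={res.p_omnibus:.2g}  "
      f"tau2={res.tau2:.4f}  I2={res.i2:.1f}%")
print(f"weighted percent difference: {weighted_percent_difference(coll):+.2f}%")

scan = quality_threshold_scan(coll, QualityMetric.COV)
print(f"k'={scan.k_prime}  windows={scan.n_windows}  "
      f"fit r2={scan.fit.r2:.2f}  p={scan.fit.p_value:.2g}")
if scan.threshold_declared:
    print(f"COV threshold T={scan.threshold_value:.1f}%  "
          f"high-quality g={scan.subgroup_high.pooled_g:+.2f} (k={scan.subgroup_high.k})  "
          f"low-quality g={scan.subgroup_low.pooled_g:+.2f} (k={scan.subgroup_low.k})  "
          f"subgroup p={scan.p_subgroup_diff:.3f}")
```

Output:

```
k=48  g=+0.144  p=0.00023  tau2=0.0001  I2=0.1%
weighted percent difference: +2.74%
k'=10  windows=39  fit r2=0.56  p=1.8e-06
```

The 48-study corpus carries a +3% true choline elevation that is switched
off in studies whose total coefficient of variation exceeds 20%; the pooled
effect (+0.16 SD, about +2.3%) is therefore an attenuated average, and the
moving-window scan fits a strongly significant rising sigmoid. Whether a
threshold is *declared* additionally requires the inflection to fall inside
the window range and the resulting subgroup comparison to be significant
(for this seed the inflection falls out of range, so no split is reported —
the procedure is deliberately conservative about converting a good fit into
a threshold claim).

A command-line interface wraps the same pipeline:

```bash
mrsmeta simulate --out corpus.csv --seed 7
mrsmeta analyze --input corpus.csv --out results/ --metrics cov,crlb,fwhm,snr
mrsmeta threshold --input corpus.csv --region MPFC --metabolite CHO --metric cov
```

`analyze` writes `results.tsv` (one pooled row per region × metabolite,
with k, g, CI, p, percent difference, I², outlier counts), `moderators.tsv`,
per-metric window-scan tables under `scans/`, an exclusion log, and
`run_meta.json` recording the configuration.

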