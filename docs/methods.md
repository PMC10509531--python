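# Methods

## Statistical model

Each *dataset* is one patient-vs-control comparison of one metabolite in
one brain region, summarised by group sizes, means and SDs. The
standardized effect is Hedges' g: d = (x̄_pt − x̄_con)/s_p with the pooled SD
s_p² = ((n_pt−1)s_pt² + (n_con−1)s_con²)/m, m = n_pt + n_con − 2, corrected
by J = 1 − 3/(4m − 1) (the standard approximation to the exact
gamma-function factor; the two differ only in the 4th decimal for the group
sizes admitted here). Sampling variance: v = (n_pt+n_con)/(n_pt·n_con) +
g²/(2(n_pt+n_con)). Negative g means patients below controls. Confidence
intervals are Wald at z = 1.959964 throughout.

Pooling is the random-effects model y_i = μ + u_i + e_i, Var(u_i) = τ²,
Var(e_i) = v_i. τ² is the restricted maximum-likelihood maximizer, found by
bounded 1-D search of the restricted log-likelihood
−½[Σlog(v_i+τ²) + log|X'WX| + Σw_i r_i²] on τ² ∈ [0, max(10·Var(y), v_max)]
to an absolute tolerance of 1e-10, with an explicit boundary check at
τ² = 0. The same criterion with a moderator design matrix X gives the
mixed-effects meta-regression; coefficients come from weighted GLS at the
REML τ², with Wald z tests and a joint QM chi-square (df = number of
moderators) on the non-intercept coefficients. For a single indicator
moderator the df = 1 QM test is the subgroup comparison.

The omnibus test of the pooled effect is the Wald chi-square
QM = (μ̂/se)² on df = 1. Residual heterogeneity is Cochran's
QE = Σ(g_i − ĝ_FE)²/v_i on df = k − 1 at fixed-effect weights, and
I² = 100·τ²/(τ² + s²) with the typical within-study variance
s² = (k−1)Σw̃ /((Σw̃)² − Σw̃²), w̃_i = 1/v_i. No Knapp–Hartung adjustment is
applied; intervals are z-based.

Small-study bias is the Egger test: the weighted regression of g on its
standard error with weights 1/v, fitted in the algebraically identical
precision form (OLS of g/se on 1/se plus a constant; the constant is the SE
coefficient), tested two-sided on t with k − 2 df. When significant at
α = 0.05, exactly one dataset is removed per invocation: the one with the
largest absolute externally studentized residual among datasets whose total
n is below the corpus median (ties: smaller n, then study id), after which
the test is re-run.

Robustness of a significant pooled result means every leave-one-out refit
stays significant. A dataset is an outlier when its 95% CI and the pooled
95% CI are disjoint; intervals touching at an endpoint overlap. Outlier
detection is single-pass and always relative to the specific model at hand
(moderator analyses re-derive their own outliers). The outlier-excluded
refit is reported when it flips significance or changes a significant
effect by at least one third of its magnitude.

## Quality metrics

Four per-dataset quality proxies: COV = 100·(sd/mean averaged over the two
groups) (%); CRLB as the reported group-averaged mean (%); FWHM as the
group-averaged mean + 2 SD (an upper envelope covering ~97.5% of subjects);
SNR as the group-averaged mean − 2 SD (a lower envelope). Missing FWHM/SNR
SDs are imputed as mean × median(SD/mean ratios) over the datasets in the
same analysis reporting both; imputation never fires when both SDs are
present. Lower is better for COV/CRLB/FWHM, higher for SNR.

## The threshold procedure

Datasets are ranked from worst to best measurement quality (ties broken by
study id). Windows of k′ = max(7, ⌈k/5⌉) consecutive ranks (k = 48 gives
k′ = 10 and 39 windows) are pooled independently by the random-effects
model (a fixed-effect switch exists). A 4-parameter logistic
y(i) = d + (a−d)/(1 + e^{b(i−c)}) is fitted to the window series by
nonlinear least squares with eight deterministic starts (both steepness
signs × four inflection quantiles), SSres tolerance 1e-10, and bounds —
asymptotes within the data range padded by one span, c ∈ [1−n, 2n] — that
exclude the degenerate runaway-asymptote optima an unconstrained 4PL
admits on drifting series. Fits are canonicalized to b ≥ 0 (the model is
invariant under (a,d,b) → (d,a,−b)), so `a` is always the poor-quality
asymptote. Significance is the F test against the intercept-only model,
F = ((SStot−SSres)/3)/(SSres/(n−4)).

When the fit is significant (α = 0.05) and c lies within [1, window
count], the threshold T is the quality-metric value at rank
r* = c + k′ − 1 (the best-quality member of the inflection window),
linearly interpolated between adjacent ranks. Each dataset's own metric
value versus T decides its subgroup, better side inclusive (e.g. COV ≤ T
is high-quality); the subgroups are pooled separately and compared via the
indicator meta-regression. Stratification requires ≥ 14 datasets reporting
the metric, and ≥ 2 datasets on each side of T.

## Synthetic corpora

The generator emulates a single region × metabolite literature. Per study:
group sizes uniform on 10–50; a site measurement CV uniform on 0.04–0.16
combined in quadrature with a 15% subject-level biological CV (total
reported COV ≈ 15.5–22.5%); a site-specific unit scale (log-normal, σ=0.2)
that cancels in g; group means drawn Normal(truth, (cv·truth)²/n) and
sample SDs from the scaled χ distribution with n − 1 df, so reported
summaries follow the exact sampling laws of normal data. The default truth
is a +3% patient–control difference. Optional sigmoid attenuation
multiplies the true difference by floor + (1−floor)/(1+e^{s(q−T)}) with q
the study's total CV; the default switch (T = 0.20, s = 300) turns the
effect off above a total COV of 20%, splits the default corpus roughly
1:3, and has a transition width of a few ranks — a genuine threshold.
Auxiliary CRLB/FWHM/SNR summaries are emitted consistently with the site's
measurement CV so every quality axis can be scanned, and moderators (echo
time on a bimodal grid, field strength, medication status, age, sex,
illness duration) are drawn from realistic grids with optional couplings
to the true difference. A global seed spawns one substream per study, so
growing k extends a corpus without reshuffling.

What the generator does *not* emulate: publication selection, correlated
multi-voxel reports from one publication, non-normal metabolite
distributions, scanner-specific artifacts, or reporting errors. Passing
tests therefore validate the pipeline's statistical machinery under its
own model assumptions, not robustness to every pathology of real
literatures.

## Calibration and known limitations

Null calibration simulates directly from the random-effects model (the
tests' own null class) with τ² > 0 at moderate-to-large k: the REML-Wald
omnibus, subgroup and Egger p-values are uniform there (the τ² = 0
boundary makes any correct REML implementation conservative, and small-k
Wald tests are mildly anticonservative — both are properties of the
estimator, not of this implementation; the engine agrees with R's metafor
to ~1e-5 on fixed instances).

Two limitations of the threshold procedure are worth stating plainly,
because the test suite measures them:

1. **The logistic-fit p-value is anticonservative.** Adjacent windows
   share k′ − 1 of k′ members, so the window series is strongly
   autocorrelated; the F test assumes independent errors and rejects far
   too often (on no-signal corpora a significant in-range fit occurs in
   the large majority of replicates, and even on iid noise the free
   steepness lets the 4PL act as a step detector, inflating rejection to
   ~8–9% at α = 5%). The fit significance is therefore a screening
   condition, not the inferential gate: the decision that quality
   moderates the effect rests on the subgroup comparison, which is
   computed on non-overlapping data. The end-to-end procedure
   (significant fit + in-range inflection + significant subgroup
   difference) has a false-positive rate near the nominal α on no-signal
   corpora.

2. **The derived threshold is biased toward the better-quality side.**
   The mapping r* = c + k′ − 1 places T at the best member of the
   inflection window, while a symmetric logistic puts c at the midpoint
   of the transition ramp — an overshoot of about k′/2 ranks — and
   ranking noise in observed COV plus the 1/CV dilution of standardized
   effects stretch the fitted transition further in the same direction.
   Under the default conditions the recovered threshold sits about 2–3
   COV points below the generative switch. Subgroup *membership* is much
   less sensitive than T itself, and the sign of the subgroup difference
   is recovered reliably; the numeric threshold should be read as an
   ordering landmark, not a calibrated estimate of the switch point.

## Problem sizes

Simulation-based tests use 200 corpora per condition for threshold
behaviour, 2000 replicates per statistic for null calibration, 50 random
instances for the REML-vs-grid oracle, and k = 48 corpora matching the
best-populated analysis the pipeline targets; the acceptance script uses
60 replicates per condition.
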