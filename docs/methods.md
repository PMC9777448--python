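# Methods

This note documents the statistical model behind `epiclock`, the choices made
where the design was genuinely open, and what the bundled simulator does and
does not capture.

## The clock

The predictor is a ridge regression of chronological age on the standardized
M-values of all CpG units of the targeted assay:

    âge = β₀ + Σ_j β_j (M_j − μ_j)/σ_j,
    β̂ = argmin_β ‖y − Zβ‖² + λ‖β‖².

*Why M-values.* Beta-values are proportions; their variance collapses near 0
and 1. The logit transform `M = log₂(b/(1−b))` is approximately
variance-stabilizing and makes a linear-in-age model tenable. The transform
diverges at the boundary, so betas are clipped to `[ε, 1−ε]` with ε = 0.001
(about ±10 on the M scale — outside the range targeted bisulfite data
realistically reach, so clipping is almost never active on real measurements).

*Why standardize.* Ridge penalizes all coefficients through a single λ;
without standardization the penalty would weigh units by the accident of
their M-value spread. Means and SDs are estimated on the training set and
stored in the model file, so a serialized model is self-contained.

*Training window.* The model is fit on reference samples aged 20–80 years,
the range in which blood methylation drift is close to linear. Prediction is
deliberately unconstrained: centenarian samples are extrapolated, not
clipped, since detecting deviation at extreme ages is the point of the tool.

*Penalty selection.* λ is chosen from a grid of 25 log-spaced values in
[1e−4, 1e4] by 5-fold cross-validation minimizing squared error, then the
model is refit on all retained samples at the chosen λ. Folds are
age-balanced: samples are binned into 10-year bins and dealt round-robin
(seeded shuffle within bin, rotating start fold), so every fold sees the full
age range; each bin's membership differs across folds by at most one. Ties
in CV error resolve to the smallest λ. The selected λ is recorded in the
model file.

*Metrics.* Spearman ρ between predicted and chronological age (midrank ties)
plus both the **median** and **mean** absolute deviation in years. The two
MAD conventions coexist in the field, so both are always reported;
`mad_median` is the headline number.

*Degenerate inputs.* Zero age variance is an error; constant CpG-unit columns
are dropped with a warning (detected with a 1e−9 tolerance on the M-value SD,
since a constant column's floating-point SD need not be exactly zero).

## Epigenetic age discrepancy (EAD)

EAD is the residual from the OLS regression of epigenetic age on
chronological age fit **once** in a designated reference set:

    EAD_i = âge_i − (a + b·age_i).

Fitting the line in the reference group rather than using `âge − age`
directly removes the systematic compression of regression-based clocks
(slope b < 1 whenever training ages carry biological-age noise). Two exact
consequences are used as tests: the mean EAD over the reference-fitting
samples is 0 (OLS residual property, asserted to 1e−9), and adding a constant
to every epigenetic age before fitting leaves all EADs unchanged.

The reference line is applied unchanged to all samples, including ages far
outside the reference range (centenarians) — no per-group refitting. In the
paired intervention workflow both the clock and the reference line are fit on
baseline (T0) samples and applied to both timepoints.

*Group comparisons.* Two-sided throughout. The Wilcoxon–Mann–Whitney test
uses full enumeration of all C(n, n_a) group assignments with midranks when
the combined size is ≤ 12 (this handles ties exactly; identical multisets
give p = 1), and the tie-corrected normal approximation with continuity
correction above that. Welch's t uses Satterthwaite degrees of freedom. The
paired t-test flags zero-variance differences as degenerate (p undefined)
rather than reporting a meaningless statistic. Intervention analyses report
the paired t, the unpaired rank-sum and Welch side by side, plus the mean of
the per-subject T1−T0 differences.

## Imputation

Targeted assays drop out sporadically. Missing betas are filled by
chained-equations regression imputation in beta space (the assay's native
scale, before the M transform): units missing in more than 30% of samples
are dropped; the rest are initialized at unit means, then for a fixed number
of sweeps (default 5) each incomplete unit is regressed on all other units
over its observed rows and its missing entries replaced by least-squares
predictions clipped to [0, 1]. A single completed dataset is produced —
the downstream clock needs one deterministic matrix, so no multiple-
imputation draws. Observed entries are never modified (asserted
bit-identically in tests). The sweep is backed by scikit-learn's
`IterativeImputer` with a `LinearRegression` estimator; the drop threshold,
beta-space policy and DataFrame surface are this package's.

## Probe selection

Candidates for a biological-age panel must do more than correlate with age.
Per probe the selector computes: Spearman correlation with age over an aging
reference set; two case–control contrasts (accelerated-aging group vs its
controls; longevity group vs its controls) as mean beta differences with
two-sided rank-sum p-values (Welch optional); and a sign-consistency flag —
age-hypermethylating probes must be higher in the accelerated group and
lower in the longevity group, and symmetrically for hypomethylating probes.
Strict selection requires all three p-values under their nominal levels
(default 0.05, no multiplicity correction by default — a Benjamini–Hochberg
style correction can be layered on the returned table) plus sign
consistency; ranking is by |Δ_accel| + |Δ_longevity|, ties broken by age
p-value then probe id, so results are invariant to input probe order. The
relaxed path drops the longevity contrast and is provably a superset of the
strict set. Constant probes are flagged degenerate and excluded. The trio
structure of typical accelerated-aging datasets is ignored (unpaired
contrast); a paired variant was considered and rejected because sibling
pairings are not always available.

## The simulator

Generative model per subject: age ~ Uniform(age_low, age_high);
`effective_age = age + δ_group + N(0, sd_accel)`; per CpG unit
`M = intercept + slope·effective_age + noise`, with unit noise SD 0.15 split
into a within-amplicon shared component (fraction ρ = 0.3 of variance) and
an independent remainder; beta = inverse logit of M; entries masked MCAR at
5%. Paired designs duplicate each subject one year later, carrying the same
subject-level acceleration and adding the intervention effect to the
follow-up effective age.

Default design: controls n = 278 ages 21–80 (δ = 0); accelerated-aging group
n = 62 ages 12–66 (δ = +11); centenarian-like group n = 106 ages 100–112
(δ = −6.5); longevity-offspring group n = 143 ages 55–89 (δ = −1.65);
paired intervention group n = 233 ages 65–79 with effect −0.58 years at
follow-up; sd_accel = 6 years throughout. The 70 units sit in six amplicons
of sizes (15, 21, 6, 7, 5, 16) matching the packaged assay; slopes mix signs
(60% positive) with magnitudes log-uniform in [0.005, 0.05] M/year and
baselines spread over beta 0.15–0.85, so both hyper- and hypomethylating
units exist and no unit saturates the logit clipping over ages 0–112. The
unit-model draw is fixed by an internal constant so the *panel* is part of
the default design; the cohort seed controls only the sampling of subjects
and noise.

What the simulator does **not** emulate: batch and plate effects,
cell-composition differences between groups (a known confounder of blood
methylation clocks), assay-specific mass-spectrometry artifacts, non-MCAR
dropout (real dropout correlates with CpG density and fragment mass), and
non-uniform empirical age distributions. Passing end-to-end tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to these real-data complications.

*Expected attenuation.* Because training ages carry acceleration noise, the
best linear prediction of age from methylation has slope
var(age)/(var(age)+sd_accel²) ≈ 0.89 with respect to effective age (plus a
little ridge shrinkage). Group-mean EADs are attenuated by the same factor;
the recovery tests compare group means to their simulated offsets within
three standard errors, which absorbs this bias at the default design's
sample sizes.

## Problem sizes and determinism

All shipped tests and the acceptance script run the full default designs
(up to 1,055 samples × 70 units); a complete pipeline pass takes a few
seconds on one core. Every stochastic stage (simulation, fold shuffling,
imputation order) is seeded; model files serialize floats with full
round-trip precision, so a reloaded model reproduces predictions
bit-identically.

## Known limitations

- Single imputation understates downstream uncertainty in predicted ages.
- No cell-composition adjustment of EAD; group EAD differences in real blood
  data partly reflect composition shifts.
- The clock is linear in M; pediatric ages (< 20) are excluded from training
  rather than handled by a nonlinear age transform.
- The exact rank-sum enumeration is O(C(n, n_a)) and is therefore capped at
  combined n = 12; beyond that the normal approximation is used.
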