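# Methods

`nodemri` implements a multiparametric functional-MRI analysis for
predicting whether a metastatic cervical lymph node will respond to
induction chemotherapy. The unit of analysis is a single node observed at
two timepoints (before and after two chemotherapy cycles). Nine
quantitative parameters per node per timepoint feed a diagnostic layer
that separates responding (RG) from non-responding (NRG) nodes.

## Signal models

**Monoexponential ADC.** `S(b) = S0 exp(-b·ADC)`, fitted as ordinary least
squares of `ln S` on `b` (slope = −ADC). With the two-point scheme
b = {0, 600} s/mm² this reduces to the closed form
`ADC = ln(S0/S600)/600`.

**Diffusion kurtosis (DKI).** `S(b) = S0 exp(-b·D + (1/6) b² D² K)`, with
D reported as MD and K as MK. Fitted by bounded nonlinear least squares
over (S0, D, K) with D ∈ (1e-5, 4e-3) mm²/s, K ∈ [0, 3], initialization
D₀ = ADC from the log-linear fit and K₀ = 0.5, and solver tolerances near
machine precision so noiseless decays are recovered to ≈1e-6 relative.
The kurtosis coefficient enters with the standard 1/6 factor of the
cumulant expansion. Default b-scheme: {0, 500, 1000, 1500, 2000} s/mm²;
the fitter requires ≥ 3 b-values spanning ≥ 1000 s/mm².

**IVIM.** The biexponential
`S(b) = S0 [(1−PF) exp(-b·D_slow) + PF exp(-b·D_fast)]` is fitted by the
standard segmented scheme: a log-linear fit restricted to b ≥ 200 s/mm²
gives D_slow and a zero-b intercept A, the perfusion fraction is
`PF = 1 − A/S0` (clamped to [0, 1]), and D_fast is then the 1-D
least-squares solution on the full curve with D_slow and PF held fixed,
bounded to [D_slow, 1] mm²/s. A simultaneous 3-parameter refinement
(`refine=True`) starts at the segmented solution, so its residual can only
improve; it doubles as the test oracle. Default b-scheme:
{0, 10, 20, 30, 50, 80, 100, 150, 200, 400, 600, 800} s/mm².

The segmented split assumes the fast compartment has fully decayed at the
split point. With b_split = 200 s/mm² this is accurate for
D_fast ≳ 25e-3 mm²/s (at the cohort mean 47e-3, the fast-compartment
residue at b = 200 is < 1e-4 of S0, giving D_slow errors well under 2% and
PF errors under 5%); as D_fast approaches ~10 × D_slow the approximation
degrades by construction, which is why the noiseless-recovery grid draws
D_fast from 25–80e-3 mm²/s and the node-level pipeline contract is looser
(5% / 10%).

**Tofts DCE.** The standard (non-extended) two-compartment model
`Ct(t) = Ktrans ∫₀ᵗ Cp(τ) exp(-Kep (t−τ)) dτ`, with Ve = Ktrans/Kep
always derived from the fitted rates, never estimated as a free
parameter — the ratio identity holds exactly in every output. The plasma
input Cp is a named population arterial input function; the default is the
Weinmann biexponential (a₁ = 3.99 kg/L, m₁ = 0.144/min, a₂ = 4.78 kg/L,
m₂ = 0.0111/min, dose 0.1 mmol/kg), stored as data so other presets can be
added without code changes. The convolution is evaluated by trapezoidal
quadrature on a uniform 0.2 s grid (halving the step changes sampled
concentrations by < 1e-4 relative; a single-exponential AIF has a closed
form the quadrature matches to the same tolerance) and interpolated at the
acquisition times. Fitting is bounded nonlinear least squares with
Ktrans ∈ [0, 5]/min, Kep ∈ [0.01, 10]/min, initialization (0.3, 1.0)/min.
Signal-to-concentration conversion is out of scope: the pipeline operates
on concentration-time curves directly, because no relaxivity/T1
information is available for the acquisition being emulated. The default
temporal design is 4 pre-contrast + 31 dynamic frames at 8 s spacing with
injection at t = 0 (baseline frames carry t < 0, where Cp ≡ Ct ≡ 0).

## Units and reporting scales

All computation uses base units (diffusivities mm²/s, rates /min, MK, PF
and Ve unitless). Tables and CSVs print fixed power-of-ten scales: ADC,
MD, D_slow ×1e-6 mm²/s; D_fast ×1e-4 mm²/s; MK, PF, Ktrans, Kep, Ve
×1e-3. Under these factors the printed cohort summaries correspond to
physically realistic values (MK ≈ 1.0, PF ≈ 0.2–0.26, Ve ≈ 0.7); the
conversion round-trips exactly. The PRE logistic score takes its inputs on
the reporting scale (its published coefficients are per reporting unit).

## Node analysis

Volume is slice-summation planimetry: Σ area × (thickness + gap), in cm³.
Two percent-change conventions are distinct named operations:
`pct_change = 100(post−pre)/pre` (signed; used for the parameter-change
rows) and `reduction_ratio = 100(pre−post)/pre` (positive = shrinkage;
used for tumor-volume reduction). They are never swapped silently.

RECIST 1.1 on the node's short-axis diameter: CR on disappearance, PR at
≥ 30% decrease, PD at ≥ 20% increase, SD otherwise; CR+PR form RG, SD+PD
form NRG. The default applies the percentage rules only (each node is its
own target lesion); `strict=True` additionally enforces the nodal rules —
CR below a 10 mm short axis and a ≥ 5 mm absolute increase for PD.

## Statistics

Pre-vs-post contrasts use a paired t-test, or the Wilcoxon signed-rank
test (normal-approximation Z above n = 25) when a Shapiro–Wilk test on the
paired differences rejects normality at α = 0.05. Group contrasts use the
pooled-variance two-sample t-test under the same per-group normality gate,
else Mann–Whitney U; pooled (not Welch) variance is used because it
exactly reproduces the published t-values from the printed group
summaries. 2×2 tables use Pearson χ² with optional Yates or Fisher modes.
No multiplicity correction is applied anywhere.

The composite predictor PRE is a maximum-likelihood binary logistic
regression (Newton–Raphson, tolerance 1e-8, ≤ 100 iterations) of responder
status on pretreatment PF and Ktrans; perfect separation yields a flagged
non-converged result. ROC analysis is fully empirical: AUC is the
Mann–Whitney concordance probability with half-credit for ties (and is
therefore invariant under monotone score transforms), candidate cutoffs
are the distinct observed scores under the rule "positive if
score ≥ cutoff", the reported cutoff maximizes the Youden index with ties
broken toward higher specificity, and the 95% AUC interval is DeLong's.
Likelihood ratios and predictive values derive from sensitivity,
specificity and the sample prevalence; predictive values are reported as
percentages. Observer agreement uses the single-measure, absolute-
agreement, two-way random-effects ICC(2,1) from the ANOVA mean squares;
it is undefined (NaN, flagged) when between-subject variance vanishes.

## The phantom

The generator emulates the study design: 52 responding and 42
non-responding nodes from 40 patients, two timepoints each. Per-node
parameters are drawn from truncated normal distributions whose (mean, SD)
defaults are the published group summaries — including the pretreatment
elevation of PF and Ktrans in responders, the effect that drives every
downstream diagnostic claim. Truncated-normal (not lognormal) marginals
were chosen to match the mean ± SD reporting directly. Sampling is by
inverse CDF through a Gaussian copula: marginals are exactly truncated
normal even under per-node bounds, and pre/post values share a copula
correlation of 0.5 so paired contrasts have realistic power (only marginal
summaries are published; the correlation is a design choice). Physical
constraints are enforced by the truncation bounds: D_fast > D_slow at both
timepoints, and Kep > Ktrans so that Ve = Ktrans/Kep ∈ (0, 1] holds
exactly in every node (the Ktrans marginal — the diagnostically relevant
one — is never distorted; Kep absorbs the conditioning).

Volumes draw from the published per-group pre-treatment summaries
(truncated above 0.3 cm³); the percent volume reduction draws from the
published per-group summaries, truncated so that the sphericity-derived
diameter (d = 2(3V/4π)^{1/3}) reproduces the assigned label under the
RECIST rules: a 30% diameter decrease equals a 65.7% volume decrease, so
responder reductions are truncated to [66, 99.9]% (truncated mean ≈ 80%
vs the nominal 76.85%) and stable-disease reductions to [−72, 65]%. The
non-responding group is 90% SD / 10% PD, PD nodes drawing a 20–40%
diameter increase; no CR nodes are generated by default since no CR/PR
split is published. Label/classifier agreement is exact by construction
and asserted at generation time.

Forward signals use the fitted models in reverse: multi-b decays with
Rician noise (magnitude of a complex Gaussian; the default scale 0.02·S0
corresponds to SNR 50, where the Rician mean inflation is < 0.03%) and
DCE concentration curves with additive Gaussian noise scaled to the curve
peak. Parameter maps paint each value into an ellipsoidal ROI on a 3-D
grid, optionally with multiplicative Gaussian texture, written as NIfTI-1
(mask coding 1 = ROI, 0 = background). Everything is deterministic given
the spec seed; identical spec + seed reproduce byte-identical CSVs.

**What the phantom does not emulate:** anatomical geometry, spatial
parameter heterogeneity beyond optional texture, registration or motion
artifacts, partial-volume and necrosis effects, observer variability
(the two-observer ICC operation therefore has no phantom exercise), and
patient-level covariate structure (sex, age, T stage). Passing tests show
the estimators and decision rules behave correctly under the published
effect sizes and realistic noise — not that they would reproduce any
particular patient cohort.

## Problem sizes

The default suite and the acceptance script use: 100 replicate cohorts of
94 nodes for the AUC properties; 100 random draws for noiseless
round-trip recovery; 200 noise replicates per estimator for median-bias
checks (SNR 50 for diffusion, 5% of peak for DCE). Cohort-dependent
quantities (AUCs ≈ 0.74/0.72/0.81 for PF, Ktrans, PRE; ROC cutoffs) are
reported as replicate means/medians: the patient data are not deposited,
so point reproduction of those values is not attempted, only the
property-level behaviour above.

## Known limitations

* Segmented IVIM is biased when D_fast is small relative to b_split (see
  above); the full-biexponential flag mitigates at extra cost.
* The published Δ% columns mix sign conventions; the package exposes both
  operations and reports the signed form for parameters, the reduction
  form for volumes.
* The published PRE cutoff appears in two variants (0.6624 / 0.6224);
  both are carried as named constants and neither is treated as a
  computable target.
* DeLong intervals are asymptotic; at n = 94 they are adequate but not
  exact.
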