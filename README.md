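# nodemri

Multiparametric functional-MRI analysis for predicting whether metastatic
cervical lymph nodes in nasopharyngeal carcinoma will respond to induction
chemotherapy.

Early identification of non-responding nodes lets clinicians escalate or
switch treatment before completing a full chemotherapy course. Four
quantitative MRI modalities probe the tissue at the voxel level, each
through a forward signal model with a dedicated fitter:

| Modality | Model | Parameters |
|---|---|---|
| DWI | S(b) = S₀ e^(−b·ADC) | ADC |
| DKI | S(b) = S₀ e^(−b·D + ⅙b²D²K) | MD, MK |
| IVIM | S(b) = S₀[(1−PF)e^(−b·D_slow) + PF·e^(−b·D_fast)] | D_slow, D_fast, PF |
| DCE (Tofts) | Ct(t) = K^trans ∫₀ᵗ Cp(τ)e^(−K_ep(t−τ))dτ | K^trans, K_ep, V_e = K^trans/K_ep |

Nodes are classified by RECIST 1.1 diameter rules into responding (RG:
complete/partial response) and non-responding (NRG: stable/progressive)
groups. The statistics layer then asks which pretreatment parameters
separate the groups: paired and two-sample contrasts with normality
gating, Pearson χ² for categorical tables, a logistic composite score
PRE = logistic(β₀ + β₁·PF + β₂·K^trans), and empirical ROC analysis with
Mann–Whitney AUC, Youden-optimal cutoffs, DeLong confidence intervals,
likelihood ratios and predictive values. Perfusion-related parameters
(PF and K^trans) carry the predictive signal; their combination in PRE
improves on either alone.

Because the underlying patient images are not publicly deposited, the
package ships a digital-phantom generator that reproduces the study's
statistical structure (group sizes, published parameter means ± SDs,
responder effect sizes, RECIST-consistent volume changes, Rician/Gaussian
measurement noise), so the entire pipeline is exercisable and testable
from a seed alone. See `docs/methods.md` for the models, assumptions and
design choices in detail.

## Worked example

Simulate a default cohort (52 RG + 42 NRG nodes), analyze it, and print
the diagnostic summary:

```sh
nodemri simulate --seed 5 --out run
nodemri analyze  --seed 5 --out run --cohort run/cohort.csv
nodemri report   --stats run/stats.json
```

```
cohort: 52 responding vs 42 non-responding nodes
    pf_pre: AUC 0.745 (0.646-0.843), cutoff 221.7, Youden 0.374, sens 73.1%, spec 64.3%
ktrans_pre: AUC 0.723 (0.619-0.826), cutoff 1248, Youden 0.425, sens 61.5%, spec 81.0%
 pre_score: AUC 0.785 (0.695-0.875), cutoff 0.6794, Youden 0.505, sens 57.7%, spec 92.9%
volume reduction: RG 78.78+-7.70% vs NRG 14.96+-49.76% (mann-whitney U = 2184.00, p = 1.03e-16)
```

Reading this: pretreatment perfusion fraction (PF, reporting scale ×10⁻³)
discriminates responders with AUC 0.745 at an optimal cutoff of ≈222;
K^trans alone reaches 0.723; the fitted two-predictor PRE score improves
to 0.785. Responding nodes shrink by ~79% in volume versus ~15% for
non-responders, and the Mann–Whitney U equals n₁·n₂ = 2184 — the two
groups' reductions do not overlap at all in this realization.

The same stages are available as library calls (`nodemri.pipeline.run_simulate`,
`run_fit`, `run_analyze`) and every model fitter is directly importable,
e.g.:

```python
from nodemri import dce
series = dce.DCESeries(times, concentrations, n_baseline=4)
fit = dce.tofts_fit(series)          # bounded NLS for (Ktrans, Kep)
fit.ve == fit.ktrans / fit.kep       # identity, always exact
```

`nodemri fit --signals run --seed 5 --out run` re-estimates all nine
parameters from the simulated voxel signals; with noise disabled
(`phantom: {noise_sd: 0}` in a config file) the fitted table matches the
ground-truth table to the fitters' documented tolerances.

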