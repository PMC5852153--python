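# clampkinetics

Hepatic and peripheral insulin clearance do different jobs: the liver removes
a fraction of newly secreted insulin before it ever reaches the circulation,
while muscle and other insulin-sensitive tissues clear it from plasma at a
rate per minute. Distinguishing the two from blood measurements alone is the
central difficulty in quantifying how insulin dynamics degrade on the way
from normal glucose tolerance (NGT) through borderline glycemia to type 2
diabetes (T2DM). This package implements, as a tested pipeline exercised on
synthetic cohorts, the standard modeling approach to that problem: a
four-variable ODE model of serum insulin `I` and C-peptide `CP` during
consecutive hyperglycemic (0–90 min) and hyperinsulinemic-euglycemic
(100–220 min) clamps,

```
dY/dt  = α(β(G − h) − Y)            if G > h, else −αY
dX/dt  = Y − mX                     if G > h, else Y
dI/dt  = k_ratio·mX − k_Iout(I − I_b) + f(t)
dCP/dt =         mX − k_CPout(CP − CP_b)
```

where `G(t)` is measured plasma glucose (an input, not a state), `f(t)` the
serum-equivalent insulin infusion, and the secretion flux `mX` runs only while
`G > h`. C-peptide is co-secreted equimolarly with insulin but not extracted
by the liver, so the fitted molar ratio `k_ratio` of post-hepatic insulin to
C-peptide separates hepatic clearance `(1 − k_ratio)` from peripheral
clearance `k_Iout` — per subject, from one clamp session.

The pipeline covers every stage: unit conversions and clamp forcing
construction; exact piecewise-linear simulation; per-subject estimation by
self-adaptive evolutionary programming plus piecewise-aware least-squares
refinement; AIC model selection across candidate structures; robust outlier
screening by medcouple-adjusted outlyingness; the temporal-pattern indices
`ipeak` and `iTPI` with their log-sensitivity analysis and 2⁻¹..2¹ parameter
sweeps; clinical indices (AUC_IRI10, ISI, MCR, clamp DI); and cohort
statistics (Wilcoxon rank-sum with Benjamini–Hochberg FDR, correlations). A
synthetic-cohort generator with group-structured parameter distributions
stands in for subject data, so every stage is testable offline. See
`docs/methods.md` for the model, numerics and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study shape on a
12-subject synthetic cohort (4 per glycemic group, 5% observation noise):

```
python analysis/01_simulate_cohort.py     # cohort CSVs + truth table
python analysis/02_fit_models.py          # candidate fits, AIC, outlier screen
python analysis/03_analyze_clearance.py   # indices, sensitivity, sweeps, stats
python analysis/04_cohort_statistics.py   # 20/group statistics on true params
```

`02_fit_models.py` fits three candidate structures to each subject and
prints:

```
best model per subject (AIC):
group       NGT  T2DM  borderline
best_model
model_vi      4     4           4

median |relative error| of the fitted full-model parameters:
  k_ratio  0.047
  k_Iout   0.017
  h        0.043
  k_CPout  0.108
```

The full model wins the AIC comparison for all 12 subjects over its reduced
variants (as it should — the data were simulated from it), and the fitted
clearance parameters land within a few percent of the generator's truth
despite the noise. `03_analyze_clearance.py` then ranks parameter
sensitivities of the two temporal-pattern indices:

```
parameter sensitivity of ipeak (cohort median, ranked):
 rank parameter  median
    1   k_ratio  1.0000
    2    k_Iout -0.4587
    3         m  0.4327

parameter sensitivity of iTPI (cohort median, ranked):
 rank parameter  median
    1    k_Iout  0.5881
    2         m  0.4650
    3      beta -0.4449
```

The hepatic fraction `k_ratio` is a pure gain on `I − I_b`, so its
sensitivity on the peak amplitude `ipeak` is exactly 1.00 while it leaves the
shape index `iTPI` untouched (numerical zero); the peripheral clearance
`k_Iout` is the top-ranked parameter for `iTPI` — raising it makes the insulin
curve more transient and lowers its peak. `04_cohort_statistics.py` confirms
at n=20/group that the planted group differences in `k_Iout`, `k_ratio`, `h`
and `X_b` are detected at FDR < 0.05, and that `k_Iout` tracks the clamp
insulin-sensitivity index (r = 0.96) and MCR (r = 0.81) while
`k_ratio·k_Iout` tracks the disposition index (r = 0.90).

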