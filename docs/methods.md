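# Methods

## The model

Serum insulin `I` (pM) and C-peptide `CP` (pM) during consecutive
hyperglycemic and hyperinsulinemic-euglycemic clamps are described by four
states driven by plasma glucose `G(t)` (mM, a measured input) and the
serum-equivalent insulin infusion `f(t)` (pM/min):

    dY/dt  = alpha * (beta * (G - h) - Y)        if G > h,  else  -alpha * Y
    dX/dt  = Y - m * X                           if G > h,  else  Y
    dI/dt  = k_ratio * m * X - k_Iout * (I - I_b) + f(t)
    dCP/dt =           m * X - k_CPout * (CP - CP_b)

with the secretion flux `m*X` present only while `G > h`, and initial
conditions `Y(0)=0`, `X(0)=X_b`, `I(0)=I_b`, `CP(0)=CP_b` (`I_b`, `CP_b` are
measured fasting values). `Y` is the glucose-driven provision rate feeding the
stored pool `X`; insulin and C-peptide are secreted equimolarly from `X`, but
only the fraction `k_ratio` of insulin survives first-pass hepatic extraction,
so `1 - k_ratio` is the hepatic insulin clearance. `k_Iout` and `k_CPout`
(1/min) are the peripheral clearance rate constants. Ties `G == h` take the
sub-threshold branch.

Eight quantities are estimated per subject (`alpha`, `beta`, `h`, `m`, `X_b`,
`k_ratio`, `k_Iout`, `k_CPout`), each inside [1e-6, 1e4] with `k_ratio <= 1`.

### Units and inputs

Plasma glucose enters as a right-continuous step function over the 5-min
average readings, each sampling time shifted back by 2 min (centering the
average in its window); before the first shifted breakpoint the subject is at
fasting steady state. The insulin infusion rate (mU/kg/min) converts to a
serum concentration equivalent via the insulin conversion factor 6.00 pmol/mU
and a blood volume of 75 (men) / 65 (women) mL/kg:

    cIIR [pM/min] = IIR * 6.00 / (BV * 1e-3)

i.e. 116.8 pM/min for the standard 1.46 mU/kg/min infusion in a man — the
value, with peripheral clearances near 0.2/min, that sustains the several-
hundred-pM hyperinsulinemic plateaus seen clinically. (A formula-literal
reading that drops a factor of 1000 would make the euglycemic segment
uninformative about `k_Iout`; see the unit test for the conversion.) The
infusion profile is summarized per subject by least-squares fitting
`ii1*exp(ii2*(t-100)) + ii3` to the converted trace beyond the 100-min onset,
with three starts over decaying time constants to avoid the flat local
minimum.

## Simulation

`G` is piecewise constant, so the right-hand side is piecewise linear and the
`G > h` switch can only toggle at glucose breakpoints. The reference
integrator (`clampkinetics.model.simulate`) restarts scipy's RK45 at every
breakpoint and at the infusion onset (rtol 1e-10), and carries four extra
integral states (cumulative secretion, insulin and C-peptide deviations,
infused insulin) so conservation checks need no quadrature: cumulative
secretion must equal C-peptide accumulation plus clearance exactly, and the
post-hepatic insulin flux must equal `k_ratio` times secretion.

Parameter estimation needs ~1e5 simulations per subject, so the search runs on
a numba-compiled fixed-step simulator that advances each step with exact
scalar exponentials (exponential-Euler with analytically averaged upstream
forcing). The scheme is unconditionally stable — rate constants anywhere in
the 10-decade search box relax to quasi-steady state instead of overflowing —
and second-order accurate; steps of 0.5 min (global search) and 0.1 min
(refinement) keep trajectory errors near 1e-4 and 2e-5 relative, well below
the data scales involved. The reference integrator is used everywhere accuracy
matters per se (indices, sensitivities, sweeps, conservation).

## Estimation

The objective is the residual sum of squares over the nine insulin and nine
C-peptide sampling points, each species normalized by a cohort-wide mean
concentration (computed from the cohort at hand by default; the original
study's constants 302.7 / 1475 pM are available as a fixed alternative).

Each of `n_restarts` restarts runs:

1. **Global phase** — self-adaptive evolutionary programming over
   log10-parameters: each of `n_parents` parents mutates its per-coordinate
   step sizes log-normally and its position with heavy-tailed (Cauchy) steps,
   and survivors are picked by 10-opponent tournament over parents+offspring.
   A step-size floor of 0.02 box-spans keeps the population exploring; the
   best-so-far improvement archive is retained. Desk-scale defaults are 100
   parents x 500 generations x 5 restarts; a 400 x 4000 x 20 configuration
   mirrors the original study's budget.
2. **Local phase** — bounded trust-region least squares. Because secretion
   switches at `G > h`, the objective is only piecewise smooth in `h`, with
   discontinuities wherever `h` crosses an observed glucose level; refinement
   therefore constrains `h` to its current smooth piece and profiles the
   candidate pieces explicitly (scan at piece midpoints, refine the best
   few, repeat until no piece improves). The local phase polishes the EP
   archive plus a few seeded auxiliary starts — half drawn at random, half
   from a data-driven heuristic (C-peptide decay gives `k_CPout`, the
   second-phase quasi-steady state ties `beta` and the `k_ratio`/`k_Iout`
   pair, the first-phase C-peptide rise sizes `X_b`). Without the piece
   handling, gradient refinement from random starts essentially never reaches
   the global basin on this landscape.

The best restart by RSS wins; equal-RSS ties go to the lowest restart index.
All randomness derives from `SeedSequence(master_seed, crc32(subject_id),
restart)`, so fits are reproducible and independent of cohort order.

## Model selection and outlier screening

AIC per subject is `n ln(2 pi RSS / n) + n + 2K` with `n = 18` sampling points
and `K` the candidate's free-parameter count; the minimum-AIC candidate wins,
ties preferring fewer parameters. The registry holds the full model (K=8) and
two reduced stand-ins that exist to exercise the machinery: no hepatic
extraction (`k_ratio = 1`, K=7) and no provision dynamics (`alpha`, `beta`
pinned at the lower bound, K=6; the stored pool only depletes, so no second
phase).

Outliers are screened twice — RSS alone (1-D) and the 8-parameter vector
(8-D), both in log10 since they live on multiplicative scales — by adjusted
outlyingness: project onto (default 8000) unit directions through random data
pairs; per projection score each point by its one-sided distance from the
median scaled by the medcouple-adjusted boxplot whisker
(`e^{-4MC}`/`e^{3MC}` exponents, mirrored for negative skew); take the
maximum over directions. The cutoff on the AO values themselves is
`Q3 + 1.5 e^{3MC} IQR`; the union of both screens is excluded. The parameter
screen only runs when the cohort has more subjects than parameters plus one —
below that every point is a vertex of the convex hull and projection
outlyingness is ill-posed. The medcouple
uses the O(n^2) kernel-median definition with the signed kernel for
median ties (cohorts here are small; correctness over speed).

## Indices and sensitivity

`ipeak = I(t_lmax) - I(0)` at the first strict decrease of the insulin curve
(plateaus do not end an increase), and `iTPI = (I(t_lmax) - I(t_lmin)) /
ipeak` with `t_lmin` the first subsequent strict increase: 1 is fully
transient, 0 fully sustained. On simulated trajectories the indices use the
1-min simulation grid (a 9-point clinical grid cannot localize the first-phase
peak); on measured series they use the sampling times. When no local maximum
or minimum exists the result is undefined with a reason code, never clamped.

Clinical indices follow the standard clamp formulas: incremental trapezoidal
AUC of insulin over 0-10 min (AUC_IRI10, uU/mL x min); ISI = mean glucose
infusion rate of the final 30 min / (end glucose x end insulin) x 100;
MCR = 1.46 x weight x Mosteller BSA / (end - fasting IRI); clamp disposition
index = AUC_IRI10 x ISI.

Log-sensitivities `S(f, x) = dlog f/dlog x` are central differences at
`0.9x`/`1.1x`, evaluated on the hyperglycemic window (0-90 min, no infusion)
for the six parameters shaping the insulin curve; cohort tables report the
median across subjects with defined indices, ranked by |median|, with
two-sided rank-sum P values against the top parameter (raw P values; the
corrected significance threshold is the user's concern, as the number of
tests depends on the battery). Two analytic anchors follow from the model
structure: `S(ipeak, k_ratio) = 1` exactly (pure gain on `I - I_b`) and
`S(iTPI, k_ratio) = 0` (gain invariance of a ratio) — both serve as
end-to-end checks of the simulation + index + sensitivity chain. Parameter
sweeps scale `k_ratio`, `k_Iout` or both by `2^-1 .. 2^1`; a scaled `k_ratio`
above 1 is allowed there (the bound is an estimation constraint, not a model
one).

## Synthetic cohorts

The generator emulates the clamp design: glucose ramps from fasting to the
200 mg/dL target by ~12 min, holds to 90 min, then decays to the euglycemic
target (90 mg/dL, or the fasting level if lower) with ~12-min time constant;
readings are 5-min averages with 1.5% noise. Insulin infuses at 40 mU/m^2/min
from 100 min with a decaying priming component (exactly of the `ii` form, so
the infusion fit is exercised on realizable data). The glucose infusion rate
trace is a smooth plausible curve whose euglycemic plateau is proportional to
the subject's `k_Iout` (with 10% noise), so clinical sensitivity indices carry
signal. Observations at the nine sampling times get multiplicative Gaussian
noise (default CV 5%, immunoassay-like), floored at the fasting value.

Parameters are log-normal per group. The medians are design choices tuned once
so the cohorts show the qualitative clinical picture — T2DM blunted in both
secretion phases, higher threshold `h`, smaller stored pool `X_b`; NGT with
the highest peripheral clearance and lowest hepatic extraction:

| parameter | NGT | borderline | T2DM | sigma(ln) |
|---|---|---|---|---|
| alpha (1/min) | 0.05 | 0.05 | 0.05 | 0.30 |
| beta | 15 | 13 | 10 | 0.25 |
| h (mM) | 5.0 | 5.8 | 7.0 | 0.05 |
| m (1/min) | 0.20 | 0.20 | 0.20 | 0.25 |
| X_b (pM-eq) | 2000 | 1700 | 900 | 0.25 |
| k_ratio | 0.55 | 0.42 | 0.38 | 0.18 |
| k_Iout (1/min) | 0.20 | 0.11 | 0.10 | 0.15 |
| k_CPout (1/min) | 0.05 | 0.05 | 0.05 | 0.20 |

Basal values: fasting insulin 35/55/50 pM, C-peptide 400/550/500 pM, glucose
5.0/5.9/7.3 mM (log-normal). The `k_Iout` and `X_b` spreads are narrow enough
that every draw keeps a well-defined first-phase peak and post-peak minimum
across the full 2^-1..2^1 sweep — a documented invariant of the generator.
What the generator does **not** emulate: the glucose clamp feedback controller
(G is a stylized trace, not a closed loop), within-assay correlation of
errors, two-compartment C-peptide kinetics, and any biological coupling
between parameters beyond the group structure. Passing recovery tests
therefore show that the estimator inverts the model under realistic noise and
forcing — not that the model is identifiable on real human data.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test (exact enumeration
when `n_x + n_y <= 12` without ties, tie-corrected normal approximation
otherwise) with Benjamini-Hochberg adjustment across the full battery of
parameter x pair tests; tables report medians with quartiles. Correlations are
Pearson by default (Spearman by flag) with the t-transform P value for no
correlation.

## Problem sizes and tolerances

Desk-scale runs use 20-24 synthetic subjects for sensitivity and recovery
experiments and 12-subject cohorts for the end-to-end pipeline scripts;
estimation uses the 100 x 500 x 5 configuration. Analytic identities are
asserted to 1e-6, conservation to 1e-6 relative, solver convergence to 1e-6
relative under grid refinement, exact-test equivalences to 1e-12, and
parameter recovery at 10% (noiseless) / 25% (5% noise) for the four
well-identified parameters (`k_ratio`, `k_Iout`, `h`, `k_CPout`); `alpha` and
`beta` are deliberately excluded from recovery claims — they trade off along a
provision-rate ridge and are the least identifiable parameters in this
design, mirroring their large cohort spread.

## Known limitations

- The deceptive-basin structure of the fit landscape means a restart can
  still converge to a wrong basin; with 5 restarts x (archive + 5 starts)
  roughly one subject in twenty may miss the 10% recovery bar even on
  noiseless data.
- The AO direction sampler uses random data pairs; with 8000 directions the
  scores are Monte-Carlo stable to ~1% but not deterministic across different
  seeds.
- The selection experiment only distinguishes the shipped stand-in variants;
  nothing is claimed about the original study's alternative model structures.
- Clinical indices from synthetic records inherit the generator's stylized
  GIR trace; their absolute scales are plausible but not calibrated to any
  assay.
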