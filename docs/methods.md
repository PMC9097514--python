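# Methods

## The design and its coding

The experimental object is a face-centered central composite design (FCC
CCD) over three continuous formulation factors: chitosan concentration
`CC` ∈ [0.1, 0.3] % w/v, chitosan/TPP mass ratio `CT` ∈ [3, 7] and
chitosan/drug mass ratio `CP` ∈ [0.25, 0.5]. Because the axial points sit
on the cube faces (α = 1), every factor takes exactly three levels, which
is what makes the full quadratic model estimable from 17 runs (8 corners,
6 face centers, 3 center replicates). Construction order is deterministic
(Yates-order corners, then face centers, then centers); all fitting is
order-invariant.

Factor levels were taken from the settings observed in the training
table itself (each factor visits exactly the three values above); the
coded scale is the affine map sending low/mid/high to −1/0/+1, and
`decode(code(x)) = x` exactly. Replicates are detected by exact raw-value
equality — designs are constructed, not measured, so no tolerance is
appropriate.

Encapsulation efficiency is handled internally as a **fraction**:
`EE = (D_theoretical − D_free)/D_theoretical ∈ [0, 1]`, with `D_free >
D_theoretical` treated as an assay inconsistency (an error, never
clamped). Fixture files store EE in percent, as assayed, and loaders
divide by 100; the published EE analysis-of-variance magnitudes (total
SS ≈ 0.09) are only consistent with the fraction scale, which is why the
convention is fixed here and the display layer multiplies by 100.

## Response-surface models

Each response is fitted by ordinary least squares on coded factors
(numerical conditioning; raw-unit coefficients are recovered exactly by
polynomial expansion of the affine substitution, no refit). The term
language is intercept + main effects + two-factor interactions + pure
quadratics. Effect heredity is enforced throughout: a child term
(interaction or quadratic) never appears without its parent main
effect(s). Under heredity, coded-space and raw-space fits span the same
column space, so predictions are coding-invariant; this is property-
tested.

The ANOVA reports sequential (type-I) sums of squares per term in fit
order, each tested against the full-model residual mean square; the
overall F is `(SS_model/df_model)/(SS_residual/df_residual)`. Residual
variation is split into lack of fit and pure error using the replicated
design points; with one center triplicate, pure error has 2 degrees of
freedom per response. No multiplicity correction is applied to the
per-term p-values — each response's model is reported on its own, and
that is the reporting convention this package mirrors.

The reported reduced term sets (size: CC, CT, CC·CT, CT²; PDI: CC, CT,
CC·CT; ZP: CC, CT, CP, CC·CT, CC·CP, CC²; EE: CC, CT) are shipped as the
"fixed" fitting mode, and the refits reproduce the published overall F
statistics to ≤0.5% and all 26 published test-set predicted values to
the printed decimal.

### Stepwise selection

The entry/exit rule of the original software is not recoverable, so the
selector's design was an open choice. Three observations drove it:

1. On a 17-run design with a 9-term candidate set, unadjusted
   small-sample information criteria (AICc, BIC) admit a spurious term
   in roughly half of pure-noise simulations — the best-of-nine search
   multiplicity overwhelms a per-parameter penalty of 2–3.
2. The classical p-threshold rule (enter/drop at 0.10 on partial F
   tests) has the same defect for discovery, but it is what interactive
   DOE software implements, and it is the mode that reproduces the
   published size and ζ-potential term sets verbatim from the training
   data.
3. Familywise control fixes discovery: Bonferroni-dividing the entry
   threshold by the candidate count gives ≥90% exact recovery of sparse
   generating term sets at strong signal and keeps ≥90% of pure-noise
   responses at the intercept-only model (both measured by simulation in
   the test suite).

The default is therefore the Bonferroni-entry rule (`criterion=
"bonferroni"`, enter at `p_enter/m`); `"pvalue"` (uncorrected 0.10/0.10)
is the software-compatible mode; an EBIC-flavoured criterion is also
offered, using the monotone `k·log m` form of the extended-BIC
multiplicity term because the exact `log C(m, k)` vanishes at the
saturated model and would paradoxically favour it on designs this small.
In every mode, additions bring missing heredity parents in as a group
(scored jointly) and parents are protected while a child remains.

### Validation

Five-fold cross-validation uses a seeded shuffle into folds and reports
the pooled held-out RMSE. Test-set predictivity Q² defaults to the
squared Pearson correlation between measured and predicted responses —
the quantity a measured-vs-predicted regression plot reports, and the
definition under which the size (0.77) and PDI (0.61) models clear the
0.6 predictivity bar while ζ potential (0.14) and EE (0.22) fail it,
matching the study's qualitative conclusions. The stricter external
variant `1 − Σ(y−ŷ)²/Σ(y−ȳ_test)²`, which additionally penalizes
calibration offset and can be negative, is available as
`method="press"` and is reported alongside in the validation driver
(size 0.44, PDI 0.08): the size model ranks unseen formulations well but
carries a systematic offset on the test batch.

## Desirability optimization

Each response maps to d ∈ [0, 1] by a one-sided power ramp (linear by
default, weight 1): for minimize, d = 1 at/below the best observed
value and 0 at/above the worst; mirrored for maximize; a tent function
for target goals. Bounds default to the observed training range per
response — the conventional choice when no explicit specification
limits exist — and overall desirability is the unweighted geometric
mean, so any d = 0 vetoes a candidate. Goals: minimize size and PDI,
maximize ζ potential and EE; all four responses participate even though
only size and PDI validated externally, with the inverse-target
workflow (size-targeted, PDI-minimizing) available as the
predictive-models-only alternative.

The optimizer is a deterministic 41³ grid scan over the coded cube
followed by Nelder–Mead polish from the five best cells (with one
restart each); the polished point is kept only if it improves on the
grid, so the result never falls below the scan and is bit-reproducible
for a fixed grid. Against a 101³ exhaustive oracle on random quadratic
model sets the gap is below 1e-6.

Under the default goals the optimum is CC ≈ 0.104 % w/v (the ζ-potential
surface's negative CC² term pulls it fractionally inside the low face;
the desirability surface is nearly flat there, D = 0.7376 vs 0.7366 at
the corner itself), C/T = 3 and C/P = 0.5 — the low-chitosan,
low-TPP-ratio, high-drug edge, which at two-decimal precision is the
corner (0.10, 3, 0.5).

Inverse targeting scans the same grid, keeps points whose predicted
primary response is within 1% of the target (default), and returns the
feasible point with the best secondary response, or the
nearest-achievable point flagged infeasible.

## Descriptor screening

Screening is per-pair ("row-wise"): one descriptor against one property
at a time, over all drugs with complete data, optionally excluding drugs
whose salt form would confound the gelation (a tartrate counter-ion can
itself cross-link chitosan). Forms: linear `y = a + bx`, logarithmic
`y = a + b ln x` (needs x > 0), exponential `y = a e^{bx}` estimated by
least squares on ln y (needs y > 0) with R² recomputed on the original
y scale and the F-test taken on the fitting scale, and quadratic
`y = a + bx + cx²`. Log-linearization was chosen over iterative
nonlinear least squares because it is deterministic and reproduces the
"invalid arguments" failure mode for non-positive values; domain
violations and zero-variance columns are reported as invalid cells with
reasons, never skipped. The signed R² carries the trend direction
(slope sign; Pearson sign for quadratic); cells are classed
weak/moderate/strong at |R²| 0.5 and 0.7, and quadratic cells whose
fitted vertex falls outside the observed descriptor range are flagged
as overfit risks. A permutation-null utility estimates how often n≈6
screens produce large R² by chance; per-cell p-values are deliberately
uncorrected to match the per-cell reporting convention.

The 15-descriptor panel (nAcid, nBase, nRings, nHBAcc, nHBDon, apol,
bpol, WPATH, WPOL, TopoPSA, TopoDiameter, Toposhape, ALogP, XLogP, and
molecular weight as the constitutional fifteenth — the panel is
configurable) is an *input*: descriptor computation is out of scope.
The per-drug measured properties behind the original screen are not
distributed numerically, so the screening driver runs on a synthetic
panel with planted relationships, labelled as such; the screening code
itself is exercised against those known truths.

## Synthetic data

`simulate_ccd_responses` draws `y = polynomial(coded x; truth) +
N(0, σ²)` i.i.d. per run, so center replicates carry genuine pure
error. `simulate_descriptor_panel` realizes planted
linear/log/exp/quadratic relations (descriptor values uniform on a
positive range so log/exp domains are valid), adds independent-noise
filler descriptors and optional constant columns. All randomness flows
from the single explicit seed in the truth object; regeneration is
bit-identical, and noise is homoscedastic Gaussian only — no
replicate-batch or heteroscedastic structure, because no replicate-level
data exist to calibrate one. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed model, not
robustness to instrument drift, batch effects or non-Gaussian error in
real measurements.

Simulation studies in the suite use a dominant-main-effect truth at
σ = 4.2 (the size surface's residual SD) for coverage — per-coefficient
±3-true-SE coverage ≥99% over 1000 replicates — and a strong sparse
truth (σ = 2) for term-set recovery (≥90% over 200 replicates); the
"±3 SE" convention is per coefficient estimate against the true
sampling SE, since joint-per-replicate coverage with estimated SEs is
bounded near 95% by the t-distribution itself.

## Known limitations and recorded discrepancies

- The published lack-of-fit rows report 8 pure-error degrees of freedom
  per response, which cannot arise from 17 runs with a single center
  triplicate (df 2); replicate preparations beyond the printed design
  were presumably used. This package computes pure error from the
  replicates actually present and makes no attempt to reproduce those
  rows.
- The published final-formulation predictions (68.9 / 102.3 / 200.1 nm;
  PDI 0.211 / 0.231) are inconsistent with the reported reduced models:
  the same setting (CC 0.15, C/T 3) appears as 99.4 nm in the test-set
  table and 102.3 nm in the final-formulation table. All 26 test-set
  predicted values match this package's refits to the printed decimal,
  so the final-formulation numbers evidently came from a different
  (full-surface profiler) model; this package evaluates the reported
  reduced models and documents the gap rather than switching models per
  table.
- Desirability shapes and bounds beyond "minimize size/PDI, maximize
  ZP/EE" are not specified anywhere recoverable; the linear-ramp,
  training-range defaults reproduce the published optimum at printed
  precision, but the optimum's exact interior CC is sensitive at the
  third decimal to those choices.
- Dissolution/release kinetics, instrument characterization and
  descriptor computation are out of scope; mixture constraints, blocked
  or D-optimal designs, robust regression and response transformation
  are not implemented.
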