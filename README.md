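# formurs

Design-of-experiment analysis of chitosan–tripolyphosphate (TPP) nanogel
formulation, built for formulation scientists who want the full workflow —
designed experiment → response-surface models → multi-response optimum →
external validation → descriptor screening — as tested, reproducible code
rather than point-and-click software.

Chitosan/TPP nanogels form by ionic gelation: the polycation chitosan is
cross-linked by the polyanion TPP, entrapping a drug (here propranolol) in
the gel network. Three formulation factors control the product — the
chitosan concentration `CC` (% w/v), the chitosan/TPP mass ratio `C/T` and
the chitosan/drug mass ratio `C/P` — and four responses characterize it:
hydrodynamic size (nm), polydispersity index (PDI), ζ potential (mV) and
encapsulation efficiency (EE, stored as a fraction).

## What the package computes

**Design.** A face-centered central composite design (FCC CCD): for k
factors, 2^k factorial corners (coded ±1), 2k face centers (α = 1) and
replicated center points; for k = 3 with 3 centers, the 17-run training
design. Raw and coded units relate by `coded = 2(raw − mid)/(high − low)`.

**Models.** Quadratic response surfaces fitted by OLS on coded factors,

    y = β₀ + Σᵢ βᵢ xᵢ + Σᵢ<ⱼ βᵢⱼ xᵢxⱼ + Σᵢ βᵢᵢ xᵢ² + ε,

with stepwise selection under effect heredity, sequential-SS ANOVA with a
lack-of-fit / pure-error split from the replicated centers, five-fold
cross-validation and test-set Q².

**Optimization.** Derringer–Suich desirabilities: each response is ramped
onto d ∈ [0, 1] against its goal, and the overall desirability
`D = (d₁ d₂ ⋯ d_m)^{1/m}` is maximized over the factor cube by a
deterministic grid scan with local polish. Inverse problems (hit a target
size while minimizing PDI) use a constrained scan of the same grid.

**Screening.** Per-pair correlation of nanogel properties with molecular
descriptors across drugs under linear, logarithmic, exponential and
quadratic forms, reporting signed R² grids with F-test p-values.

**Synthetic data.** Seeded generators for CCD responses (known polynomial
plus Gaussian noise) and descriptor panels with planted relationships, so
every stage is testable against ground truth.

The 17-run training table and 13-run test table ship as packaged CSV
fixtures, so everything runs offline.

## Worked example

```python
import formurs as f

train = f.load_training_design()
size = f.fit_ols(train, f.ModelSpec.from_strings("size", f.REPORTED_TERM_SETS["size"]))
print(f.anova(size, train).to_text())
```

prints the size-model ANOVA (F = 649.04 on 4 and 12 df; the chitosan
concentration alone carries SS 46 444 of the 47 021 total — particle size
is almost entirely a chitosan-concentration effect):

```
     source  df     sum_sq    mean_sq         F       p
      model   4 46804.8968 11701.2242  649.0404 <0.0001
         CC   1 46444.2250 46444.2250 2576.1558 <0.0001
         CT   1     0.5290     0.5290    0.0293  0.8668
      CC:CT   1   182.4050   182.4050   10.1176  0.0079
       CT^2   1   177.7378   177.7378    9.8587  0.0085
   residual  12   216.3420    18.0285
lack_of_fit  10   196.4553    19.6455    1.9757  0.3825
 pure_error   2    19.8867     9.9433
      total  16 47021.2388
```

Running the optimizer (`python analysis/03_optimize_formulation.py`):

```
Optimum: CC = 0.104 % w/v, C/T = 3.00, C/P = 0.500  (overall D = 0.7376)
  size: predicted   69.997 nm  d = 0.913
   PDI: predicted    0.218     d = 0.996
    ZP: predicted   25.372 mV  d = 0.514
    EE: predicted   30.003 %   d = 0.633
```

i.e. the best compromise formulation uses the lowest chitosan
concentration, the lowest chitosan/TPP ratio and the highest drug ratio:
~70 nm, narrowly dispersed particles, at the cost of middling surface
charge and encapsulation.

The numbered scripts under `analysis/` run the stages in order
(fit → validate → optimize → screen → recovery study) and write their
tables to `results/`.

## Layout

- `src/formurs/` — library: `design_space`, `response_surface`,
  `desirability`, `descriptor_screen`, `synthetic`, `workflow`, `cli`,
  packaged fixtures under `data/`
- `analysis/` — numbered narrative drivers
- `tests/` — pytest suite (unit, property-based and reproduction tests)
- `docs/methods.md` — modeling assumptions, conventions and limitations

A `formurs` console script exposes the stages
(`formurs design|fit|optimize|target|screen|simulate|run`); see
`formurs --help`.
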