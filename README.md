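# grainfill

Kinetics of dry matter and mineral element accumulation in developing rice
grain.

During grain filling (~5–30 days after fertilization, DAF), a rice grain
loads dry matter and a panel of mineral elements — macronutrients (N, P, K,
S, Ca, Mg), micronutrients (Fe, Mn, Cu, Zn, B, Mo) and non-essential
elements (As, Cd) — each on its own schedule. `grainfill` is a toolkit for
analysing replicated grain-filling time courses: it fits accumulation
kinetics, classifies elements by when their loading rate peaks, budgets how
much of each element was remobilized from vegetative tissues, and mines the
grain transcriptome time course for significant temporal expression
profiles. A built-in simulator generates study-shaped data with known
ground truth, so every stage can be validated end to end.

## The models

**Accumulation kinetics.** Content per grain W at time x (DAF) follows the
three-parameter logistic curve

    W(x) = a / (1 + exp(-k (x - x_c)))

with asymptotic content `a`, growth rate `k` (d⁻¹) and inflection time
`x_c`. The accumulation rate is the first derivative

    dW/dx = a k e^(-k(x-x_c)) / (1 + e^(-k(x-x_c)))²,

symmetric about `x_c` and maximal there with peak value `a·k/4`. Elements
are classified by where this peak falls relative to the sampling window
[t_first, t_last]: **early** (peak at or before t_first — K, B, Mn, Ca
behave this way), **mid** (inside the window, tracking dry matter — N, P,
S, Mg, Cu, Zn, Mo, As, Cd), or **sustained** (still rising at t_last — Fe).

**Redistribution budget.** For tissue i (grain, flag leaf, node I), the net
accumulation over filling is ΔCᵢ = C30ᵢ − C5ᵢ; a negative value marks the
tissue as a source. Each source tissue's contribution ratio to the grain is
Rᵢ = |ΔCᵢ| / C30_grain × 100 (%), and the remainder
100 − ΣRᵢ is attributed to other sources (stem transport, continued root
uptake).

**Temporal expression profiles.** Stage-mean FPKM trajectories are reduced
to log₂ ratios against the first stage, filtered at |log₂ ratio| ≥ 1, and
matched to a library of m = 20 model profiles selected from all integer
templates with bounded unit changes (STEM-style short time-series mining).
Profile membership is tested against the exact permutation null over all
T! time orderings, with binomial tail p-values and Bonferroni control.

## Worked example

```python
from grainfill import fit_logistic
from grainfill.simulate import ElementArchetype, simulate_grain_series

arch = ElementArchetype("N", "mid", a=160.0, k=0.30, x_c=13.0,
                        unit="ug", noise_cv=0.05)
series = simulate_grain_series(arch, seed=42)   # 7 DAF x 4 replicates
res = fit_logistic(series)
print(res.summary())
```

```
Logistic accumulation fit
========================================
converged: True   nobs: 28
 a (asymptote):      159.785  (SE 1.54)
 k (rate, d-1):     0.308384  (SE 0.01163)
     x_c (DAF):      12.9651  (SE 0.1432)
     R-squared:     0.995413
   residual SD:      3.97357
     peak rate:      12.3188 at 13 DAF
```

The fit recovers the planted parameters (a = 160 µg, k = 0.30 d⁻¹,
x_c = 13 DAF) from 5%-CV noisy replicates: nitrogen loading peaks at
~13 DAF at ~12.3 µg d⁻¹ per grain, i.e. this element follows the
mid-accumulation pattern of dry matter. `res.rate_curve(grid)` evaluates
the rate curve, `res.conf_band(grid)` gives the pointwise 95% t-band of
the mean curve.

## Command line

```bash
grainfill simulate --scenario full --seed 1 --out data/
grainfill all --content data/contents.csv \
              --budget data/budget_contents.csv \
              --expression data/expression.tsv \
              --seed 1 --out results/
```

`simulate` writes tidy content tables, multi-tissue budget tables and an
FPKM matrix (with ground-truth sidecars); `all` runs fit → classify →
budget → trend (→ spatial, when a panicle-position table is given) and
writes per-stage CSV/TSV tables plus `summary.json`. Identical inputs and
seed reproduce byte-identical outputs.

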