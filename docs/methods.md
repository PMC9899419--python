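# Methods

This note documents the models implemented in `grainfill`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Logistic accumulation kinetics

Content per grain W(x) at x DAF is modelled as
`W(x) = a / (1 + exp(-k (x - x_c)))` with a > 0 (asymptotic content, in the
element's own unit), k > 0 (growth rate, d⁻¹) and x_c (inflection, DAF).
The accumulation rate is the analytic first derivative; it is symmetric
about x_c, peaks there at a·k/4, and integrates to a over the whole
transition — properties the tests verify against quadrature and fine-grid
argmax.

**Fitting.** Nonlinear least squares (trust-region reflective with analytic
Jacobian) on all replicate observations, unweighted. Fitting at replicate
level rather than on stage means uses all information and yields honest
residual degrees of freedom for the bands. Starting values: a₀ = 1.05 ×
max(W); x_c₀ where the interpolated stage means cross a₀/2 (one day outside
the window when the crossing is unobserved); k₀ from the slope of
logit(W/a₀) against x. Bounds: a ∈ (0, 10·max W], k ∈ (0, 5], x_c ∈
[t_first − 30, t_last + 30] — the wide x_c bounds are required because
early- and sustained-pattern elements invert outside the sampling window.
Convergence: relative parameter tolerance 10⁻⁸, at most 500 iterations
(2000 residual evaluations). Non-convergence — including constant series,
for which k is unidentifiable — is reported via a `converged=False` results
object, never an exception; downstream quantities (rate curve, peak, bands)
refuse to compute from a failed fit.

**Uncertainty.** Parameter covariance is the linearized (Gauss–Newton)
estimate s²(JᵀJ)⁻¹. Pointwise confidence bands for the mean curve use the
delta method with the t quantile at the fit's residual df; coverage of the
true curve at interior DAF is checked by simulation (400 replicates,
90–99% observed for a nominal 95% band).

## Pattern classification

Because the logistic rate always peaks at x_c, the three accumulation
patterns reduce to comparing x_c with the sampling window: early if
t_peak ≤ t_first, sustained if t_peak ≥ t_last, mid otherwise. Window-edge
ties resolve outward (early/sustained) — the rate is already falling
(resp. still rising) throughout the observed window in those cases. The
window rule is an explicit formalization of what is otherwise judged
visually from rate curves. For mid elements the offset from dry matter,
t_peak(element) − t_peak(dry matter), is reported as a signed number of
days rather than as sub-classes.

When the logistic fit fails, an empirical fallback classifies the
finite-difference rates between successive stage means: *early* requires
the largest rate in the first interval **and** a decreasing rank trend
(Spearman ρ ≤ −0.5); *sustained* is the mirror image; everything else is
mid. The ρ threshold alone is not enough: a mid hump whose peak sits in
the first half of the window has mostly decreasing rates and would
otherwise be mislabelled early. Both the threshold (±0.5) and the
peak-interval requirement are package choices, recorded in the output's
`basis` column (`fitted` vs `empirical-fallback`).

## Redistribution budget

Net accumulation ΔCᵢ = C30ᵢ − C5ᵢ is computed from replicate means of the
observed contents at 5 and 30 DAF, not from fitted curves — the budget is
defined on measured endpoints. Tissues with ΔCᵢ < 0 are sources and get
contribution ratio Rᵢ = |ΔCᵢ| / C30_grain × 100; tissues with ΔCᵢ ≥ 0 are
sinks and get Rᵢ = 0 (applying the absolute-value formula to a sink would
count an inflow as a contribution). "Other sources" is the remainder
100 − ΣRᵢ(sources), a bookkeeping quantity, floored at zero with a warning
when nominal source losses exceed the grain's content (possible when part
of the exported element goes elsewhere than the grain). Ratios are
invariant to rescaling all contents by a positive constant; units are
never converted across the four content scales (mg, µg, ng, pg per grain).

## Temporal expression profiles

The transcriptome design is five stages (5, 9, 13, 17, 21 DAF) × 3
replicates. FPKM is count·10⁹/(length·library size). Replicates are
averaged per stage before ratios; the analysis operates on stage-level
trajectories. Log₂ ratios are taken against the first stage with a
pseudo-value ε = 1 FPKM (configurable) so silent genes are defined; the
first ratio column is identically zero. Genes pass the filter when
max_t |e_gt| ≥ 1 log₂ unit (inclusive; monotone in the threshold).

**Model profiles.** All integer templates of length T starting at 0 with
successive changes in [−c, c], excluding the flat profile —
(2c+1)^(T−1) − 1 candidates; defaults c = 2, T = 5 give 624. From these,
m = 20 representatives are selected greedily under d = 1 − Pearson r of
the value vectors: seed with the most distant pair, then repeatedly add
the candidate maximizing its minimum distance to the selected set.
Distances within 10⁻⁹ are treated as tied (exactly anticorrelated pairs
differ only by floating-point noise) and all ties resolve to the
lexicographically smaller profile; selected profiles are renumbered
0..m−1 in lexicographic order, so profile ids are reproducible. The
monotone-decreasing extreme (0,−2,−4,−6,−8) is always id 0. `c` and `m`
are exposed in the run configuration.

**Assignment and significance.** Each filtered gene goes to the profile
maximizing Pearson correlation with its ratio vector (ties → lowest id;
constant vectors are unassignable and excluded with a logged count). The
null permutes the time order of each gene's stage means; since
log₂((F_s+ε)/(F_r+ε)) = e_s − e_r, permuted ratio vectors are derived
directly from observed ones. Expected profile size is the mean assigned
count over all T! = 120 permutations (exact mode, default; a seeded
sampled mode exists for T > 7). The p-value is the binomial tail
P(X ≥ observed | n genes, expected/n), Bonferroni-corrected over the m
profiles. The filtered gene set is held fixed across permutations. On
planted data, the three planted shapes (monotone decreasing, monotone
increasing, mid-peaking) surface as exactly three significant profiles.

**Supporting views.** Sample PCA operates on log₂(FPKM+1), gene-centered.
Hierarchical clustering of (row-)Z-scored matrices uses average linkage
with Euclidean distance by default; correlation distance is available as
an option since "Euclidean" vs "correlation" is a genuinely open choice
for expression heat maps. Zero-variance rows are excluded with a warning;
a Newick rendering of the dendrogram is provided.

## Group statistics

Z-scores use the sample (n−1) SD, giving exactly zero mean and unit SD
(checked to 10⁻¹²). Regressions of grain values on panicle position
(labels A–G encoded as equally spaced ranks 1–7 — the minimal metric
assumption) or on seed-setting rate (50/75/100%) are ordinary least
squares on replicate values, with the Pearson r, its two-sided t-test,
and a pointwise t confidence band for the mean response. One-way ANOVA is
followed by Tukey HSD (Tukey–Kramer standard error for unequal n) and a
compact letter display built by insert-and-absorb over means sorted
descending: groups share a letter exactly when Tukey does not separate
them. No multiple-testing correction is applied across elements.

## Synthetic data generator

The generator emulates the study design: 7 sampling times (5, 9, 13, 17,
21, 25, 30 DAF) × 4 replicates for element contents; 5 stages × 3
replicates for expression; tissues grain, flag leaf and node I.

* **Element contents** follow exact logistic trajectories times
  multiplicative lognormal noise with a given CV (mean-1 factors);
  contents are positive and replicate scatter on positive measurements is
  naturally multiplicative. The default CV is 0.10; recovery experiments
  use 0.05, a tight but realistic replicate CV for pooled-grain element
  determinations.
* **The 14-entry default panel** (dry matter + 13 elements) plants 4
  early, 9 mid and 1 sustained archetype with asymptotes chosen so peak
  rates fall on realistic per-grain scales (e.g. dry matter 18 mg ×
  0.30 d⁻¹ / 4 = 1.35 mg d⁻¹ at 13 DAF; N peaking ≈ 12 µg d⁻¹). Random
  archetypes draw x_c from (1, 4.5), (9, 21) and (30.5, 40) for
  early/mid/sustained: inflections sit clearly inside or outside the
  window, not on its knife edge, mirroring the panel.
* **Budget scenarios** plant per-tissue loss fractions relative to the
  grain content at the end of filling, so the assembled budget recovers
  the fractions exactly at zero noise; negative fractions create sink
  tissues (rising content).
* **Expression** plants genes on integer shapes at 2^shape fold changes
  over a log-uniform baseline (10–200 FPKM) with lognormal noise
  (default CV 0.10); null genes are flat plus noise, hence
  time-exchangeable. Ground truth is always emitted alongside.

What the generator does **not** emulate: read-count sampling
(negative-binomial dispersion, library-size imbalance), correlated
replicate effects, element detection limits, within-panicle covariance
between elements, and tissue trajectories more complex than linear
gain/loss. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
feature of field data.

## Problem sizes and determinism

All randomness flows from integer seeds through `numpy`'s `SeedSequence`;
equal seeds give byte-identical written outputs (fixed `%.10g`
formatting). The validation suite uses 200 series for parameter recovery,
150 elements (50 per archetype) for pattern recovery, 1000
time-exchangeable genes for null calibration of profile significance,
10,000 null replicates for the regression type-I rate, and a full bundle
of 14 elements / 3 tissues / 5000 genes for the end-to-end determinism
check; these sizes make every check reproducible on a single CPU in a few
minutes.

## Limitations

* One growth law: no Gompertz/Richards alternatives, no mixed-effects
  pooling across elements.
* The empirical fallback classifier is deliberately crude; it exists for
  series the logistic cannot fit, and its label is marked as such.
* "Other sources" in the budget is a remainder, not a measurement, and
  inherits all endpoint noise.
* Exact permutation significance assumes genes are independent given the
  stage means; co-expression inflates the effective signal of large
  profiles.
* FPKM is used as the expression unit throughout; no TPM or
  count-model alternative is offered.
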