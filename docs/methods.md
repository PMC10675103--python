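# Methods

## Model

`fuzzygrowth` models five biometric responses of a crop (leaf number and
fresh/dry shoot and root biomass) as functions of two crisp inputs —
sampling time in days after transplanting (DAT ∈ [14, 35]) and irrigation
level as a percentage of crop evapotranspiration (IL ∈ [25, 125] % ETc) —
with one independent Mamdani system per (water source, cycle) slice, four
systems in a full two-cycle experiment.

### Partition construction

Input universes are covered by trapezoids on the breakpoint grid
`x_j = x_min + j·k`, `j = −1 … 2n`, with spacing
`k = (x_max − x_min)/(2n − 1)`; set *i* is the trapezoid
`(x_{2i−3}, x_{2i−2}, x_{2i−1}, x_{2i})`. The outermost feet extend one
spacing beyond the universe, every design anchor (the five irrigation
levels, the four sampling days) attains membership 1 in exactly one set,
and adjacent ramps share their two endpoints, which makes the partition a
partition of unity: at any interior point the memberships sum to exactly
1 and at most two sets are active. For five level sets k = 11.11 % ETc;
for four DAT sets k = 3 days.

Output universes are data-driven. Twenty percentile levels
`0, k, 2k, …, 19k` with `k = 100/19 ≈ 5.26 %` are evaluated on the
empirical distribution of the response (linear interpolation between
order statistics — the most common quantile rule; it is recorded in the
model file). Output set *m* (of ten) is the trapezoid over delimiters
`2m−3 … 2m` on that level grid; the first set's lower foot is extended
below the minimum by `P(k) − P(0)` and the last set's upper foot above
the maximum by `P(100) − P(100−k)`, mirroring the one-spacing extension
used for the input partitions. Percentile levels are kept as exact
fractions `j·100/19` rather than the two-decimal display values.

The percentiles are computed from the slice's **20 cell means** — the
same quantities that drive rule induction. Twenty values exactly satisfy
the partition's minimum-data requirement, and using means keeps the
output sets, the rules, and the evaluation on one consistent scale.

### Rule induction

One rule per design cell: the antecedent is the (DAT set, level set)
pair whose anchors define the cell, and the consequent for each variable
is the output set in which the cell mean attains its greatest
membership. Because adjacent output ramps share endpoints, that
classification reduces to delimiter comparisons with the transition-band
midpoint as the boundary; exact midpoints resolve to the lower set
index. This midpoint form is used instead of a floating-point argmax of
memberships, which cannot honour exact ties (the two ramp evaluations
differ by an ulp). Classification is monotone — a larger value never
maps to a lower set — and total over the real line via clamping at `C1`
and `C10`.

### Inference and defuzzification

Classical Mamdani: firing strength = min of the two antecedent
memberships; each fired consequent set is clipped at the strength (min
implication); clipped sets are aggregated by max; the crisp output is
the discrete centroid `Σ μ(x)·x / Σ μ(x)` on a uniform grid of
`defuzz_resolution` points (default 1001) spanning the output universe
from `C1`'s lower foot to `C10`'s upper foot. Crisp inputs are clipped
to the modelled rectangle; the model deliberately does not extrapolate
beyond the fuzzy-set supports. Inference is vectorised over input grids
and a point query is the 1 × 1 case of the same code path, so simulated
surfaces and `infer` calls agree bit-for-bit. Surfaces are simulated at
a configurable step (0.1 by default: 211 × 1001 nodes) and
`find_optimum` takes the grid argmax with ties resolved row-major
(smallest DAT, then smallest IL).

Numerical notes: at resolution 1001 the discrete centroid of a single
consequent trapezoid is within one grid step of the analytic centroid,
and at anchor inputs — where exactly one rule fires at full strength —
the crisp output deviates from the true cell mean by at most half the
consequent set's support width plus one grid step (the 10-bin
quantization bound). Doubling the resolution moves any output by well
under 1 % of the output span.

## Screening

Before modelling, each (variable, water, cycle) slice is screened:
Anderson–Darling on the pooled within-cell residuals (raw values are a
mixture across cells whose means differ by design, so residuals are the
meaningful test target) and Bartlett's test across the 20 design cells
(≥ 2 replicates per cell required). If either rejects at α (default
0.05), a Box–Cox transform is applied with λ maximising the profile
log-likelihood over the grid [−2, 2] in steps of 0.01 (ties to the
smaller λ); λ = 0 is the natural-log limit. Noise-free data make both
tests degenerate and raise an explicit error. No multiplicity correction
is applied across the five variables.

## Baseline regression

Per (water, cycle) slice, OLS on the seven-term additive cubic in IL and
DAT (no interactions), with R², the overall F test, and two-sided
t tests per coefficient at α = 0.05. The design needs ≥ 9 observations
and ≥ 4 distinct values of each input, and full column rank. A pooled
mode fits one model to all slices with a binary water dummy (CW = 0,
MW = 1) instead; the per-slice form is the default because it matches
the reported per-surface structure of this kind of trial.

## Evaluation

Models are scored against the 20 cell means of their slice (a
replicate-level mode exists behind a flag) with MSE, Pearson r (its
two-sided significance is reported alongside), and the Willmott index of
agreement `d = 1 − Σ(p−o)² / Σ(|p−ō| + |o−ō|)²` with ō the observed
mean — d = 1 for a perfect model, d = 0 for a constant-at-mean
predictor. The comparison table has one row per (variable, water, model,
cycle): 40 rows for a full run.

## Synthetic data generator

The generator emulates the 5 × 2 factorial design: irrigation levels
25–125 % ETc × water source (MW/CW), samplings at 14/21/28/35 DAT, four
replicates, two cycles. The cell mean is

```
asymptote[v] · logistic(DAT; rate, midpoint)
             · max(0, 1 − curvature·(IL − optimum)²)
             · (water_gain if MW else 1)
```

Defaults: rate 0.25 d⁻¹ and midpoint 24.5 DAT (half-maximal growth
mid-cycle); optimum 100 % ETc with curvature 1e-4 (% ETc)⁻² (mild
deficit/excess penalty, ~44 % response loss at 25 % ETc); water gain
1.15 (a moderate advantage of treated water); asymptotes 30 leaves and
250/30/12/3 g for FSB/FRB/DSB/DRB, typical of mature greenhouse
lettuce; noise 8 % of the cell mean. Symmetric noise is
mean-proportional Gaussian; the right-skewed family is multiplicative
lognormal with matched mean and coefficient of variation, giving a
regime where Box–Cox is actually needed. Leaf counts are rounded to
integers; biomass is truncated at zero. A single integer seed drives one
explicit generator instance.

What the generator does **not** emulate: evapotranspiration dynamics and
weather, plot/spatial correlation, replicate-level measurement error
structure of real instruments, or cycle-to-cycle heterogeneity beyond
the shared mean surface. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline on data with the
assumed factorial structure, not agronomic validity on any particular
field data set.

Two special configurations matter for testing. A *flat* configuration
(curvature 0, water gain 1, rate ≈ 0) yields a constant mean surface and
hence i.i.d. equal-variance Gaussian replicates — the proper null for
calibrating the screening and F tests, since the default
mean-proportional noise is heteroscedastic across cells by construction.
A *strongly non-cubic* configuration (curvature 2e-4, so the irrigation
response clips to zero at 25 % ETc) produces a kinked, product-form
surface that the additive cubic cannot represent; on it the fuzzy model
consistently attains lower MSE and higher d — the structural behaviour
the comparison framework is designed to expose.

## Design choices and limitations

- Problem sizes in the tests: null calibration uses 500 single-cycle
  simulations; surface checks run one full 211 × 1001 surface at
  resolution 1001; comparison checks use three fixed seeds. A full
  pipeline run (two cycles, five variables) takes a few seconds.
- One rule base per (water, cycle) keeps the four surfaces independent;
  pooling across cycles would require a cycle input variable, out of
  scope here.
- Rule bases are induced once from cell means; no pruning, weighting or
  optimisation.
- The fuzzy model quantizes: its best-case accuracy at the anchors is
  limited by the 10-bin output partition, which is why evaluation
  against training means yields d close to, but not exactly, 1.
- Inputs outside [14, 35] × [25, 125] are clipped rather than rejected;
  predictions at the boundary are held, not extrapolated.
- All artifacts serialize to JSON/CSV with 17 significant digits, so a
  rerun from the same seed reproduces outputs byte-identically.
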