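# Methods

## Scope and data model

`metstab` analyses balanced multi-environment trials: g genotypes × e
environments × r replicates, one observation per (genotype, environment,
replicate) triple, laid out as a randomized complete block design within
each environment. Balance is enforced at load time and unbalanced data are
rejected rather than imputed: the ANOVA degrees of freedom and the exact
orthogonality of the sum-of-squares decomposition presuppose a complete
layout, and silent imputation would change every downstream SS. Genotype and
environment order is first-appearance order in the input so that score
tables align with the user's file; all outputs carry explicit labels.
Values are carried at full float precision end to end; rounding happens only
in the report layer (parallel `*_2dp` columns).

## ANOVA

For the RCBD-across-environments layout the strata are Environment (df
e−1), Rep(Environment) (e(r−1)), Genotype (g−1), GEI ((g−1)(e−1)), and the
pooled residual (e(g−1)(r−1)); their SS are the standard balanced-design
deviation sums and add exactly to the total SS. The F ratio for Environment
uses the Rep(Environment) mean square as denominator — the conventional
test when blocks are nested in environments — while all other effects are
tested against the pooled residual. p-values come from `scipy.stats.f`;
stars mark 0.05/0.01/0.001.

The interaction principal components are the SVD axes of the doubly-centered
cell-mean matrix; axis k carries SS r·λ_k² (the PC rows partition SS_GEI
exactly) and is tested with Gollob df g+e−1−2k against the residual mean
square. No cross-validation or FR-type axis selection is provided.

%SS accounting: main strata are expressed as a share of the five-strata
total (Environment + Rep(E) + Genotype + GEI + Residuals); PC rows as a
share of SS_GEI. The signal/noise partition sets SS_noise = df_GEI ×
MS_residual, clamped to SS_GEI with a warning when the interaction is
smaller than its pure-error expectation, and SS_signal = SS_GEI − SS_noise.

## Numerical conventions

* **SVD sign**: each axis is oriented so the genotype singular-vector entry
  of largest magnitude is positive. This makes results deterministic across
  linear-algebra backends (an SVD is only defined up to per-axis sign).
* **Spectrum clamping**: singular values below 1e−10 × the cell-mean
  magnitude are set to exactly zero, so purely additive data yield an
  exactly zero interaction, zero scores and zero MASI instead of
  rounding-noise values.
* **Score scaling**: reported IPCA scores are symmetrically scaled
  (singular-vector entry × √λ); the raw orthonormal vectors are also kept on
  the fit. MASI ranks are unaffected by any common rescaling (see below).
* **Ranks**: integer ranks 1..g, best first; exact ties get consecutive
  ranks broken by input order and are flagged in the output, because
  biplot/stability packages differ silently on this point and published
  tables print integer (not fractional) ranks.

## Stability indices

MASI_i = √(Σ_{n≤N′} PC_in²·θ_n²) with θ_n = λ_n²/Σλ² the proportion of
interaction SS on axis n. θ is used as a proportion (0–1); MASI is
positively homogeneous in θ, so using percentages instead would rescale
every MASI by the same factor and cannot change a rank or SSI — a property
under test. N′ defaults to all K = min(g−1, e−1) axes (with e = 3 only two
exist); an override supports significance-filtered variants. SSI adds the
MASI rank to the performance rank of the genotype's marginal mean (under
balance this is the least-squares adjusted mean); the minimum-SSI
genotype(s) are reported as selected.

The published reference table shipped in `metstab.reference_data` prints
MASI at 2 decimals; its ranks were computed by the original authors from
unrounded values. Where printed values are exactly tied (three RUE MASI
groups), the printed within-tie order is not a function of the printed
table, so re-derived ranks can only be guaranteed to match where the
printed columns determine them — the corresponding strict full-table test
documents this as an expected discrepancy of 4 entries for RUE.

## GGE biplots

Defaults are locked to the standard protocol for yield-trial biplots: no
transformation, no scaling, environment centering (the analysed matrix is
C_ij = ȳ_ij − ȳ_·j, i.e. genotype main effect + interaction), and
column-metric-preserving singular-value partition (svp = 2: environments
get λ·v, genotypes the bare u). Both partitions reproduce the same rank-2
approximation C ≈ G·Eᵀ. The 2-D explained share is 100(λ₁²+λ₂²)/Σλ².

* **Which-won-where**: convex hull of genotype points (`scipy.spatial`);
  the winner of an environment is the hull vertex maximizing the dot
  product with its vector (for exactly rank-2 data this equals the column
  argmax of C). An environment lying exactly on a sector boundary goes to
  the counter-clockwise sector: among dot-product-tied vertices, the one
  reached by the largest CCW rotation from the environment vector. Data
  whose centered matrix is effectively rank 1 (collinear points) raise a
  geometry error rather than an arbitrary sectoring.
* **Mean vs stability**: the AEC abscissa is the unit vector toward the
  mean environment coordinate; projection = mean-performance proxy,
  |perpendicular component| = instability.
* **Discriminativeness vs representativeness**: vector length and cosine to
  the AEC axis. The type-1/2/3 classification (type-2 = length ≥ median and
  cos ≥ cos 45°; type-3 = long but unrepresentative; type-1 otherwise) is
  this package's operationalization of qualitative descriptions in the
  biplot literature; both thresholds are configurable arguments.
* **Ideal genotype**: the point on the AEC axis at the maximum observed
  projection; genotypes are ranked by Euclidean distance to it.

Plotting (`metstab.plotting`) is a thin optional matplotlib layer; every
analysis result exists as a plain table, so nothing downstream parses
images.

## Synthetic generator

`generate_met` draws from exactly the model the analysis fits. Design
choices that matter:

* Interaction score vectors are centered then orthonormalized (QR), so the
  planted multiplicative term has zero row/column sums — a valid
  interaction that cannot leak into main effects; with zero noise the fit
  recovers μ, G, E to machine precision and the λ spectrum exactly.
* Main-effect vectors are centered draws rescaled to sum of squares exactly
  (n−1)·sd²: random direction, deterministic magnitude. With e = 3 a raw
  χ²₂-distributed environment SS would dominate the run-to-run variance of
  the %SS shares; fixing the magnitude makes expected shares equal the
  configured ones without changing what the analysis can be tested on.
* Replicate effects are drawn per (environment, replicate) to populate the
  Rep(E) stratum; residuals are i.i.d. Gaussian. Non-normal errors and
  genetic relatedness among genotypes are out of scope.
* The truth record (effects, scores, spectrum, block effects, noise-free
  cells) is returned with the data so tests assert recovery directly.

`groundnut_trial_config()` encodes the reference study conditions: 30 × 3 ×
2, grand mean 190 g/m², seasonal rainfall 504.1/228.0/538.2 mm, and effect
scales solved from the expected-SS identities to give shares ≈ 82% / 4% /
13% / 0.05% / 1.1% (environment / genotype / GEI / Rep(E) / residual), with
planted singular values (440, 170) splitting the interaction signal ≈ 87/13
between two axes and residual σ² = 464. These constants are derived in the
docstring; Monte-Carlo means over 200 simulations land within a fraction of
a point of the targets.

What the generator does *not* emulate: spatial field trend, year-specific
error variances, non-normal yield distributions, and any genotype-rainfall
mechanism (rainfall is carried as metadata only). Passing tests therefore
demonstrate correctness of the estimation chain under the assumed model,
not robustness to real-field violations of it.

## Problem sizes used in the shipped checks

Unit and property tests run on designs with g, e, r ≤ 5 plus the 30 × 3 × 2
reference design; Monte-Carlo checks use 200 simulated trials, which keeps
the whole suite in the seconds range while the quantities being averaged
(SS shares, axis-recovery indicators) are already stable at that count.

## Known limitations

* Only balanced complete designs; no covariates, lattice/alpha designs or
  mixed-model shrinkage.
* IPCA significance is Gollob-only (liberal relative to resampling tests).
* Absolute MASI magnitudes depend on score scaling; only ranks are
  scale-free, and published MASI magnitudes cannot be re-derived without
  the raw data.
* RUE is computed exactly as yield/rainfall × scale; the scale of published
  RUE summaries is not always documented, so no absolute-RUE comparisons
  are made — rank-based results are scale-invariant.
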