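# Methods

## The trade-off model

A fungus garden has a finite provisioning capacity: per gram of fresh
garden a *Termitomyces* cultivar can build only so much nodule volume.
The isoquant model makes that capacity a single constant,

    L = V × D,

with V the sphere volume (mm³) of the average nodule diameter,
D the nodule density (count g⁻¹), and L the production limit
(mm³ g⁻¹). On a log–log volume–density plot the model is a line of
slope −1; clades differ in where they sit on the line (few large vs
many small nodules), not in L.

Volume is computed as the sphere volume of the *mean* diameter,
V = (4π/3)(d̄/2)³, not as the mean of per-nodule volumes. The two
differ by Jensen's inequality on dispersed data; the model's d is the
average diameter, so the former is the faithful reduction (the test
suite pins this with a two-point example where the alternatives
disagree).

### Estimation

Density is treated as the regression response: it comes from a single
manual count and is the noisier measurement, while V aggregates 50
diameter measurements. Minimising SSE(L) = Σ (Dᵢ − L/Vᵢ)² is linear in
L and has the exact solution

    L̂  = Σ(Dᵢ/Vᵢ) / Σ(1/Vᵢ²),
    se(L̂) = sqrt( σ̂² / Σ(1/Vᵢ²) ),   σ̂² = SSE/(n−1),

with t = L̂/se on n−1 degrees of freedom (one fitted parameter). The
iterative nonlinear least-squares fit (scipy `least_squares`) is
initialised at the closed form with relative convergence 1e−10 in L;
closed form, iterative fit and a 10⁴-point grid search over
[0, 2·L̂] form an oracle triangle that the tests verify agree on every
dataset (closed vs iterative to relative 1e−6, grid to one grid step).

Two alternative parameterisations sit behind the `response` flag:
`volume` (fits V = L/D, the mirror-image weighting) and `loglog` (an
orthogonal fit with slope fixed at −1 in log space, estimating
log L̂ = mean(log V + log D)). They agree exactly on noise-free data
and differ on noisy data; reported results use the density response.
The fit can also be run on the 7 clade-mean points instead of the 43
per-nest points (`per_clade_mean`); per-nest is the default since
nests are the independent replicates.

Degenerate input (all densities zero) yields L̂ = 0 with a flagged
degenerate fit rather than an error.

### Standard errors under multiplicative noise

The classical se above assumes additive homoscedastic residuals on D.
The generator's noise is multiplicative (sd(Dᵢ) ≈ σ·L/Vᵢ), so
residual variance grows as 1/V², and because the closed form weights
observations by 1/Vᵢ², small-volume nests dominate both the estimate
and its true sampling variance. Jensen's inequality
(mean(1/V⁴) ≥ mean(1/V²)²) then makes the classical se an
underestimate: in a 1000-replicate recovery study at σ = 0.2 the
±2·se interval covered the true L only 64% of the time. A sandwich
(heteroscedasticity-robust) se is therefore also reported
(`se_L_robust`); its measured coverage is ≈ 0.89, close to nominal,
and the tests assert that ordering. For inference on real surveys the
robust se is the safer default diagnostic; the classical se is kept as
the primary field because it is the textbook one-parameter NLS
formula.

### Recovery and bias correction

`recover_production_limit` simulates n replicate surveys, reduces each
to nest traits and refits, reporting relative bias, RMSE and coverage.
Lognormal density noise inflates the estimator by
E[exp(ε)] = exp(σ²/2) (≈ 1.020 at σ = 0.2, ≈ 1.133 at σ = 0.5);
corrected quantities divide by this factor. A second, smaller bias
(≈ −1 to −2%) comes from measurement error in V̂: the fitted volumes
derive from 50 sampled diameters, and error in a regressor that also
builds the weights attenuates the estimate. At the default design the
corrected bias is well inside ±5% (measured ≈ −0.4 to −1.0% across
seeds at 200 replicates).

## The synthetic-survey generator

The generator emulates the study design the analysis assumes: 43 nests
over 4 genera (*Macrotermes* 10, *Odontotermes* 15, *Ancistrotermes*
8, *Microtermes* 10), 7 cultivar clades (I–VII), 50 nodule diameters
and 3 minor-worker head widths per nest, one density per nest. Per
nest it draws a clade from the genus's compatibility weights, diameters
i.i.d. Normal(clade mean, mean·CV/100) truncated at 0.05 mm, head
widths i.i.d. Normal per genus truncated positive, and a density
D = L/V_true · exp(ε), ε ~ N(0, σ²), where V_true is the volume of the
clade's *true* mean diameter — so at σ = 0 every nest satisfies
V_true·D = L exactly and the generating limit is a recoverable ground
truth. A truncation guard rejects configurations whose floor would
discard more than 1% of draws.

Defaults and why:

* **Production limit L = 25.067 mm³ g⁻¹** — the published point
  estimate for this symbiosis; the generator's densities are built on
  it.
* **Clade diameter means 0.60–1.60 mm, ordered III > IV > VI > VII >
  V > II > I** — the published ordering; the numeric values are
  stand-ins chosen to span a realistic range (per-clade means are not
  published numerically) and are flagged as such.
* **Clade diameter CVs 14–30%** — inside the observed 12.4–31.9% band
  for nodule-diameter variation.
* **Density noise σ = 0.5** — lognormal, because density is a positive
  count-like rate with strongly right-skewed dispersion; σ = 0.5 gives
  a density CV of sqrt(exp(σ²)−1) ≈ 53%, inside the observed 40–93%
  band. (A smaller σ of 0.35 would give ≈ 36%, below that band, which
  is why 0.5 is the default.)
* **Head widths 1.00/1.40/1.90/2.60 mm** for *Microtermes* /
  *Ancistrotermes* / *Odontotermes* / *Macrotermes* — realistic
  minor-worker scale, preserving the published size ranking.
* **Compatibility weights** assign large clades to large genera
  (e.g. *Macrotermes* → III, IV; *Microtermes* → I, II), encoding
  farmer–cultivar size matching; `uniform_compatibility` flattens them
  for null calibration.

Randomness is hierarchical: the global seed spawns one independent
`SeedSequence` child per nest (keyed by global nest index), so
identical configurations are bit-identical and appending nests never
shifts earlier nests' draws. Densities are kept continuous by default
so the isoquant ground truth is exact; `round_density` rounds them to
whole counts for realism.

What the generator does **not** emulate: among-nest variation in a
clade's true diameter (diameters are i.i.d. within clade, so per-nest
mean diameters vary only by sampling error ≈ CV/√50 ≈ 2–4%, well below
the 12–32% among-nest CV a field survey shows — pooled nodule-level
CVs are the quantity that matches the configured band); multi-strain
gardens (one clade per nest); spatial structure within mounds; any
phylogenetic signal beyond the categorical clade labels. Passing tests
therefore validate the estimators and pipeline under the stated
statistical structure, not the field values themselves.

## Trait summaries and group statistics

* CV is the sample statistic 100·sd/mean with the n−1 denominator
  (the denominator convention is not standardised in the field; n−1 is
  chosen and fixed). By default clade CVs are computed on per-nest
  values — nests are the replicates; a pooled nodule-level alternative
  (`diameter_unit="nodule"`) is exposed without any claim of
  equivalence between the two.
* Normality of per-nest mean diameters within a clade is assessed by
  Shapiro–Wilk and reported as a p-value only, never used as a filter;
  it is NaN below three nests. The test's measured level at n = 10 is
  0.042–0.050, inside the 3–8% calibration band the suite asserts.
* One-way ANOVA is computed from the classical sum-of-squares
  decomposition (cross-checked against scipy to 1e−10); the analysis
  unit is the nest (nest mean diameter, density, mean head width).
  Pooling all 2150 nodules into the diameter ANOVA is available
  (`unit="nodule"`) but flagged pseudoreplicated. Welch's correction
  is available behind a flag and off by default.
* Correlations are Pearson r with an OLS line on log(n+1)-transformed
  pairs (natural log; the base is a fixed choice), p two-sided from t
  with n−2 df. Three ANOVAs and two correlations are reported without
  multiple-testing correction, matching standard practice for this
  design; the report notes as much here.

## Pipeline determinism and numerics

The pipeline is a pure function of its two input CSVs: no clocks, no
ambient randomness; `report.json` floats are serialized at 12
significant digits and keys sorted, so repeated runs are
byte-identical. Validation reports every violation with file and line
before any computation. Floats written to CSV use pandas' shortest
round-trip representation, so simulate → write → read → analyse equals
the in-memory analysis exactly.

Problem sizes used by the test and acceptance runs — one default
survey (43 nests, 2150 nodules) for design and trait checks, 200
replicates for recovery and type-I calibration, 100 for the
sign-pattern rate, 100 random datasets for the oracle triangle, 1500
samples for Shapiro level — keep the full suite under a minute while
leaving Monte-Carlo error far smaller than the asserted bands.

## Known limitations

* The generator's clade means and head widths are plausible stand-ins,
  not published values; quantities that depend on them (e.g. the t
  statistic of a simulated fit) are structural analogues, not
  reproductions.
* The classical se undercovers under the generator's own noise model
  (see above); use `se_L_robust` for honest intervals on
  heteroscedastic data.
* The isoquant is fitted globally; per-clade limits, multi-parameter
  production functions and phylogenetically corrected regressions are
  out of scope.
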