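# Methods

## The problem

The last dated fossil of a species predates its true extinction: with a
finite sighting record, the youngest occurrence t₁ underestimates how long
the species persisted (the Signor–Lipps effect). `lastsight` infers the
extinction time T_E of a taxon from a record of directly dated occurrences
t₁ ≤ t₂ ≤ … ≤ t_n (calibrated calendar years BP, youngest first), with
per-date 1σ calibration errors σᵢ. The packaged reference data are the 23
published radiocarbon dates of late cave bear (*Ursus spelaeus* sensu
lato) remains younger than 26,000 ¹⁴C years BP, with curated flags marking
the dates excluded under a conservative collagen-quality reading of the
record.

All estimator mathematics is written on the BP axis (larger = older). The
"95% bound" of the closed-form methods is the one-sided confidence
boundary *toward the present*: proposed extinction times younger than the
bound are rejected at α.

## Record filtering

Three analysis variants are built from one table:

* `include_poz` / `include_gda` — the same specimen from Stajnia Cave was
  dated twice (lab codes Poz-61719, 20,930 ± 140 ¹⁴C BP, and GdA-3894,
  21,900 ± 90 ¹⁴C BP). Only one duplicate may enter a calculation, so each
  variant drops the other.
* `conservative` — drops every record flagged `conservative_excluded`
  (dates younger than the first youngest date with well-examined collagen
  chemistry; this removes both Stajnia dates as well). The flag is a
  curated boolean column, not an automated collagen computation: no
  algorithmic criterion exists for the published chemistry notes.

An age-range acceptance window discards dates calibrated older than
50,500 cal BP (47,500 + 3,000). Only the older side is cut; a younger-side
cut would delete the youngest records, which are the object of study.
Sorting ties on the calibrated mean are broken by lab code for
determinism.

## Radiocarbon calibration

A determination y ± s (¹⁴C years) is calibrated against a gridded curve
(μ(τ), σ(τ)) by evaluating p(τ) ∝ N(y; μ(τ), s² + σ(τ)²) on a 1-year
calendar grid with linear interpolation of both curve mean and curve
error, then normalizing. Summaries are the posterior mean, SD, median and
the *central* 95% interval (2.5th/97.5th percentiles of cumulative mass).
OxCal prints highest-posterior-density ranges instead; central intervals
are unique and testable, and the difference is absorbed in comparison
tolerances. No reservoir corrections or phase models: single-date
calibration only.

The package reads real IntCal-format `.14c` files but does not ship one
(the curve is distributed by intcal.org); tests validate the engine
against analytic identity/linear/wiggle curves, where the posterior is
known in closed form, and against a brute-force numerical-integration
oracle.

## The seven estimators

With r = t_n − t₁ and sighting count n:

* **Strauss–Sadler**: bound = t₁ − r·(α^(−1/(n−1)) − 1). Exact one-sided
  coverage 1 − α under uniform sightings with exact dates.
* **Solow (1993)**: bound = t₁ − r·(α^(−1/n) − 1); slightly older than
  Strauss–Sadler for the same data.
* **McInerny et al.**: constant per-year sighting probability n/r;
  bound = t₁ − ln α / ln(1 − n/r). Requires n/r < 1.
* **Solow–Roberts**: bound = t₁ − (t₂ − t₁)(1 − α)/α, i.e. 19 gaps at
  α = 0.05. Depends only on the two youngest sightings; very conservative
  and prone to type-II-style artifacts (bounds far in the future are
  reported as printed and flagged "no extinction signal" when negative).
* **Roberts–Solow OLE**: the k youngest sightings (default k = min(10, n),
  a common window for this estimator) are modelled as Weibull extreme
  order statistics. Shape estimate
  v̂ = (1/(k−1)) Σ_{i=1}^{k−2} ln[(x₁−x_k)/(x₁−x_{i+1})] in forward time
  x = −t; weights a = Λ⁻¹e/(eᵀΛ⁻¹e) with
  Λ_ij = Γ(2v̂+i)Γ(v̂+j)/(Γ(v̂+i)Γ(j)) for j ≤ i (symmetric, computed via
  log-gamma; condition number above 1e12 raises a conditioning error with
  the advice to reduce k). Point estimate Σ aᵢtᵢ.
  Confidence-limit convention: restatements of this interval differ in
  the constant; this package uses the one-sided form
  bound = t₁ − (t_k − t₁)/(c − 1) with c = (−ln α / k)^(−v̂). Chosen over
  the α/2 (two-sided) variant because simulation under the uniform model
  (n = 25, k = 10, R = 4,000) gives one-sided coverage 0.953 for this form
  versus 0.977 for the α/2 form; the coverage experiment in the test suite
  is the standing validation.
* **Inverse-weighted McInerny (deterministic core)**: for each i ≥ 2,
  rate λᵢ = i/(tᵢ − t₁), extension eᵢ = ln α / ln(1 − λᵢ) (pairs with
  λᵢ ≥ 1 are skipped and counted), candidate Tᵢ = t₁ − eᵢ, weight
  wᵢ = 1/(tᵢ − t₁); estimate Σ wᵢTᵢ / Σ wᵢ. Recent gaps dominate.
* **GRIWM**: Gaussian resampling — each iteration redraws tᵢ* ~ N(tᵢ, σᵢ),
  re-sorts, applies the core; reports the median and central 95% interval
  over iterations (default 10,000 iterations, α = 0.05).
* **BRIWM**: bootstrap resampling of the n dates with replacement instead
  of Gaussian noise; iterations collapsing to < 2 distinct dates are
  redrawn up to 100 times, then counted as failed. Failure fractions above
  1% are logged.

Numerical conventions: dates closer than 0.5 years are merged (mean value,
counts preserved) before pairwise formulas, since calibrated means are
continuous and exact ties are rounding artifacts; resampled sets are
re-sorted every iteration so negative gaps cannot occur; all resampling is
driven by a caller-supplied seed and is bit-reproducible.

## Record-density model

The calibrated dates of a variant are fitted by maximum likelihood with
four candidate two-parameter families (normal, lognormal, gamma, Weibull;
location fixed at zero for the positive-support families, valid because
cal BP ages are positive). Normal and lognormal maxima are closed-form;
gamma and Weibull shapes are profiled to a one-dimensional score equation
solved by Brent's method (xtol 1e-12), so the stationarity of the fit is
machine-precise and the AIC/BIC identities (aic = 2k − 2ℓ,
bic = k ln n − 2ℓ) hold to 1e-9. The AIC winner is returned; the BIC
ranking is logged and disagreement warned. AICc is intentionally not the
default, matching the criteria named for the original analysis. The
averaged density is the pointwise mean of the two fits obtained with
either duplicate Stajnia date — itself a proper density.

## Climate-proxy correlation

The averaged density is evaluated on an inclusive uniform grid from an
older to a younger bound (default step 20 years — this step reproduces the
published pairing counts n = 464 for 34,510–25,250 cal BP and n = 131 for
27,850–25,250 cal BP, and is recorded here as an inference from those
counts, not a stated choice). A proxy series (e.g. Greenland δ¹⁸O) is
linearly interpolated onto the grid; the Pearson coefficient is tested
with the two-sided t-transform on n − 2 degrees of freedom. No
autocorrelation correction is applied by default, matching the original
analysis; serially correlated series therefore overstate significance,
and the p-values should be read accordingly.

## Synthetic data

`simulate_sightings` draws n true sighting times on (T_E, T₀) either
uniformly or with a linearly declining rate toward extinction
(`decline_fraction` of the initial rate at T_E, default 0.2, emulating the
observed thinning of the record before disappearance), then adds Gaussian
dating error: none, constant σ (default 200 years, the order of the
calibrated SDs in the reference table), or proportional c·t. What it does
*not* emulate: calibration-curve plateaus and multimodal posteriors,
inter-laboratory offsets, taphonomic spatial clustering, and non-Gaussian
dating error. Passing coverage tests therefore validate the estimators
under their own model assumptions, not the fidelity of those assumptions
to any real fossil record.

`coverage_experiment` measures P(T_E ≥ bound) over seeded replicates
(default 2,000, Monte-Carlo SE ≈ 0.005 at 95% coverage); estimator
failures are counted and reported, never dropped.

## Problem sizes and defaults

Resampling defaults to 10,000 iterations; coverage experiments use
R = 2,000 replicates of n = 20–25 uniform records; selection-recovery
checks use 100 repeats at n = 5,000; the correlation null calibration uses
500 repeats of length-1,000 white-noise series. These sizes put every
Monte-Carlo standard error well below the tolerance of the property they
support.

## Known limitations

* The packaged record table is the published 23-date young tail, not the
  full 207-date compilation used for the original headline numbers; the
  pipeline reproduces the two-sighting bounds and grid counts exactly, and
  validates the remaining estimators by oracle equivalence and simulation
  rather than by asserting numbers whose inputs are not available.
* The OLE confidence constant is a documented convention (see above), not
  a uniquely published formula.
* Calibration summaries follow the central-interval convention, not
  OxCal's HPD ranges.
* GRIWM/BRIWM follow the pairwise inverse-gap weighting stated above; the
  original authors' code is not redistributed, and the in-repo naive
  oracle is the arbiter of internal consistency.
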