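# Methods

## Scope and model

`benthoscale` analyzes one site at a time: a samples × taxa count table,
projected planar station coordinates in kilometres, continuous
environmental covariates, and one categorical habitat-province label per
station. Everything downstream operates on the Hellinger-transformed
abundances `x_ia = sqrt(count_ia / rowtotal_a)`; samples with zero total
abundance are excluded (the transform is undefined for them), as are taxa
observed nowhere. Geographic (lon/lat) coordinates are not supported —
every distance is a planar Euclidean distance in km.

The central quantity is the empirical multivariate variogram

    γ(h) = Σ_i (1 / (2 n_h)) Σ_{pairs (a,b) in class h} (x_ia − x_ib)²,

whose pair-count-weighted mean over classes covering all pairs equals the
total variance s² (the sum of per-taxon sample variances, (n−1)
denominator). This identity is asserted in the tests at 1e-10 and anchors
all variance bookkeeping.

## Distance classing

Classes are half-open `[lower, upper)` multiples of a fixed interval —
the half-open convention is a determinism choice; the class "distance" is
the arithmetic midpoint of the edges. Only classes below the cutoff
(default h_max/2, with h_max the maximum station separation) are used:
beyond half the extent, central stations stop contributing pairs and the
estimate biases. When no interval is given, the narrowest of 0.25 / 0.50 /
0.75 km that yields at most 12 classes under the cutoff is chosen, aiming
at roughly ten γ(h) values; classes with fewer than 30 pairs trigger a
warning (their γ estimates are unstable).

The per-class standard error of γ is the standard deviation over pairs of
the per-pair semivariance `Σ_i (x_ia − x_ib)² / 2`, divided by √n_h. Pairs
are reused across classes' construction, so this ignores between-pair
dependence; it is used only to build the diagnostic envelope below.

## Variogram families and fitting

Five families are fitted, each with nugget c0 ≥ 0, partial sill c1 ≥ 0 and
rate/range a > 0:

| family            | γ(h) − c0                                  | range |
|-------------------|--------------------------------------------|-------|
| exponential       | c1 (1 − e^{−h/a})                          | −a ln(0.05 (c0+c1)/c1) |
| gaussian          | c1 (1 − e^{−h²/a²})                        | a √(−ln(0.05 (c0+c1)/c1)) |
| spherical         | c1 (1.5 h/a − 0.5 h³/a³), clamped at c1    | a |
| piecewise linear  | c1 h/a, clamped at c1                      | a |
| logistic          | c1 a h² / (1 + a h²)                       | closed-form inverse of the 95 % rule |

For the asymptotic families the range is the distance at which the model
reaches 95 % of the sill c0 + c1; when 95 % of the sill falls below c0
(c1 ≈ 0, pure nugget) the range is undefined and reported as NaN. The
logistic a is a curvature with km⁻² semantics and is reported as-is.

Fitting minimizes Σ_h n_h (γ(h) − γ_model(h))² with bound constraints,
from a small grid of starts (nugget at 25 %/50 % of the first-class γ,
range-like starts at 25 %/50 %/100 % of the cutoff, mapped through each
family's range convention); the best converged solution is kept. Family
selection uses AICc = n ln(RSS/n) + 2K + 2K(K+1)/(n−K−1) with n the number
of usable classes and K = 4 (three curve parameters plus the residual
variance, the common convention for least-squares AICc). No standard
errors are attached to variogram parameters: samples are reused across
pairs, so resampling-based error estimates are invalid here.

## RDA and model search

RDA is OLS of each centered Hellinger column on a shared design (intercept
absorbed by centering; continuous covariates z-standardized; provinces as
0/1 indicators, one per province with no reference level dropped — a
rank-deficient full set is resolved by greedily dropping collinear columns
with a warning). Canonical eigenvalues are the eigenvalues of the fitted
matrix's covariance (n−1 denominator) and are reported as fractions of s².
The RDA AICc uses the species-pooled residual sum of squares with
K = rank + 2.

Forward selection adds, at each step, the candidate with the largest
conditional gain in explained fraction (ties broken by name for
determinism), records the full path, and truncates at the minimum-AICc
prefix — possibly empty. The province-merge search starts from singleton
groups and greedily merges the pair whose merger least reduces explained
variance, returning the minimum-AICc grouping along the path; provinces
with a single station are first folded into the group with the nearest
mean composition. Greedy agglomeration replaces an exhaustive search over
set partitions (2^k − 1 combinations); for k = 3 it provably coincides
with the exhaustive optimum, which the tests verify.

## MSO diagnostics

Inserting the RDA split into the variogram gives, per class,
γ = γ_fit + γ_res + γ_cross, with the cross term twice the covariance of
fitted and residual differences (identity asserted at 1e-12).

* **Scale dependence.** Envelope γ(h) ± z_{1−α/(2m)} · se(γ(h)) over the m
  testable classes (n_h ≥ 5); a class whose γ_fit + γ_res escapes the
  envelope marks a nonzero cross term, i.e. a biotic-environmental
  relationship that changes with scale. Normal critical values with the
  per-class se above; this is the natural reading of a Bonferroni-corrected
  point confidence interval.
* **Residual autocorrelation.** Per class, the Mantel statistic correlates
  Euclidean residual distances (over all pairs under the cutoff) with the
  binary membership matrix of the class; the null permutes station labels
  (999 permutations by default, seeded), and the two-sided p-value is
  compared to α/m. Two-sided is a deliberate choice: short-range
  similarity shows up as a *negative* correlation for the near classes.
* **Stationarity.** A pair-count-weighted least-squares line through γ_res
  over the upper half of the classes; residuals are stationary when the
  slope's 95 % interval covers zero. A rising γ_res indicates a missing
  spatially structured driver.

A caution discovered while calibrating the diagnostics: fitting province
*group means* induces negative within-group correlation among residuals,
and provinces are spatially contiguous, so residual Mantel tests against
distance classes become anticonservative even when the model is correct
(family-wise rates near 0.5 in simulations with ~10 stations per
province). The tests' null calibration therefore uses designs whose
residuals are genuinely exchangeable; on real analyses a significant
residual Mantel test after a province-mean fit should be read with this
bias in mind.

## Within/between-province partition

Geographic classes are replaced by two pair classes — within-province and
between-province — which partition all pairs; γ, γ_fit, γ_res are computed
per class and overall, and overall values recombine pair-count-weighted
(the "overall" figures use pair weighting, one of two defensible
conventions). The site-level nugget c0 from the selected variogram model
is subtracted from γ_res in each class; a single site-level c0 is used
because per-province variograms would need far denser sampling than the
designs emulated here. Where γ_res − c0 < 0 the negative adjusted residual
is preserved and flagged and the adjusted fraction capped at 1 — never
silently clamped.

## Synthetic sites

The generator emulates a stratified-random grab survey over a province
mosaic: Voronoi tessellation of uniform seed points; stations allocated to
provinces by largest-remainder proportional quotas with a minimum of three
per province when feasible (falling back to unstratified with a warning);
per-species latent log-abundance = species baseline + province shift
(scale `province_effect`) + Gaussian random field + white noise; softmax
composition; counts multinomial given a Poisson total (default mean 300)
or independent Poissons. Environmental covariates are a smooth depth trend
and province-driven granulometry, each with observation noise.

Defaults mirror a moderate coastal survey: 80 stations, 4 × 2 km domain,
6 provinces, 30 taxa, latent effective range 0.8 km (under a fifth of the
site extent), and a target nugget fraction of 0.45 — regimes in which
nugget fractions around 0.35–0.6 and scaled ranges around 0.15–0.25 are
realistic for benthic surveys.

Two conventions matter:

* `spatial_range_km` is the *effective* (95 %) range of the exponential
  latent field, i.e. covariance scale φ = range/3 — directly comparable to
  the 95 %-rule range the model module reports.
* The white-noise sd targeting `nugget_frac_target` is derived from a
  latent-scale variance budget whose "unresolvable" part collects count
  noise, the spatial-sill fraction decorrelated below the typical
  nearest-neighbour spacing, and province shifts across boundaries closer
  than that spacing (Buffon-type crossing probability). The Hellinger
  transform preserves component *shares* only to first order, so realized
  fractions land within roughly ±0.06 of the target; `calibrate_nugget`
  bisects the white variance against the realized median scaled nugget
  (11 replicate seeds by default, tolerance 0.05) when accuracy matters,
  and reports the count-noise floor when the target is unreachable.

What the generator does **not** emulate: zero-inflated or overdispersed
taxa beyond the multinomial, anisotropy, temporally repeated sampling,
province-specific spatial ranges, and gradational (non-mosaic) habitat
transitions. Passing tests therefore demonstrate correctness of the
estimators under a clean mosaic-plus-field world, not robustness to every
feature of real survey data.

## Numerical choices and degenerate inputs

* All randomness flows from explicit seeds; the same seed and
  configuration reproduce byte-identical sites and permutation p-values.
* Simulation-backed tests use deliberately modest problem sizes — 40–200
  stations, 8–50 replicates for power/consistency checks, 200 replicates
  for null calibration — chosen so each statistical assertion has adequate
  Monte-Carlo precision for its margin.
* Monte-Carlo assertions on a *rate* compare against the nominal level
  plus a one-sided 95 % binomial allowance; the structural Bonferroni
  bound m/(n_perm+1) ≤ α is asserted exactly.
* Empty distance classes are reported as missing (NaN), never zero; a
  Cholesky jitter of 1e-10 stabilizes the latent-field factorization when
  stations nearly coincide; multinomial draws that produce an empty sample
  receive one count at the most probable taxon so the Hellinger transform
  stays defined.
* The pipeline records per-stage timings and writes every table (variogram,
  selection trace, MSO, partition) beside a JSON report; a stage failure
  aborts with the stage name after persisting partial outputs.

## Known limitations

Variogram-parameter uncertainty is unquantified (by design, see above),
so nugget-adjusted fractions inherit unknown error from c0. The greedy
merge search is exact only for small k. The Mantel residual test's
anticonservatism under group-mean designs is documented but not corrected
— a restricted permutation scheme would be the remedy. Range estimates are
meaningful only when one spatial process dominates; where a province
mosaic and a latent field both contribute, the fitted range blends their
scales.
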