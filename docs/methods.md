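# Methods

## The synthetic world

Real multi-origin element panels are rarely public, so the package
generates one with the statistical structure the analysis assumes.
Concentrations are modelled on the decadic-log scale:

    log10 c_{s,e} = base_e + separation · δ_{country(s),e} + ε_{s,e}

* `base_e` — a fixed vector of typical kernel concentrations (mg/kg),
  spanning ~0.002 (Tl) to ~1500 (Mg). Only magnitudes matter; no
  attempt is made to match any real data set's absolute ranges.
* `δ` — country/element offsets drawn **once** from N(0, 0.1²) when the
  config is built and frozen into it, scaled by the `country_separation`
  knob. `separation = 0` removes the country effect entirely (the null
  world); the default 1.0 gives realistic partial overlap; ≥5 gives a
  world any classifier separates perfectly (the sanity ceiling).
* `ε` — within-country biological variability, multivariate normal with
  an equicorrelated covariance (SD 0.1 log10 units ≈ 26% CV,
  between-element correlation 0.3). Elemental fingerprints co-vary
  through soil chemistry; a single shared factor is the simplest
  structure with that property.
* Harvest year is carried as metadata only; no year effect is simulated.

Instrument noise is **multiplicative log-normal**: a single
determination multiplies the true value by `exp(N(0, σ))` with
`σ = sqrt(ln(1 + cv²))`, so one draw has relative SD exactly
`analytic_cv` and is unbiased on the log scale; a measured profile is
the mean of `replicates` (default 3) independent draws, whose SD
shrinks as `1/√replicates`. Concentrations stay strictly positive and
log10 pretreatment stays well defined. The default `analytic_cv = 0.05`
for every element is a generic mid-range repeatability figure for
solution ICP-MS, exposed per element because no element-wise
repeatability data is modelled; treat it as a placeholder for
sensitivity studies, not a measured property.

What the generator does **not** emulate: harvest-year drift, detection
limits and censoring, isobaric interferences, digestion recovery
differences, and matrix effects that correlate noise across elements.
Tests passing on this world demonstrate the pipeline's logic and
calibration, not performance on real walnut data.

## Mixtures

A mixture is the exact convex combination of its two parents
(element-wise, in mg/kg). Ratios are stored as integer percents
(10–90) and converted to fractions at computation time, avoiding
floating drift on a 0.1 grid. Every record keeps both parents, their
countries, the ratio and a provenance flag (`calculated` — the exact
combination; `measured` — the noisy triplicate-averaged determination
of that truth). The directed view reads each physical mixture from both
parents' perspectives: record (A, B, x) is a mixture of focal country A
at adulteration level 100 − x (the share of the foreign parent) and of
focal country B at level x.

### The measured plan

The study design requires a fixed number of mixtures per country and
mixing ratio (default 10, hence 6 × 9 × 10 = 540 directed records from
270 physical mixtures). How those are distributed over country *pairs*
is a free design choice; the planner balances them with a circulant
design: for each ratio pair {x, 100 − x} every ordered country pair
receives an equal share via fixed-point-free permutation rounds, and
the symmetric 50/50 level uses round-robin perfect matchings (even
country count) or paired permutation rounds (odd count, which then
requires an even per-country quota). Parent samples are drawn uniformly
within each slot, with global deduplication of (parent pair, ratio).

## Pretreatments

Four column-wise transforms, fitted on training data only and always
inside each CV training fold (fitting on the full set before splitting
would leak test statistics): `none`; `log10` with a per-element floor
at half the smallest positive training value; `autoscale` (mean centre,
sample n−1 SD); `robust` (median centre, IQR with linear-interpolation
quantiles). A zero-spread column is an error naming the element rather
than a silent divide-by-zero. The menu deliberately treats `log10` and
the scaling methods as mutually exclusive alternatives.

## One-class SIMCA

Per modelled class: pretreat, mean-centre, PCA by SVD. With k
components (default: smallest k explaining ≥90% of variance, capped
below the data rank), membership of a new observation is judged by two
statistics:

* **score distance** — Mahalanobis-type distance in the component
  subspace, `Σ_j t_j²/λ_j`;
* **orthogonal distance** — squared residual norm outside the subspace.

Each gets a chi-squared critical limit with moment-matched
(data-driven) degrees of freedom, `dof = 2·mean²/var` of the training
distances. Because the two statistics are independent under the PCA
model, each limit is set at level `sqrt(1 − α)` so that the joint
acceptance region covers ≈ `1 − α` of in-class observations (default
α = 0.05). Degenerate directions (exactly low-rank training data) give
a near-zero orthogonal limit, so off-plane points are outliers.

Numerical caveats: the chi-squared approximation of the orthogonal
distance is a Satterthwaite-type moment match — accurate when the
residual eigenvalues are comparable, optimistic in the tail when one
residual direction dominates; and with training sets much smaller than
~10× the feature count, the moment estimates are noisy and the realised
acceptance rate can deviate by several points from `1 − α`. The
calibration test therefore uses a large training draw and a spectrum
with a clear gap; with 12–60 samples per country (the realistic
regime), the limits should be read as approximate.

## Supervised models and cross-validation

The supervised menu delegates to scikit-learn behind a uniform
interface: radial SVM (C = 1, γ = "scale"), LDA, random forest
(500 trees, √p features per split), SVR, PLSR and random-forest
regression; one-class SVM (ν = 0.05) for approach I. Defaults are
ordinary textbook settings — there is deliberately no tuning
framework. Validation is repeated k-fold CV (stratified for
classification), default 5 × 5; approach I uses 4-fold CV on the pure
class; approaches IV/V default to 10 folds × 5 repeats. All estimator
and splitter seeds derive from the scheme's seed, so every run is
reproducible bit for bit. Class weighting is off by default (matching
an unweighted setup despite the pure-vs-mixture imbalance); ties in
votes resolve to the lexicographically first label via the estimator's
own convention.

One practical note from this implementation: the radial SVM is
scale-sensitive, and on unstandardised log10 features (which span
−3…+3 across the 17 elements) it underfits at C = 1 where LDA and
random forests do not; autoscaling restores it. This mirrors why a
pretreatment menu is worth scanning at all.

## The approaches

"Accuracy" for a mixture test set always means the **detection rate** —
the fraction of mixtures given that approach's positive outcome
(outlier for I, own class for II, rest class for III, correct level for
IV/V). Per-level tables report levels 10…90 with measured and
calculated columns and their absolute difference in percentage points
(one decimal); **conformity** summarises a per-level table as 100 minus
the mean absolute difference — an interpretation, since the term has no
standard definition.

Approach-specific choices:

* **II** — mixtures built from parents that sit in a CV training fold
  are allowed in the test fold (no grouping by parent sample). This
  mirrors a design that does not group-split and is slightly
  optimistic; group-aware CV is a known extension, not implemented.
* **III** — shares its one-vs-rest trainer with the baseline, so the
  two stay consistent by construction.
* **IV/V** — trained on calculated mixtures only, with every calculated
  **twin** of a measured mixture (same unordered parent pair, same
  oriented ratio) excluded from training and scored as its own held-out
  test set. The class/target is the directed adulteration level for a
  single focal country.

### Null behaviour of the level models

At zero country separation the country-signal approaches (baseline, II,
III) score at the majority rate, and this is enforced by test. The
level classifier (IV) does **not** drop to 1/9 in that world: with a
finite pool of parents, low-level mixtures cluster near the focal
country's few parent profiles and high-level ones near the foreign
parents, which is genuine level information independent of any country
effect. The correct null for IV is therefore permutation of the level
labels, which does bring it to chance; both facts are covered by tests.

## Problem sizes and numerical tolerances

* Combinatorial checks run on the full 206-sample layout (exact
  integers, no tolerance).
* Mixture arithmetic: composition closure to 1e-12 relative; convexity
  to 1e-9 relative.
* SIMCA calibration: 50,000 training draws, 10,000 test draws, judged
  against the 99% binomial band around 1 − α.
* Monte-Carlo noise-response and monotonicity studies average 20–24
  seeds on a compact 68-sample six-country world with 4 mixtures per
  country and ratio — the smallest design whose per-level cells still
  average away Bernoulli noise.
* Noiseless recovery uses a two-country world with constant parent
  profiles, where the adulteration level is recoverable in closed form
  and RMSE below 1 percentage point is the pass line.

## Known limitations

* The synthetic world is stationary and year-free; conclusions about
  real panels require real data.
* SIMCA limits are approximate for small classes (see above).
* The planner guarantees per-country quotas but fixes one balanced
  pair distribution; alternative distributions (e.g. weighted toward
  expensive-origin pairs) are not explored.
* No hyperparameter search; reported model ranks depend on the default
  settings.
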