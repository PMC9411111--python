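# Methods

## Model and conventions

The ecosystem structure function *R*(*n*, ε | *S*, *N*, *E*) =
e^(−λ₁n − λ₂nε)/*Z* is defined on *n* ∈ {1, …, ⌊N⌋} and ε ∈ [1, *E*].
Both support choices are modelling decisions, not consequences of the
MaxEnt derivation itself: truncating the abundance sum at *N* keeps every
moment finite and follows the standard construction of this theory; the
lower limit ε = 1 encodes the units convention that the smallest individual
metabolic rate in a plot equals 1, and the upper limit *E* is the largest
value consistent with the energy constraint. State variables must satisfy
*S* ≥ 2, *N* > *S*, *E* > *N*; *S* and *N* are accepted as positive reals so
intensive-ratio analyses are expressible, while census-derived values are
integers.

## Solving for the multipliers

The two constraint equations *S*⟨*n*⟩ = *N* and *S*⟨*n*ε⟩ = *E* are solved
for (λ₁, λ₂) as a 2-D root-finding problem in (λ₁, log λ₂), seeded from the
classical approximations β ln(1/β) = *S*/*N* and λ₂ = *S*/(*E* − *N*). A
quasi-Newton (hybrid Powell) solve is tried first; if the verified relative
residuals exceed the tolerance (default 10⁻¹⁰), nested bracketed 1-D solves
take over — outer Brent iteration on λ₁ against the abundance constraint,
inner Brent iteration on log λ₂ against the energy constraint, with
geometric bracket expansion. Every solution labelled `exact_root` carries
residuals checked against the tolerance; the seed approximations are
available separately and always labelled `approximation`. λ₁ may be
negative (it often is at large *N*/*S* with modest *E*/*N*); only λ₂ > 0 is
required.

Inner integrals ∫₁^E ε^p e^(−aε) dε use the closed form
Γ(p+1) a^(−(p+1)) [P(p+1, aE) − P(p+1, a)] in regularized incomplete gamma
functions, switching to the upper-tail difference Q(p+1, a) − Q(p+1, aE)
when both lower tails are near 1, and to a three-term Watson-lemma expansion
e^(−a)/a · (1 + p/a + p(p−1)/a²) when the gamma difference underflows
(a ≳ 700, where the term is negligible anyway). All moment sums over *n*
are computed in log-space with `logsumexp`; for ⌊N⌋ > 2¹⁸ the sum proceeds
in chunks and terminates once a decreasing tail contributes less than 10⁻¹⁶
of the running total. Adaptive quadrature serves as an independent
cross-check of the closed-form integrals (and as a runtime fallback), never
as the primary route.

## Predictors

* `predict_biomass_numerical` — *S* Σ *n* ∫ ε^(1/θ) *R* dε with the solved
  multipliers; θ is the metabolic-scaling exponent (3/4 default; 2/3 and 1
  allowed). With θ = 1 the integrand reduces to the energy constraint and
  the predictor returns *E* to solver precision.
* `predict_biomass_analytic` — *c* *E*^(4/3)/(*S*^(1/3) ln(1/β)) with
  *c* = (7/2)Γ(7/3) ≈ 4.1672 and β from the closed relation. Defined for
  θ = 3/4 only; the analogous closed form for θ = 2/3 is not derived here,
  so the bundled `predict` reports closed forms as absent for non-3/4
  exponents.
* `predict_biomass_corrected` — the analytic form times 1 − 1.16 β^(1/3).
  The coefficient 1.16 is treated as a fixed constant. Note that on the
  feasible branch β < 1/e, so the factor is bounded below by ≈ 0.167 and
  can never vanish; the domain guard against a non-positive factor is
  defensive only.
* `predict_productivity` — the algebraic inverse
  *E* = *c*^(−3/4) *S*^(1/4) *B*^(3/4) ln^(3/4)(1/β).
* `predicted_ratio_curves` — *E*/*B*^θ with *B* from the numerical
  predictor, along a grid in *S* or *N* with the other two variables fixed
  (infeasible grid points are skipped with a warning).

β used inside the closed forms is always the root of β ln(1/β) = *S*/*N*,
not λ₁ + λ₂ from the exact solve; both are reported so they can be
compared. They agree only when *S* is large as well as *N*/*S*: the closed
relation drops the truncation of the abundance sum at *N*, which matters
whenever 1/β is comparable to *N*, i.e. unless *S* ≫ ln(1/β). At
(*S* = 10, *N* = 1000) the two differ by almost a factor of two; at
(*S* = 100, *N* = 10⁵) they agree to < 0.1%.

## Accuracy of the closed forms (known limitation)

The acceptance script measures the maximum deviation of the closed forms
from the exact numerical solution over logarithmic grids spanning their
nominal regimes. Two structural error sources dominate at the grid edges:

1. The plain closed form replaces Σ n^(−4/3) e^(−βn) by its β → 0 limit
   ≈ 7/2. The next term is ≈ −4.06 β^(1/3), i.e. a relative error of
   1.16 β^(1/3) — about 13% at *N*/*S* = 100. (Dividing 4.06 by 7/2 gives
   exactly the 1.16 of the correction factor, which is how the corrected
   form removes this term.)
2. Both forms use *E*^(4/3) where the energy constraint actually fixes
   λ₂ ≈ *S*/(*E* − *N*), implying (*E* − *N*)^(4/3); at *E*/*N* = 5 this is
   a (1 − 1/5)^(4/3) ≈ 26% gap.

Consequently the measured grid maxima are ~20% (plain form, worst at
*S* = 10, *N*/*S* = 100, *E*/*N* = 25) and ~30% (corrected form, worst at
*E*/*N* = 5) rather than 10%: the 10%-level accuracy attaches to the
interior of the regimes, not uniformly to their boundaries. The numerical
predictor itself is validated independently by 10⁶-draw Monte-Carlo
sampling of *R* and by per-*n* adaptive quadrature (agreement well within
sampling error).

The productivity elasticity ordering (strongest in *B*, then *S*, weakest
in *N*) likewise holds only where ln(1/β) is appreciably large (roughly
*N*/*S* ≳ 300); nearer the regime edge the logarithmic *N*-dependence can
exceed the *S*^(1/4) term.

## Census processing

Order of operations: filter to live individuals with measurements → combine
stems per individual (root-sum-of-squares of diameters, so basal areas add)
→ rescale so the plot minimum equals 1 → sum powers. For `mass` data
*B* = Σ m̃ᵢ and *E* = Σ m̃ᵢ^θ; for `metabolic_proxy` data *E* = Σ ε̃ᵢ and
*B* = Σ ε̃ᵢ^(1/θ). The provided measurement column is taken as the proxy
as-is (for trees, basal-area-derived size is the usual estimator of ε). A
user-supplied `rescale_factor` can replace the within-plot minimum, for
plots where the smallest individual was estimated rather than measured.
Ties at the minimum all map to exactly 1. The ≥ 10 species selection rule
is on by default and relaxable (`allow_fewer`), since it is a data-curation
criterion rather than a mathematical requirement. *E* ≥ *B*^θ holds for
every processed census by the power-mean inequality, and all outputs are
invariant under global rescaling of the raw measurements.

## Synthetic communities

`mete_exact` draws, for each of *S* species independently, an abundance
from the *n*-marginal of the solved *R*, then that many metabolic rates
from the conditional truncated exponential (rate λ₂n on [1, *E*]) by
inverse CDF, and emits masses m = ε^(1/θ). Realized *N*, *E*, *B*
fluctuate around their targets — *R* defines per-species marginals, not a
census-level law, and independent species draws are one faithful reading of
it; `condition_on_n` optionally rejects draws outside a relative band
around *N*. One root seed determines everything; replicate streams are
spawned from it deterministically, so any subset of replicates is
reproducible. The canonical ensemble condition used in the tests is
(*S* = 30, *N* = 3000, *E* = 10⁵) with 200 replicates; there the ensemble
mean of observed *B* matches the numerical prediction at the generating
triple within sampling error, and a 30-plot survey spanning
*S* ∈ [10, 100], *N*/*S* ∈ [10, 500], *E*/*N* ∈ [10, 500] yields
log-biomass regression *R*² > 0.99.

What the generator does **not** emulate: spatial structure, temporal
disturbance, interspecific mass correlations beyond the structure function,
measurement error, or taxonomic aggregation. Passing the self-consistency
tests therefore demonstrates internal correctness of the chain
(sampling → census processing → prediction), not that field data obey the
equation of state.

`lognormal_mass` keeps the same abundance marginal but draws masses i.i.d.
lognormal (default log-sd 1.35, putting ~3 decades between the smallest and
largest masses, tree-like), decoupling size from abundance; prediction
errors grow accordingly, which the tests use as a misspecification
direction check.

## Validation statistics

Predictions are always computed from each plot's own observed
(*S*, *N*, *E*). "Variance explained" is reported both as the squared
Pearson correlation of the two quantities (regression *R*²) and as
1 − SS_identity/SS_total about the y = x line (which can be negative and is
reported as-is); logarithms are natural. Plots whose solve fails are
excluded with a logged reason. Pairwise *R*² over all six pairs of
{ln *S*, ln *N*, ln *E*, ln *B*} is provided for survey-level context.

## Problem sizes and determinism

Default test and acceptance computations use grids of 27 and 36 triples
(largest *N* = 10⁵), 10⁶-draw Monte-Carlo checks at five triples, and
200-replicate ensembles at the canonical condition; these sizes make the
whole suite and the acceptance script each run in well under a minute on a
single core while leaving Monte-Carlo standard errors far below the
tolerances they guard. All grids are deterministic; all sampling flows from
explicit seeds.
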