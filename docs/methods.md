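# Methods

This note documents the models, numerical choices and defaults behind
`redflux`, and what the bundled synthetic networks do and do not show.

## Flux space and parametrization

A model defines net fluxes `v` constrained by `S·v = 0` over the balanced
(intracellular) pools, user equalities/inequalities `C·v ≤ c`, global net
bounds (default ±100 relative to the normalization flux), and per-reaction
exchange bounds (default [0, 200]).  Unidirectional reactions are floored at
net ≥ 0.  The *normalization* flux declares the reporting scale (typically
the main substrate uptake = 100); it may be pinned by an equality
(`fixed="true"`) or left free when only the scale is meant — the chain
fixture uses the latter so that its polytope retains an interior.

Free net fluxes are chosen by column-pivoted QR of the equality system
(stoichiometry + pinned rates + user equalities): pivot columns become
dependent, the remaining reaction fluxes — in declaration order — are the
free coordinates.  The selection is deterministic but not canonical; any
nullspace basis parametrizes the same polytope.  Each bidirectional reaction
contributes one exchange coordinate on its natural bounded scale, with
`fwd = max(net,0)+xch` and `bwd = max(−net,0)+xch`.  Exchange coordinates
are *not* re-transformed to a [0, 1] scale; consequently all
covariance-based criteria are defined on this natural scale, and criterion
values are comparable only between runs using the same parametrization.

Degenerate (lower-dimensional) polytopes are rejected with a pointer to
convert near-equality inequality pairs into explicit equalities; the
strictly interior starting point is the Chebyshev center (an LP).

## Uniform flux sampling

Hit-and-run MCMC with isotropic Gaussian directions on a coordinate-rescaled
polytope (per-coordinate widths from the exact bounding box) to mitigate the
anisotropy of flux polytopes.  Defaults: burn-in 1000 steps, thinning
⌈dim²⌉, `numpy.random.default_rng` (PCG64) with a single recorded integer
seed.  These defaults are stated choices, not tuned values; the suite
verifies first/second moments on boxes and exact feasibility of every
emitted sample.  A truncated-Gaussian chord target is available as a hook
for prior-informed sampling; it is off by default.

`center_of_mass` (the coordinate-wise sample mean, feasible by convexity) is
the deterministic single-point surrogate used when a classical one-point
design is wanted for comparison.

## Labeling simulation

The production simulator decomposes the network into elementary metabolite
units (EMUs) reachable from the measured fragments and solves one linear
balance system per EMU size; condensation reactions enter as convolutions of
smaller-EMU MIDs.  The balance of a pool's EMU uses the total *production*
flux on the diagonal (equal to consumption at steady state, and also correct
for sink pools), which keeps every simulated MID normalized to 1 by
construction.  Levels are solved by dense LU up to 200 EMUs per level and a
sparse LU above; a condition estimate > 1e12 raises a singular-system error
naming the zero-throughput pool.  Substrate pools are fixed boundary
conditions: per species an independent per-position Bernoulli model (labeled
positions carry ¹³C with probability purity/100, unlabeled positions with a
configurable background, default 0), mixed by the mixture fractions.

Natural-abundance correction matrices for derivatization atoms are *not*
modeled; the affine measurement error model σ(y) = 4.120·10⁻²·y + 6.655·10⁻³
is taken to absorb that effect.  Measurement groups are fragment MIDs;
rate measurements (net fluxes with configured standard deviations) are
appended to the measurement vector and the diagonal covariance.

An independent brute-force oracle simulates the same measurements through
the full cumomer cascade (all 2ⁿ cumulative isotopomer fractions per pool,
Möbius inversion back to isotopomer fractions) and must agree with the EMU
path to 1e-8; it is practical up to ~12 carbons per metabolite.  Because
labeling depends on fluxes only through the ratios of each pool's input
fluxes, the simulated y is invariant under global flux scaling, and it is
affine in a substrate's mixture fractions only on pathways where that
substrate never meets itself in a condensation (exact on the chain fixture;
quadratic terms appear wherever two EMUs of the same substrate convolve).

## Sensitivities

The Jacobian ∂y/∂z with respect to the free coordinates (net block then
exchange block) is computed by implicit differentiation of the EMU cascade:
per level, `A·dX = dR − dA·X`, reusing the LU factorization of `A`.
Direction-flux gradients use the right derivative of the fwd/bwd split at
net = 0; evaluations with a bidirectional net flux within 1e-9 of the kink
are flagged on the record.  Rate rows are the constant affine map from free
coordinates to measured net fluxes.  A central finite-difference oracle
(default step 1e-6·max(1,|z|), halved near the polytope boundary)
cross-checks the analytic path to 1e-5 relative in the tests.

## Design metrics

`FIM = Jᵀ Σ⁻¹ J` (symmetrized; Σ diagonal).  Identifiability thresholds:
smallest singular value of the restricted FIM ≥ 1e-9·‖FIM‖₂ and condition
number ≤ 1e10 — both configurable and recorded in the pool, since no
canonical values exist for these cutoffs.  Non-identifiable fluxes are
removed greedily: while the thresholds are violated, drop the flux with the
largest absolute component in the singular vector of the smallest singular
value (ties by declaration order).  For ≤ 12 free fluxes an exhaustive
subset search is available; among admissible subsets of equal size the one
with minimal det(Cov) is preferred (trace selectable).  The greedy result
can be cross-checked against enumeration (`verify=True`), recording whether
it attained the enumerated optimum.

The D-criterion is normalized to a reference mixture over the *same* active
set, `Φ_D = (det Cov_ref / det Cov)^(1/(2·n_act))`, read as an average
standard-deviation ratio; the exponent is configurable to `1/n_act`.  The
reference covariance is recomputed per candidate on the candidate's active
set at the same flux sample; if the reference mixture cannot identify that
set the record carries a reference-degenerate flag and no Φ_D.

Tracer cost is `Σ fraction × grams(substrate) × price($/g)`, with grams
derived from chemostat settings (concentration g/L × working volume L ×
residence times; the dilution rate cancels between rate and duration).

## Aggregation

Per mixture and design size: coverage = percentage of flux samples for
which `n_act` fluxes are identifiable (simulation failures count as
non-covering and are tallied separately); the median D-criterion runs over
the achieving, reference-identifiable samples only — the excluded fraction
is exactly the coverage complement, so no information is hidden.  Per-flux
outputs are the frequency with which each flux appears in the chosen active
set and the quartiles of its standard deviation; dimension-reduced
single-flux designs use the diagonal FIM element (all other fluxes fixed to
the sample's values), with σ = 1/√FIM_ff.  Mixture grids store fractions as
integer multiples of the step, so mixture identities are exact.  The
aggregated pool carries provenance (seed, thresholds, objective, exponent,
model hash) and round-trips through HDF5/CSV.

## Bundled synthetic networks

Three deterministic generators stand in for real models; all their manifest
facts are re-verified by the test suite.

* **chain** — pass-through pathway; analytic expectations (terminal MID =
  substrate distribution, zero labeling Jacobian) are exact.
* **branch_cycle** — minimal two-substrate split/condense motif with one
  reversible condensation.  Because steady-state labeling sees only the
  ratios of each pool's input fluxes, its labeling Jacobian has structural
  rank 2; with the two rate measurements the maximal identifiable design
  size is 3 of the 4 free coordinates, *for every mixture*.  The manifest
  therefore declares 3 as the attainable design size; the all-unlabeled
  mixture never reaches it (coverage 0 %) while the declared informative
  mixture always does (coverage 100 %) — the qualitative
  informative-vs-singular phenomenon the aggregation is designed to expose.
* **clavam_analog** — a reduced two-substrate analog of a
  glycerol/arginine antibiotic-producer scenario: 19 pools, 18 reactions
  (2 bidirectional), glycolysis-, pentose-phosphate-, TCA-, anaplerosis-,
  urea-cycle- and 8-carbon product-pathway-like blocks, amino-acid-like
  fragment measurements, and a 4+3-species catalogue whose prices are
  synthetic except two published price points (0.36 $/g unlabeled 3-carbon
  substrate, 3,449 $/g fully labeled 5-carbon substrate).  Mild lower
  bounds on a few pathway fluxes keep every measured pool's throughput
  strictly positive so that random flux samples yield solvable labeling
  systems.  It mirrors pathway *structure* only; its stoichiometry,
  bounds and most prices are invented, so results on it demonstrate the
  workflow, not any organism-scale finding.

Test and example runs use small problem sizes (tens to hundreds of flux
samples, coarse mixture grids) — sufficient for the exact combinatorial
checks and the qualitative phenomena above, chosen to keep the suite fast.
What passing tests show is correctness of the machinery (oracle
equivalences, exact identities, invariances), not that any particular
mixture is optimal for a real organism: real networks are larger, their
measurement sets sparser, and their polytopes far more anisotropic, which
makes sampler mixing and threshold choices materially harder than on the
fixtures.

## Known limitations

* Isotopically nonstationary (INST) labeling, NMR/tandem-MS observables and
  natural-abundance correction matrices are out of scope.
* Only the D-criterion is implemented; the selection/covariance interface
  accepts alternatives but none are shipped.
* No Pareto-front optimization — the workflow is deliberately exploratory;
  ranking and filtering happen on the aggregated pool.
* Exchange-flux criteria depend on the natural-scale parametrization (see
  above).
* The greedy active-set heuristic can miss the enumerated optimum on
  adversarial FIMs; enable `verify`/exhaustive selection for small designs
  when that matters.
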