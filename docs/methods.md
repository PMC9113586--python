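# Methods

`freshprior` implements catchment-based systematic conservation planning for
freshwater biodiversity: given planning units (river/lake catchments with
areas, downstream pointers, ecoregion membership and protected-area
fractions), species with IUCN Red List categories, and a sparse
species-by-catchment occurrence relation, it selects a near-minimum-cost set
of catchments that represents every species at a status-dependent target
level, and then scores how well the resulting conservation priorities line
up with existing protection.

## The minimum-set problem

A candidate network is a set *S* of catchments. Its objective is

```
objective(S) = cost(S) + shortfall(S) + structure(S) + cap(S)
```

* **cost** — Σ area (km²) of selected catchments; area is the standard proxy
  for the cost of protection.
* **shortfall** — Σ over species of `spf · max(0, t − c) / t`, where *t* is
  the species' representation target (in occurrence counts), *c* the number
  of its occurrences inside *S*, and `spf` the species penalty factor.
  `spf` defaults to 10 × the mean catchment area, putting a full shortfall
  on the same scale as the cost of the handful of catchments that would
  remedy it. It is finite on purpose: with a binding area budget some
  targets can rationally remain unmet, which is what the coverage reports
  are for. Override via `build_target_table(spf_scale=…)` or
  `penalty_factor=…`.
* **structure** — spatial-coherence penalty, one of two modes.
  *Boundary* mode charges `BLM ×` the total weight of adjacency pairs with
  exactly one member selected (exposed boundary → clumped solutions);
  default BLM = 10. *River* mode replaces the boundary file with the
  directed river connections (each catchment → its immediate downstream
  neighbour, weight 1) and charges `CP ×` the weight of **broken upstream
  connections**: pairs whose downstream member is selected while the
  immediate upstream member is not. The asymmetry encodes that upstream
  catchments condition downstream ones far more than the reverse —
  protecting a catchment without its upstream supply is what the penalty
  discourages. Default CP = 10; `CompiledProblem(symmetric_river=True)`
  switches to symmetric counting for sensitivity analysis.
* **cap** — the solution's area is capped at 17% of the planning region
  (the Aichi Target 11 level) as a *soft* constraint:
  `cap_weight × max(0, cost − cap)` with `cap_weight = 1000` per km².
  At 1000× the per-km² cost of selection, exceeding the cap is never
  worthwhile for free catchments, while a locked-in set larger than the cap
  remains representable (it simply carries the penalty, and
  `build_problem` records a feasibility warning).

## Representation targets

Targets are counts of occurrences, set from Red List status first and range
restriction second (status wins conflicts because it demands more):
CR → 100% of occurrences; EN → 75%; VU → 50%; otherwise, species whose
total occupied area falls strictly under 20 000 km² (fish, molluscs — weak
dispersers) or 50 000 km² (odonates, aquatic plants) → 25%; all remaining
species → two occurrences. Fractional targets round by **ceiling** — the
conservative direction, a species is never under-represented by rounding —
and every target is capped at the species' occurrence count (a target above
it would be unmeetable by construction). The full rule table is enforced
against an independently coded lookup oracle in the test suite.

## Scenarios and locks

Catchments whose assemblage is "unique" — where ecoregion-restricted
(single-ecoregion) fish and mollusc species are ≥ 5% of the fish and
mollusc species present — are locked into every solution, in all scenarios.
Catchments with no fish or molluscs never qualify (the ratio is undefined,
not zero). On top of that:

1. **Scenario 1** ignores protection.
2. **Scenario 2** locks IN well-protected catchments (protected fraction
   strictly above 70%) — does building on existing protection help?
3. **Scenario 3** locks them OUT — where is priority not yet protected?

"At least 5%" is read as ≥ and "exceeded 70%" as >, following the wording
of the rules. A catchment that is both endemism-qualifying and
well-protected under Scenario 3 resolves to **locked in**: the exclusion is
a statement about protection, the endemism rule a statement about
biodiversity, and the biodiversity statement wins. Locked-out catchments
stay in the boundary/connectivity graphs as unselected neighbours.

## Search

The solver is simulated annealing followed by iterative improvement, in the
tradition of reserve-selection tools:

* Initial state: the locked-in set plus a random subset of free catchments
  sized so the starting cost sits near the area cap (starting far above the
  cap would make early deltas meaningless against the cap cliff).
* Proposals mix three kinds of move: single toggles (45%); paired
  remove/add swaps (30%), which exchange catchments without crossing the
  cap penalty in between; and coverage-directed swaps (25%) that add a
  catchment holding an occurrence of a currently-unmet species while
  dropping a random selected one — the standard unmet-feature heuristic. On cap-saturated instances plain toggles cannot
  exchange catchments (any add is blocked by the cap cliff), which is why
  the paired moves matter.
* Temperature: geometric cooling over two decades, with the initial
  temperature set to a robust (median-absolute-deviation) scale of the
  objective deltas along a random probe walk — a plain standard deviation
  is destroyed by the occasional ±10⁵ cap-penalty delta.
* Iteration budget: `max(2000, 100 × n_catchments)` annealing moves.
* Finish: up to five rounds of exhaustive greedy single-toggle passes
  interleaved with the same number of improving-only random moves, stopping
  when a round no longer improves — "two-step" iterative improvement.

Each portfolio repeats the run `n_runs` times with seeds `base_seed + i`.
The **best network** is the run with the lowest objective (ties: lowest
cost, then lexicographically smallest id set). **Selection frequency** —
how often each catchment appears across the per-run solutions — is the
irreplaceability proxy; locked-in catchments score `n_runs`, locked-out 0,
by construction. Coverage reports give per-species captured counts, met
flags and the proportion of the range covered (occurrence-count based, to
match how targets are defined; an area-weighted column is also provided),
plus met/unmet counts per Red List category.

On instances small enough to enumerate (≤ 20 free catchments),
`exhaustive_optimum` computes the exact optimum by vectorized enumeration;
the test suite requires best-of-100 annealing runs to attain it on ≥ 95% of
50 random 12-catchment instances. An incremental-vs-from-scratch objective
audit must agree to 1e-9 relative tolerance after arbitrary move sequences.

## Priority-vs-protection correspondence

With irreplaceability `I ∈ [0, n_runs]` and protected fraction
`p ∈ [0, 1]`, three complementary scores:

1. **Quadrants** — median splits of both variables (strictly above the
   median is "high"; ties go low — with realistically continuous inputs
   ties are immaterial, the rule just fixes the edge case).
2. **OLS residuals** — residuals of `I ~ p` (plain OLS of counts on
   fractions; the bounded, heteroscedastic response is deliberately not
   corrected, matching standard practice for this diagnostic; the slope's
   two-sided t-test p-value is reported unadjusted, as a single regression
   needs no multiplicity correction).
3. **Ideal-line deviation** — `I − n_runs·p`, the signed distance from a
   perfect 1:n_runs relationship; positive = more priority than protection.

Group summaries (mean ± SE by ecoregion or country, SE = sd/√n, undefined
for n = 1, ranked by mean) support regional league tables.

## Synthetic worlds

Real inputs at continental scale (basin hierarchies, expert range maps,
protected-area overlays) are large and license-encumbered; the generator
reproduces their *statistical structure* so the full pipeline is testable
offline. Features and defaults (all in `WorldConfig`):

* **Dendritic forest** — `n_outlets` (25) rooted trees over `n_catchments`
  (200); each new catchment either extends a basin's most recent member
  upstream (`topology_elongation` = 0.6, giving the long mainstem +
  tributary chains of real river networks) or branches off a uniform
  member. Terrestrial adjacency = tree edges plus `cross_link_fraction`
  (0.3) random cross-links.
* **Areas** — i.i.d. lognormal(7.8, 0.8) km² (mean ≈ 3.4 × 10³ km²,
  basin-scale units chosen so the absolute 20 000/50 000 km²
  range-restriction thresholds separate small-range from widespread species
  the way they do at continental scale), rank-coupled negatively to species
  richness with a Gaussian copula (`area_richness_bias` = 0.5): hotspot
  catchments — mountainous, coastal, karstic — run smaller than the
  continental average. Copula couplings are pure permutations, so marginals
  are preserved exactly.
* **Species** — counts per taxon default to the observed European ratio
  (fish 94, molluscs 121, odonates 23, plants 62 out of 300). Range sizes
  are geometric with continuation parameter `range_contiguity` (0.95, mean
  20 catchments); ranges grow to that size along the adjacency graph,
  preferring the frontier catchment most connected to the range (compact,
  nested-subbasin-like shapes, as in catchment-based range mapping). The
  smallest-ranged 40% of species seed at one of `n_hotspots` (1) hotspot
  catchments — range-restricted species cluster in refugium-like endemism
  hotspots — while widespread species seed uniformly. Red List categories
  are drawn i.i.d. from a mixture approximating the observed status
  frequencies (9% CR, 9% EN, 16% VU, 8% NT, 52% LC, 6% DD) and rank-aligned
  so the most threatened categories carry the smallest ranges
  (`threat_range_bias` = 1.0), the dominant pattern in Red List data.
* **Protection** — i.i.d. beta(0.25, 1.5) fractions, copula-coupled to
  richness (`protection_biodiversity_bias` = 0.65; protected areas are in
  part designated for biodiversity) and smoothed once along the adjacency
  graph (`protection_autocorrelation` = 0.25). Under the defaults a few
  percent of catchments exceed the 70% threshold, with ~2–4% of total area
  well-protected.
* **Planted structure** — optionally, CR fish species confined to
  well-protected catchments in two ecoregions (naturally well-protected,
  richest-first; forced above the threshold only when none exist). These
  give worlds a known protection-vs-priority conflict: such species are
  guaranteed met when well-protected catchments are locked in and
  guaranteed unmet when they are locked out.

Ground truth (endemics, endemism-qualifying catchments, well-protected and
planted sets) is recomputed with independent plain-Python code and returned
alongside the bundle.

**What the generator does not emulate:** polygon geometry and map
projections; real spatial covariance of protection with countries and
legislation; taxonomic non-independence of ranges; observational error in
occurrence data; the three named data-curation exceptions applied to the
real occurrence set. Passing tests therefore demonstrate the machinery —
the rules, the optimizer, the accounting — under realistic structure, not
empirical conclusions about any real region.

## Study sizes used by the test suite

Scenario comparisons run on 20 worlds of 200 catchments and 300+2 species
(two planted), with 8-run portfolios at the default iteration budget —
sizes at which per-world scenario met-counts are reproducible across
portfolio seeds. The enumeration oracle uses 50 instances of 12 catchments
and 20 species with 100 annealing runs each. The acceptance script scales
the scenario sweep to 8 worlds and uses a 100-run portfolio for the
correspondence regression.

## Numerical notes and edge cases

* Ids are opaque strings ordered lexicographically everywhere; all
  randomness flows through explicit integer seeds (`random.Random` in the
  annealer, `numpy.random.default_rng` in the generator), so identical
  configurations reproduce byte-identical outputs across platforms.
* Marxan-dialect files are tab-delimited with headers; statuses 0/2/3
  (available / locked in / locked out); re-reading uses round-trip float
  parsing so write → read → write is byte-identical.
* A zero target is vacuously met; shortfall for it is zero.
* Degenerate OLS (constant protection) raises rather than returning NaNs.
* `protection_beta_params` with huge concentration collapses to 0.5;
  `range_contiguity = 0` yields all-singleton ranges; `n_ecoregions = 1`
  makes every species endemic — all exercised in tests.

## Known limitations

* The annealer is a stochastic heuristic; on large, cap-saturated worlds
  different portfolios can disagree by a species or two near the budget
  margin. The exact-ILP formulation is a natural extension and was left
  out of scope.
* The area cap is soft; reported solutions can exceed it when locked-in
  area alone does.
* Selection frequency is a priority proxy, not a probability of inclusion
  in any optimal solution.
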