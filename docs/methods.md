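# Methods

This note documents the models, algorithmic choices and limitations of
osteokit, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Input schemas

* `specimens.csv` — one row per bone fragment: `record_id, unit, square,
  taxon, size_class, element, portion_codes, side, age_class,
  surface_mods, burn_code, breakage, is_retoucher`. Comma-separated,
  UTF-8, "." decimal; multi-valued cells (portion codes, burn codes,
  marks) use ";" internally; marks are `kind:count` pairs. A record is
  identified either to a taxon or to a mammal body-size class 1–5, never
  both. Portion codes are integers 1–20; burn codes 0–5; age classes
  F (foetal/neonatal), J (juvenile), SAd (sub-adult), Ad (adult),
  S (senile) or indeterminate.
* `template.csv` — one row per taxon × element: `skeleton_count` (copies
  in a complete skeleton), `region` (axial/appendicular), `density`
  (maximum bone density, scaled to (0, 1]), optional utility indices
  (MGUI, FUI, CFUI, Marrow, Grease, UMI), per-age useable meat weights
  (kg, taxon-level), and taxon `habitat` (mountain/plain) and prey
  `rank` (high/low).
* Indeterminate family/genus pools ("Capridae (size 3–4)" and the like)
  are ordinary taxon strings; diet-breadth and ratio analyses operate on
  whichever taxon set the caller passes, and the bundled reference
  tables flag the six determined ungulate species explicitly.

## MNE and MNI

MNE is computed as the exact minimum number of whole elements into which
the observed fragments can be partitioned, subject to: disjoint portion
codes within an element, compatible sides (a determinate left can never
join a determinate right), and compatible age classes (the five
determinate classes are mutually exclusive; indeterminate joins any).
The popular shortcut — the maximum repetition count of any single
portion code — is only a lower bound: fragments `{1,2}, {2,3}, {1,3}`
repeat no code more than twice yet force three elements because they
pairwise overlap. The solver splits fragments into connected components
of the label-compatibility relation (components cannot share elements),
takes a first-fit-decreasing greedy partition, accepts it when it meets
the repetition lower bound, and otherwise runs a branch-and-bound search
with empty-group symmetry reduction. The search is exact; a node budget
(500k) guards against pathological inputs, falling back to the greedy
bound with a logged warning — never reached at realistic per-element
fragment counts. Indeterminate-side and indeterminate-age fragments are
therefore placed wherever they minimise the total, which is the
conservative (minimal) reading of the evidence.

MNI per element derives from the MNE decomposition. For paired elements
(skeleton count 2) the element instances form a graph whose edges link
instances that could belong to one individual (not the same determinate
side, compatible ages); the minimum number of individuals is instances
minus a maximum-cardinality matching (networkx). For elements occurring
k times per skeleton, sides are ignored and the exact bound
`max(ceil(N/k), Σ_a ceil(n_a/k))` applies, with indeterminate-age
instances filling residual capacity first. The assemblage MNI is the
maximum over elements; the per-age breakdown is taken from the element
attaining it (ties broken by template order). Both the MNE and MNI
routines are tested against exhaustive-assignment oracles on all
fixtures of ≤ 8 fragments / ≤ 6 instances.

A taxon represented only by specimens with no element attribution gets
MNE 0 and MNI 0 here: individuals are inferred from elements only, which
keeps the invariant MNI ≤ ΣMNE ≤ NISP on common records.

## Diet and mortality statistics

Inverse Simpson uses the plug-in form `1/Σ(nᵢ/N)²`, not the unbiased
`Σnᵢ(nᵢ−1)/N(N−1)` variant; the plug-in form is what reproduces the
published diversity values from the published counts. "Juveniles" are
F + J + SAd and "adults" Ad + S throughout (ratio, prime-age share,
ternary coordinates). Ternary points from fewer than five individuals
are flagged `excluded_from_plot`, following the usual reliability
convention for mortality triangles. Printed-precision comparisons round
half away from zero (`round_half_up`), matching how the source tables
print; one published NISP-based diversity value appears to be truncated
rather than rounded, so comparisons at that precision allow one unit in
the last printed place.

The bundled reference tables carry per-taxon NISP/MNI and unit-level
ungulate age rows only: per-taxon age breakdowns are not recoverable
unambiguously from the published tables, and no downstream statistic
needs them. Meat weights are configurable per taxon and age class
because published biomass figures imply age-dependent values that are
only partially recoverable; the synthetic caprine template ships one
plausible set.

## Transport–attrition model

Element probabilities are
`pᵢ ∝ skeleton_countᵢ · w(regionᵢ, α) · dᵢ^β` with `w = 1−α` (axial) and
`1+α` (appendicular), and observed MNE counts are multinomial over
elements. The linear transport weight is the simplest map matching the
interpretation endpoints (α = −1 excludes appendicular-…, α = +1 axial
elements; α = 0 transports everything); the power-law survivorship
`d^β` satisfies the qualitative constraints of density-mediated
attrition (β = 0 no loss; survival increasing in density; strong β
compatible with single-digit-percent preservation at typical densities).
Both are explicit modelling choices of this package; the original
method's exact parameterisation is unpublished in the source we follow,
so its printed point estimates are treated as format illustrations, not
validation targets. Overdispersion beyond multinomial sampling is not
modelled.

Priors are uniform: α on [−1, 1], β on [0, 12] (the default β_max
comfortably exceeds any attrition that leaves a recoverable assemblage:
at β = 12 a density-0.6 element survives 0.2% of the time). Sampling is
Gaussian random-walk Metropolis with boundary reflection; default
proposal scales (0.08 for α, 0.45 for β) give 20–50% acceptance on
assemblages of a few hundred MNE. A seed is mandatory and the sampler is
bit-reproducible. Convergence is reported as split-half R-hat (single
chain split in two; cross-checked against arviz in the tests) with a
warning above 1.1, and a warning (not an error) is issued below a total
MNE of 50, mirroring the applicability threshold customary for
skeletal-profile inference, plus a stronger one below 20. The
`preservation_fraction` summary is
`Σ skeleton_countᵢ·dᵢ^β / Σ skeleton_countᵢ`.

Validation: likelihood maximised at the generating parameters on a
grid; posterior recovery of (α = 0.1, β = 2.0) from N = 200 over a
20-element template within ±0.15 / ±0.5; per-parameter 90%-credible
coverage ≥ 80% over 20 replicates; marginal total-variation distance
< 0.05 between MCMC and direct 101×101 grid evaluation on a 5-element
template; label-swap symmetry (exchanging axial/appendicular negates the
α posterior).

## Catchment

Slope is the Horn 3×3 kernel, expressed as percent (100·tan); border
cells use edge replication and any window touching nodata yields nodata.
Walking speed is Tobler's hiking function (parameters exposed in
config), evaluated on the gradient along each step — the source
methodology names only "empirical formulae depending on distance, slope
angles, movement direction", and Tobler's function is the canonical such
formula. Travel times are exact shortest paths (Dijkstra).

The move stencil is 16 directions (queen + knight) by default. A plain
8-move stencil was rejected because its travel-time metric's unit ball
is an octagon covering only 2√2/π ≈ 90% of the Euclidean disc: flat-
terrain isochrone areas would be biased low by ~10% no matter how fine
the grid. The 16-move stencil reduces the metric deficit to ≈ 1.4%,
which together with cell quantisation keeps flat-DEM isochrone areas
within 5% of the analytic disc π(vt)². Knight moves are disallowed when
either cell they pass between is a barrier or nodata, so walls cannot be
hopped. Default isochrones are 72 and 129 minutes and the habitat split
is at 30% slope (beyond which grazing suitability is depleted); all
configurable. DEM I/O is Esri ASCII grid (plain text). The published
catchment areas for the real site are documentation only — they require
the site's DEM, which is not packaged.

## NPP and rank statistics

NPP series are consumed as data (kg/m²/year against years BP); the
ecosystem simulation that produces them is out of scope. Unit statistics
are the arithmetic mean and sample SD (ddof = 1) over timestamps inside
the occupation interval. Mann–Whitney uses exact enumeration of all
C(n, n_a) group assignments when the pooled size is ≤ 12 — this handles
ties, which the classical exact tables do not — and scipy's
tie-corrected normal approximation above; the two-sided exact p is
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Spearman uses midranks with the
standard tie correction; p is a full n!-permutation enumeration for
n ≤ 7 and the Student-t approximation above (published correlation
tables listing p = 0 reflect software truncation, not exact zeros).
Sidedness is two-sided throughout, as none of the source analyses state
otherwise.

## Synthetic generator

`generate_assemblage` draws, per individual and element copy: retention
with probability `w(region, α)/max(w)`, survival `d^β`, then
fragmentation into `1 + Poisson(intensity − 1)` fragments carrying
contiguous portion-code runs that partition {1..20} — contiguity makes
the MNE code-repetition machinery meaningfully exercised, since real
fragments are spatially coherent pieces of bone. Cut, percussion and
carnivore marks are independent per-fragment Bernoulli draws and burn
codes are categorical over 0–5. Default age structure (25% J, 10% SAd,
55% Ad, 10% S) approximates a living-structure cull of a medium ungulate
population. All randomness flows from one integer seed through numpy's
`SeedSequence` spawning, so per-taxon streams are independently
reproducible.

What the generator does *not* emulate: spatial excavation structure
beyond unit labels, recovery/sieving bias, inter-element correlation in
fragmentation (each element breaks independently), and
carnivore-accumulated (as opposed to carnivore-modified) components.
Passing tests therefore demonstrate the correctness of the estimators
under the stated formation model, not the realism of that model for any
particular site.

## Problem sizes

Defaults used in the test and acceptance experiments: 20-element
templates with N = 200 observed elements for recovery; 20 replicate
datasets for coverage at 8,000 iterations each; a 60,000-iteration
chain against the 101×101 grid posterior; 101×101 flat DEMs at 150 m
cells for the isochrone geometry check. These sizes were chosen so each
experiment carries enough information to discriminate a broken
implementation while the full suite remains quick to run routinely.

## Known limitations

* MNE exactness is guaranteed only within the search budget; extremely
  large single-component fragment sets would fall back to the greedy
  upper bound (logged).
* The MNI matching treats skeleton-count-k (k ≠ 2) elements as unsided
  pools; side information on such elements (e.g. sided phalanges) is
  ignored there.
* The transport/attrition posterior conditions on element identities of
  surviving MNE only; it ignores fragmentation intensity, which carries
  additional information about processing.
* Travel-time anisotropy assumes the DEM resolution resolves the
  terrain; gradients are finite differences along moves, not sub-cell
  interpolation.
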