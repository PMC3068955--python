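# Methods

## Network construction

A metabolic reconstruction enters as a table of reactions (substrates,
products, reversibility, flattened gene association, optional pathway
labels). The directed reaction-centric graph has an edge R1 → R2 iff a
non-currency metabolite is among R1's products and R2's substrates.
Three choices here are genuinely open and are resolved as follows:

- **Reversibility.** A reversible reaction is expanded into both
  orientations before the intersection test. This is the permissive
  reading: a reversible step can feed either neighbour, so pathway
  reachability is preserved.
- **Self-edges.** A gene catalysing two consecutive reactions would
  produce a self-edge at the gene level and make that node trivially
  "connected", inflating the coherence ratio; self-edges are dropped at
  both the reaction and gene level.
- **Pathway scoping.** When reactions carry pathway labels, adjacency
  is additionally restricted to reaction pairs sharing a label, which
  reproduces pathway-database-style constructions in which links only
  form inside a declared pathway. Without labels the global rule
  applies.

**Currency metabolites.** ATP, cofactors and similar ubiquitous
compounds connect nearly everything and carry no pathway information.
They are excluded either (a) globally, from an explicit list, (b) by a
degree heuristic flagging the `ceil(fraction × n)` highest-degree
metabolites (default fraction 0.04; degree counts distinct reactions,
ties broken lexicographically so the result is deterministic), or
(c) per reaction, via an optional `local_currency` column that silences
a metabolite only for the adjacency tests of that one reaction. Growing
the currency set can only remove edges; this monotonicity is tested.

**Gene projection.** Each reaction edge R1 → R2 expands to gene edges
g1 → g2 over the associated gene sets. Three mapping variants handle
ambiguous gene-reaction relations: using all multiplicities; dropping
reaction edges whose gene sets overlap; or keeping only edges between
reactions with single, distinct genes. The three edge sets are nested
(single-distinct ⊆ exclude-shared ⊆ all), which the suite checks on
random inputs. Gene-association Boolean structure (complexes vs
isozymes) is flattened to the union of genes: the coherence statistic
operates on gene presence, not enzyme logic. Genes of retained
reactions are kept as nodes even when isolated — they belong to the
null model's sampling universe. Networks from independent
reconstructions can be intersected (common nodes, common same-direction
edges) after the caller harmonises gene identifiers.

## Coherence statistics

The effective subnetwork is the node-induced subgraph on the
significant genes; a node is *connected* when it has at least one
incident edge within the subnetwork, in either direction (the statistic
asks whether changed genes are adjacent, not whether flux direction is
respected). Significant genes absent from the network are excluded from
the ratio but counted and reported.

MC is the z-score of the observed connected-node ratio against
size-matched random gene sets drawn uniformly *without replacement*
from the static network's node set — the universe is the network, not
the full array complement, so the statistic measures placement on the
network rather than array coverage. The default is 5000 null
realizations; each realization uses an RNG substream derived from
`(seed, realization_index)`, so results are independent of evaluation
order and parallelisation. Sample standard deviation (ddof = 1) is
used. A zero-variance null (e.g. a clique, where every subset is fully
connected) is reported as z = 0 with a `degenerate` flag rather than an
error, so batch runs over many networks never crash.

The jackknife removes `floor(drop_fraction × n_calls)` entries from the
call table (significant and non-significant alike; default 10 %, 100
repeats) and recomputes MC. The null-model seed is held fixed across
repeats and only the removal varies, so the reported spread isolates
data-removal sensitivity and the zero-drop limit reproduces the
full-data MC exactly, repeat by repeat.

## TRN statistics

The regulatory network is filtered to links whose *target* is a
metabolic gene; regulators are retained regardless of their own
metabolic status. The digital CTC is literally the MC machinery run on
this graph (one shared implementation; an equality test enforces it).

For sign consistency, an effective link requires a significant, signed
call at both endpoints — a TF whose own expression is unchanged
contributes no effective links, a deliberate choice over inferring TF
activity. Activation is consistent with equal signs, repression with
opposite signs; dual-effect links (ambiguous "+-" annotations) are
excluded from both numerator and denominator since neither verdict is
defined for them, and this exclusion is recorded in the output
metadata. The null permutes the observed sign multiset over the
effective nodes — a permutation, not an independent ±1 resampling, so
the sign composition is preserved exactly in every realization. The
consistency predicate is invariant under a global sign flip, which the
suite checks.

## Flux balance analysis

FBA maximizes the biomass flux subject to steady state (S·v = 0) and
bounds, solved with HiGHS via `scipy.optimize.linprog`. Exchange
reactions are identified by single-metabolite stoichiometry (a
single-metabolite biomass drain in minimal toy models is exempted) and
are written in export orientation: uptake is negative flux, and a
medium is a map of non-negative uptake bounds applied to exchange lower
bounds before solving; exchanges absent from the medium are closed for
uptake but open for secretion. Infinite bounds are capped at 1e6 flux
units for the solver.

Optimal vertices are generally not unique, and the set of active
reactions depends on which vertex the solver returns. The default is
therefore *parsimonious*: a second LP fixes the biomass optimum and
minimizes total |v|, giving a canonical solution. Only the objective
value is contracted across solvers; active sets are documented as
solution-dependent. A reaction is active when |v| > 1e-6 (the
threshold exists because solver output is never exactly zero; 1e-6 is
far below any meaningful flux at uptake bounds of order 10).

Activity filtering re-runs the projection on the active reaction
subset, so genes attached only to inactive reactions drop out and no
gene edge survives across an inactive gap. Medium reduction starts
from a rich medium and repeatedly removes one uniformly chosen
*removable* component (one whose removal keeps biomass > 1e-6 —
strict positivity, not a fraction of maximal growth) until none
remains; the final medium is verified minimal post hoc. Many
trajectories exist; the MC-vs-medium curve averages over seeded
trajectories, indexing steps from the rich end and reporting per-step
n when trajectories have unequal lengths.

## Synthetic data

The generator emulates the statistical structure of a
four-background × two-condition supercoiling study at desk scale, not
its biology:

- **Toy metabolism** — 15 linear pathways of 4–8 reactions over
  private metabolites, one gene per reaction, plus 2 currency hubs
  riding on both sides of ~30 % of reactions (the ATP/ADP pattern).
  ~90 metabolic genes total: large enough for stable z-scores with 25
  significant genes, small enough that 5000-realization nulls run in
  fractions of a second.
- **Planted expression calls** — ⌈p·k⌉ of k = 25 significant genes are
  collected by random walks along network edges, the rest drawn
  uniformly; the planting fraction p interpolates smoothly between the
  null (p = 0 is *exactly* the null sampler, verified by a two-sample
  chi-square on selection frequencies) and fully pathway-contiguous
  selection (p = 1). Walk-based planting, rather than whole-pathway
  selection, makes mean MC a monotone dose in p — the basis of the
  parameter-recovery check. Signs are coherent within a walk with
  probability 0.9. The four-background preset is p = 0.8 (wild type),
  0.35 (each single NAP mutant), 0.1 (double mutant): the wild type
  converts the perturbation into pathway-coherent changes, mutants
  progressively degrade to noise.
- **Toy TRN** — 12 TFs regulating 40 metabolic targets, each target
  having exactly one regulator so a fully consistent sign assignment
  always exists; 60 % activation. Companion generators emit fully
  consistent and sign-shuffled call sets.
- **Toy flux model** — ⌈n/2⌉ substitutable nutrients feeding a common
  precursor chain and the rest essential, each required by biomass; the
  optimum min(n_sub·u, u) for uptake bound u = 10 is recorded as ground
  truth, as are the essential/substitutable labels that the
  medium-reduction tests verify independently.

What passing tests on these data do **not** show: robustness to the
gene-identifier mismatches, incomplete reconstructions, compartment
duplication and correlated measurement noise of real databases and
arrays. The synthetic metabolism is tree-like per pathway; real
metabolic networks have cycles and hub enzymes beyond currency
metabolites, which typically lower null variance and hence shift MC
magnitudes.

## Numerical and scale choices

Monte-Carlo checks compare sampled null moments with exhaustive subset
or sign-permutation enumeration within 3 exact standard errors (the
variance comparison uses the exact fourth moment). Calibration and
recovery tests use 1000-realization nulls and 100–200 synthetic
datasets; the acceptance script uses 5000 realizations for headline
statistics and 1000 for replicate sweeps. All stochastic entry points
take explicit integer seeds; derived substreams come from
`numpy.random.SeedSequence` keyed tuples, making every result
reproducible bit for bit from the seed recorded in the output.

## Known limitations

- Stoichiometric coefficients do not enter adjacency (presence/absence
  only), and AND/OR gene-association semantics are flattened.
- No identifier harmonisation across reconstructions; intersection
  assumes the caller already mapped gene namespaces.
- The null matches effective-set size only (no degree matching).
- Active-reaction sets inherit LP alternate-optima ambiguity; the
  parsimonious default makes them reproducible, not unique in any
  biological sense.
- TRN consistency requires a significant call on the regulator; TF
  activity changes without expression changes are invisible.
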