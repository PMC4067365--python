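# Methods

## Model

`ecotypesim` simulates a well-mixed (strictly sympatric) population of
haploid asexual organisms competing for `R` perfectly substitutable
resources. Individual `i` is fully described by its phenotype, a vector of
resource affinities `c_ik` confined to the discrete grid
{0, 0.1, ..., 1.0}. Fitness combines Monod (half-saturation) uptake
kinetics with an explicit trade-off cost:

    F_i = 1/(1 + D_i) * sum_k c_ik * r_k / (r_k + gamma_k)
    D_i = sum_k ( sigma1 * c_ik + sigma2 * xi(c_ik) ),   xi(c) = [c > 0]

`sigma1` prices affinity magnitude (diminishing returns of investing in
uptake), `sigma2` prices each maintained uptake pathway regardless of its
strength. With both at zero a generalist "superspecies" is unbeatable;
with strong costs, specialists on single resources win and coexist through
negative frequency-dependent selection: a phenotype feeding on a crowded
resource sees that resource depleted, while a rare phenotype's resource is
nearly untouched.

Resource `k` follows chemostat-like dynamics integrated by forward Euler
with one step per update:

    r_k <- max(0, r_k + N*lam_k - c0*r_k - sum_i F_ik)

Influx `N*lam_k` is a property of the environment (the configured
population-size parameter `N` times the per-individual influx `lam_k`),
decay is proportional with rate `c0`, and consumption equals the summed
per-resource fitness of the pre-update population. Without consumption the
abundance relaxes geometrically (ratio `1 - c0` per update) to
`N*lam/c0`; with total consumption and no decay it holds at `N*lam`.
Over-consumption clamps at zero rather than rescaling individual fitness:
fitness is always evaluated from the pre-update abundances.

## Population process

Constant-census mode is a death-birth Moran process with multiple events
per update: `round(kill_fraction * N)` individuals (default 1%) are removed
uniformly at random, then each vacancy is filled by the offspring of a
surviving parent drawn with probability proportional to fitness, with
replacement (one survivor may parent several offspring in one update). At
1% turnover one generation is about 100 updates. Fitness is computed once
per update from the pre-update resource state; deaths happen before
births, and parents are drawn from survivors only. If every survivor has
exactly zero fitness, parents are drawn uniformly — the process degrades
to neutral drift instead of halting.

Offspring inherit the parent's phenotype, and every trait mutates
independently with probability `mu` (so simultaneous multi-trait mutations
occur at rate ~`mu^2` per pair). A fraction `trait_lethal_fraction`
(default 0.7) of mutations are trait-lethals that reset the affinity to 0
— motivated by the fragility of linear metabolic pathways, where one loss
disrupts the whole trait; the rest step the affinity by +-0.1 with equal
probability, clamped (as a no-op) at the grid ends. Affinities are stored
as integer tenths internally, so grid membership is exact by construction.

Variable-census mode replaces fitness-proportional replacement with an
absolute-fitness rule: the same fraction is removed uniformly (with a
floor of one removal per update; a plain `round` would freeze any census
below `1/(2*kill_fraction)` at zero deaths), then every survivor
reproduces independently with probability `min(F_i, 1)`. The census is
stationary where mean fitness balances the removal rate. Note that the
influx reference in the resource update stays at the configured `N` in
this mode: the environmental supply rate is fixed, which is what makes a
stationary census possible at all — if influx tracked the census, the
per-capita fitness ceiling would be `R*lam` at every size and no census
could balance a removal rate above it. This choice also reproduces the
stationary sizes the constant-mode runs are compared against (about 755 at
`lam = 1e-3` with `N = 1000`, about 2520 at `lam = 10^-2.4`). Extinction
is a normal terminal outcome, reported on the result, and
`initial_population` sets the starting census (near the expected
stationary size, to keep the initial transient from killing the run).

## Measurement protocols

**Zero-mutation competition.** Ecotypes are counted under the Ecological
Species Concept: distinct phenotypes that stably coexist. From a run
endpoint the dynamics continue with `mu = 0` so no new phenotypes arise
and transients are competitively excluded. The competition spends its
full budget of 80,000 updates, exiting early only when the population is
monomorphic: in near-neutral regimes exclusion is drift-paced, and
stopping at apparent stationarity over any finite window would
systematically over-count slowly dying phenotypes. Steadiness over a
trailing window of 5,000 updates (snapshots every 250; no phenotype
lost, no above-threshold frequency moving more than 20% relative) is
still computed and reported: `capped` flags an assay whose composition
was not yet steady when the budget ran out, and `stabilized_at` records
when the surviving set last changed. Phenotypes below 0.5% frequency
at the end are ignored as drift debris — far below any per-ecotype
equilibrium frequency in the specialized regimes (~1/R of the
population). Phenotype identity is exact equality of the affinity vector;
the grid is discrete, so no clustering is needed.

**Invasion when rare.** The direct test of negative frequency-dependent
coexistence: rebuild the population with the focal ecotype at 1% (at
least one individual) and the remainder split among the others
proportional to their assay frequencies, run `mu = 0` dynamics, and
declare success if the focal count exceeds twice its initial value for
500 consecutive updates before extinction or timeout. Identical
phenotypes are counted by row equality, so an invader identical to a
resident is frequency-indifferent and fails the strict recovery
threshold.

**Niche breadth.** `B = sum_{i,k} xi(c_ik) / (N*R)`: 1/R for pure
specialists, 1 for pure generalists.

## Genealogies

Every birth is recorded as a parent pointer; the phenotype is stored only
at phenotype-changing births, so a line of descent compresses to its
mutational history. The forest is pruned every 1,000 updates to ancestors
of the living, which provably never changes MRCA or line-of-descent
answers for living individuals. The MRCA of a set of individuals is the
most recent record ancestral to all of them (possibly none, when several
founders' lineages persist). A mutation's selection coefficient is

    s = F_mutant / F_parent - 1

evaluated at the resource state the mutant was born into (the state at
the start of its birth update); it is undefined (NaN, flagged) when the
parent's fitness is zero. This is the standard relative-fitness
coefficient; it makes the first affinity-gaining mutation of a starving
founder population enormously beneficial (order 10), since it taps
near-pristine resources. Phylograms are exact genealogies, not
inferences: internal nodes sit at coalescence updates, branch lengths are
in updates (all reported timings are in updates), and trees are emitted
as Newick with lineages from distinct founders joined at a root of age 0.

## Numerical choices

Fitness is not clamped in constant-census mode: parent choice is
proportional to fitness, so only relative values matter, and with weak
costs and many high affinities `F_i` can arithmetically exceed 1. In
variable-census mode, where `F_i` is used directly as a reproduction
probability, it is clamped to `min(F_i, 1)`. Ties and degenerate cases:
all-zero survivor fitness falls back to uniform parent choice; a +-0.1
mutation drawn at a grid end is a no-op (clamp, not reflect or resample);
the number of constant-mode deaths is `round(kill_fraction * N)` (one per
update at N=100). Reproducibility is bit-for-bit in (config, seed): all
randomness flows through one generator per run, and sweep run seeds are
`base_seed + run_index`.

## Defaults and problem sizes

Defaults follow the reported parameterization: `R = 9`, `gamma = 100`,
`c0 = 0.1`, `kill_fraction = 0.01`, `trait_lethal_fraction = 0.7`,
`mu = 0.05`, `N = 1000`, 40,000-update runs with up to 80,000 assay
updates. `gamma` and `lam` accept per-resource vectors but are scalars in
every study condition. The headline measurements in
`scripts/acceptance.py` use 5 replicates per condition (10 at `N = 100`,
2 at `N = 2520`), the package's own desk-scale replication choice;
replicate seeds are spawned from the command-line seed.

The test suite includes a neutral control in which all phenotypes carry
zero affinity: fitness is identically zero, the uniform-parent fallback
produces pure drift, and founder-label fixation times are checked against
an independent neutral multi-death Moran simulation.

## What the simulations do and do not show

All data here are generated by the model itself; there is no external
data. The simulator emulates resource competition with explicit
trade-offs, not any particular organism: resources are perfectly
substitutable, space and migration are absent, reproduction is clonal,
and there is no explicit genetics (trade-offs are imposed by the cost
function rather than emerging from pleiotropy or epistasis). Passing
tests therefore demonstrate the internal logic of trade-off-driven
specialization — transitions in ecotype number with influx, costs,
trait-lethal fraction, and population size — not quantitative predictions
for any empirical system.

## Known limitations

- The ecotype count in near-neutral regimes (high influx, weak costs,
  small populations) depends on the competition budget: exclusion there
  is drift-paced, and some slowly dying phenotypes survive any finite
  assay. The 80,000-update cap matches the reference protocol; the
  capped flag reports when it was hit.
- The stability window cannot distinguish very slow exclusion from true
  coexistence; invasion experiments are the decisive instrument and are
  available for every assay output.
- Variable-census runs below the viability range (roughly
  `lam < 2e-4` at `N = 1000`) go extinct during the initial transient;
  this is expected model behavior, reported per run.
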