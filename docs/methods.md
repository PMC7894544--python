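# Methods

`genechron` dates the birth and spread of microbial gene families — its
motivating application is the nitrogen-cycle enzyme repertoire (nitrogenase
subunits *nifH/D/K* and the alternative *vnf*/*anf* systems, nitrate and
nitrite reductases *narG/napA/nasA/nirK/nirS/nirB/nrfA*, *norB*, *nosZ*,
*nxrA*) — by reconciling gene trees against a fossil-calibrated chronogram
of the host species and aggregating the inferred events through time.  This
note records the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Homolog screening

Candidate gene sets arrive as homology-search hit tables (BLAST outfmt-6
dialect with an extra `query_length` column).  Screening applies, in order:

1. an e-value ceiling — default `1e-12`; per-gene overrides, shipped for
   *nifD*/*nifK* at `1e-30` because the two subunits share an ancient
   duplication history and cross-hit at looser thresholds;
2. a minimum aligned fraction of the query — default 0.5 (hits covering
   less than half the query are discarded);
3. optional key-residue checks on a reference alignment (a sequence passes
   only if every required column holds an allowed residue; gaps never
   pass).  Residue specs are user-supplied input files: curated residue
   sets are gene-specific expert knowledge, and the example spec shipped
   with the fixtures is synthetic and illustrative only;
4. ortholog-group confirmation — ids whose assignment differs from the
   expected label are dropped; ids missing from the assignment table are
   dropped and counted separately in the attrition log.

Thresholds are sided so a hit at exactly the ceiling, or exactly half
coverage, passes.  Both filters are idempotent and monotone: tightening any
threshold can only shrink the retained set.

## Chronogram estimation

The species topology is fixed; only node ages and clock parameters are
estimated.

**Prior.**  The root age carries a normal prior (default mean 3800 Mya, SD
200 Myr) truncated below by the oldest applicable hard calibration bound.  A
gamma alternative with the same mean/SD is available as a config option but
not endorsed.  Interior node ages, expressed as fractions of the root age,
are uniform over the valid root-to-tip orderings (the order polytope of the
internal-node poset); hard minimum ages on named clades (fossil or
geochemical anchors, e.g. the six-row calibration table bundled with the
fixtures) are enforced as indicator constraints, so every retained sample
satisfies every bound.  Exact draws from this prior are obtained by sampling
a uniformly random linear extension of the tree poset (bottom-up uniform
riffles) and attaching the order statistics of iid uniforms; interior minima
are imposed by bounded rejection.

**Clock.**  `strict` uses one global rate with a lognormal prior (default
median 1e-4 subs/site/Myr, log-SD 0.5).  `ugam` (uncorrelated gamma) further
multiplies each branch by an independent gamma variable with mean one
(default shape 2); this is the closest standard reading of an uncorrelated
relaxed clock.  Autocorrelated clocks (rates evolving along the tree, e.g. a
Cox–Ingersoll–Ross process) are out of scope; published comparisons report
the same broad temporal patterns under either family.

**Likelihood.**  Felsenstein pruning under the equal-rates, equal-frequency
K-state model (Jukes–Cantor at K=4), vectorised over compressed site
patterns.  Branch expected substitutions are `rate x multiplier x duration`.
Richer substitution models belong to upstream tree inference, which this
package deliberately takes as input; the model interface is pluggable.

**Sampler.**  Metropolis-within-cycle sweeps: (i) every interior node's
relative height slides uniformly within its parent/child window (a
prior-conditional proposal, so acceptance is the likelihood ratio alone);
(ii) a random-walk move on the root age; (iii) a joint rescaling that
multiplies the root age by `c` and divides the global rate by `c` — the
likelihood depends only on rate x time products, so this move is
likelihood-invariant and mixes the otherwise prior-identified time scale
efficiently; (iv) multiplicative moves on the global rate and (for UGAM)
each branch multiplier.  Each chain draws a fixed number of random variates
per cycle, so runs are reproducible from the seed and extending a run
reproduces the shorter run's samples exactly.

**Convergence and summaries.**  Two chains run by default.  The run passes
when every node-age effective sample size exceeds 100 (autocorrelation-based
ESS) and the maximum two-sample Kolmogorov–Smirnov distance between the
chains' node-age marginals is below 0.3; the first 20% of cycles are
discarded as burn-in (configurable).  Summaries pool post-burn-in samples:
point age = posterior mean, interval = 2.5/97.5 percentiles.  Prior-only
runs (likelihood omitted) support prior-sensitivity checks.  With a free
global rate the data inform the root age only through interior calibration
anchors: prior-only sampling satisfies a clade minimum by floating that
clade's relative height, whereas sequence data pin the height and transmit
the bound to the root.  The bundled sensitivity check therefore anchors
several mid-depth clades at their true simulated ages — the idealized
fossil minimum — and requires a Kolmogorov–Smirnov separation above 0.1
between the prior-only and with-data root-age marginals.

## Time-sliced DTL reconciliation

The chronogram is cut into slices at its distinct node ages; within a slice
the set of living branch segments is constant, and a transfer may only
connect two segments of the same slice — this is the temporal consistency
constraint that distinguishes dated from undated reconciliation.

Penalties default to transfer 3, duplication 2, loss 1, speciation 0.  The
minimum-penalty scenario is found by a dynamic program over (gene node x
segment x slice), bottom-up in time.  Within a slice a lineage may duplicate,
branch by transfer, or jump segments via a transfer whose donor copy is
immediately lost (charged as one transfer plus one loss; a single jump
suffices because chained jumps are never cheaper).  At a slice boundary a
lineage continues, speciates (both sides survive; one speciation logged), or
passes through the speciation node losing one side (one loss logged, no
speciation — losses are charged per lost species branch).  The gene birth is
free and may sit on any segment in any slice, so a family confined to a
subclade is explained by a birth on that subclade's stem with no losses.

**Feasible intervals.**  Each event is reported with the temporal region in
which it could have occurred: for a transfer, the coexistence window of
donor and recipient branches; for duplications, losses and births, the host
branch's span; for speciations, the node age itself.  The reported event
date is the interval midpoint.  (An earlier, narrower convention — the
single DP slice — was rejected: planted transfers fall inside the one-slice
window only ~30% of the time even when donor and recipient are exactly
recovered, because the minimum-cost placement is free to slide across
slices; the coexistence window is the defensible meaning of "when this
event could have happened".)

**Rooting.**  Unrooted gene trees are reconciled once per branch-rooting and
the cheapest kept; ties break by the lexicographically smallest (HGT, DUP,
LOS) count vector, then branch index, so results are reproducible.

**Bootstraps.**  Bootstrap replicate sets are reconciled independently and
aggregated: events are matched by (class, location, interval), support is
the fraction of replicates containing the event, and the consensus keeps
events at support >= 0.5 (configurable).  The reported penalty is the median
across replicates.  This replaces opaque multi-tree amalgamation with a
transparent consensus contract serving the same purpose (robustness of the
event list to gene-tree uncertainty).

**Correctness.**  The DP is checked against an independent exhaustive
oracle — a uniform-cost search over global scenario states (slice index x
set of pending gene-lineage placements) that enumerates bounded within-slice
event chains and all boundary outcomes.  On hundreds of random instances
with up to five species and five gene leaves, under three penalty schemes,
the DP minimum equals exhaustive enumeration exactly.

## Event aggregation

Birth intervals: a family's birth is bracketed by the chronogram node above
its host branch (upper, the earliest possible timing) and the node below
(lower, the latest), each reported with its 95% credible interval; a birth
at the species root is reported as root age over the older root child's age.
The midpoint dates the birth and a geologic era labels it.  Era boundaries
default to the international chronostratigraphic values (Eoarchean
4000–3600, Paleoarchean 3600–3200, Mesoarchean 3200–2800, Neoarchean
2800–2500, Paleoproterozoic 2500–1600, Mesoproterozoic 1600–1000,
Neoproterozoic 1000–541, Phanerozoic 541–0 Mya), user-overridable; a shared
boundary age belongs to the older era.  Reported dates round half-even to
two decimals.  Note that a midpoint recomputed from two-decimal node dates
can differ from a midpoint computed on unrounded ages in the final digit
(e.g. a printed 963.735 splits either way); era labels are insensitive to
this.

Event densities bin event midpoints per gene (default 100-Myr bins), for all
events and for transfers alone, with per-gene proportions and an ordering
key (the gene's oldest event) for stacked panel plots.

## Synthetic data: what it emulates, what it does not

The generator provides every input with known ground truth:

* **Species trees** — constant-rate birth–death, conditioned on the number
  of surviving tips by bounded rejection (default 10,000 attempts),
  rescaled to the chosen root age (default 3800 Mya); extant-only leaves,
  strictly binary.  Default rates 1e-3 births and 4e-4 deaths per lineage
  per Myr give realistic crown shapes at 10–20 taxa.
* **Gene families** — lineages copy at speciations, duplicate/transfer/die
  at exponential waiting times; transfers are additive with a recipient
  drawn uniformly among co-existing branches.  The planted log records
  every event with its true time, and the generator also reports the
  *observable* event multiset — what a perfect parsimony reconciliation of
  the surviving tree could report: events in fully extinct subtrees vanish,
  a one-sided speciation collapses to a loss, a transfer whose donor copy
  died collapses to transfer+loss, and one-sided branchings above the first
  surviving split vanish entirely (a free birth placement absorbs them).
  Recovery benchmarks compare against this observable set, because no
  method can count events that left no trace.
* **Alignments** — the equal-rates K-state process above.
* **Hit tables** — outfmt-6-like rows with log-uniform e-values and uniform
  aligned fractions, each row labelled with its ground-truth filter verdict.

Topological noise is modelled by nearest-neighbour interchanges rather than
re-inferring trees from sequences; this keeps the noise level an explicit
dial with the truth known.  The noise level has no field-anchored default
and is an experiment parameter.

Passing the synthetic benchmarks shows the machinery is internally correct
and well calibrated under its own generating assumptions.  It does not show
robustness to model misspecification in real data: alignment error, rate
heterogeneity across sites and lineages, replacement transfers, transfers
from extinct donors, and biased taxon sampling are all absent from the
generator.

## Benchmark sizes

These are the problem sizes the bundled test suite runs; each was chosen as
the smallest size at which the corresponding check is statistically
meaningful.  All quantities are recomputed by the tests on every run.

* DP-vs-enumeration: 200 random instances (species and gene trees up to 5
  leaves), three penalty schemes — exact agreement required.
* Planted-event recovery: 100 families on a 20-taxon, 3800-Mya chronogram
  at rates 2e-5 dup / 6e-5 hgt / 2e-5 loss per lineage-Myr (about two
  non-speciation events per family).  Requirement: >= 80% of all planted
  transfers recovered with the true time inside the inferred interval and
  the matching recipient branch; aggregate class counts within 20% of the
  observable totals.
* Clock calibration: 20 replicates, 10 taxa, 2000 sites, strict clock,
  truth drawn from the prior (root, interior orderings, rate) so nominal
  95% coverage is exact for a correct sampler; single chains of 1800
  cycles, 20% burn-in.  Requirement: coverage within binomial tolerance of
  0.95, all hard bounds satisfied in every sample, median absolute relative
  age error < 15%.

## Known limitations

* Parsimony, not likelihood: no probabilistic DTL rates, no transfer from
  extinct lineages, no replacement transfers.
* The DP's rooting search is exhaustive per gene tree; on large gene trees
  with hundreds of leaves it is quadratic-ish in practice and would need
  the usual reuse tricks.
* The dating model's substitution process is deliberately simple; real
  amino-acid alignments should be dated with their inference-grade models
  upstream, with this package consuming the resulting chronogram.
* Era assignment requires ages within the configured table; chronograms
  older than 4000 Mya need a user-supplied table with a Hadean row.
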