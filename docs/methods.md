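# Methods

## The simulation scheme

polysim simulates template-based polymerization processes — replication,
transcription, translation — with Gillespie's exact stochastic simulation
algorithm (SSA) over a hybrid state representation:

* **Pools.** Freely diffusing chemicals and template sequences are
  populations: a single integer count (molecule number or copy number).
* **Particles.** A chemical bound to a template is an individually tracked
  `BoundUnit` holding exactly four fields: the sequence it sits on, its
  reading position, the binding site it arrived through, and whether it is
  still on that origin site. Particles belong to exactly one external
  state class (`BoundChemical`, e.g. "RNAP in elongation"); reactions
  address classes and draw the fired particle uniformly, so a single
  generic reaction set (one loading rule per nucleotide or codon, one
  translocation, one release) serves every gene simultaneously.
* **Bookmarking filters.** Two incremental structures expose the eligible
  subset of a class: a *family filter* (particles still on an origin site
  of one family, hence able to unbind — kept per site so unbinding can be
  weighted by each site's k_off) and a *template filter* (particles
  partitioned by the motif currently under their reading window, hence
  able to load the matching monomer carrier). Filters are updated on
  every class add/remove; position changes happen only while a particle is
  detached, which keeps the update rule local. Particle objects are
  recycled through a free-list.

Site occupancy is tracked in aggregate per binding site:
`available = copies − occupied`. Occupancy is acquired at binding and
returned the moment a particle leaves its origin site (first
translocation, unbinding, destruction). Bound particles do not exclude
one another along the sequence body — no polymerase/ribosome collisions —
and sequences are immutable; both are deliberate scope limits of the
representation.

## Reaction classes and propensities

* `ChemicalReaction` — mass action with falling factorials for repeated
  reactants (`A+A` at count n fires at `k·n·(n−1)`), so a channel can
  never fire with insufficient molecules. At most one bound class per
  side; a bound reactant with no bound product destroys the particle; a
  bound reactant *and* product carry the particle (and its position)
  across, which is how the polymerization step of an elongation cycle is
  expressed. Reversible reactions are stored once but scheduled as two
  independent channels.
* `SequenceBinding` — forward propensity
  `free_count · Σ_sites k_on·available(site)`; the site actually bound is
  drawn proportionally to `k_on·available`. Reverse propensity sums
  `k_off` over particles still on their origin site.
* `Translocation` — `rate · |class|`; the landing position is checked
  against switch annotations (input class must match the post class), so
  terminators and regulatory sites trigger exactly on arrival. Landing
  positions are checked only where the particle lands — annotations for
  codon-stepping processes must sit on the reading frame. Positions are
  capped at the sequence length.
* `Loading` — one propensity channel per loading reaction, valued
  `Σ_motifs rate_m · carrier_count_m · |partition_m|`; at firing the motif
  is drawn proportionally to this decomposition, then the particle
  uniformly within the partition. (One channel per *motif* would force
  every translation step to refresh ~61 codon channels; the single-channel
  form is equivalent in law and keeps the dependency fan-out constant.)
* `Release` — detaches a uniform particle, frees the listed chemicals and
  creates the product sequence selected by (origin family, position)
  interval lookup, e.g. the mRNA for a given promoter/terminator
  combination. Unmatched positions raise by default (silent product loss
  hides model bugs); a warn-and-continue mode exists.
* `TimedEvent` — ADD / SET / REMOVE_FREE on free pools. REMOVE_FREE
  clamps at zero and touches only the free pool, which is what makes
  wash-out experiments leave sequestered complexes behind.

## The solver

The main loop is the classic exact SSA: draw τ ~ Exponential(total
propensity), advance, select a channel with probability a_j/total, fire,
refresh the channels whose inputs changed. Firing returns the state keys
it touched (pools, class populations, site families); an inverted
read-map then identifies exactly the dependent channels, so the refresh
cost per event is the dependency fan-out, not the channel count. Timed
events are interleaved exactly: when t+τ would cross the next event time
the clock advances to the event, the event applies, and τ is discarded
and redrawn — valid by memorylessness.

Three interchangeable selection structures implement the same
distribution (ties at the threshold resolve to the first channel whose
cumulative sum reaches `u·total`, in all three):

* **direct** — linear cumulative scan, O(R);
* **tree** — binary tree of partial sums, O(log R) updates and selection;
* **cr** (default) — composition–rejection: channels grouped by the
  power-of-two bracket `a_j ∈ [2^g, 2^(g+1))`; groups chosen by
  composition over group sums (the group list is scanned linearly; its
  length is bounded by the log of the propensity dynamic range), the
  channel inside by rejection against the group cap, with fewer than two
  expected rejections per draw. O(1) in the number of channels.

All stochastic choices (τ, channel, site, particle, motif) draw from one
seeded PCG64 stream in a fixed order, so (model, seed, solver) determines
the trajectory bit for bit. Stored totals are refreshed from scratch
every 10⁶ events to bound floating-point summation drift, and a
zero-total selection triggers a defensive full refresh.

Per-event cost is measured on conversion cascades in their *spread*
regime (molecules distributed along the pathway — the state a long run
spends nearly all events in), with one-off setup costs cancelled by
differencing two runs of different event budgets. Measuring from the
initial all-at-stage-zero state would flatter the direct method, whose
scan stops at the first propensity mass.

## Gene-expression models

`synthesize_genome` generates random ACGT genomes with well-formed
per-gene annotations: 10 nt promoter, transcription start, a 30 nt
transcript leader containing the ribosome binding site, ATG + sense
codons + stop (coding length divisible by 3; internal stops excluded so
the generic codon table never strands a ribosome), a 15 nt trailer, and
the terminator position. It emulates the *annotation classes* of a real
bacterial gene set, not its statistics: no operons, no overlapping genes,
no strand structure (a double-stranded template would simply be two
sequence objects), uniform base composition. Tests passing on these
genomes demonstrate the engine's bookkeeping and kinetics, not biological
realism of any particular genome.

`build_gene_expression` wires one shared (generic) machinery set —
4-motif nucleotide loading, polymerization, translocation, terminator
switch, release for transcription; 61-codon loading, transpeptidation,
3-step translocation, stop switch, release for translation — plus
per-gene annotations and initiation records. Granularities:

* **detailed** — elongation base per base and codon per codon through the
  generic set;
* **aggregated** — binding stays sequence-based, then two reactions per
  gene replace elongation: a +50-base hop (which frees the binding site)
  and a one-step synthesis+release whose rate is the elongation speed
  over the gene length, so synthesis occupancy times match the detailed
  description. The one-step synthesis does not consume monomer carriers
  (pools are buffered under the default metabolism);
* **hybrid** — a seeded random fraction of genes (default 5%) detailed,
  the rest aggregated; specific genes can be forced detailed.

Initiation and termination are identical in all granularities and last
about 1 s. Messengers and proteins are not degraded and accumulate.

### Kinetic parameters (defaults, per second)

| process | limiting step | other cycle steps |
|---|---|---|
| transcription | translocation 50 | polymerization 500, loading 1000 effective |
| translation | loading ≈20 effective | transpeptidation 150, translocation 150 |
| replication | translocation 750 | polymerization 10 000, loading 3000 effective |

Effective loading rates are realized as rate-constant × carrier-pool
size, so loading scales with monomer abundance. Note the realized cycle
speed is the harmonic combination `1/Σ(1/k_i)` — 43.5 bases/s for the
transcription settings, 566 bp/s for replication — 10–25% below the
limiting-step headline rate; the validation suite reports both numbers.

Replication is provided as a single-origin, single-fork base-per-base
template plus the lagging-strand recruitment arithmetic: 1000 bp Okazaki
fragments at a 750 bp/s fork mean a polymerase recruitment every 1.33 s,
encoded as |DNAP_free|·r_recruitment = 3/4 (10 polymerase copies, ~7.5
free, recruitment rate 0.1/s); the builder refuses off-balance
parameters. Multi-fork replication is out of scope.

Metabolite renewal modes: **constant** (buffered pools, default),
**detailed** (per-molecule regeneration reactions), **stacked**
(regeneration in stacks of 100 or 1000). Stacked regeneration uses a
gated zeroth-order rate law (propensity k once a full stack is
available) rather than mass action: a falling factorial with
stoichiometry 100 is astronomically large and physically meaningless for
a stack-transfer pseudo-reaction.

### Desk-scale study conditions

The benchmark genome has 10 genes of 300–600 nt served by 5 RNA
polymerases and 8 ribosomes — machine counts scaled to the gene count so
the machinery is busy but not pathologically queued. These, with the
rate table above, are the package's default conditions for the
case-study and consistency experiments; genome-scale runs (thousands of
genes, ~3×10⁶ proteins per cycle) are expressly not reproduction targets.

## Case studies

**Tetracycline** extends a detailed model by one reversible reaction:
loading-phase ribosomes + free tetracycline ⇌ stalled ribosomes
(k_on 10⁻⁵ per molecule per second, k_off 0.1/s — slow dissociation, so
sequestration outlasts the wash), an injection event at t=200 s and
repeated REMOVE_FREE washes from t=400 s. At 20 000 molecules the
capture rate (0.2/s) is comparable to the release rate, inhibiting
translation partially; at 10⁶ (capture 10/s) ribosomes are almost fully
sequestered. Final protein output therefore decreases monotonically in
the injected amount.

**T-box attenuation** regulates one detailed gene: a switch site 25 nt
into the transcript leader reroutes elongating polymerases into a
`tbox_RNAP` state, which resolves by second-order reactions with the two
tRNA forms (the tRNA acts as a sensor and returns to its pool): uncharged
tRNA resumes elongation, charged tRNA sends the polymerase to an aborting
class whose release emits an annotated aborted transcript. Charging
(tyrosine + uncharged → charged at 10⁻⁶, i.e. ~1/s per tRNA at the 10⁶
tyrosine pool) against a 0.05/s discharge keeps ~95% of the 1000 tRNAs
charged while tyrosine is present, so ~95% of initiations abort;
depletion (SET 0 at t=200 s) drains the charged pool with a ~20 s time
constant and transcription reads through; re-injection at t=600 s
restores abortion. In the attenuation experiment the regulated gene gets
a 4× promoter so its initiation flux is measurable against the shared
polymerase pool.

## Validation oracles

Every stochastic component is checked against an independent closed form
or distributional law that shares no code with the engine path it
checks:

* waiting times vs the Exponential(total) law (one-sample KS, α=0.01);
* selection frequencies of all three structures vs a_j/total;
* cross-solver equivalence: terminal counts of a 100-molecule reversible
  isomerization (rates 0.05/0.05, t_end=50 — ten relaxation times) over
  2000 replicates, pairwise two-sample KS plus a chi-square match to the
  Binomial(100, ½) stationary law;
* exact event counts of closed conversion cascades (initial molecules ×
  stages, a lattice-path count independent of seed and solver);
* Erlang transit means through unit-rate cascades;
* the harmonic-cycle elongation speed against a simulated single
  polymerase on a 10 000-base template;
* the recruitment-interval arithmetic against simulated exponential
  recruitment clocks;
* filter and occupancy bookkeeping against full recomputation after 10⁴
  random engine firings.

Statistical tests run at α=0.01 on seeded streams, so reports are
reproducible.

## Numerical choices and edge cases

* Coordinates 0-based, intervals half-open, `position` = index of the
  next letter to read; this resolves every off-by-one ambiguity once.
* Selection tie-break: first channel whose cumulative sum reaches the
  threshold (the ≥ rule) — measure-zero but deterministic.
* τ draws reject u=0; a selection returning no channel (float residue in
  a stored total) triggers a full propensity refresh.
* Logging records the state left-continuously at grid multiples of the
  logging period, plus a final row at the stop time; times are strictly
  increasing.
* Degenerate inputs (empty classes, exhausted pools, out-of-bounds
  sites, non-divisor cascade lengths, negative rates) raise typed errors
  rather than firing.

## Known limitations

No excluded-volume interactions between bound particles (collisions,
queueing, polymerase–ribosome coupling); no complex formation between
particles; no sequence mutation or internal cleavage; no degradation of
products; no rule-based pattern matching; no SBML/BNGL import; single
replication fork. The synthetic genomes and desk-scale machine counts
demonstrate correctness of the algorithms, not genome-scale biology.
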