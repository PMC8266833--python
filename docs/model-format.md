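# Model-definition format

A model is a directory containing one or more `*.in` files, read in
**lexicographic order**. Every name must be declared before it is used
across the concatenation of all files; duplicate declarations are errors.
This makes extension trivial: dropping one extra file (say
`z_tetracycline.in`) into a model directory adds its records without
touching any existing ones.

Lines are whitespace-delimited records, one record per line. `#` starts a
comment (to end of line). Blank lines separate records and terminate
tables. Parse errors always report the file name and 1-based line number.

## Records

```
FreeChemical <name> [<count>] [buffered]
```
A freely diffusing pool. `buffered` marks a constant-concentration species:
it gates propensities but reactions do not change its count (timed events
still can).

```
Sequence <name> inline <letters> [<copies>]
Sequence <name> fasta <file> <record_id> [<copies>]
```
A population of identical template copies. Letters come inline or from a
standard FASTA file (path relative to the model directory, record selected
by id). Copies default to 0 (products start empty).

```
BoundChemical <name>
```
An external state class for bound particles (e.g. `RNAP_elongating`).

```
BindingSite <family> <sequence> <first> <last> <k_on> <k_off> <reading_offset>
```
A binding interval `[first, last)` (0-based, half-open) on a sequence,
grouped under a named family. A newly bound particle starts reading at
`reading_offset`. Availability is `copies - occupied`, tracked in
aggregate over the sequence population.

```
Switch <name> <input_class> <output_class>
SwitchSite <sequence> <position> <switch>
```
Annotation-triggered state changes: when a particle of `input_class` lands
(by translocation) on an annotated position, it is reassigned to
`output_class`. Transcription terminators are the canonical use.

```
ChemicalReaction <k_forward> <k_backward> [threshold] <side> -> <side>
```
where `<side>` is `"<stoich> <name>"` pairs joined by `+`, or `-` for an
empty side. `k_backward 0` means irreversible. At most one bound class per
side (stoichiometry 1); a bound reactant with no bound product destroys
the fired particle and detaches it. Propensities follow mass action with
falling factorials for repeated reactants; the optional `threshold` token
switches to a gated zeroth-order law (propensity `k` iff every count
covers its stoichiometry), meant for stack-wise regeneration reactions.

```
SequenceBinding <free> <bound> <family>
```
Binding of the free chemical to any unoccupied site of the family,
creating a particle in `<bound>`; the reverse channel (active when any
site has `k_off > 0`) unbinds particles still sitting on their origin
site.

```
Translocation <mobile_class> <post_class> <step> <rate>
```
Moves a uniformly drawn particle by `step` positions (1 for nucleotides,
3 for codons) and reassigns it to `post_class`.

```
Loading <loader_class> <motif_length>
<motif> <loaded> <rate> <post_class> [<byproduct> ...]
...
(blank line)
```
Template-directed consumption: a particle reading `<motif>` consumes one
`<loaded>` molecule at `rate` per loaded molecule, emits the byproducts
and moves to `<post_class>`. One motif per table line, terminated by a
blank line.

```
Release <class> <rate> <freed1,freed2,...|->
<family> <first> <last> <product>
...
(blank line)
```
Detaches a uniformly drawn particle, increments the freed pools and
creates one copy of the product sequence selected by the particle's origin
family and current position (first matching `[first, last)` interval).
A position matching no interval is an error by default.

```
Event <time> <ADD|SET|REMOVE_FREE> <target> <amount>
```
Scheduled changes of a free pool; `REMOVE_FREE` clamps at zero and only
touches the free pool (bound complexes are untouched).

```
Init <name> <count>
```
Overrides the initial count of a free chemical or the copy number of a
sequence (counts default to 0 when never set).

```
Observe <name> [<name> ...]
```
Adds observables to the trajectory output: free-chemical counts, bound
class populations, or sequence copy numbers.

## Output

Trajectories are TSV: column 1 is time (6 significant digits), one integer
column per observable, one row per logging point. A sidecar key-value
text file records seed, solver and versions.
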