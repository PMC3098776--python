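# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `fernbz`. All empirical figures mentioned here are
computed by the test suite or by `scripts/acceptance.py`.

## Sequence and annotation model

The unit of analysis is an annotated DNA record: uppercase residues over
`{A,C,G,T,N}` plus strand-aware features with 1-based inclusive
coordinates (GenBank convention at the API surface; 0-based half-open
only inside slice arithmetic, with a single conversion helper).
Intergenic spacers are defined gene-end-exclusive on both sides and
always reported on the forward strand of the parent record. Abutting or
overlapping annotations yield a length-0 spacer with a logged warning —
the degenerate case has no established convention, so the package picks
the conservative one and says so at run time.

The nine BZ loci map to single letters (`B C N M D Y E G Z` for rpoB,
trnC-GCA, petN, psbM, trnD-GUC, trnY-GUA, trnE-UUC, trnG-GCC, psbZ) via
a shipped, user-extendable table.

## Gene orders and inversions

A BZ gene order is a signed sequence anchored by `B` first and `Z` last;
anchors never participate in inversions. Orientation ambiguity of the
underlying record is resolved by canonicalisation: a record sequenced on
the opposite strand is reverse-complemented (order reversed, signs
flipped) so extraction is strand-invariant, and the sign frame is chosen
so `B` carries `+`.

`inversion_distance` is exact: iterative-deepening depth-first search
over all interior segment choices (28 events for a 9-locus order), with
an admissible breakpoint bound (an inversion removes at most two
breakpoints, so ⌈b/2⌉ prunes). The search is capped (default 4; BZ
biology never requires more) and returns `None` beyond the cap rather
than an estimate. `enumerate_intermediates` requires distance exactly 2
and returns every order at distance 1 from both endpoints.

The three named orders ship as data (`data/gene_orders.txt`), not code.
Established observations fix the D/Y/E relative orientation (trnD
antisense to trnY/trnE in all types) and the two inversion events
relating the types; the orientations of N and M follow from requiring
that the trnC..trnE inversion maps the ancestral order onto the
Plagiogyria type.
G and Z orientations are known only from diagram artwork and are
recorded as `+` with a comment in the data file.

## Maximal repeat matches

A repeat match is a *pair of spans* (REPuter/VMATCH reporting: match
pairs, not element occurrences) agreeing under one of four relations —
direct, reverse, complement, reverse complement — with at most `k`
substitutions (Hamming model, no indels, per the mismatch semantics of
seed-based repeat finders), and inextensible on either side within that
budget. Defaults: length ≥ 20, `k` = 3.

Implementation: for each relation the sequence is compared against its
transformed self; every comparison diagonal contributes equality runs.
All diagonals are concatenated with sentinel mismatch blocks and every
maximal ≤`k`-mismatch window is found in one vectorised pass over the
global mismatch-position array; windows are clamped back to their
diagonal and nested intervals dropped. Matches found via mirrored
relations are canonicalised (`pos1 ≤ pos2`) and de-duplicated. The
trivial direct self-match is excluded. A quadratic per-start-pair
extension oracle (independent code path) validates the enumerator over
hundreds of seeded sequences in the test suite.

Masking ("non-redundant" repeats) is deliberately explicit, since
published pipelines state that overlaps were masked but not how: matches
are visited longest-first (ties: fewer mismatches, then leftmost) and
accepted iff neither span overlaps an already-accepted span by more than
50% of the match length. The rule is deterministic and order-invariant.

Families are built by single-linkage over accepted spans: two spans link
iff their global-alignment identity (match +1, mismatch −1, linear gap
−2; identity = identical columns / alignment columns) is ≥ 1 − 0.15.
Consensus calling aligns family members by a center-star progressive
alignment under the same scoring, then per column emits the IUPAC code
covering every residue present in ≥ 20% of non-gap rows; columns gapped
in more than half the rows are dropped. Singleton families are allowed
(their consensus is the member itself).

## Stem-loop scanner

For every possible placement of a loop of fixed length (default 7 nt)
the scanner reports the maximal perfectly complementary stem flanking
it, provided the stem reaches 3 bp. One hit per loop placement — not
one per (placement, stem-length) combination — so each element is binned
once in the stem-length histogram. Wobble pairs are excluded: the
context is DNA and the reference stem families (e.g. `GGA/TCC`) are
Watson–Crick.

The AAA signature tests the three loop bases adjacent to a stem arm;
the default side is the 3′ arm (the published drawings do not fix the
side unambiguously, so it is configurable: `loop3`, `loop5`, `either`).
The stem family key is the triplet of base pairs proximal to the loop,
written as `5'-triplet/3'-triplet`. Because a stem is its own reverse
complement outside the loop, the key is invariant under
reverse-complementing the region — a property the tests exercise.

Coverage is reported in two modes: `union` (each base counted once) and
`sum` (hit spans added up, overlaps counted multiply). Both are exposed
because "total length of the repeats" in the comparative literature can
mean either; for the planted study-condition histogram the summed length
is the quantity that reproduces the planted percentage exactly, and the
acceptance script reports the sum mode alongside the counts. The
library default remains `union`.

## Tandem arrays

Detection is self-offset matching, chosen over wraparound dynamic
programming for transparency at desk scale: for each candidate period
`p` (default 20–40 nt), positions where the sequence matches itself
shifted by `p` at ≥ 80% identity are chained into runs. Chains bridge
breaks of up to `3p` — the worst-case footprint of a single divergent
copy on the self-comparison — because module-head copies (~30%
divergent) would otherwise split one biological array into per-module
fragments. Each run is cut into full-period copies at the phase
maximising mean copy-to-consensus identity (ties: leftmost); arrays from
all periods are then selected greedily without overlap, longest span
first, which also suppresses period harmonics. When the flanking base
happens to continue the period, the cut phase can legitimately rotate by
a base or two; span length, period, copy count and module structure are
unaffected, and tests compare coordinates with a ±2 nt allowance.

Module segmentation classifies each copy against the whole-array
majority consensus: a copy below 1 − 0.25 identity is a "head" and opens
a module boundary (a run of consecutive divergent copies opens a single
module). The straightforward alternative — a running within-module
consensus — cascades wrongly immediately after a head opens a new
module, because the next ordinary copy is then compared against the head
alone; the whole-array reference avoids this while giving the same
answer on uniform arrays, head-led modules and trailing divergent
copies.

Unit origin is scored by local alignment (same scoring as clustering)
of a copy against a window of the trnY gene covering the D-arm stem and
the anticodon arm. The window (positions 19–43 of the gene model) ships
as configurable data, since only a verbal description of the region is
published. Column identity saturates for short spurious local matches,
so comparisons against controls use the raw alignment score.

## Promoter scan

A transparent consensus-plus-mismatch scan substitutes for trained
promoter predictors: all placements of `TTGACA` (≤ 2 mismatches)
followed after a 15–19 nt spacer by `TATAAT` (≤ 1 mismatch), on both
strands, sorted by total mismatches. The claims this supports are
presence/absence and strand of a box pair upstream of a tRNA locus
(e.g. the inverted trnD); no strength prediction is attempted.

## Synthetic data generator

The generator exists so every detector can be validated against planted,
machine-readable truth. Background is i.i.d. nucleotide sequence at
GC 0.33 (plastome spacers are AT-rich); no k-mer structure or indel
evolution is modelled, which is sufficient because all detectors are
pattern-driven — but it means passing tests demonstrate correctness of
the algorithms, not robustness to every property of real plastome
sequence (e.g. homopolymer runs or microsatellites, which can add
background hits).

Planted features and their defaults are the study conditions:

* **Tandem array**: period 27, 17 copies in modules 5/6/6 (459 bp), the
  two later modules led by one shared head copy at 30% divergence
  ("distantly homologous", and identical between modules); body copies
  mutated at 2% per base (quasi-identical). The unit is the trnY
  anticodon window plus 2 nt when a gene model is simulated, random
  otherwise. Default spacer length 619 nt.
* **Hairpin elements**: each spec plants `count` identical copies of one
  randomly drawn element (stems conserved across copies, 7-nt A-rich
  loop fixed), emulating families of dispersed direct repeats that fold
  into one conserved stem-loop. The Equisetum-like profile plants 68
  elements with the stem histogram {3:21, 4:3, 5:8, 6:8, 7:2, 8:16,
  9:6, 10:2, 13:2} in 5,000 nt, i.e. 1,286 nt = 25.72% summed length.
  Flanking bases are set so each planted stem is maximal at its nominal
  length.
* **Promoters**: exact box pairs with configurable spacer and strand,
  either free-standing or pinned upstream of a gene (respecting an
  inverted gene's orientation).
* **Gene region**: genes laid out from a named order (optionally
  scrambled by recorded random inversions), with a designed trnY gene
  whose positions 19–43 carry a real anticodon arm — `CAGGA` stem,
  `TGTAAAA` loop (GUA anticodon, AAA adjacent to the 3′ arm), `TCCTG` —
  so the tandem unit, the stem-loop scanner and the similarity scorer
  all see the same biology the region exhibits.

Placement is seeded rejection sampling with non-overlap margins; an
infeasible packing raises before any output. Identical seeds give
byte-identical records, and the truth object round-trips losslessly
through JSON.

Because background sequence can fold by chance, censuses on planted
regions slightly exceed the plant: at GC 0.33 a random loop position
carries a ≥3 bp stem with probability ≈ 2%, and the AAA filter passes
≈ 4% of those loops, adding a handful of hits and roughly one coverage
point per 5 kb — the recovery tests therefore assert agreement within
±3 percentage points, and the acceptance output reports the measured
values, not the planted ones.

## Problem sizes and numerical choices

The test suite and acceptance script run on desk-scale problems chosen
to exercise every code path: oracle-equivalence over 100 seeded
sequences per scanner (up to 2 kb for repeats, 1 kb for stem-loops),
50 seeded gene-order pairs against a breadth-first-search oracle, 20
seeds for each parameter-recovery check, and single synthetic records of
2.7–5 kb for the end-to-end profiles. The repeat enumerator handles the
largest studied region (≈ 7.6 kb, all four kinds) in a few seconds.

Tie-breaking is deterministic everywhere (documented sort keys);
reported fractions are rounded only at the reporting layer. Alignment
scoring is match +1, mismatch −1, gap −2 (linear) throughout.

## Limitations

* Annotations are inputs; nothing here calls genes or tRNAs.
* The hairpin matcher is combinatorial: no free energy, no bulges, no
  wobble pairs, fixed loop length per scan.
* The promoter scan is a labelled stand-in for trained predictors and
  should not be compared against their box coordinates base-by-base.
* Repeat masking implements one declared rule; published "non-redundant"
  counts produced by unstated rules need not match it exactly.
* The inversion machinery targets the 9-locus BZ scale; it is exact but
  exponential, and deliberately out of scope for genome-scale signed
  permutation theory.
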