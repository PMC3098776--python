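# fernbz

Comparative sequence analysis of the **rpoB–psbZ (BZ) region** of fern
plastid genomes — the rearrangement-prone, tRNA-dense stretch of the
large single-copy region whose intergenic spacers expand up to 5 kb in
horsetails and carry tRNA-derived repeat arrays in filmy ferns.

The package is a library (plus a thin `fernbz` command-line wrapper) for
researchers studying plastome structural evolution. It provides, over a
common annotated-sequence model:

* **Dispersed repeats** — enumeration of all *maximal matches* (direct,
  reverse, complement, reverse-complement) of length ≥ *L* within a
  Hamming distance *k* (defaults *L* = 20, *k* = 3, the standard
  REPuter/VMATCH setting); greedy 50%-overlap masking to a non-redundant
  set; single-linkage clustering into families at ≤ 15% dissimilarity
  (global alignment, match +1 / mismatch −1 / gap −2) and per-family
  IUPAC ambiguity consensus.
* **Stem-loop scanner** — for every placement of a fixed 7-nt loop, the
  maximal perfect Watson–Crick stem (≥ 3 bp); the "AAA" loop signature
  (three adenines adjacent to the stem, the mark shared with the trnY
  anticodon loop); stem families keyed by the three base pairs proximal
  to the loop (e.g. `GGA/TCC`); stem-length histograms and coverage.
* **Tandem arrays** — self-offset detection of head-to-tail
  quasi-identical units (period 20–40 nt), phase-optimised copy cutting,
  segmentation into modules led by divergent "head" copies, and local
  alignment of units against the trnY anticodon-arm window.
* **Promoter boxes** — transparent σ70-style scan for −35/−10 hexamer
  pairs (`TTGACA`/`TATAAT`, ≤ 2/≤ 1 mismatches, 15–19 nt spacer) on both
  strands, e.g. upstream of the independently transcribed, inverted trnD.
* **Gene orders** — signed orders over the nine BZ loci
  (`B C N M D Y E G Z`), exact inversion distances by exhaustive
  iterative-deepening search, enumeration of one-step intermediates, and
  classification against the named Angiopteris / Plagiogyria / Adiantum
  types shipped as data.
* **Synthetic data** — a seeded generator that plants all of the above
  with machine-readable ground truth, at the feature statistics of the
  studied spacers (17 × 27 bp tandem copies in 5/6/6 modules over 459 bp
  inside a 619-nt spacer; 68 A-rich hairpins with stems 3–13 bp in a
  5,000-nt spacer).

## The core model

A BZ gene order is a signed permutation anchored by `B` (rpoB) and `Z`
(psbZ); an inversion reverses an interior segment and flips its signs.
With the shipped orders, the package computes

```
d(Angiopteris, Plagiogyria) = 1    (the "CE" inversion, trnC..trnE)
d(Plagiogyria, Adiantum)    = 1    (the "DE" inversion, the DYE block)
d(Angiopteris, Adiantum)    = 2
```

and verifies that the Plagiogyria-type order is one of exactly two
orders lying a single inversion from both endpoints — the combinatorial
content of the competing intermediate-versus-back-inversion hypotheses.

A *maximal match* is a pair of spans that agree under the kind's strand
relation with ≤ *k* substitutions and cannot be extended on either side
within that budget; matches are counted as span pairs, exactly as
suffix-tree repeat finders report them.

## Worked example

```python
from fernbz.seq_io import extract_igs
from fernbz.simulate import simulate_region, vandenboschia_like_config
from fernbz.tandem import find_tandem_arrays

aseq, truth = simulate_region(vandenboschia_like_config(seed=2))
igs = extract_igs(aseq, "trnY-GUA", "trnE-UUC")
(array,) = find_tandem_arrays(igs.residues, period_min=20, period_max=40)
print(igs.length, array.period, array.copy_number, array.modules)
```

prints `619 27 17 [5, 6, 6]`: a 619-nt trnY–trnE spacer whose tandem
array of seventeen 27-bp copies falls into one five-copy module and two
six-copy modules — the five/six/six organisation in which each later
module is led by a distantly homologous head copy.  Running
`python examples/tandem_array_scan.py` additionally scores a unit
against the trnY anticodon-arm window (identity 1.00 over 25 nt),
the signature of a partial tRNA-gene duplication.  The other scripts in
`examples/` walk through the repeat census, the stem-loop histogram
(`python examples/stemloop_census.py` reports 70 AAA-signature hairpins
summing to 26.28% of a 5,000-nt spacer, against 68 planted elements
summing to 25.72%), promoter detection and the full pipeline.

## Command line

```
fernbz simulate --profile vandenboschia --seed 2 --out-prefix rec
fernbz extract-igs rec.fasta rec.features.tsv --left trnY-GUA --right trnE-UUC
fernbz repeats rec.fasta --min-len 20 --hamming 3 --cluster
fernbz stemloops rec.fasta --require-aaa --coverage sum
fernbz tandem rec.fasta --period-min 20 --period-max 40
fernbz gene-order Angiopteris Adiantum
fernbz run rec.fasta --features rec.features.tsv --out report.json
```

## Scope

Annotations are consumed, not produced (no gene calling or tRNA
structure prediction); hairpin matching is combinatorial, not
thermodynamic; promoter scanning is a consensus-mismatch stand-in for
trained predictors, adequate for presence/absence questions. See
`docs/methods.md` for the model, parameter and design details.
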