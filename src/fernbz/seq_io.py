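"""Sequence and annotation IO for plastome region analysis.

The unit of work is an :class:`AnnotatedSequence`: a DNA string (the
``rpoB``–``psbZ`` region of a fern plastome, or a synthetic stand-in)
plus a strand-aware gene feature table.  From it we derive the two
objects everything downstream consumes: intergenic spacers
(:class:`IgsRegion`, e.g. the trnY–trnE spacer whose expansion drives
the repeat analyses) and signed gene orders (see :mod:`fernbz.gene_order`).

Conventions
-----------
* Coordinates are 1-based inclusive at the API surface (GenBank style)
  and converted to 0-based half-open only inside slice arithmetic.
* FASTA residues are uppercased and U is normalised to T on input.
* A feature table is a TSV with header ``locus, kind, strand, start, end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "AnnotatedSequence",
    "IgsRegion",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "extract_igs",
    "extract_gene_order",
    "locus_symbol_table",
    "locus_to_symbol",
    "reverse_complement",
]

_VALID_STRANDS = {"+", "-"}
_ALLOWED = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return str(Seq(seq).reverse_complement())


def _slice(residues: str, start: int, end: int) -> str:
    """Slice by 1-based inclusive coordinates (single-sourced converter)."""
    return residues[start - 1 : end]


@dataclass(frozen=True)
class Feature:
    """A gene/tRNA annotation with 1-based inclusive coordinates."""

    locus: str
    kind: str  # "gene" or "tRNA"
    strand: str  # "+" or "-"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.locus}")
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"feature {self.locus}: start {self.start} < 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedSequence:
    """A DNA sequence plus an ordered list of gene features."""

    seq_id: str
    residues: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(f"{self.seq_id}: non-DNA characters {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.residues):
                raise ValueError(
                    f"{self.seq_id}: feature {f.locus} end {f.end} beyond "
                    f"sequence length {len(self.residues)}"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.residues)

    def feature_by_locus(self, locus: str) -> Feature:
        """The unique feature whose locus (or symbol) matches ``locus``."""
        hits = [f for f in self.features if _locus_matches(f.locus, locus)]
        if not hits:
            raise KeyError(f"{self.seq_id}: no feature for locus {locus!r}")
        if len(hits) > 1:
            raise KeyError(f"{self.seq_id}: locus {locus!r} is not unique")
        return hits[0]

    def reverse_complemented(self) -> "AnnotatedSequence":
        """The same record written on the opposite strand."""
        n = len(self.residues)
        feats = [
            replace(
                f,
                strand="+" if f.strand == "-" else "-",
                start=n - f.end + 1,
                end=n - f.start + 1,
            )
            for f in self.features
        ]
        return AnnotatedSequence(self.seq_id, reverse_complement(self.residues), feats)


@dataclass(frozen=True)
class IgsRegion:
    """An intergenic spacer on the forward strand of its parent record."""

    parent_id: str
    left_locus: str
    right_locus: str
    start: int  # 1-based inclusive; start > end encodes a length-0 spacer
    end: int
    residues: str

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


# ---------------------------------------------------------------------------
# locus symbol table


def locus_symbol_table(extra: dict[str, str] | None = None) -> dict[str, str]:
    """Map from locus name (upper-cased) to single-letter symbol.

    The shipped table covers the nine BZ loci; ``extra`` entries
    (locus -> symbol) extend or override it.
    """
    text = resources.files("fernbz.data").joinpath("locus_symbols.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        symbol, locus = line.split("\t")
        table[locus.strip().upper()] = symbol.strip()
    if extra:
        for locus, symbol in extra.items():
            table[locus.strip().upper()] = symbol
    return table


_DEFAULT_TABLE = locus_symbol_table()


def locus_to_symbol(locus: str, table: dict[str, str] | None = None) -> str:
    """Single-letter code for a locus name; raises KeyError if unmappable."""
    table = table if table is not None else _DEFAULT_TABLE
    key = locus.strip().upper()
    if key in table:
        return table[key]
    if len(key) == 1 and key in set(table.values()):
        return key
    raise KeyError(f"locus {locus!r} has no single-letter symbol")


def _locus_matches(feature_locus: str, query: str) -> bool:
    if feature_locus.strip().upper() == query.strip().upper():
        return True
    try:
        return locus_to_symbol(feature_locus) == locus_to_symbol(query)
    except KeyError:
        return False


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read a FASTA file into feature-less :class:`AnnotatedSequence` records.

    Residues are uppercased and RNA ``U`` is normalised to ``T``.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("U", "T")
        if not residues:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        records.append(AnnotatedSequence(rec.id, residues))
    if not records:
        # SeqIO silently yields nothing for malformed/empty files
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[AnnotatedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read a TSV feature table (columns locus/kind/strand/start/end)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["locus", "kind", "strand", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    feats = []
    for row in df.itertuples(index=False):
        strand = str(row.strand).strip().replace("−", "-")  # minus sign
        feats.append(
            Feature(
                locus=str(row.locus).strip(),
                kind=str(row.kind).strip(),
                strand=strand,
                start=int(row.start),
                end=int(row.end),
            )
        )
    return feats


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    df = pd.DataFrame(
        [(f.locus, f.kind, f.strand, f.start, f.end) for f in features],
        columns=["locus", "kind", "strand", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# extraction


def extract_igs(aseq: AnnotatedSequence, left: str, right: str) -> IgsRegion:
    """The spacer strictly between two uniquely-annotated loci.

    ``left``/``right`` may be given in either genomic order; the spacer is
    reported on the forward strand of the parent, exclusive of both gene
    spans.  Overlapping or abutting genes yield a length-0 spacer with a
    warning (coordinates then satisfy ``start = end + 1``).
    """
    fa = aseq.feature_by_locus(left)
    fb = aseq.feature_by_locus(right)
    first, second = (fa, fb) if fa.start <= fb.start else (fb, fa)
    start, end = first.end + 1, second.start - 1
    if start > end:
        warnings.warn(
            f"{aseq.seq_id}: features {first.locus} and {second.locus} abut or "
            "overlap; spacer length reported as 0",
            stacklevel=2,
        )
        end = start - 1
        residues = ""
    else:
        residues = _slice(aseq.residues, start, end)
    return IgsRegion(aseq.seq_id, first.locus, second.locus, start, end, residues)


def extract_gene_order(
    aseq: AnnotatedSequence,
    from_locus: str = "rpoB",
    to_locus: str = "psbZ",
    table: dict[str, str] | None = None,
):
    """Signed gene order between two anchor loci, canonically oriented.

    The order is read along the record between the two anchors and each
    locus is mapped to its single-letter symbol with sign = strand.  If the
    record was sequenced on the opposite strand (the ``from`` anchor comes
    last), the order is reverse-complemented so the result is invariant to
    the sequencing orientation, then signs are flipped globally if needed so
    the ``from`` anchor carries ``+``.
    """
    from .gene_order import GeneOrder  # local import to avoid a cycle

    fa = aseq.feature_by_locus(from_locus)
    fb = aseq.feature_by_locus(to_locus)
    lo, hi = (fa, fb) if fa.start <= fb.start else (fb, fa)
    inside = [f for f in aseq.features if lo.start <= f.start and f.end <= hi.end]
    unmappable = []
    loci = []
    for f in inside:
        try:
            sym = locus_to_symbol(f.locus, table)
        except KeyError:
            unmappable.append(f.locus)
            continue
        loci.append((sym, +1 if f.strand == "+" else -1))
    if unmappable:
        raise KeyError(f"{aseq.seq_id}: unmappable loci {unmappable}")
    order = GeneOrder(tuple(loci))
    anchor = locus_to_symbol(from_locus, table)
    if order.loci and order.loci[-1][0] == anchor:
        order = order.global_flip()
    if order.loci and order.loci[0][0] == anchor and order.loci[0][1] < 0:
        # record annotated with the from-anchor antisense: flip sign frame
        order = GeneOrder(tuple((s, -g) for s, g in order.loci))
    return order
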