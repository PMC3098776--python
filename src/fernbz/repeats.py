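"""Dispersed-repeat detection, masking, family clustering and consensus.

The detector enumerates *maximal matches*: pairs of sequence spans that
agree up to a Hamming distance budget and cannot be extended on either
side without exceeding it (REPuter/VMATCH-style reporting; a match is a
span *pair*, not an element occurrence).  Four kinds are recognised —
direct, reverse, complement and reverse-complement (palindromic) — the
second span being respectively the same strand, the reversed sequence,
the complemented sequence, or the reverse complement of the first.

Downstream, overlapping matches are reduced to a non-redundant span set
by a declared greedy rule, spans are clustered into families by
single-linkage at a global-alignment identity threshold, and each family
receives an IUPAC ambiguity consensus from a progressive alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import IUPAC_CODES, identity, star_msa
from .seq_io import reverse_complement

__all__ = [
    "RepeatMatch",
    "RepeatFamily",
    "KINDS",
    "find_repeats",
    "mask_overlaps",
    "extract_span_seqs",
    "cluster_families",
    "consensus_iupac",
]

KINDS = ("direct", "reverse", "complement", "revcomp")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True, order=True)
class RepeatMatch:
    """A maximal pair of similar spans; positions are 1-based starts."""

    kind: str
    pos1: int
    pos2: int
    length: int
    mismatches: int

    @property
    def span1(self) -> tuple[int, int]:
        return (self.pos1, self.pos1 + self.length - 1)

    @property
    def span2(self) -> tuple[int, int]:
        return (self.pos2, self.pos2 + self.length - 1)


@dataclass
class RepeatFamily:
    """A cluster of repeat spans with an IUPAC consensus."""

    members: list[str]
    consensus: str = ""
    spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# maximal-match enumeration


def _transform(seq: str, kind: str) -> str:
    if kind == "direct":
        return seq
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return seq.translate(_COMPLEMENT)
    if kind == "revcomp":
        return reverse_complement(seq)
    raise ValueError(f"unknown repeat kind {kind!r}")


def _second_span_start(kind: str, j0: int, length: int, n: int) -> int:
    """Map a 0-based start in the transformed string back onto the sequence."""
    if kind in ("direct", "complement"):
        return j0
    return n - j0 - length  # reverse / revcomp mirror the coordinate


def _all_diagonal_matches(
    s: np.ndarray, t: np.ndarray, offsets, min_len: int, max_hamming: int
):
    """Maximal ≤max_hamming matches over many s×t diagonals in one pass.

    Yields (i0, j0, length, mismatches) with 0-based starts.  All
    diagonal equality vectors are laid end to end, separated by sentinel
    blocks of ``max_hamming + 1`` forced mismatches; every maximal window
    with ≤ ``max_hamming`` mismatches is then found with a single scan of
    the global mismatch-position array, clamped back to its diagonal and
    de-duplicated (sentinel-straddling windows only ever produce nested
    sub-intervals of true windows, which the containment filter drops).
    """
    n, m = len(s), len(t)
    k = max_hamming
    gap = k + 1
    diags = []  # (i_start, j_start, global_start, overlap)
    pos = gap  # leading sentinel block
    chunks = []
    for offset in offsets:
        i0 = max(0, -offset)
        j0 = i0 + offset
        ov = min(n - i0, m - j0)
        if ov < min_len:
            continue
        diags.append((i0, j0, pos, ov))
        chunks.append((pos, s[i0 : i0 + ov] == t[j0 : j0 + ov]))
        pos += ov + gap
    if not diags:
        return
    big = np.zeros(pos, dtype=bool)  # sentinel positions stay "mismatch"
    for start, eq in chunks:
        big[start : start + len(eq)] = eq
    mism = np.flatnonzero(~big)
    # candidate windows: k mismatches between bounding mismatches idx, idx+k+1
    lens = mism[gap:] - mism[:-gap] - 1
    cand = np.flatnonzero(lens >= min_len)
    if len(cand) == 0:
        return
    diag_starts = np.array([d[2] for d in diags])
    seen: dict[tuple[int, int], tuple[int, int]] = {}
    for idx in cand:
        lo = int(mism[idx]) + 1
        hi = int(mism[idx + gap]) - 1
        d = int(np.searchsorted(diag_starts, lo, side="right")) - 1
        if d < 0:
            continue
        i0, j0, g0, ov = diags[d]
        lo_c = max(lo, g0)
        hi_c = min(hi, g0 + ov - 1)
        if hi_c - lo_c + 1 < min_len:
            continue
        key = (d, lo_c)
        if key in seen and seen[key][0] >= hi_c:
            continue
        mm = int(
            np.searchsorted(mism, hi_c, side="right")
            - np.searchsorted(mism, lo_c, side="left")
        )
        seen[key] = (hi_c, mm)
    # drop intervals contained in another on the same diagonal
    by_diag: dict[int, list[tuple[int, int, int]]] = {}
    for (d, lo_c), (hi_c, mm) in seen.items():
        by_diag.setdefault(d, []).append((lo_c, hi_c, mm))
    for d, intervals in by_diag.items():
        i0, j0, g0, ov = diags[d]
        intervals.sort(key=lambda iv: (iv[0], -iv[1]))
        best_hi = -1
        for lo_c, hi_c, mm in intervals:
            if hi_c <= best_hi:
                continue  # contained in a previous (wider) interval
            best_hi = hi_c
            local = lo_c - g0
            yield i0 + local, j0 + local, hi_c - lo_c + 1, mm


def find_repeats(
    seq: str,
    min_len: int = 20,
    max_hamming: int = 3,
    kinds: tuple[str, ...] = KINDS,
) -> list[RepeatMatch]:
    """All maximal repeat matches of the requested kinds.

    A match pairs two spans of ``seq`` (1-based starts, ``pos1 <= pos2``;
    the trivial direct self-match is excluded) whose sequences agree under
    the kind's relation with at most ``max_hamming`` substitutions, and
    which cannot be extended on either side within that budget.
    """
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    out: set[RepeatMatch] = set()
    for kind in kinds:
        if kind not in KINDS:
            raise ValueError(f"unknown repeat kind {kind!r}")
        t = np.frombuffer(_transform(seq, kind).encode(), dtype=np.uint8)
        offsets = range(1, n) if kind == "direct" else range(-(n - 1), n)
        for i0, j0, length, mm in _all_diagonal_matches(
            s, t, offsets, min_len, max_hamming
        ):
            p1 = i0
            p2 = _second_span_start(kind, j0, length, n)
            if kind == "direct" and p1 == p2:
                continue
            lo, hi = min(p1, p2), max(p1, p2)
            out.add(RepeatMatch(kind, lo + 1, hi + 1, length, mm))
    return sorted(out, key=lambda r: (r.pos1, r.pos2, -r.length, r.kind))


# ---------------------------------------------------------------------------
# masking


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def mask_overlaps(matches: list[RepeatMatch]) -> list[RepeatMatch]:
    """Greedy non-redundant subset of matches.

    Matches are visited longest first (ties: fewer mismatches, then
    leftmost); one is accepted iff neither of its spans overlaps an
    already-accepted span by more than 50% of the match length.  The
    result is deterministic and independent of input order.
    """
    ranked = sorted(
        matches, key=lambda r: (-r.length, r.mismatches, r.pos1, r.pos2, r.kind)
    )
    accepted: list[RepeatMatch] = []
    pool: list[tuple[int, int]] = []
    for m in ranked:
        limit = m.length / 2
        if any(
            _overlap(span, acc) > limit
            for span in (m.span1, m.span2)
            for acc in pool
        ):
            continue
        accepted.append(m)
        pool.extend((m.span1, m.span2))
    return sorted(accepted, key=lambda r: (r.pos1, r.pos2, r.kind))


def extract_span_seqs(
    seq: str, matches: list[RepeatMatch]
) -> list[tuple[tuple[int, int], str]]:
    """Unique (span, subsequence) pairs covered by a list of matches."""
    spans = sorted({m.span1 for m in matches} | {m.span2 for m in matches})
    return [(sp, seq[sp[0] - 1 : sp[1]]) for sp in spans]


# ---------------------------------------------------------------------------
# clustering and consensus


def cluster_families(
    spans: list,
    max_dissimilarity: float = 0.15,
) -> list[RepeatFamily]:
    """Single-linkage clustering of repeat spans into families.

    ``spans`` is either a list of sequences or of ``(span, sequence)``
    pairs as produced by :func:`extract_span_seqs`.  Two spans link iff
    their global-alignment identity is at least ``1 - max_dissimilarity``.
    Families come back sorted by copy number (descending), each with an
    IUPAC consensus.
    """
    if not spans:
        return []
    if isinstance(spans[0], str):
        coords = [None] * len(spans)
        seqs = list(spans)
    else:
        coords = [sp for sp, _ in spans]
        seqs = [sq for _, sq in spans]

    threshold = 1.0 - max_dissimilarity
    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if find(i) != find(j) and identity(seqs[i], seqs[j]) >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), []).append(i)

    families = []
    for idxs in groups.values():
        fam = RepeatFamily(
            members=[seqs[i] for i in idxs],
            spans=[coords[i] for i in idxs if coords[i] is not None],
        )
        fam.consensus = consensus_iupac(fam)
        families.append(fam)
    families.sort(key=lambda f: (-f.copy_number, f.consensus))
    return families


def consensus_iupac(family: RepeatFamily) -> str:
    """IUPAC ambiguity consensus of a family from a progressive alignment.

    Per column, the code covers every residue present in at least 20% of
    the non-gap rows; columns gapped in more than half the rows are
    dropped.
    """
    members = family.members
    if len(members) == 1:
        return members[0]
    rows = star_msa(members)
    n_rows = len(rows)
    out = []
    for col in zip(*rows):
        gaps = col.count("-")
        if gaps * 2 > n_rows:
            continue
        residues = [c for c in col if c != "-"]
        cutoff = 0.2 * len(residues)
        keep = frozenset(
            b for b in set(residues) if residues.count(b) >= cutoff
        )
        out.append(IUPAC_CODES.get(keep, "N"))
    return "".join(out)
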