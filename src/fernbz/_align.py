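"""Shared pairwise/star alignment helpers.

Scoring everywhere: match +1, mismatch -1, gap -2 (linear), matching the
settings used to cluster repeat families and score tRNA-derived units.
"""

from __future__ import annotations

from Bio import Align

__all__ = ["make_aligner", "identity", "star_msa", "IUPAC_CODES", "iupac_match"]


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def identity(a: str, b: str, mode: str = "global") -> float:
    """Fraction of identical columns in the best alignment of a and b."""
    if not a or not b:
        return 0.0
    aln = make_aligner(mode).align(a, b)[0]
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return 0.0
    return counts.identities / columns


def _pairwise_rows(center: str, other: str) -> tuple[str, str]:
    """Gapped (center_row, other_row) strings from a global alignment."""
    aln = make_aligner("global").align(center, other)[0]
    return str(aln[0]), str(aln[1])


def star_msa(members: list[str]) -> list[str]:
    """Progressive (center-star) multiple alignment of short sequences.

    The center is the member with the highest summed pairwise score to the
    others; every member is aligned to the center and the pairwise gaps are
    merged into one coordinate frame.
    """
    if len(members) == 1:
        return list(members)
    aligner = make_aligner("global")
    scores = [
        sum(aligner.score(m, o) for k, o in enumerate(members) if k != i)
        for i, m in enumerate(members)
    ]
    center = members[max(range(len(members)), key=lambda i: scores[i])]

    pairs = [_pairwise_rows(center, m) for m in members]
    # ins[j] = max gap run length seen before center position j (j = 0..len)
    ins = [0] * (len(center) + 1)
    for crow, _ in pairs:
        j = run = 0
        for ch in crow:
            if ch == "-":
                run += 1
            else:
                ins[j] = max(ins[j], run)
                run = 0
                j += 1
        ins[len(center)] = max(ins[len(center)], run)

    rows = []
    for crow, mrow in pairs:
        out = []
        j = run = 0
        for cch, mch in zip(crow, mrow):
            if cch == "-":
                out.append(mch)
                run += 1
            else:
                out.append("-" * (ins[j] - run))
                out.append(mch)
                run = 0
                j += 1
        out.append("-" * (ins[len(center)] - run))
        rows.append("".join(out))
    width = {len(r) for r in rows}
    assert len(width) == 1, "star merge produced ragged rows"
    return rows


IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

_IUPAC_SETS = {code: bases for bases, code in IUPAC_CODES.items()}


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` is covered by the ambiguity letter ``code``."""
    return base in _IUPAC_SETS.get(code, frozenset(code))
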