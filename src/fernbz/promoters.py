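"""Sigma70-style promoter-box scanning (-35/-10 hexamer pairs).

A transparent consensus + mismatch scan: every placement of a -35 box
(consensus TTGACA, up to 2 mismatches) followed, after a 15–19 nt
spacer, by a -10 box (consensus TATAAT, up to 1 mismatch) is reported,
on both strands.  This deliberately simple detector stands in for
trained promoter predictors; the biological claims it supports here are
qualitative — conserved box pairs sit upstream of the independently
transcribed (inverted) trnD gene and upstream of trnY in the
repeat-expanded spacers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import reverse_complement

__all__ = ["PromoterHit", "scan_promoters", "MINUS35", "MINUS10"]

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


@dataclass(frozen=True)
class PromoterHit:
    """A -35/-10 box pair; spans are 1-based inclusive, forward frame."""

    minus35: tuple[int, int]
    minus35_seq: str
    minus10: tuple[int, int]
    minus10_seq: str
    spacer: int
    mismatches35: int
    mismatches10: int
    strand: str

    @property
    def total_mismatches(self) -> int:
        return self.mismatches35 + self.mismatches10


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _scan_one_strand(seq: str, max_mm35, max_mm10, spacer_range):
    """Yield (start35_0based, start10_0based, mm35, mm10) on this strand."""
    n = len(seq)
    lo, hi = spacer_range
    box = len(MINUS35)
    for i in range(n - box + 1):
        mm35 = _hamming(seq[i : i + box], MINUS35)
        if mm35 > max_mm35:
            continue
        for spacer in range(lo, hi + 1):
            j = i + box + spacer
            if j + len(MINUS10) > n:
                break
            mm10 = _hamming(seq[j : j + len(MINUS10)], MINUS10)
            if mm10 <= max_mm10:
                yield i, j, spacer, mm35, mm10


def scan_promoters(
    seq: str,
    window: tuple[int, int] | None = None,
    max_mm35: int = 2,
    max_mm10: int = 1,
    spacer: tuple[int, int] = (15, 19),
) -> list[PromoterHit]:
    """All -35/-10 pairs in a window (1-based inclusive; default: whole seq).

    Hits on the minus strand are reported with spans in forward
    coordinates (the -35 box then lies right of the -10 box).  Sorted by
    total mismatches, then position.
    """
    if window is None:
        window = (1, len(seq))
    lo, hi = window
    if not (1 <= lo <= hi <= len(seq)):
        raise ValueError(f"window {window} outside sequence of length {len(seq)}")
    sub = seq[lo - 1 : hi]
    hits = []
    for i, j, sp, mm35, mm10 in _scan_one_strand(sub, max_mm35, max_mm10, spacer):
        hits.append(
            PromoterHit(
                minus35=(lo + i, lo + i + 5),
                minus35_seq=sub[i : i + 6],
                minus10=(lo + j, lo + j + 5),
                minus10_seq=sub[j : j + 6],
                spacer=sp,
                mismatches35=mm35,
                mismatches10=mm10,
                strand="+",
            )
        )
    rc = reverse_complement(sub)
    m = len(sub)
    for i, j, sp, mm35, mm10 in _scan_one_strand(rc, max_mm35, max_mm10, spacer):
        # map rc offsets back onto the forward frame
        s35 = lo + (m - i - 6)
        s10 = lo + (m - j - 6)
        hits.append(
            PromoterHit(
                minus35=(s35, s35 + 5),
                minus35_seq=rc[i : i + 6],
                minus10=(s10, s10 + 5),
                minus10_seq=rc[j : j + 6],
                spacer=sp,
                mismatches35=mm35,
                mismatches10=mm10,
                strand="-",
            )
        )
    hits.sort(key=lambda h: (h.total_mismatches, h.minus35[0], h.strand))
    return hits
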