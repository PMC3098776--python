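"""Hairpin (stem-loop) scanning with fixed loop length and A-rich calling.

The scanner enumerates, for every possible 7-nt loop placement, the
maximal perfectly Watson–Crick stem flanking it; a placement yields a
hit when that stem reaches the minimum length (3 bp by default).  Hits
carry two classifications used throughout the expanded trnY–trnE
spacers of horsetails: the "AAA" signature (three adenines in the loop
immediately adjacent to the stem — the mark shared with the trnY
anticodon loop) and a stem family keyed by the three base pairs
proximal to the loop (e.g. ``GGA/TCC``, the dominant family and the
anticodon-stem core of trnY).

No thermodynamics is involved: this is a combinatorial matcher, with
wobble pairs deliberately excluded (DNA context; the reference families
are all Watson–Crick).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import reverse_complement

__all__ = [
    "StemLoopHit",
    "StemLoopCensus",
    "scan_stemloops",
    "aaa_signature",
    "stem_family",
    "census",
]

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class StemLoopHit:
    """One hairpin: 5' arm + fixed-length loop + 3' arm.

    ``start`` is the 1-based position of the first base of the 5' arm;
    ``arm3`` is the exact reverse complement of ``arm5`` and ``stem_len``
    is maximal for this loop placement.
    """

    start: int
    stem_len: int
    loop_seq: str
    arm5: str
    arm3: str

    @property
    def loop_len(self) -> int:
        return len(self.loop_seq)

    @property
    def end(self) -> int:
        return self.start + 2 * self.stem_len + self.loop_len - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def family_key(self) -> str:
        return stem_family(self)

    @property
    def aaa_flag(self) -> bool:
        return aaa_signature(self)


@dataclass
class StemLoopCensus:
    """Histogram, total and coverage of a set of hairpin hits."""

    hits: list[StemLoopHit]
    histogram: dict[int, int]
    total: int
    covered_nt: int
    region_len: int
    coverage_mode: str = "union"

    @property
    def fraction(self) -> float:
        return self.covered_nt / self.region_len if self.region_len else 0.0


def scan_stemloops(
    seq: str, loop_len: int = 7, min_stem: int = 3
) -> list[StemLoopHit]:
    """All hairpins with the given loop length and stem >= ``min_stem``.

    One hit per loop placement, at the maximal perfect stem; hits may
    overlap each other.
    """
    n = len(seq)
    hits = []
    for p in range(1, n - loop_len):  # 0-based loop start; needs >=1 nt each side
        # extend outwards: seq[p-1-x] pairs seq[p+loop_len+x]
        max_l = min(p, n - loop_len - p)
        stem = 0
        while stem < max_l and _PAIR.get(seq[p - 1 - stem]) == seq[p + loop_len + stem]:
            stem += 1
        if stem >= min_stem:
            arm5 = seq[p - stem : p]
            arm3 = seq[p + loop_len : p + loop_len + stem]
            hits.append(
                StemLoopHit(
                    start=p - stem + 1,
                    stem_len=stem,
                    loop_seq=seq[p : p + loop_len],
                    arm5=arm5,
                    arm3=arm3,
                )
            )
    return hits


def aaa_signature(hit: StemLoopHit, side: str = "loop3") -> bool:
    """True iff the three loop bases adjacent to the chosen arm are AAA.

    ``loop3``: adjacent to the 3' arm (loop end); ``loop5``: adjacent to
    the 5' arm (loop start); ``either``: one or the other.
    """
    if hit.loop_len < 3:
        raise ValueError("loop shorter than the 3-nt signature")
    at3 = hit.loop_seq[-3:] == "AAA"
    at5 = hit.loop_seq[:3] == "AAA"
    if side == "loop3":
        return at3
    if side == "loop5":
        return at5
    if side == "either":
        return at3 or at5
    raise ValueError(f"unknown side {side!r}")


def stem_family(hit: StemLoopHit) -> str:
    """Family key: the three 5'-arm bases next to the loop, with their pairs."""
    if hit.stem_len < 3:
        raise ValueError("stem shorter than 3 bp has no family key")
    five = hit.arm5[-3:]
    return f"{five}/{reverse_complement(five)}"


def census(
    hits: list[StemLoopHit],
    region_len: int,
    require_aaa: bool = False,
    aaa_side: str = "loop3",
    coverage: str = "union",
) -> StemLoopCensus:
    """Stem-length histogram and coverage of (optionally AAA-only) hits.

    ``coverage="union"`` counts each covered base once; ``"sum"`` adds up
    the individual hit spans, so overlapping hits count multiply.
    """
    if hits and region_len < max(h.end for h in hits):
        raise ValueError("region_len is shorter than the furthest hit")
    if require_aaa:
        hits = [h for h in hits if aaa_signature(h, aaa_side)]
    histogram: dict[int, int] = {}
    for h in hits:
        histogram[h.stem_len] = histogram.get(h.stem_len, 0) + 1
    if coverage == "sum":
        covered = sum(h.end - h.start + 1 for h in hits)
    elif coverage == "union":
        covered = 0
        last_end = 0
        for h in sorted(hits, key=lambda h: h.span):
            lo, hi = max(h.start, last_end + 1), h.end
            if hi >= lo:
                covered += hi - lo + 1
                last_end = hi
            last_end = max(last_end, h.end)
    else:
        raise ValueError(f"unknown coverage mode {coverage!r}")
    return StemLoopCensus(
        hits=list(hits),
        histogram=dict(sorted(histogram.items())),
        total=len(hits),
        covered_nt=covered,
        region_len=region_len,
        coverage_mode=coverage,
    )
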