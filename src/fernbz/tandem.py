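"""Tandem-array detection, module segmentation and tRNA-similarity scoring.

Targets the geometry seen in the expanded trnY–trnE spacer of
*Vandenboschia radicans*: an array of quasi-identical ~27-bp units
repeated head-to-tail (17 copies over 459 bp), organised into modules —
contiguous runs of near-identical copies, each (after the first) led by
a distantly homologous "head" copy — and derived from the anticodon
domain of the adjacent trnY gene.

Detection is by self-offset matching: for a candidate period ``p``,
positions where the sequence matches itself shifted by ``p`` are chained
into maximal runs; runs are then cut into unit copies at the phase that
maximises copy-to-consensus identity.  Chaining tolerates short breaks
(up to three periods — the worst-case footprint of one divergent copy on
the self-comparison) so that a module head does not split an array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._align import identity, make_aligner
from .repeats import RepeatFamily, consensus_iupac

__all__ = [
    "TandemArray",
    "AnticodonSimilarity",
    "find_tandem_arrays",
    "segment_modules",
    "anticodon_similarity",
    "trny_anticodon_region",
]


@dataclass
class TandemArray:
    """A periodic region segmented into abutting unit copies and modules."""

    start: int  # 1-based inclusive
    end: int
    period: int
    copies: list[str]
    modules: list[int] = field(default_factory=list)  # sizes of contiguous runs
    consensus_unit: str = ""

    @property
    def copy_number(self) -> int:
        return len(self.copies)

    @property
    def span_len(self) -> int:
        return self.end - self.start + 1

    def copy_start(self, index: int) -> int:
        """1-based start of copy ``index`` (copies abut left to right)."""
        return self.start + sum(len(c) for c in self.copies[:index])


@dataclass(frozen=True)
class AnticodonSimilarity:
    """Best local alignment of a repeat unit against a tRNA sub-region.

    ``identity`` is computed over alignment columns and saturates for
    short spurious matches; ``score`` (the raw local-alignment score) is
    the right quantity for comparing a unit against controls.
    """

    identity: float
    aligned_len: int
    trna_region: str
    score: float = 0.0


# ---------------------------------------------------------------------------
# detection


def _majority_consensus(copies: list[str]) -> str:
    """Plain per-column majority over equal-length copies (ties: A<C<G<T)."""
    out = []
    for col in zip(*copies):
        counts = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def _copy_identity(a: str, b: str) -> float:
    """Hamming identity for equal-length unit copies."""
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_tandem_arrays(
    seq: str,
    period_min: int = 20,
    period_max: int = 40,
    min_copies: int = 3,
    max_unit_divergence: float = 0.2,
) -> list[TandemArray]:
    """Non-overlapping tandem arrays within a period range, longest first.

    For each period ``p``, positions ``i`` where ``seq[i:i+p]`` matches
    ``seq[i+p:i+2p]`` at identity >= ``1 - max_unit_divergence`` are
    chained into runs; breaks of up to ``3p`` are bridged, the worst-case
    footprint of a single divergent module-head copy on the self-offset
    comparison, so a head does not split an array.  Each run is cut
    into full-period copies at the phase with the best mean
    copy-to-consensus identity (ties: leftmost start).  Arrays from all
    periods are then selected greedily without overlap, longest span
    first (ties: smaller period).
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[TandemArray] = []
    for p in range(period_min, min(period_max, n // 2) + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.int32)
        if len(eq) < p:
            continue
        win = np.convolve(eq, np.ones(p, dtype=np.int32), mode="valid")
        ok = win >= np.ceil((1.0 - max_unit_divergence) * p)
        idx = np.nonzero(ok)[0]
        if len(idx) == 0:
            continue
        # chain into runs, bridging gaps <= 3p (one divergent copy's footprint)
        runs = []
        run_start = prev = int(idx[0])
        for i in idx[1:]:
            i = int(i)
            if i - prev > 3 * p:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            region_len = b - a + 2 * p
            if region_len // p < min_copies:
                continue
            candidates.append(_cut_array(seq, a, region_len, p))
    candidates = [c for c in candidates if c.copy_number >= min_copies]
    candidates.sort(key=lambda t: (-t.span_len, t.period, t.start))
    chosen: list[TandemArray] = []
    for cand in candidates:
        if all(
            cand.end < t.start or cand.start > t.end for t in chosen
        ):
            chosen.append(cand)
    for t in chosen:
        t.modules = segment_modules(t)
        t.consensus_unit = consensus_iupac(RepeatFamily(members=list(t.copies)))
    chosen.sort(key=lambda t: (-t.span_len, t.start))
    return chosen


def _cut_array(seq: str, region_start0: int, region_len: int, p: int) -> TandemArray:
    """Phase the copy cut inside a periodic region (0-based region start)."""
    best = None
    for phase in range(p):
        start0 = region_start0 + phase
        k = (region_len - phase) // p
        if k < 1:
            continue
        copies = [seq[start0 + t * p : start0 + (t + 1) * p] for t in range(k)]
        cons = _majority_consensus(copies)
        score = sum(_copy_identity(c, cons) for c in copies) / k
        key = (k, score, -start0)  # prefer more copies, better score, leftmost
        if best is None or key > best[0]:
            best = (key, start0, copies)
    _, start0, copies = best
    return TandemArray(
        start=start0 + 1,
        end=start0 + len(copies) * p,
        period=p,
        copies=copies,
    )


# ---------------------------------------------------------------------------
# modules


def segment_modules(array: TandemArray, head_divergence: float = 0.25) -> list[int]:
    """Module sizes: boundaries open before each divergent "head" copy.

    A copy is a head when its identity to the whole-array majority
    consensus drops below ``1 - head_divergence``; a run of consecutive
    heads opens a single module (so an isolated divergent copy — e.g. at
    the array end — forms or leads its own module).
    """
    copies = array.copies
    if len(copies) <= 1:
        return [len(copies)]
    cons = _majority_consensus(copies)
    divergent = [_copy_identity(c, cons) < 1.0 - head_divergence for c in copies]
    sizes = [1]
    for k in range(1, len(copies)):
        if divergent[k] and not divergent[k - 1]:
            sizes.append(1)
        else:
            sizes[-1] += 1
    return sizes


# ---------------------------------------------------------------------------
# tRNA similarity


def trny_anticodon_region(locus: str = "trnY-GUA") -> tuple[int, int]:
    """Shipped 1-based coordinates of the anticodon-arm window within trnY."""
    text = (
        resources.files("fernbz.data").joinpath("trny_anticodon_region.tsv").read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("locus"):
            continue
        name, start, end = line.split("\t")
        if name.strip().upper() == locus.strip().upper():
            return int(start), int(end)
    raise KeyError(f"no anticodon region for locus {locus!r}")


def anticodon_similarity(
    unit: str, trna_gene: str, region: tuple[int, int] | None = None
) -> AnticodonSimilarity:
    """Score a tandem unit against a tRNA sub-region by local alignment.

    ``region`` is 1-based inclusive within the gene (default: the shipped
    trnY anticodon-arm window).  Identity is counted over alignment
    columns of the best local alignment (match +1, mismatch -1, gap -2).
    """
    if region is None:
        region = trny_anticodon_region()
    lo, hi = region
    if not (1 <= lo <= hi <= len(trna_gene)):
        raise ValueError(f"region {region} outside gene of length {len(trna_gene)}")
    ref = trna_gene[lo - 1 : hi]
    aln = make_aligner("local").align(unit, ref)
    if len(aln) == 0 or aln[0].length == 0:
        return AnticodonSimilarity(0.0, 0, f"{lo}..{hi}", 0.0)
    best = aln[0]
    counts = best.counts()
    return AnticodonSimilarity(
        identity=counts.identities / best.length,
        aligned_len=best.length,
        trna_region=f"{lo}..{hi}",
        score=float(best.score),
    )
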