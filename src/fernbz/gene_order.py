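"""Signed gene orders of the BZ region and inversion-pathway reasoning.

A BZ gene order is a signed sequence over the nine loci
``B C N M D Y E G Z`` (rpoB .. psbZ), anchored by B first and Z last;
the anchors are never inside an inversion.  An inversion event reverses
an interior segment and flips its signs.  The module answers the
questions the comparative analysis asks: how many inversions separate
two observed orders (exact, by iterative-deepening search with a
breakpoint lower bound), which single-step intermediates lie between two
orders at distance 2, and which named type — Angiopteris (ancestral),
Adiantum (derived) or Plagiogyria (the novel intermediate-like order) —
an observed order matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "GeneOrder",
    "InversionEvent",
    "apply_inversion",
    "inversion_distance",
    "enumerate_intermediates",
    "classify_order",
    "load_catalog",
    "format_distance",
]


@dataclass(frozen=True)
class InversionEvent:
    """Reversal of the interior segment [i..j] (1-based positions)."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i > self.j:
            raise ValueError(f"inversion with i {self.i} > j {self.j}")


@dataclass(frozen=True)
class GeneOrder:
    """An ordered tuple of (symbol, sign) pairs, signs in {+1, -1}."""

    loci: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.loci]
        if len(set(symbols)) != len(symbols):
            raise ValueError(f"duplicate symbols in gene order {symbols}")
        if any(g not in (1, -1) for _, g in self.loci):
            raise ValueError("signs must be +1 or -1")

    # -- construction / rendering ------------------------------------------
    @classmethod
    def from_string(cls, text: str) -> "GeneOrder":
        """Parse ``"B,-E,-Y,D,M,N,-C,G,Z"`` style notation."""
        loci = []
        for tok in text.strip().split(","):
            tok = tok.strip().replace("−", "-")
            if not tok:
                continue
            sign = -1 if tok.startswith("-") else 1
            loci.append((tok.lstrip("+-"), sign))
        return cls(tuple(loci))

    def __str__(self) -> str:
        return ",".join(("-" if g < 0 else "") + s for s, g in self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    # -- elementary operations ---------------------------------------------
    def global_flip(self) -> "GeneOrder":
        """The same order read from the opposite end (reverse + flip signs)."""
        return GeneOrder(tuple((s, -g) for s, g in reversed(self.loci)))

    def symbols(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.loci)


def apply_inversion(order: GeneOrder, ev: InversionEvent) -> GeneOrder:
    """Reverse segment [ev.i .. ev.j] and flip its signs.

    Indices are 1-based; the first and last loci are anchors and may not
    be part of the segment.
    """
    n = len(order)
    if ev.i < 2 or ev.j > n - 1:
        raise ValueError(
            f"inversion [{ev.i}..{ev.j}] touches an anchor of a {n}-locus order"
        )
    loci = list(order.loci)
    seg = [(s, -g) for s, g in reversed(loci[ev.i - 1 : ev.j])]
    return GeneOrder(tuple(loci[: ev.i - 1] + seg + loci[ev.j :]))


def _interior_events(n: int) -> list[InversionEvent]:
    return [InversionEvent(i, j) for i in range(2, n) for j in range(i, n)]


def _as_signed_perm(a: GeneOrder, b: GeneOrder) -> tuple[int, ...]:
    """Rename so that b reads +1..+n; return a in that frame."""
    if a.symbols() != b.symbols():
        raise ValueError(
            f"gene orders over different symbol sets: {sorted(a.symbols())} "
            f"vs {sorted(b.symbols())}"
        )
    rank = {s: k + 1 for k, (s, _) in enumerate(b.loci)}
    sign_b = {s: g for s, g in b.loci}
    return tuple(g * sign_b[s] * rank[s] for s, g in a.loci)


def _breakpoint_bound(perm: tuple[int, ...]) -> int:
    """Admissible lower bound: ceil(breakpoints / 2).

    With the frame extended by 0 and n+1, an adjacency (x, y) is intact
    iff y = x + 1; a single reversal removes at most two breakpoints.
    """
    ext = (0,) + perm + (len(perm) + 1,)
    b = sum(1 for x, y in zip(ext, ext[1:]) if y != x + 1)
    return (b + 1) // 2


def inversion_distance(a: GeneOrder, b: GeneOrder, cap: int = 4) -> int | None:
    """Exact minimum number of interior inversions turning ``a`` into ``b``.

    Returns ``None`` when the distance exceeds ``cap`` (render with
    :func:`format_distance`).  Exhaustive iterative-deepening search over
    all interior segment choices, pruned by a breakpoint lower bound.
    """
    target = _as_signed_perm(b, b)  # identity frame
    start = _as_signed_perm(a, b)
    if start == target:
        return 0
    n = len(start)
    events = [(i - 1, j) for i in range(2, n) for j in range(i, n)]  # 0-based slices

    def neighbors(p: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        for lo, hi in events:
            yield p[:lo] + tuple(-x for x in reversed(p[lo:hi])) + p[hi:]

    def dfs(p: tuple[int, ...], depth: int) -> bool:
        if p == target:
            return True
        if depth == 0 or _breakpoint_bound(p) > depth:
            return False
        for q in neighbors(p):
            if dfs(q, depth - 1):
                return True
        return False

    for d in range(1, cap + 1):
        if dfs(start, d):
            return d
    return None


def format_distance(d: int | None, cap: int = 4) -> str:
    return str(d) if d is not None else f">={cap + 1}"


def enumerate_intermediates(a: GeneOrder, b: GeneOrder) -> set[GeneOrder]:
    """All orders one inversion from each of ``a`` and ``b`` (d(a,b) must be 2)."""
    d = inversion_distance(a, b, cap=4)
    if d != 2:
        raise ValueError(f"enumerate_intermediates requires distance 2, got {d}")
    out = set()
    for ev in _interior_events(len(a)):
        m = apply_inversion(a, ev)
        if inversion_distance(m, b, cap=1) == 1:
            out.add(m)
    return out


def classify_order(order: GeneOrder, catalog: dict[str, GeneOrder] | None = None) -> str:
    """Name of the catalog order matching exactly (or as a global flip)."""
    catalog = catalog if catalog is not None else load_catalog()
    flipped = order.global_flip()
    for name, ref in catalog.items():
        if order == ref or flipped == ref:
            return name
    return "novel"


def load_catalog(path: str | Path | None = None) -> dict[str, GeneOrder]:
    """Named BZ gene orders (Angiopteris, Plagiogyria, Adiantum types).

    The default catalog ships with the package; a user file has the same
    format: ``name<TAB>B,-E,...`` with ``#`` comments.
    """
    if path is None:
        text = resources.files("fernbz.data").joinpath("gene_orders.txt").read_text()
    else:
        text = Path(path).read_text()
    catalog = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, spec = line.split("\t")
        catalog[name.strip()] = GeneOrder.from_string(spec)
    return catalog
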