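"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive algorithms (per-start-pair greedy extension,
exhaustive double loops, breadth-first search) so that agreement with the
package's vectorised/pruned implementations is meaningful.
"""

from __future__ import annotations

from collections import deque

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _transform(seq: str, kind: str) -> str:
    if kind == "direct":
        return seq
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return "".join(_PAIR[c] for c in seq)
    if kind == "revcomp":
        return "".join(_PAIR[c] for c in reversed(seq))
    raise ValueError(kind)


def repeat_matches_bruteforce(seq: str, kind: str, min_len: int, k: int) -> set:
    """All maximal matches as (kind, pos1, pos2, length, mismatches) tuples.

    For every ordered start pair, extend greedily to the right within the
    mismatch budget, then keep the match only if it cannot be extended to
    the left (free, or within budget).
    """
    t = _transform(seq, kind)
    n = len(seq)
    out = set()
    for i in range(n):
        for j in range(n):
            if kind == "direct" and j <= i:
                continue
            mm = 0
            L = 0
            while i + L < n and j + L < n:
                if seq[i + L] != t[j + L]:
                    if mm == k:
                        break
                    mm += 1
                L += 1
            if L < min_len:
                continue
            if i > 0 and j > 0:
                if seq[i - 1] == t[j - 1]:
                    continue  # extensible left at no cost
                if mm < k:
                    continue  # extensible left within budget
            p2 = j if kind in ("direct", "complement") else n - j - L
            if kind == "direct" and i == p2:
                continue
            lo, hi = min(i, p2), max(i, p2)
            out.add((kind, lo + 1, hi + 1, L, mm))
    return out


def stemloops_bruteforce(seq: str, loop_len: int, min_stem: int) -> set:
    """All (start, stem_len) hairpins by testing every (loop, stem) pair."""
    n = len(seq)
    out = set()
    for p in range(0, n - loop_len + 1):  # 0-based loop start
        best = 0
        stem = 1
        while True:
            lo = p - stem
            hi = p + loop_len + stem - 1
            if lo < 0 or hi >= n:
                break
            if all(
                _PAIR[seq[p - 1 - x]] == seq[p + loop_len + x] for x in range(stem)
            ):
                best = stem
                stem += 1
            else:
                break
        if best >= min_stem:
            out.add((p - best + 1, best))  # 1-based hit start
    return out


def inversion_distance_bfs(a, b, cap: int = 5) -> int | None:
    """Breadth-first search over the interior-inversion graph."""
    from fernbz.gene_order import apply_inversion, InversionEvent

    if a == b:
        return 0
    n = len(a)
    events = [InversionEvent(i, j) for i in range(2, n) for j in range(i, n)]
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        cur, d = frontier.popleft()
        if d == cap:
            continue
        for ev in events:
            nxt = apply_inversion(cur, ev)
            if nxt == b:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    return None


def best_period_exhaustive(seq: str, period_min: int, period_max: int):
    """Score every (period, phase, copy count) exhaustively; return the
    (period, start0, n_copies) maximising total aligned copies, for tiny
    fixtures only."""
    best = None
    n = len(seq)
    for p in range(period_min, period_max + 1):
        for start in range(0, n - 2 * p + 1):
            count = 1
            while start + (count + 1) * p <= n:
                a = seq[start + (count - 1) * p : start + count * p]
                b = seq[start + count * p : start + (count + 1) * p]
                ident = sum(x == y for x, y in zip(a, b)) / p
                if ident < 0.8:
                    break
                count += 1
            if count >= 3:
                key = (count * p, -p)
                if best is None or key > best[0]:
                    best = (key, p, start, count)
    if best is None:
        return None
    _, p, start, count = best
    return p, start, count
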