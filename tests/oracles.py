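"""Independent brute-force oracles used to validate the optimized paths.

Deliberately naive: each reimplements its operation from the definition,
without sharing code with the library internals it checks.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_window_counts(seq: str, base: str, window: int, step: int, mode_fn) -> list[int]:
    """Per-window triplet recount straight from the definition."""
    n = len(seq)
    runs = []
    i = 0
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if n < window:
        return [sum(mode_fn(e - s) for s, e in runs)]
    counts = []
    for p in range(0, n - window + 1, step):
        counts.append(sum(mode_fn(e - s) for s, e in runs if s >= p and e <= p + window))
    return counts


def oracle_enumerate_motifs(seq: str, max_len=45, min_g=3, loop_min=0, loop_max=36):
    """All 4-run motif candidates by exhaustive combination checking.

    Runs are anchored at maximal-run starts with every prefix length from
    min_g to the full run; all quadruples are checked against the loop and
    span filters by direct position arithmetic.
    """
    n = len(seq)
    maximal = []
    i = 0
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_g:
                maximal.append((i, j - i))
            i = j
        else:
            i += 1
    choices = [
        (start, length)
        for start, full in maximal
        for length in range(min_g, full + 1)
    ]
    motifs = set()
    for combo in itertools.combinations(choices, 4):
        starts = [c[0] for c in combo]
        if len(set(starts)) < 4 or starts != sorted(starts):
            continue
        ok = True
        for (s1, l1), (s2, _l2) in zip(combo, combo[1:]):
            loop = s2 - (s1 + l1)
            if not loop_min <= loop <= loop_max:
                ok = False
                break
        if not ok:
            continue
        span = combo[3][0] + combo[3][1] - combo[0][0]
        if span > max_len:
            continue
        motifs.add((tuple(starts), tuple(c[1] for c in combo)))
    return motifs


def oracle_best_complement(a: str, b: str, min_len=6, exact_max=9, min_pct=90.0):
    """Best qualifying ungapped alignment by scanning all substring pairs.

    The segment a[i:i+L] is compared position-by-position against the
    reverse complement of b[j:j+L].  Returns (length, matches, offset_a,
    offset_b) or None, ranked by length, pct, leftmost offsets.
    """
    best = None
    la, lb = len(a), len(b)
    for L in range(min(la, lb), min_len - 1, -1):
        need = L if L <= exact_max else math.ceil(min_pct / 100.0 * L)
        for i in range(la - L + 1):
            for j in range(lb - L + 1):
                matches = sum(
                    1 for t in range(L) if a[i + t] == _COMP[b[j + L - 1 - t]]
                )
                if matches < need:
                    continue
                key = (L, matches / L, -i, -j)
                if best is None or key > best[0]:
                    best = (key, (L, matches, i, j))
    return None if best is None else best[1]


def brute_nearest_distance(query, features) -> int | None:
    """Quadratic nearest end-to-end gap (0 if overlapping)."""
    best = None
    for f in features:
        if f.chrom != query.chrom:
            continue
        if f.start < query.end and query.start < f.end:
            return 0
        gap = f.start - query.end if f.start >= query.end else query.start - f.end
        if best is None or gap < best:
            best = gap
    return best
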