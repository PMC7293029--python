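"""Loop extraction and reverse-complement loop:loop ("G4 kissing") pairing.

Loops are the spacers between neighboring G-runs inside an LG4; in a folded
quadruplex they are single-stranded and free to base-pair with loops of
neighboring G4 units.  Admitted loops are 5-39 nt (exclusive bounds 4 and
40) and N-free.  Two loops are called complementary when some ungapped
local alignment of one against the reverse complement of the other is at
least 6 bp long, with 6-9 bp alignments fully complementary and longer
alignments at least 90% complementary (Watson-Crick matches only, no
wobble).  Alignment is exhaustive - loops are short enough that a full
substring-pair scan is cheap and deterministic - accelerated by a shared
5-mer gate: any qualifying alignment allows at most floor(len/10)
mismatches, so it always contains >= 5 consecutive matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import GenomeRecord, revcomp
from .scanner import LG4Locus, RICH_BOTH, RICH_MINUS, find_base_runs

LOOP_MIN = 5
LOOP_MAX = 39

PATTERN_SELF = "self"
PATTERN_NEIGHBORING = "neighboring"
PATTERN_NONE = "none"


@dataclass(frozen=True)
class KissThresholds:
    min_len: int = 6
    exact_max: int = 9
    min_pct: float = 90.0

    def required_matches(self, length: int) -> int:
        if length <= self.exact_max:
            return length
        return math.ceil(self.min_pct / 100.0 * length)


@dataclass(frozen=True)
class G4Loop:
    """A loop between two neighboring G-runs of one locus."""

    locus_id: str
    index: int
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LoopComplement:
    """Best qualifying ungapped alignment between two loop sequences.

    ``offset_a``/``offset_b`` are 0-based positions of the aligned segment
    within each loop's own sequence; the segment of ``seq_a`` is compared
    against the reverse complement of the segment of ``seq_b``.
    """

    seq_a: str
    seq_b: str
    offset_a: int
    offset_b: int
    length: int
    matches: int
    loop_a: G4Loop | None = None
    loop_b: G4Loop | None = None

    def __post_init__(self) -> None:
        # contract: 6-9 bp pairs are perfect, >9 bp pairs >= 90%
        if self.length < 6:
            raise ValueError("reported pair shorter than 6 bp")
        if self.length <= 9 and self.matches != self.length:
            raise ValueError("6-9 bp pair must be 100% complementary")
        if self.length > 9 and self.pct < 90.0 - 1e-9:
            raise ValueError(">9 bp pair must be >= 90% complementary")

    @property
    def pct(self) -> float:
        return 100.0 * self.matches / self.length


@dataclass(frozen=True)
class LocusKissSummary:
    locus_id: str
    n_pairs: int
    mean_pair_length: float | None
    pattern: str


def extract_loops(
    locus: LG4Locus,
    records: Mapping[str, GenomeRecord],
    loop_min: int = LOOP_MIN,
    loop_max: int = LOOP_MAX,
) -> tuple[list[G4Loop], list[G4Loop]]:
    """All admitted loops of a locus plus the deduplicated unique set.

    Loops are the gaps between consecutive rich-base runs of length >= 3
    inside the locus span; admitted loops are ``loop_min``..``loop_max`` nt
    and N-free.  The unique set retains first-occurrence coordinates.
    """
    record = records[locus.chrom]
    base = _rich_base(locus, record)
    return extract_loops_from_seq(
        record.seq[locus.start : locus.end],
        base,
        locus_id=locus.name or f"{locus.chrom}:{locus.start}-{locus.end}",
        origin=locus.start,
        loop_min=loop_min,
        loop_max=loop_max,
    )


def _rich_base(locus: LG4Locus, record: GenomeRecord) -> str:
    if locus.rich_strand == RICH_MINUS:
        return "C"
    if locus.rich_strand == RICH_BOTH:
        seq = record.seq[locus.start : locus.end]
        g = sum(r.length // 3 for r in find_base_runs(seq, "G"))
        c = sum(r.length // 3 for r in find_base_runs(seq, "C"))
        return "G" if g >= c else "C"
    return "G"


def extract_loops_from_seq(
    seq: str,
    base: str = "G",
    locus_id: str = "seq",
    origin: int = 0,
    loop_min: int = LOOP_MIN,
    loop_max: int = LOOP_MAX,
) -> tuple[list[G4Loop], list[G4Loop]]:
    runs = [r for r in find_base_runs(seq, base) if r.length >= 3]
    loops: list[G4Loop] = []
    for i in range(len(runs) - 1):
        gap_start, gap_end = runs[i].end, runs[i + 1].start
        gap_seq = seq[gap_start:gap_end]
        if not (loop_min <= len(gap_seq) <= loop_max):
            continue
        if "N" in gap_seq:
            continue
        loops.append(
            G4Loop(locus_id, len(loops), origin + gap_start, origin + gap_end, gap_seq)
        )
    unique: list[G4Loop] = []
    seen: set[str] = set()
    for loop in loops:
        if loop.seq not in seen:
            seen.add(loop.seq)
            unique.append(loop)
    return loops, unique


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _safe_seed_len(thresholds: KissThresholds, max_len: int) -> int:
    """Longest k such that any qualifying alignment shares a k-mer.

    An alignment of length L with at most f mismatches contains an exact
    run of at least ceil((L - f) / (f + 1)) matches; minimize over every
    admissible L (capped at 8, the pigeonhole bound grows with L).
    """
    worst = 8
    for L in range(thresholds.min_len, max(thresholds.min_len, max_len) + 1):
        if L <= thresholds.exact_max:
            f = 0
        else:
            f = int(L - math.ceil(thresholds.min_pct / 100.0 * L))
        worst = min(worst, math.ceil((L - f) / (f + 1)))
    return worst


def best_complement(
    a: str,
    b: str,
    thresholds: KissThresholds = KissThresholds(),
    loop_a: G4Loop | None = None,
    loop_b: G4Loop | None = None,
) -> LoopComplement | None:
    """Highest-ranking qualifying ungapped alignment of ``a`` vs revcomp(``b``).

    Ranking: longest, then highest percent complementarity, then leftmost
    ``offset_a``, then leftmost ``offset_b``.  Returns None if no alignment
    satisfies the thresholds.  Equivalent to a brute-force scan over all
    substring pairs.
    """
    if "N" in a or "N" in b:
        return None
    rc = revcomp(b)
    # seed gate: every qualifying alignment contains an exact-match run of
    # at least _safe_seed_len bases, hence a shared k-mer of that length
    seed = _safe_seed_len(thresholds, min(len(a), len(b)))
    if seed >= 3 and not (_kmers(a, seed) & _kmers(rc, seed)):
        return None
    la, lb = len(a), len(rc)
    best: tuple[int, float, int, int, int] | None = None  # (L, pct, -i, -ob, matches)
    for d in range(-(lb - 1), la):
        i0 = max(0, d)
        j0 = i0 - d
        m = min(la - i0, lb - j0)
        if m < thresholds.min_len:
            continue
        prefix = [0]
        for t in range(m):
            prefix.append(prefix[-1] + (1 if a[i0 + t] == rc[j0 + t] else 0))
        for L in range(m, thresholds.min_len - 1, -1):
            need = thresholds.required_matches(L)
            for s in range(m - L + 1):
                matches = prefix[s + L] - prefix[s]
                if matches < need:
                    continue
                i = i0 + s
                offset_b = lb - (j0 + s) - L
                key = (L, 100.0 * matches / L, -i, -offset_b, matches)
                if best is None or key > best:
                    best = key
    if best is None:
        return None
    L, _, neg_i, neg_ob, matches = best
    return LoopComplement(
        seq_a=a, seq_b=b, offset_a=-neg_i, offset_b=-neg_ob,
        length=L, matches=matches, loop_a=loop_a, loop_b=loop_b,
    )


def find_loop_pairs(
    unique_loops: Sequence[G4Loop | str],
    thresholds: KissThresholds = KissThresholds(),
) -> tuple[list[LoopComplement], list[LoopComplement]]:
    """Best qualifying alignment per unordered pair of distinct unique loops.

    Returns ``(pairs, self_hits)``: one LoopComplement per qualifying pair
    of distinct unique sequences, plus one per unique sequence whose best
    alignment against its own reverse complement qualifies (palindromic or
    internally complementary loops, used by pattern classification).
    """
    loops = [_as_loop(l, i) for i, l in enumerate(unique_loops)]
    loops = [l for l in loops if "N" not in l.seq]
    pairs: list[LoopComplement] = []
    for i in range(len(loops)):
        for j in range(i + 1, len(loops)):
            if loops[i].seq == loops[j].seq:
                continue
            hit = best_complement(
                loops[i].seq, loops[j].seq, thresholds,
                loop_a=loops[i], loop_b=loops[j],
            )
            if hit is not None:
                pairs.append(hit)
    self_hits: list[LoopComplement] = []
    for loop in loops:
        hit = best_complement(loop.seq, loop.seq, thresholds, loop_a=loop, loop_b=loop)
        if hit is not None:
            self_hits.append(hit)
    return pairs, self_hits


def _as_loop(loop: G4Loop | str, index: int) -> G4Loop:
    if isinstance(loop, G4Loop):
        return loop
    return G4Loop("panel", index, 0, len(loop), loop)


def classify_locus_pattern(
    pairs: Sequence[LoopComplement],
    self_hits: Sequence[LoopComplement],
    majority: float = 0.5,
) -> str:
    """Self vs neighboring complementarity pattern of one locus.

    ``self`` when more than ``majority`` of the pairing mass comes from
    loops complementary to themselves (palindromic segments, or instances
    of one identical sequence pairing); ``neighboring`` otherwise; ``none``
    with no qualifying pairing at all.
    """
    total = len(pairs) + len(self_hits)
    if total == 0:
        return PATTERN_NONE
    if len(self_hits) / total > majority:
        return PATTERN_SELF
    return PATTERN_NEIGHBORING


def expected_random_spacing(k: int) -> int:
    """Expected bp between random occurrences of a fixed k-nt complement.

    Under a uniform i.i.d. base model a specific k-mer occurs once every
    4**k bp; e.g. the complement to a 6 nt loop once every 4096 bp.
    """
    if not isinstance(k, int) or isinstance(k, bool) or k <= 0:
        raise ValueError("loop length must be a positive integer")
    return 4 ** k


def summarize_kissing(
    results: Sequence[tuple[str, Sequence[LoopComplement], Sequence[LoopComplement]]],
    majority: float = 0.5,
) -> tuple[list[LocusKissSummary], dict[str, float | int | None]]:
    """Per-locus summaries plus cohort statistics.

    ``results`` holds (locus_id, pairs, self_hits) per locus.  Cohort means
    are computed over loci with at least one qualifying pairing; the mean
    pair length is weighted by each locus's pair count.
    """
    summaries: list[LocusKissSummary] = []
    for locus_id, pairs, self_hits in results:
        events = list(pairs) + list(self_hits)
        n = len(events)
        mean_len = sum(e.length for e in events) / n if n else None
        pattern = classify_locus_pattern(pairs, self_hits, majority)
        summaries.append(LocusKissSummary(locus_id, n, mean_len, pattern))
    with_pairs = [s for s in summaries if s.n_pairs > 0]
    total_pairs = sum(s.n_pairs for s in with_pairs)
    total_len = sum(s.n_pairs * s.mean_pair_length for s in with_pairs)  # type: ignore[operator]
    cohort: dict[str, float | int | None] = {
        "n_loci": len(summaries),
        "n_with_pairs": len(with_pairs),
        "mean_pairs_per_locus": (total_pairs / len(with_pairs)) if with_pairs else None,
        "mean_pair_length": (total_len / total_pairs) if total_pairs else None,
    }
    return summaries, cohort
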