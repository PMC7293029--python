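"""Minimal intramolecular G4 motif enumeration and density.

A minimal quadruplex-forming motif is four ordered G-runs (each at least
``min_g`` long) separated by three loops of bounded length, with the whole
motif no longer than ``max_len``.  Defaults (45 nt max, G-runs >= 3, loops
0-36 nt) select for intramolecular G4 only.  Runs longer than ``min_g``
contribute every prefix length from ``min_g`` up to their full length as a
legal run choice; candidates identical in all four run intervals are
reported once.  Densities count greedily selected non-overlapping motifs,
summed over both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import GenomeRecord, Interval, revcomp
from .scanner import find_base_runs


@dataclass(frozen=True)
class MotifParams:
    max_len: int = 45
    min_g: int = 3
    loop_min: int = 0
    loop_max: int = 36

    def __post_init__(self) -> None:
        if self.max_len < 4 * self.min_g:
            raise ValueError("max_len must be >= 4 * min_g")
        if not 0 <= self.loop_min <= self.loop_max:
            raise ValueError("need 0 <= loop_min <= loop_max")


@dataclass(frozen=True)
class G4Motif:
    """Four G-runs and their three loops; coordinates are half-open."""

    run_starts: tuple[int, int, int, int]
    run_lengths: tuple[int, int, int, int]

    @property
    def start(self) -> int:
        return self.run_starts[0]

    @property
    def end(self) -> int:
        return self.run_starts[3] + self.run_lengths[3]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def loop_lengths(self) -> tuple[int, int, int]:
        return tuple(
            self.run_starts[i + 1] - (self.run_starts[i] + self.run_lengths[i])
            for i in range(3)
        )  # type: ignore[return-value]

    def overlaps(self, other: "G4Motif") -> bool:
        return self.start < other.end and other.start < self.end


def enumerate_g4_motifs(seq: str, params: MotifParams = MotifParams()) -> list[G4Motif]:
    """Every candidate motif on the given strand satisfying the filters.

    The caller supplies the reverse complement to scan the other
    orientation.  Returned sorted by (start, end, run intervals).
    """
    runs = [r for r in find_base_runs(seq, "G") if r.length >= params.min_g]
    n = len(runs)
    motifs: list[G4Motif] = []
    for a in range(n - 3):
        ra = runs[a]
        # any motif anchored at ra spans at least to its 4th run start + min_g
        for b in range(a + 1, n - 2):
            rb = runs[b]
            if rb.start + 3 * params.min_g - ra.start > params.max_len:
                break
            la_range = _run_length_range(ra, rb, params)
            if la_range is None:
                continue
            for c in range(b + 1, n - 1):
                rc = runs[c]
                if rc.start + 2 * params.min_g - ra.start > params.max_len:
                    break
                lb_range = _run_length_range(rb, rc, params)
                if lb_range is None:
                    continue
                for d in range(c + 1, n):
                    rd = runs[d]
                    if rd.start + params.min_g - ra.start > params.max_len:
                        break
                    lc_range = _run_length_range(rc, rd, params)
                    if lc_range is None:
                        continue
                    ld_max = min(rd.length, params.max_len - (rd.start - ra.start))
                    if ld_max < params.min_g:
                        continue
                    for la in range(*la_range):
                        for lb in range(*lb_range):
                            for lcl in range(*lc_range):
                                for ld in range(params.min_g, ld_max + 1):
                                    motifs.append(
                                        G4Motif(
                                            (ra.start, rb.start, rc.start, rd.start),
                                            (la, lb, lcl, ld),
                                        )
                                    )
    motifs.sort(key=lambda m: (m.start, m.end, m.run_starts, m.run_lengths))
    return motifs


def _run_length_range(run, next_run, params: MotifParams) -> tuple[int, int] | None:
    """Legal prefix lengths for ``run`` given the loop to ``next_run``.

    The loop is the gap between the chosen prefix end and the next run
    start; it must lie in [loop_min, loop_max].
    """
    gap = next_run.start - run.start
    lo = max(params.min_g, gap - params.loop_max)
    hi = min(run.length, gap - params.loop_min)
    if lo > hi:
        return None
    return lo, hi + 1


def select_nonoverlapping(motifs: Sequence[G4Motif]) -> list[G4Motif]:
    """Greedy selection: smallest start (tie: smallest end), drop overlaps."""
    ordered = sorted(motifs, key=lambda m: (m.start, m.end))
    selected: list[G4Motif] = []
    cursor = -1
    for m in ordered:
        if m.start >= cursor:
            selected.append(m)
            cursor = m.end
    return selected


def count_nonoverlapping_both_orientations(seq: str, params: MotifParams = MotifParams()) -> int:
    """Non-overlapping motif count, orientations counted independently then summed."""
    fwd = len(select_nonoverlapping(enumerate_g4_motifs(seq, params)))
    rev = len(select_nonoverlapping(enumerate_g4_motifs(revcomp(seq), params)))
    return fwd + rev


def motif_density(
    interval: Interval,
    records: Mapping[str, GenomeRecord],
    params: MotifParams = MotifParams(),
) -> float:
    """Non-overlapping motifs per kb inside ``interval`` (both orientations)."""
    record = records[interval.chrom]
    if interval.length == 0:
        raise ValueError("zero-length interval")
    if interval.end > record.length:
        raise ValueError(f"{interval.chrom}:{interval.start}-{interval.end} beyond record")
    seq = record.seq[interval.start : interval.end]
    return count_nonoverlapping_both_orientations(seq, params) / (interval.length / 1000.0)


def flanking_densities(
    locus: Interval,
    records: Mapping[str, GenomeRecord],
    flank: int = 1500,
    params: MotifParams = MotifParams(),
) -> tuple[float | None, float, float | None]:
    """(upstream, locus, downstream) motif densities.

    Flanks are clipped at chromosome ends and their effective lengths used
    as denominators; a zero-length flank is reported as None.
    """
    record = records[locus.chrom]
    up_start, up_end = max(0, locus.start - flank), locus.start
    down_start, down_end = locus.end, min(record.length, locus.end + flank)

    def _density(start: int, end: int) -> float | None:
        if end <= start:
            return None
        seq = record.seq[start:end]
        return count_nonoverlapping_both_orientations(seq, params) / ((end - start) / 1000.0)

    return (
        _density(up_start, up_end),
        motif_density(locus, records, params),
        _density(down_start, down_end),
    )
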