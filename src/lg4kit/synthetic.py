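"""Synthetic genome fixtures with planted ground truth.

Generates multi-chromosome FASTA genomes containing planted G-triplet-dense
repeat regions (detectable and sub-threshold), kissing-loop pairs, telomeric
TTAGGG tracts, loop-size negative controls and variant hotspots, together
with a ledger of everything planted, so the scanner, motif, kissing and
association modules can all be verified without any download.

Two deliberate departures from pure i.i.d. background keep recovery tests
meaningful: background windows that would meet the scan threshold by chance
are locally resampled, and a window-width buffer flanking every planted span
is scrubbed of G/C triplets so planted boundaries are identifiable.  Filler
loops inside planted repeat regions are drawn from an A/C alphabet, which
cannot base-pair with any other A/C loop, so the only loop:loop complements
in a region are the ones planted there.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeRecord, Interval, revcomp
from .kissing import KissThresholds, find_loop_pairs
from .scanner import ScanParams, TRIPLET_MODES, find_base_runs, window_triplet_counts

log = logging.getLogger("lg4kit")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class UnitSpec:
    """One repeat unit: a G (or C) run followed by a loop spacer.

    Loops outside 5-39 nt are legal here - they serve as negative controls
    for loop extraction.  The loop must not contain a run of >= 3 of the
    unit's own base, which would fuse adjacent units.
    """

    run_base: str = "G"
    run_length: int = 3
    loop_seq: str = "TT"

    def __post_init__(self) -> None:
        if self.run_base not in ("G", "C"):
            raise ValueError("run_base must be G or C")
        if self.run_length < 3:
            raise ValueError("run_length must be >= 3")
        if not 0 <= len(self.loop_seq) <= 60:
            raise ValueError("loop_seq must be 0-60 nt")
        if self.run_base * 3 in self.loop_seq:
            raise ValueError("loop_seq would fuse adjacent units")


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    kind: str  # positive | kissing | subthreshold | negative_loops | telomeric
    n_units: int
    expected_triplets: int
    expected_density: float
    detectable: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.kind,
                        round(self.expected_density, 2), "+")


@dataclass(frozen=True)
class PlantedLoopPair:
    chrom: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    seq_a: str
    seq_b: str
    length: int
    pct: float
    expected: bool  # False for planted negatives (e.g. 5-bp complements)


@dataclass
class SyntheticTruth:
    """Ledger of every planted object in a benchmark genome."""

    regions: list[PlantedRegion] = field(default_factory=list)
    loop_pairs: list[PlantedLoopPair] = field(default_factory=list)
    variants: list[Interval] = field(default_factory=list)
    variant_rates: dict[str, float] = field(default_factory=dict)

    def detectable_regions(self) -> list[PlantedRegion]:
        return [r for r in self.regions if r.detectable]

    def expected_pairs(self) -> list[PlantedLoopPair]:
        return [p for p in self.loop_pairs if p.expected]

    def regions_bed(self) -> list[Interval]:
        return [r.to_interval() for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            rows.append({
                "record_type": "region", "chrom": r.chrom, "start": r.start,
                "end": r.end, "label": r.kind, "n_units": r.n_units,
                "expected_triplets": r.expected_triplets,
                "expected_density": r.expected_density,
                "flag": r.detectable,
            })
        for p in self.loop_pairs:
            rows.append({
                "record_type": "loop_pair", "chrom": p.chrom, "start": p.a_start,
                "end": p.a_end, "b_start": p.b_start, "b_end": p.b_end,
                "seq_a": p.seq_a, "seq_b": p.seq_b, "length": p.length,
                "pct": p.pct, "flag": p.expected,
            })
        for v in self.variants:
            rows.append({
                "record_type": "variant", "chrom": v.chrom, "start": v.start,
                "end": v.end, "label": v.name,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t")
        truth = cls()
        for _, row in df.iterrows():
            if row["record_type"] == "region":
                truth.regions.append(PlantedRegion(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    str(row["label"]), int(row["n_units"]),
                    int(row["expected_triplets"]), float(row["expected_density"]),
                    bool(row["flag"]),
                ))
            elif row["record_type"] == "loop_pair":
                truth.loop_pairs.append(PlantedLoopPair(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    int(row["b_start"]), int(row["b_end"]),
                    str(row["seq_a"]), str(row["seq_b"]),
                    int(row["length"]), float(row["pct"]), bool(row["flag"]),
                ))
            elif row["record_type"] == "variant":
                truth.variants.append(Interval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]),
                    str(row["label"]),
                ))
        return truth


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions emulated by the benchmark generator.

    Positives span densities 85-120 triplets/kb at 1.5-3 kb, comfortably
    above the ~80.7/kb detection floor; sub-threshold decoys span 60-75/kb
    (at most 112 triplets per 1.5 kb window, below the 121 threshold).
    Kissing regions plant reverse-complement loop pairs of ~8 nt, matching
    the reported mean pair length.  Background GC 0.45 approximates bulk
    genomic sequence.
    """

    n_chromosomes: int = 2
    chrom_length: int = 125_000
    gc: float = 0.45
    n_positive: int = 8
    positive_lengths: tuple[int, ...] = (1500, 2000, 2500, 3000)
    positive_densities: tuple[float, ...] = (85, 90, 100, 110, 120, 95, 105, 115)
    n_subthreshold: int = 4
    subthreshold_length: int = 1500
    subthreshold_densities: tuple[float, ...] = (60, 65, 70, 75)
    n_kissing_regions: int = 3
    kissing_pairs_per_region: int = 4
    n_telomeric: int = 2
    telomeric_units: int = 25
    include_negative_loops: bool = True
    variant_rate_in: float = 0.02
    variant_rate_out: float = 0.002
    buffer: int = 1500


def random_background(
    length: int,
    gc_fraction: float,
    rng: np.random.Generator,
    scan_params: ScanParams = ScanParams(),
    max_rounds: int = 50,
) -> str:
    """I.i.d. background with P(G)=P(C)=gc/2, filtered for scanner hits.

    Any window whose G- or C-triplet count reaches the scan threshold is
    locally resampled (logged), so background alone never produces a locus.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = np.array([at, gc, gc, at])
    arr = rng.choice(4, size=length, p=probs)
    seq = "".join(_BASES[arr])
    for _ in range(max_rounds):
        offending: list[int] = []
        for base in "GC":
            counts = window_triplet_counts(seq, base, scan_params)
            if len(seq) < scan_params.window:
                if counts[0] >= scan_params.threshold:
                    offending.append(0)
            else:
                offending.extend(int(p) for p in np.nonzero(counts >= scan_params.threshold)[0])
        if not offending:
            return seq
        log.info("resampling %d background window(s) meeting the scan threshold",
                 len(offending))
        chars = list(seq)
        for p in sorted(set(offending)):
            w = min(scan_params.window, length - p)
            chars[p : p + w] = _BASES[rng.choice(4, size=w, p=probs)]
        seq = "".join(chars)
    raise RuntimeError("background resampling did not converge")


def build_lg4_region(
    units: Sequence[UnitSpec], triplet_mode: str = "floor3"
) -> tuple[str, int, list[dict]]:
    """Concatenate run+loop units into a repeat region.

    Returns (sequence, expected triplet count under ``triplet_mode``, loop
    records).  Loop records cover the gaps *between* consecutive runs (the
    final unit's loop trails the last run and is not a G4 loop); each has
    region-relative start/end, the sequence, and whether the loop length is
    admitted by the kissing module (5-39 nt).
    """
    if len(units) < 2:
        raise ValueError("a repeat region needs >= 2 units")
    weight = TRIPLET_MODES[triplet_mode]
    parts: list[str] = []
    loops: list[dict] = []
    pos = 0
    for i, unit in enumerate(units):
        parts.append(unit.run_base * unit.run_length)
        pos += unit.run_length
        parts.append(unit.loop_seq)
        if i < len(units) - 1:
            loops.append({
                "start": pos,
                "end": pos + len(unit.loop_seq),
                "seq": unit.loop_seq,
                "admitted": 5 <= len(unit.loop_seq) <= 39 and "N" not in unit.loop_seq,
            })
        pos += len(unit.loop_seq)
    triplets = sum(weight(u.run_length) for u in units)
    return "".join(parts), triplets, loops


def _ac_loop(n: int, rng: np.random.Generator) -> str:
    """Filler loop over {A, C} with no CCC run (cannot pair with A/C loops)."""
    while True:
        s = "".join(np.array(list("AC"))[rng.choice(2, size=n)])
        if "CCC" not in s:
            return s


def _pair_seq(n: int, rng: np.random.Generator) -> str:
    """A planted kissing-loop sequence: mixed alphabet, no GGG/CCC, not palindromic.

    First and last bases are restricted to A/T so that neither the sequence
    nor its reverse complement can fuse with the flanking G-runs when placed
    as a loop.
    """
    if n < 3:
        raise ValueError("pair sequences must be >= 3 nt")
    at = np.array(list("AT"))
    while True:
        s = (
            str(at[rng.choice(2)])
            + "".join(_BASES[rng.choice(4, size=n - 2)])
            + str(at[rng.choice(2)])
        )
        if "GGG" in s or "CCC" in s or s == revcomp(s):
            continue
        return s


def make_repeat_region(
    length: int,
    density: float,
    rng: np.random.Generator,
    n_pairs: int = 0,
    thresholds: KissThresholds = KissThresholds(),
    max_redraws: int = 100,
) -> dict:
    """Build one G-rich repeat region of the requested triplet density.

    ``n_pairs`` reverse-complement loop pairs are planted in randomly chosen
    interior loop slots; the region's loop panel is then verified to yield
    exactly the planted pairs (filler loops are A/C and inert), redrawing
    pair sequences on the rare collision.
    """
    n_units = round(density * length / 1000.0)
    if n_units < 2:
        raise ValueError("density/length too low for a repeat region")
    loop_total = length - 3 * n_units
    if loop_total < 0:
        raise ValueError("density too high for the requested length")
    base_loop, rem = divmod(loop_total, n_units)
    loop_lengths = [base_loop + 1 if i < rem else base_loop for i in range(n_units)]
    if min(loop_lengths[:-1], default=base_loop) < 5 and n_pairs > 0:
        raise ValueError("loops too short to host kissing pairs")

    # interior slots (between runs) whose loop length equals the modal length
    interior = list(range(n_units - 1))
    for attempt in range(max_redraws):
        loops = [_ac_loop(n, rng) for n in loop_lengths]
        planted: list[tuple[int, int, str]] = []  # (slot_a, slot_b, seq)
        if n_pairs:
            eligible = [i for i in interior if loop_lengths[i] == base_loop]
            if len(eligible) < 2 * n_pairs:
                eligible = interior
            slots = sorted(rng.choice(eligible, size=2 * n_pairs, replace=False))
            for k in range(n_pairs):
                a, b = int(slots[2 * k]), int(slots[2 * k + 1])
                n = min(loop_lengths[a], loop_lengths[b])
                s = _pair_seq(n, rng)
                loops[a] = s + _ac_loop(loop_lengths[a] - n, rng)
                loops[b] = revcomp(s) + _ac_loop(loop_lengths[b] - n, rng)
                planted.append((a, b, s))
        units = [UnitSpec("G", 3, lp) for lp in loops]
        seq, triplets, loop_recs = build_lg4_region(units)
        if _verify_planted_pairs(seq, loop_recs, planted, thresholds):
            return {
                "seq": seq,
                "n_units": n_units,
                "expected_triplets": triplets,
                "expected_density": triplets / (len(seq) / 1000.0),
                "loops": loop_recs,
                "pairs": [
                    {
                        "a_start": loop_recs[a]["start"], "a_end": loop_recs[a]["end"],
                        "b_start": loop_recs[b]["start"], "b_end": loop_recs[b]["end"],
                        "seq_a": loop_recs[a]["seq"], "seq_b": loop_recs[b]["seq"],
                        "length": len(s), "pct": 100.0,
                    }
                    for a, b, s in planted
                ],
            }
    raise RuntimeError("could not draw a collision-free kissing-pair panel")


def _verify_planted_pairs(seq, loop_recs, planted, thresholds) -> bool:
    """The region's extracted loop panel must yield exactly the planted pairs.

    Extraction is re-run on the assembled sequence so that loops fused or
    shifted by edge effects are caught, not just the intended loop strings.
    """
    from .kissing import extract_loops_from_seq

    extracted, unique_loops = extract_loops_from_seq(seq, "G")
    expected_gaps = {(rec["start"], rec["end"]) for rec in loop_recs if rec["admitted"]}
    if {(lp.start, lp.end) for lp in extracted} != expected_gaps:
        return False
    unique = [lp.seq for lp in unique_loops]
    pairs, self_hits = find_loop_pairs(unique, thresholds)
    if self_hits:
        return False
    found = {frozenset((p.seq_a, p.seq_b)) for p in pairs}
    want = {
        frozenset((loop_recs[a]["seq"], loop_recs[b]["seq"])) for a, b, _ in planted
    }
    if found != want:
        return False
    by_key = {frozenset((p.seq_a, p.seq_b)): p for p in pairs}
    for a, b, s in planted:
        hit = by_key[frozenset((loop_recs[a]["seq"], loop_recs[b]["seq"]))]
        if hit.length != len(s) or hit.matches != len(s):
            return False
    return True


def _negative_loop_region(rng: np.random.Generator) -> dict:
    """A short region exercising loop-size bounds and the 6-bp pair floor.

    Gaps of 4 and 40 nt (excluded from extraction), a 39 nt gap (included)
    and an exact 5-bp complement pair (admitted loops, but below the 6 bp
    alignment floor).
    """
    s5 = _pair_seq(5, rng)
    loops = [
        _ac_loop(7, rng),
        "ACTA",                      # 4 nt: below the admitted range
        _ac_loop(40, rng).replace("CCC", "CAC"),  # 40 nt: above the range
        _ac_loop(39, rng),           # 39 nt: upper admitted bound
        s5,                          # 5-bp complement pair: admitted ...
        revcomp(s5),                 # ... but no >= 6 bp alignment exists
        _ac_loop(8, rng),
    ]
    units = [UnitSpec("G", 3, lp) for lp in loops]
    seq, triplets, loop_recs = build_lg4_region(units)
    return {
        "seq": seq, "n_units": len(units), "expected_triplets": triplets,
        "expected_density": triplets / (len(seq) / 1000.0),
        "loops": loop_recs, "pairs": [
            {
                "a_start": loop_recs[4]["start"], "a_end": loop_recs[4]["end"],
                "b_start": loop_recs[5]["start"], "b_end": loop_recs[5]["end"],
                "seq_a": s5, "seq_b": revcomp(s5), "length": 5, "pct": 100.0,
            }
        ],
    }


_TRIPLET_RE = re.compile("GGG|CCC")


def scrub_triplets(seq: str) -> str:
    """Destroy every G/C triplet by mutating run middles (buffer scrubbing)."""
    while True:
        m = _TRIPLET_RE.search(seq)
        if m is None:
            return seq
        mid = "A" if seq[m.start()] == "G" else "T"
        seq = seq[: m.start() + 1] + mid + seq[m.start() + 2 :]


def generate_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
    seed: int = 0,
    scan_params: ScanParams = ScanParams(),
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Emit a benchmark genome plus its ground-truth ledger.

    Deterministic: identical config and seed give byte-identical output.
    The master seed expands into per-component child seeds (background per
    chromosome, placement, region construction) via numpy SeedSequence.
    """
    ss = np.random.SeedSequence(seed)
    ss_bg, ss_place, ss_regions = ss.spawn(3)
    rng_place = np.random.default_rng(ss_place)
    rng_regions = np.random.default_rng(ss_regions)

    items: list[dict] = []
    for i in range(config.n_positive):
        length = config.positive_lengths[i % len(config.positive_lengths)]
        density = config.positive_densities[i % len(config.positive_densities)]
        region = make_repeat_region(length, density, rng_regions)
        region.update(kind="positive", detectable=True)
        items.append(region)
    for i in range(config.n_kissing_regions):
        region = make_repeat_region(
            1500, 100.0, rng_regions, n_pairs=config.kissing_pairs_per_region
        )
        region.update(kind="kissing", detectable=True)
        items.append(region)
    for i in range(config.n_subthreshold):
        density = config.subthreshold_densities[i % len(config.subthreshold_densities)]
        region = make_repeat_region(config.subthreshold_length, density, rng_regions)
        region.update(kind="subthreshold", detectable=False)
        items.append(region)
    if config.include_negative_loops:
        region = _negative_loop_region(rng_regions)
        region.update(kind="negative_loops", detectable=False)
        items.append(region)
    for i in range(config.n_telomeric):
        seq = "TTAGGG" * config.telomeric_units
        items.append({
            "seq": seq, "kind": "telomeric", "detectable": False,
            "n_units": config.telomeric_units,
            "expected_triplets": config.telomeric_units,
            "expected_density": config.telomeric_units / (len(seq) / 1000.0),
            "loops": [], "pairs": [],
        })

    # round-robin assignment, then a shuffled sequential layout per chromosome
    per_chrom: list[list[dict]] = [[] for _ in range(config.n_chromosomes)]
    for i, item in enumerate(items):
        per_chrom[i % config.n_chromosomes].append(item)

    truth = SyntheticTruth()
    records: list[GenomeRecord] = []
    bg_seeds = ss_bg.spawn(config.n_chromosomes)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        rng_bg = np.random.default_rng(bg_seeds[ci])
        chars = list(random_background(config.chrom_length, config.gc, rng_bg, scan_params))
        order = rng_place.permutation(len(per_chrom[ci]))
        cursor = config.buffer + int(rng_place.integers(0, 2000))
        spans: list[tuple[int, int]] = []
        for oi in order:
            item = per_chrom[ci][int(oi)]
            seq = item["seq"]
            start, end = cursor, cursor + len(seq)
            if end + config.buffer > config.chrom_length:
                raise ValueError("planted items do not fit the chromosome; "
                                 "increase chrom_length or reduce item counts")
            chars[start:end] = list(seq)
            spans.append((start, end))
            truth.regions.append(PlantedRegion(
                chrom, start, end, item["kind"], item["n_units"],
                item["expected_triplets"],
                round(item["expected_density"], 6),  # exact TSV round-trip
                item["detectable"],
            ))
            for pair in item["pairs"]:
                truth.loop_pairs.append(PlantedLoopPair(
                    chrom,
                    start + pair["a_start"], start + pair["a_end"],
                    start + pair["b_start"], start + pair["b_end"],
                    pair["seq_a"], pair["seq_b"], pair["length"], pair["pct"],
                    expected=pair["length"] >= 6,
                ))
            cursor = end + config.buffer + 500 + int(rng_place.integers(0, 2500))
        # scrub G/C triplets from the buffers flanking every planted span
        for start, end in spans:
            lo, hi = max(0, start - config.buffer), start
            chars[lo:hi] = list(scrub_triplets("".join(chars[lo:hi])))
            lo, hi = end, min(config.chrom_length, end + config.buffer)
            chars[lo:hi] = list(scrub_triplets("".join(chars[lo:hi])))
        records.append(GenomeRecord(chrom, "".join(chars)))
    truth.regions.sort(key=lambda r: (r.chrom, r.start))
    truth.loop_pairs.sort(key=lambda p: (p.chrom, p.a_start))
    return records, truth


def plant_variants(
    chrom_sizes: Mapping[str, int],
    loci: Sequence[Interval],
    rate_in: float,
    rate_out: float,
    seed: int | np.random.Generator,
) -> tuple[list[Interval], dict[str, float]]:
    """Poisson point variants at ``rate_in`` per bp inside loci, ``rate_out`` outside.

    Returns the sorted variant list plus realized counts and footprint sizes
    for ratio checks.  Deterministic given the seed.
    """
    if rate_in < 0 or rate_out < 0:
        raise ValueError("rates must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, list[Interval]] = {}
    for iv in sorted(loci, key=lambda iv: (iv.chrom, iv.start)):
        by_chrom.setdefault(iv.chrom, []).append(iv)
    variants: list[Interval] = []
    n_in = n_out = bp_in = bp_out = 0

    def _emit(start: int, end: int, rate: float) -> int:
        nonlocal variants
        span = end - start
        if span <= 0 or rate == 0:
            return 0
        n = int(rng.poisson(rate * span))
        if n:
            pos = np.sort(rng.integers(start, end, size=n))
            for p in pos:
                variants.append(Interval(chrom, int(p), int(p) + 1,
                                         f"v{len(variants):06d}"))
        return n

    for chrom in chrom_sizes:
        cursor = 0
        for locus in by_chrom.get(chrom, []):
            n_out += _emit(cursor, locus.start, rate_out)
            bp_out += max(0, locus.start - cursor)
            n_in += _emit(locus.start, locus.end, rate_in)
            bp_in += locus.length
            cursor = max(cursor, locus.end)
        n_out += _emit(cursor, chrom_sizes[chrom], rate_out)
        bp_out += max(0, chrom_sizes[chrom] - cursor)

    variants.sort(key=lambda iv: (iv.chrom, iv.start))
    stats = {
        "rate_in": rate_in, "rate_out": rate_out,
        "n_in": float(n_in), "n_out": float(n_out),
        "bp_in": float(bp_in), "bp_out": float(bp_out),
    }
    return variants, stats
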