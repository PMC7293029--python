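"""Genomic association analytics for LG4 loci.

Size-matched random controls, gene-context classes, variant / CNV-breakpoint
density profiles, overlap and nearest-distance enrichments against matched
controls, chromosome-end distances and telomeric-repeat density, plus the
basic statistical tests used to compare them (Welch t, chi-square without
continuity correction, one-way ANOVA).

Distances are end-to-end gap lengths, zero when intervals overlap; overlap
means at least one shared base.  Loci on chromosomes absent from a feature
set are reported as missing (None) and excluded from means, never imputed.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core_io import GenomeRecord, Interval, read_bed, validate_intervals

log = logging.getLogger("lg4kit")

FEATURE_KINDS = (
    "gene", "predicted_gene", "enhancer", "variant_point", "breakpoint", "generic",
)


@dataclass
class FeatureSet:
    """A named, sorted collection of BED-like intervals."""

    name: str
    intervals: list[Interval]
    kind: str = "generic"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._trees: dict[str, IntervalTree] | None = None
        self._index: dict[str, tuple[list[int], list[int], list[int]]] | None = None

    @classmethod
    def from_bed(cls, path, name: str | None = None, kind: str = "generic") -> "FeatureSet":
        intervals = read_bed(path)
        return cls(name or str(path), intervals, kind)

    @property
    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for iv in self.intervals:
                self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, query: Interval) -> list[Interval]:
        return sorted(
            (hit.data for hit in self._tree(query.chrom).overlap(query.start, query.end)),
            key=lambda iv: (iv.start, iv.end),
        )

    def overlaps_any(self, query: Interval) -> bool:
        return bool(self._tree(query.chrom).overlap(query.start, query.end))

    def _chrom_index(self, chrom: str):
        """Per-chrom (starts, ends, prefix-max of ends) for nearest queries."""
        if self._index is None:
            self._index = {}
            by_chrom: dict[str, list[Interval]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for c, ivs in by_chrom.items():
                starts = [iv.start for iv in ivs]
                ends = [iv.end for iv in ivs]
                prefix_max = list(np.maximum.accumulate(ends))
                self._index[c] = (starts, ends, prefix_max)
        return self._index.get(chrom)

    def nearest_distance(self, query: Interval) -> int | None:
        """Gap to the nearest feature on the same chromosome (0 if overlap)."""
        idx = self._chrom_index(query.chrom)
        if idx is None:
            return None
        starts, _ends, prefix_max = idx
        if self.overlaps_any(query):
            return 0
        best: int | None = None
        # nearest feature starting at/after the query end
        k = bisect.bisect_left(starts, query.end)
        if k < len(starts):
            best = starts[k] - query.end
        # nearest feature ending at/before the query start
        k = bisect.bisect_right(starts, query.start) - 1
        if k >= 0:
            left = query.start - prefix_max[k]
            if left >= 0 and (best is None or left < best):
                best = left
        return best


@dataclass(frozen=True)
class ProfileBin:
    label: str
    start: int
    end: int
    span: int
    count: int
    density: float | None


@dataclass(frozen=True)
class DensityProfile:
    locus_id: str
    unit: int
    bins: tuple[ProfileBin, ...]

    @property
    def total_count(self) -> int:
        return sum(b.count for b in self.bins)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    control_values: tuple[float, ...]
    fold: float | None
    test: str
    statistic: float | None
    p_value: float | None

    @property
    def n_controls(self) -> int:
        return len(self.control_values)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float | None
    p_value: float | None
    note: str = ""


# ---------------------------------------------------------------------------
# size-matched random controls


def sample_control_loci(
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
    seed: int | np.random.Generator,
    exclusions: FeatureSet | None = None,
    n_sets: int = 1,
    genome: Mapping[str, GenomeRecord] | None = None,
    max_tries: int = 1000,
) -> list[list[Interval]]:
    """Draw ``n_sets`` random interval sets preserving the length multiset.

    Placement is uniform over valid start positions (chromosomes weighted
    by the number of positions that fit the length); rejection resampling
    avoids the exclusion set and, when a genome is supplied, runs of N.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sets: list[list[Interval]] = []
    for set_idx in range(n_sets):
        drawn: list[Interval] = []
        for li, length in enumerate(lengths):
            weights = np.array(
                [max(0, chrom_sizes[c] - length + 1) for c in chroms], dtype=float
            )
            if weights.sum() == 0:
                raise ValueError(f"no chromosome can hold a control of length {length}")
            probs = weights / weights.sum()
            placed = False
            for _ in range(max_tries):
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
                candidate = Interval(chrom, start, start + length,
                                     f"ctrl_{set_idx}_{li}")
                if exclusions is not None and exclusions.overlaps_any(candidate):
                    continue
                if genome is not None and "N" in genome[chrom].seq[start : start + length]:
                    continue
                drawn.append(candidate)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place control of length {length} after {max_tries} tries"
                )
        sets.append(sorted(drawn, key=lambda iv: (iv.chrom, iv.start)))
    return sets


# ---------------------------------------------------------------------------
# gene context and transcription strand


def classify_gene_context(
    loci: Sequence[Interval],
    genes: FeatureSet,
    predicted_genes: FeatureSet | None = None,
    margin: int = 5000,
) -> list[str]:
    """Per-locus class: known_gene > predicted_gene > unassociated.

    A locus belongs to a class when it overlaps, or lies within ``margin``
    bp of, a feature of that set (end-to-end distance, 0 when overlapping).
    """
    out = []
    for locus in loci:
        d_known = genes.nearest_distance(locus)
        if d_known is not None and d_known <= margin:
            out.append("known_gene")
            continue
        d_pred = (
            predicted_genes.nearest_distance(locus) if predicted_genes is not None else None
        )
        if d_pred is not None and d_pred <= margin:
            out.append("predicted_gene")
        else:
            out.append("unassociated")
    return out


def strand_vs_transcription(rich_strand: str, gene_strand: str | None) -> str:
    """mRNA G/C richness implied by locus rich strand vs gene orientation.

    The mRNA copies the non-template (sense) strand: when the G-rich strand
    is the sense strand the mRNA is G-rich, when it is the template the
    mRNA is C-rich.  ``both`` loci or absent genes are not applicable.
    """
    if rich_strand not in ("+", "-") or gene_strand not in ("+", "-"):
        return "not_applicable"
    return "G_rich_mRNA" if rich_strand == gene_strand else "C_rich_mRNA"


# ---------------------------------------------------------------------------
# variant density profiles


def _point_positions(variants: FeatureSet, chrom: str) -> np.ndarray:
    return np.array(
        sorted(iv.start for iv in variants.intervals if iv.chrom == chrom), dtype=np.int64
    )


def _count_in(positions: np.ndarray, start: int, end: int) -> int:
    return int(
        np.searchsorted(positions, end, side="left")
        - np.searchsorted(positions, start, side="left")
    )


def variant_density_profile(
    locus: Interval,
    variants: FeatureSet,
    chrom_length: int,
    mode: str = "snp",
    transcript: Interval | None = None,
) -> DensityProfile:
    """Point-feature density in and around a locus.

    ``snp`` mode: events per 100 bp for the locus and 100-bp bins covering
    1-2000 bp on each side.  ``cnv`` mode: breakpoints per kb for the
    locus, 1-kb bins out to 3 kb on each side and, when a transcript is
    supplied, the rest of the transcript.  Bins are clipped at chromosome
    ends and their effective spans used as denominators; bin counts always
    sum to the features overlapping the profiled span.
    """
    if mode == "snp":
        unit, bin_size, n_bins = 100, 100, 20
    elif mode == "cnv":
        unit, bin_size, n_bins = 1000, 1000, 3
    else:
        raise ValueError("mode must be 'snp' or 'cnv'")
    positions = _point_positions(variants, locus.chrom)

    raw: list[tuple[str, int, int]] = []
    for k in range(n_bins, 0, -1):  # upstream, far to near
        raw.append((f"up_{k * bin_size}", locus.start - k * bin_size,
                    locus.start - (k - 1) * bin_size))
    raw.append(("locus", locus.start, locus.end))
    for k in range(1, n_bins + 1):  # downstream, near to far
        raw.append((f"down_{k * bin_size}", locus.end + (k - 1) * bin_size,
                    locus.end + k * bin_size))
    if mode == "cnv" and transcript is not None:
        if transcript.chrom != locus.chrom:
            raise ValueError("transcript on a different chromosome")
        flank_lo = max(0, locus.start - n_bins * bin_size)
        flank_hi = min(chrom_length, locus.end + n_bins * bin_size)
        if transcript.start < flank_lo:
            raw.append(("rest_of_transcript_5p", transcript.start, flank_lo))
        if transcript.end > flank_hi:
            raw.append(("rest_of_transcript_3p", flank_hi, transcript.end))

    bins: list[ProfileBin] = []
    for label, s, e in raw:
        cs, ce = max(0, s), min(chrom_length, e)
        span = max(0, ce - cs)
        count = _count_in(positions, cs, ce) if span else 0
        density = count / (span / unit) if span else None
        bins.append(ProfileBin(label, cs, ce if span else cs, span, count, density))

    profile = DensityProfile(locus.name, unit, tuple(bins))
    spans = [(b.start, b.end) for b in profile.bins if b.span]
    total = sum(_count_in(positions, s, e) for s, e in spans)
    assert profile.total_count == total, "profile bin counts must conserve overlaps"
    return profile


# ---------------------------------------------------------------------------
# enrichment vs controls


def overlap_enrichment(
    loci: Sequence[Interval],
    features: FeatureSet,
    control_sets: Sequence[Sequence[Interval]],
) -> EnrichmentResult:
    """Loci with >= 1 bp feature overlap, vs size-matched control sets."""
    observed = sum(1 for locus in loci if features.overlaps_any(locus))
    controls = tuple(
        float(sum(1 for iv in control_set if features.overlaps_any(iv)))
        for control_set in control_sets
    )
    mean_ctrl = float(np.mean(controls)) if controls else 0.0
    fold = observed / mean_ctrl if mean_ctrl > 0 else None
    statistic = p_value = None
    if len(controls) >= 2 and np.std(controls) > 0:
        t = stats.ttest_1samp(controls, observed)
        statistic, p_value = float(t.statistic), float(t.pvalue)
    return EnrichmentResult(
        observed=float(observed),
        control_values=controls,
        fold=fold,
        test="one-sample t of control counts vs observed (two-tailed)",
        statistic=statistic,
        p_value=p_value,
    )


def nearest_feature_distance(
    loci: Sequence[Interval], features: FeatureSet
) -> tuple[list[int | None], float]:
    """Per-locus nearest-feature gap plus the cohort mean over defined loci."""
    if not features.intervals:
        raise ValueError("empty feature set")
    distances = [features.nearest_distance(locus) for locus in loci]
    defined = [d for d in distances if d is not None]
    if not defined:
        raise ValueError("no locus shares a chromosome with the feature set")
    return distances, float(np.mean(defined))


def distance_enrichment(
    loci: Sequence[Interval],
    features: FeatureSet,
    control_sets: Sequence[Sequence[Interval]],
) -> dict[str, float]:
    """Mean nearest distances and the control/locus ratio ("times closer")."""
    _, loci_mean = nearest_feature_distance(loci, features)
    control_means = [nearest_feature_distance(cs, features)[1] for cs in control_sets]
    mean_ctrl = float(np.mean(control_means))
    return {
        "loci_mean_bp": loci_mean,
        "control_mean_bp": mean_ctrl,
        "times_closer": mean_ctrl / loci_mean if loci_mean > 0 else float("inf"),
    }


def chromosome_end_distance(
    loci: Sequence[Interval],
    chrom_sizes: Mapping[str, int],
    thresholds: Sequence[int] = (2_000_000, 6_000_000),
) -> tuple[list[int], dict[int, float]]:
    """Distance to the nearer chromosome end, and fractions within thresholds."""
    validate_intervals(loci, chrom_sizes)
    distances = [
        min(locus.start, chrom_sizes[locus.chrom] - locus.end) for locus in loci
    ]
    fractions = {
        t: (sum(1 for d in distances if d < t) / len(distances)) if distances else 0.0
        for t in thresholds
    }
    return distances, fractions


def telomeric_repeat_density(
    locus: Interval,
    records: Mapping[str, GenomeRecord],
    motif: str = "TTAGGG",
) -> float:
    """Exact (non-overlapping) motif occurrences per 1000 bp of locus."""
    seq = records[locus.chrom].seq[locus.start : locus.end]
    if not seq:
        raise ValueError("zero-length locus")
    return seq.count(motif) / (len(seq) / 1000.0)


# ---------------------------------------------------------------------------
# basic statistical tests


def welch_t(x: Sequence[float], y: Sequence[float], pooled: bool = False) -> TestResult:
    """Unpaired two-tailed t-test; Welch by default, Student with pooled=True."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        return TestResult("t", None, None, note="degenerate variance")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return TestResult("t", float(res.statistic), float(res.pvalue))


def chi_square(table: Sequence[Sequence[float]]) -> TestResult:
    """Chi-square on a contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("chi-square needs nonnegative counts")
    try:
        res = stats.chi2_contingency(arr, correction=False)
    except ValueError:
        return TestResult("chi-square", None, None, note="degenerate table")
    return TestResult("chi-square", float(res[0]), float(res[1]))


def one_way_anova(*groups: Sequence[float]) -> TestResult:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("ANOVA needs >= 2 groups of >= 2 observations")
    if all(np.var(g) == 0 for g in arrays):
        return TestResult("anova", None, None, note="degenerate variance")
    res = stats.f_oneway(*arrays)
    return TestResult("anova", float(res.statistic), float(res.pvalue))
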