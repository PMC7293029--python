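import numpy as np
import pytest
from scipy import stats as sps

from oracles import brute_nearest_distance

from lg4kit.association import (
    FeatureSet,
    chi_square,
    chromosome_end_distance,
    classify_gene_context,
    distance_enrichment,
    nearest_feature_distance,
    one_way_anova,
    overlap_enrichment,
    sample_control_loci,
    strand_vs_transcription,
    telomeric_repeat_density,
    variant_density_profile,
    welch_t,
)
from lg4kit.core_io import GenomeRecord, Interval
from lg4kit.synthetic import plant_variants


SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


class TestControlSampler:
    def test_length_multiset_preserved(self):
        lengths = [500, 1843, 4973]
        (controls,) = sample_control_loci(SIZES, lengths, seed=1)
        assert sorted(iv.length for iv in controls) == sorted(lengths)

    def test_determinism(self):
        a = sample_control_loci(SIZES, [100] * 20, seed=5, n_sets=3)
        b = sample_control_loci(SIZES, [100] * 20, seed=5, n_sets=3)
        assert a == b

    def test_exclusions_respected(self):
        exclusions = FeatureSet(
            "excl", [Interval("chr1", 0, 900_000), Interval("chr2", 0, 900_000)]
        )
        (controls,) = sample_control_loci(SIZES, [1000] * 30, seed=2,
                                          exclusions=exclusions)
        for iv in controls:
            assert not exclusions.overlaps_any(iv)

    def test_n_runs_avoided_with_genome(self):
        genome = {
            "chrN": GenomeRecord("chrN", "A" * 5000 + "N" * 5000),
        }
        (controls,) = sample_control_loci({"chrN": 10_000}, [500] * 10, seed=3,
                                          genome=genome)
        for iv in controls:
            assert "N" not in genome["chrN"].seq[iv.start : iv.end]

    def test_unsatisfiable_placement_errors(self):
        with pytest.raises((ValueError, RuntimeError)):
            sample_control_loci({"c": 100}, [500], seed=0)

    def test_uniform_across_equal_chromosomes(self):
        """Chi-square goodness of fit over 1000 draws is not rejected."""
        sizes = {f"c{i}": 100_000 for i in range(4)}
        sets = sample_control_loci(sizes, [100] * 1000, seed=11)
        counts = [sum(1 for iv in sets[0] if iv.chrom == c) for c in sizes]
        res = sps.chisquare(counts)
        assert res.pvalue > 0.01


class TestGeneContext:
    GENES = FeatureSet("genes", [Interval("chr1", 100_000, 110_000, "g1", ".", "+")],
                       kind="gene")
    PRED = FeatureSet("pred", [Interval("chr1", 500_000, 505_000)], kind="predicted_gene")

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (105_000, 106_000, "known_gene"),     # overlapping
            (115_000 - 1, 116_000, "known_gene"),  # 4,999 bp gap
            (115_002, 116_000, "unassociated"),    # 5,001 bp gap
            (505_100, 505_200, "predicted_gene"),
            (700_000, 701_000, "unassociated"),
        ],
    )
    def test_classes_and_margins(self, start, end, expected):
        (cls,) = classify_gene_context(
            [Interval("chr1", start, end)], self.GENES, self.PRED
        )
        assert cls == expected

    def test_known_precedes_predicted(self):
        genes = FeatureSet("genes", [Interval("chr1", 0, 1000)])
        pred = FeatureSet("pred", [Interval("chr1", 0, 1000)])
        (cls,) = classify_gene_context([Interval("chr1", 500, 600)], genes, pred)
        assert cls == "known_gene"

    def test_no_features(self):
        empty = FeatureSet("genes", [])
        (cls,) = classify_gene_context([Interval("chr1", 0, 100)], empty)
        assert cls == "unassociated"


class TestStrandVsTranscription:
    @pytest.mark.parametrize(
        "rich,gene,expected",
        [
            ("+", "+", "G_rich_mRNA"),
            ("+", "-", "C_rich_mRNA"),
            ("-", "+", "C_rich_mRNA"),
            ("-", "-", "G_rich_mRNA"),
            ("both", "+", "not_applicable"),
            ("+", None, "not_applicable"),
        ],
    )
    def test_convention(self, rich, gene, expected):
        assert strand_vs_transcription(rich, gene) == expected


class TestVariantProfile:
    def test_uniform_locus_density(self):
        variants = FeatureSet(
            "v", [Interval("chr1", 10_000 + i * 100, 10_001 + i * 100) for i in range(10)],
            kind="variant_point",
        )
        locus = Interval("chr1", 10_000, 11_000, "L1")
        profile = variant_density_profile(locus, variants, 1_000_000, mode="snp")
        locus_bin = next(b for b in profile.bins if b.label == "locus")
        assert locus_bin.count == 10
        assert locus_bin.density == pytest.approx(1.0)  # per 100 bp

    def test_zero_variants(self):
        profile = variant_density_profile(
            Interval("chr1", 0, 1000, "L"), FeatureSet("v", []), 10_000
        )
        assert profile.total_count == 0
        assert all(b.count == 0 for b in profile.bins)

    def test_bins_clip_at_chromosome_start(self):
        locus = Interval("chr1", 500, 1500, "L")
        profile = variant_density_profile(locus, FeatureSet("v", []), 1_000_000)
        spans = {b.label: b.span for b in profile.bins}
        assert spans["up_2000"] == 0  # fully clipped
        assert spans["up_600"] == 0   # ends exactly at position 0
        assert spans["up_500"] == 100  # covers [0, 100)

    def test_cnv_mode_bins(self):
        locus = Interval("chr1", 50_000, 52_000, "L")
        transcript = Interval("chr1", 40_000, 70_000, "tx")
        profile = variant_density_profile(
            locus, FeatureSet("v", []), 1_000_000, mode="cnv", transcript=transcript
        )
        labels = [b.label for b in profile.bins]
        assert labels.count("locus") == 1
        assert "up_3000" in labels and "down_3000" in labels
        assert "rest_of_transcript_5p" in labels and "rest_of_transcript_3p" in labels

    def test_planted_hotspot_ratio(self):
        """In/out density ratio of planted variants matches the planted
        10x rate within Poisson error (aggregated over seeds)."""
        sizes = {"chr1": 200_000}
        loci = [Interval("chr1", 50_000 + i * 30_000, 52_000 + i * 30_000, f"L{i}")
                for i in range(5)]
        n_in = n_out = bp_in = bp_out = 0
        for seed in range(10):
            _, truth = plant_variants(sizes, loci, 0.02, 0.002, seed=seed)
            n_in += truth["n_in"]; n_out += truth["n_out"]
            bp_in += truth["bp_in"]; bp_out += truth["bp_out"]
        ratio = (n_in / bp_in) / (n_out / bp_out)
        se_log = np.sqrt(1 / n_in + 1 / n_out)
        assert abs(np.log(ratio / 10.0)) < 4 * se_log


class TestOverlapEnrichment:
    def test_identical_loci_all_overlap(self):
        loci = [Interval("chr1", i * 10_000, i * 10_000 + 500) for i in range(10)]
        features = FeatureSet("f", list(loci))
        controls = sample_control_loci(SIZES, [500] * 10, seed=9, n_sets=3)
        enr = overlap_enrichment(loci, features, controls)
        assert enr.observed == len(loci)

    def test_empty_features(self):
        loci = [Interval("chr1", 0, 100)]
        enr = overlap_enrichment(loci, FeatureSet("f", []), [[]])
        assert enr.observed == 0
        assert enr.fold is None

    def test_planted_enrichment_fold(self):
        """Loci placed inside planted features are enriched vs uniform controls
        by roughly the constructed factor."""
        rng = np.random.default_rng(21)
        features = FeatureSet(
            "f", [Interval("chr1", int(s), int(s) + 2000)
                  for s in rng.choice(900_000, size=50, replace=False)]
        )
        inside = [Interval(f.chrom, f.start + 100, f.start + 300)
                  for f in features.intervals[:30]]
        controls = sample_control_loci(SIZES, [200] * 30, seed=22, n_sets=5)
        enr = overlap_enrichment(inside, features, controls)
        assert enr.observed == 30
        expected_ctrl = 30 * (50 * 2000 * 2) / sum(SIZES.values())  # ~ uniform rate
        assert np.mean(enr.control_values) < expected_ctrl * 3
        assert enr.fold > 5

    def test_null_fold_near_one(self):
        """When loci are drawn exactly like the controls, fold ~ 1."""
        all_sets = sample_control_loci(SIZES, [1000] * 40, seed=33, n_sets=21)
        loci, controls = all_sets[0], all_sets[1:]
        rng = np.random.default_rng(34)
        features = FeatureSet(
            "f", [Interval("chr1", int(s), int(s) + 5000)
                  for s in rng.choice(990_000, size=60, replace=False)]
        )
        enr = overlap_enrichment(loci, features, controls)
        ctrl = np.array(enr.control_values)
        # count noise floor: a single set's count is ~Poisson(mean)
        spread = max(ctrl.std(ddof=1), np.sqrt(ctrl.mean()))
        assert abs(enr.observed - ctrl.mean()) <= 3 * spread


class TestDistances:
    def test_point_feature_distance(self):
        features = FeatureSet("f", [Interval("chr1", 500, 501)])
        distances, mean = nearest_feature_distance(
            [Interval("chr1", 100, 200)], features
        )
        assert distances == [300] and mean == 300

    def test_overlap_distance_zero(self):
        features = FeatureSet("f", [Interval("chr1", 150, 160)])
        distances, _ = nearest_feature_distance([Interval("chr1", 100, 200)], features)
        assert distances == [0]

    def test_chromosome_without_features_is_na(self):
        features = FeatureSet("f", [Interval("chr1", 0, 10)])
        distances, mean = nearest_feature_distance(
            [Interval("chr1", 100, 200), Interval("chr2", 100, 200)], features
        )
        assert distances == [90, None]
        assert mean == 90

    def test_no_shared_chromosome_errors(self):
        features = FeatureSet("f", [Interval("chrX", 0, 10)])
        with pytest.raises(ValueError):
            nearest_feature_distance([Interval("chr1", 0, 10)], features)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        features = [
            Interval(f"c{int(rng.integers(3))}", int(s), int(s) + int(rng.integers(1, 500)))
            for s in rng.integers(0, 100_000, size=200)
        ]
        fs = FeatureSet("f", features)
        for _ in range(200):
            start = int(rng.integers(0, 100_000))
            q = Interval(f"c{int(rng.integers(3))}", start,
                         start + int(rng.integers(1, 1000)))
            assert fs.nearest_distance(q) == brute_nearest_distance(q, features)

    def test_planted_distance_enrichment(self):
        breaks = FeatureSet(
            "bp", [Interval("chr1", p, p + 1, "b") for p in range(10_000, 900_000, 50_000)]
        )
        loci = [Interval("chr1", p + 10, p + 110) for p in range(10_000, 400_000, 50_000)]
        controls = sample_control_loci(SIZES, [100] * len(loci), seed=8, n_sets=5)
        result = distance_enrichment(loci, breaks, controls)
        assert result["loci_mean_bp"] < 20
        assert result["times_closer"] > 10


class TestChromosomeEnds:
    def test_distance_definition(self):
        sizes = {"c": 10_000_000}
        distances, _ = chromosome_end_distance(
            [Interval("c", 1_000_000, 1_001_000), Interval("c", 0, 1000)], sizes
        )
        assert distances == [1_000_000, 0]

    def test_fraction_within_thresholds(self):
        sizes = {"c": 20_000_000}
        loci = [Interval("c", 100_000, 101_000), Interval("c", 10_000_000, 10_001_000)]
        _, fractions = chromosome_end_distance(loci, sizes)
        assert fractions[2_000_000] == 0.5
        assert fractions[6_000_000] == 0.5

    def test_locus_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            chromosome_end_distance([Interval("c", 0, 2000)], {"c": 1000})


class TestTelomericDensity:
    def test_planted_repeats(self):
        seq = ("TTAGGG" * 10) + "A" * 940
        records = {"c": GenomeRecord("c", seq)}
        assert telomeric_repeat_density(Interval("c", 0, 1000), records) == pytest.approx(10.0)

    def test_motif_free(self):
        records = {"c": GenomeRecord("c", "A" * 1000)}
        assert telomeric_repeat_density(Interval("c", 0, 1000), records) == 0.0

    def test_translation_invariance(self):
        core = ("TTAGGG" * 5) + "C" * 470
        for pad in (0, 2000):
            seq = "A" * pad + core + "A" * (3000 - pad)
            records = {"c": GenomeRecord("c", seq)}
            d = telomeric_repeat_density(Interval("c", pad, pad + 500), records)
            assert d == pytest.approx(10.0)


class TestBasicTests:
    def test_chi_square_balanced_table(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)

    def test_chi_square_closed_form(self):
        # sum (O-E)^2/E with all E = 15 gives 20/3
        res = chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3)

    def test_t_of_sample_against_itself(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        res = welch_t([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value is None
        assert "degenerate" in res.note

    def test_welch_vs_pooled_differ_on_unequal_variance(self):
        x = [1.0, 2.0, 1.5, 2.5, 1.8]
        y = [10.0, 30.0, 5.0, 45.0]
        assert welch_t(x, y).statistic != welch_t(x, y, pooled=True).statistic

    def test_anova_detects_shifted_group(self):
        res = one_way_anova([1, 2, 1, 2], [1.5, 2.5, 1.2], [10, 11, 12])
        assert res.p_value < 0.01

    def test_profile_conservation_invariant(self):
        """Bin counts always sum to the features overlapping the profiled span."""
        rng = np.random.default_rng(13)
        variants = FeatureSet(
            "v", [Interval("chr1", int(p), int(p) + 1)
                  for p in rng.integers(0, 50_000, size=400)],
            kind="variant_point",
        )
        for _ in range(20):
            start = int(rng.integers(0, 40_000))
            locus = Interval("chr1", start, start + int(rng.integers(200, 3000)), "L")
            profile = variant_density_profile(locus, variants, 50_000, mode="snp")
            lo = min(b.start for b in profile.bins if b.span)
            hi = max(b.end for b in profile.bins if b.span)
            inside = sum(1 for iv in variants.intervals if lo <= iv.start < hi)
            assert profile.total_count == inside
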