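"""Overlap enrichment of loci against size-matched random controls.

Places test loci inside planted "enhancer" features, draws five control
sets preserving the length multiset, and reports the observed overlap
count, the control mean, the fold enrichment and a two-tailed one-sample
t-test of the control counts against the observation.
"""

import numpy as np

from lg4kit import FeatureSet, Interval, overlap_enrichment, sample_control_loci

SIZES = {"chr1": 2_000_000, "chr2": 2_000_000}
rng = np.random.default_rng(30)

starts = rng.choice(1_900_000, size=80, replace=False)
features = FeatureSet(
    "enhancers", [Interval("chr1", int(s), int(s) + 2500) for s in starts]
)
loci = [Interval(f.chrom, f.start + 200, f.start + 700)
        for f in features.intervals[:40]]

controls = sample_control_loci(SIZES, [iv.length for iv in loci], seed=31, n_sets=5)
enr = overlap_enrichment(loci, features, controls)

print(f"loci overlapping a feature : {enr.observed:.0f}/{len(loci)}")
print(f"mean control overlaps (n={enr.n_controls}): "
      f"{np.mean(enr.control_values):.1f}")
print(f"fold enrichment            : {enr.fold:.1f}x")
print(f"{enr.test}: t={enr.statistic:.2f}, p={enr.p_value:.2g}")

# Loci constructed inside features overlap ~40/40; uniform controls overlap
# only at the features' genomic footprint rate, giving a large fold.
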