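"""Scan a synthetic genome and compare reported loci with the planted truth.

Builds a two-chromosome benchmark genome (250 kb) containing G-triplet-dense
repeat regions at 60-120 triplets/kb, scans it with the default 1.5 kb /
121-triplet sliding window, and prints each reported locus next to the
planted region it recovers.  Regions planted below ~80.7 triplets/kb are
decoys and must not appear.
"""

from lg4kit import generate_benchmark, scan_genome

records, truth = generate_benchmark(seed=11)
loci = scan_genome(records)
planted = truth.detectable_regions()

print(f"planted detectable regions: {len(planted)}   reported loci: {len(loci)}")
print(f"{'locus':>9} {'chrom':>6} {'span':>15} {'strand':>6} "
      f"{'triplets':>8} {'per_kb':>7}  planted")
for locus in loci:
    match = next(
        (r for r in planted
         if r.chrom == locus.chrom and abs(r.start - locus.start) <= 60),
        None,
    )
    label = f"{match.kind}@{match.start}" if match else "NONE"
    print(f"{locus.name:>9} {locus.chrom:>6} "
          f"{f'{locus.start}-{locus.end}':>15} {locus.rich_strand:>6} "
          f"{locus.triplet_count:>8} {locus.density:>7.1f}  {label}")

# Every reported density sits above the ~80.7/kb post-refinement floor, and
# each locus lines up with one planted region (decoys stay unreported).
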