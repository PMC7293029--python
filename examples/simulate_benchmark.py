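"""Generate a benchmark genome with its ground-truth ledger on disk.

Writes FASTA, chrom.sizes, truth BED/TSV and a planted-variant BED under
scratch/ (the same artifacts the `lg4kit simulate` subcommand emits), then
reads the ledger back and prints what was planted.
"""

from pathlib import Path

import numpy as np

from lg4kit import (
    SyntheticTruth,
    generate_benchmark,
    plant_variants,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)

out = Path("scratch")
out.mkdir(exist_ok=True)
records, truth = generate_benchmark(seed=2)
sizes = {r.chrom: r.length for r in records}
variants, vstats = plant_variants(
    sizes, [r.to_interval() for r in truth.detectable_regions()],
    rate_in=0.02, rate_out=0.002, seed=2,
)
truth.variants = variants

write_fasta(records, out / "bench.fa")
write_chrom_sizes(sizes, out / "bench.sizes")
write_bed(truth.regions_bed(), out / "bench.truth.bed")
write_bed(variants, out / "bench.variants.bed")
truth.to_tsv(out / "bench.truth.tsv")

ledger = SyntheticTruth.from_tsv(out / "bench.truth.tsv")
kinds = sorted({r.kind for r in ledger.regions})
print(f"genome: {len(records)} chromosomes, {sum(sizes.values()):,} bp")
for kind in kinds:
    n = sum(1 for r in ledger.regions if r.kind == kind)
    print(f"  planted {kind:>15}: {n}")
print(f"  planted kissing pairs : {len(ledger.expected_pairs())}")
ratio = (vstats['n_in'] / vstats['bp_in']) / (vstats['n_out'] / vstats['bp_out'])
print(f"  variant density ratio : {ratio:.1f}x (planted 10x)")

# The ledger round-trips through TSV, so every downstream module can be
# checked against exactly what was planted.
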