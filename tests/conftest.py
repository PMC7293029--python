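import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from lg4kit import GenomeRecord, generate_benchmark, scan_genome
from lg4kit.core_io import records_by_chrom


def make_window_record(n_triplets: int, window: int = 1500, chrom: str = "c1") -> GenomeRecord:
    """One window-sized sequence with exactly n isolated GGG runs."""
    body = ("GGG" + "TT") * n_triplets
    if len(body) > window:
        raise ValueError("too many triplets for the window")
    return GenomeRecord(chrom, body + "A" * (window - len(body)))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


@pytest.fixture(scope="session")
def benchmark():
    """One default benchmark genome, its truth ledger and its scan, shared."""
    records, truth = generate_benchmark(seed=7)
    loci = scan_genome(records)
    return {
        "records": records,
        "by_chrom": records_by_chrom(records),
        "truth": truth,
        "loci": loci,
        "sizes": {r.chrom: r.length for r in records},
    }
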