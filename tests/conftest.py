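import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from epatarget import (
    GeneAnnotation,
    GenomicInterval,
    SyntheticConfig,
    Transcript,
    generate_dataset,
)


def make_annotation(genes, chrom_len=1_000_000, chrom="chr1"):
    """genes: iterable of (id, tss, strand); gene bodies are 2 kb."""
    ts = []
    for gid, tss, strand in genes:
        if strand == "+":
            iv = GenomicInterval(chrom, tss, min(tss + 2000, chrom_len), "+")
        else:
            iv = GenomicInterval(chrom, max(0, tss - 1999), tss + 1, "-")
        ts.append(Transcript(gid, gid.upper(), iv))
    return GeneAnnotation(ts, {chrom: chrom_len})


@pytest.fixture(scope="session")
def dataset():
    """The default genome-scale synthetic bundle, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
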