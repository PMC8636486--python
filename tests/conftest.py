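import numpy as np
import pandas as pd
import pytest

from zga.genome import FragmentSet, GenomeBuild
from zga.synthetic import SimConfig, simulate_truth_genome


@pytest.fixture(scope="session")
def toy_build():
    return GenomeBuild((("chr1", 100_000), ("chr2", 50_000), ("spike", 5_000)),
                       frozenset({"spike"}))


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    """Truth genome at the default study conditions (shared, read-only)."""
    return simulate_truth_genome(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down genome for fast end-to-end checks."""
    return SimConfig(
        seed=7,
        n_genes=80,
        chrom_length=400_000,
        edge_margin=110_000,
        groseq_frags_per_gene=400.0,
        polii_frags_per_gene=2000.0,
        prot_n=300,
    )


def make_fragments(build, rows):
    """rows: (chrom, start, end, strand[, assay, condition, replicate])"""
    full = [(r + ("assay", "Ctrl", "1"))[:7] for r in rows]
    frame = pd.DataFrame(
        full, columns=["chrom", "start", "end", "strand", "assay", "condition", "replicate"]
    )
    return FragmentSet(frame, build)
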