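import numpy as np
import pandas as pd
import pytest

from rd3d.genome import Genome, GenomicInterval
from rd3d.hic import SignificantInteractionSet
from rd3d.io import CONTACT_COLUMNS


@pytest.fixture
def small_genome():
    return Genome({"chr1": 2_000_000, "chr2": 1_000_000})


def make_contacts(rows):
    """rows: (rna_id, biotype, gene_chrom, gene_start, gene_end, dna_chrom, dna_pos)."""
    return pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4], ".", r[5], r[6]) for r in rows],
        columns=CONTACT_COLUMNS,
    )


def make_peaks(pairs, bin_size=10_000, fdr=0.05, chrom="chr1"):
    """pairs: iterable of (bin_a, bin_b) or (chrom_a, bin_a, chrom_b, bin_b)."""
    rows = []
    for p in pairs:
        if len(p) == 2:
            rows.append((chrom, p[0], chrom, p[1], 1e-6, 1e-4))
        else:
            rows.append((p[0], p[1], p[2], p[3], 1e-6, 1e-4))
    table = pd.DataFrame(rows, columns=["chrom_a", "bin_a", "chrom_b", "bin_b", "p", "q"])
    return SignificantInteractionSet(table, fdr=fdr, bin_size=bin_size)


@pytest.fixture
def contacts_factory():
    return make_contacts


@pytest.fixture
def peaks_factory():
    return make_peaks
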