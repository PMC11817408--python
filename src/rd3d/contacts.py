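"""Operations on RNA-DNA contact tables.

A contact table is a DataFrame with one row per contact (see
:data:`rd3d.io.CONTACT_COLUMNS`). Binning reduces each RNA's contact
track to occupied Hi-C bins with multiplicities; downstream pair
statistics use the occupied-bin support, making them robust to
amplification duplicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, position_to_bin
from .io import validate_contacts


def bin_contacts(contacts: pd.DataFrame, bin_size: int, genome: Genome | None = None) -> pd.DataFrame:
    """Bin each RNA's contacts at *bin_size*.

    Returns a DataFrame (rna_id, chrom, bin, count) where count is the
    contact multiplicity in that bin; the sum of counts equals the number
    of input contacts.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if genome is not None:
        validate_contacts(contacts, genome)
    df = contacts.assign(bin=position_to_bin(contacts["dna_pos"].to_numpy(), bin_size))
    out = (
        df.groupby(["rna_id", "dna_chrom", "bin"], sort=True, observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"dna_chrom": "chrom"})
    )
    return out


def occupied_bins(binned: pd.DataFrame, rna_id: str, chrom: str) -> np.ndarray:
    """Sorted occupied bin indices (the support) for one RNA on one chromosome."""
    m = (binned["rna_id"] == rna_id) & (binned["chrom"] == chrom)
    return np.sort(binned.loc[m, "bin"].to_numpy())


def gene_locus(contacts: pd.DataFrame, rna_id: str) -> GenomicInterval:
    """The source-gene locus recorded for *rna_id* in the contact table."""
    row = contacts.loc[contacts["rna_id"] == rna_id].iloc[0]
    strand = row["gene_strand"] if isinstance(row["gene_strand"], str) else None
    return GenomicInterval(str(row["gene_chrom"]), int(row["gene_start"]), int(row["gene_end"]), strand)


def gene_table(contacts: pd.DataFrame) -> pd.DataFrame:
    """One row per RNA: rna_id, biotype, gene_chrom, gene_start, gene_end."""
    return (
        contacts[["rna_id", "biotype", "gene_chrom", "gene_start", "gene_end"]]
        .drop_duplicates("rna_id")
        .reset_index(drop=True)
    )


def split_cis_trans(contacts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split contacts into cis (gene chromosome) and trans (other chromosomes)."""
    cis_mask = contacts["dna_chrom"] == contacts["gene_chrom"]
    return contacts[cis_mask].copy(), contacts[~cis_mask].copy()


def classify_contacts_by_distance(contacts: pd.DataFrame, close_distance: int = 20_000_000) -> pd.Series:
    """Classify each contact as close / distant / trans relative to its gene.

    Close: same chromosome, nearest gene edge < *close_distance* away
    (contacts inside the gene have distance 0). Distant: same chromosome
    otherwise. Trans: a different chromosome.
    """
    pos = contacts["dna_pos"].to_numpy()
    start = contacts["gene_start"].to_numpy()
    end = contacts["gene_end"].to_numpy()
    dist = np.maximum(np.maximum(start - pos, pos - end + 1), 0)
    cis = (contacts["dna_chrom"] == contacts["gene_chrom"]).to_numpy()
    labels = np.where(~cis, "trans", np.where(dist < close_distance, "close", "distant"))
    return pd.Series(labels, index=contacts.index, name="distance_class")


def select_top_rnas(per_rna_counts: pd.Series | dict, n: int) -> list[str]:
    """The *n* RNAs with the largest counts; ties broken lexicographically.

    Mirrors the convention of keeping the 6000 most peak-rich RNAs per
    dataset. Deterministic: sorting is by (-count, rna_id).
    """
    items = per_rna_counts.items() if hasattr(per_rna_counts, "items") else per_rna_counts
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n]]
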