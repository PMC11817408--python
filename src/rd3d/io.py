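"""Readers and writers for the plain-text formats the pipeline touches.

Contact tables, Hi-C sparse triplets, BED/BEDPE annotation tracks and
result tables are all tab-separated text. Coordinates are 0-based
half-open on disk except GTF, which is converted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome

CONTACT_COLUMNS = [
    "rna_id",
    "biotype",
    "gene_chrom",
    "gene_start",
    "gene_end",
    "gene_strand",
    "dna_chrom",
    "dna_pos",
]

TRIPLET_COLUMNS = ["chrom_a", "bin_a", "chrom_b", "bin_b", "count"]


def read_chromsizes(path) -> Genome:
    """Two-column chromosome-sizes text -> :class:`Genome`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return Genome(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def read_contacts(path, genome: Genome | None = None) -> pd.DataFrame:
    """Read an RNA-DNA contact table (tab-separated with header).

    Columns: rna_id, biotype, gene_chrom, gene_start, gene_end,
    gene_strand, dna_chrom, dna_pos. If *genome* is given, contacts are
    validated against chromosome bounds.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rna_id": str, "biotype": str})
    missing = set(CONTACT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    df = df[CONTACT_COLUMNS].copy()
    if genome is not None:
        validate_contacts(df, genome)
    return df


def validate_contacts(df: pd.DataFrame, genome: Genome) -> None:
    for chrom, sub in df.groupby("dna_chrom"):
        if chrom not in genome:
            raise ValueError(f"contact on unknown chromosome {chrom!r}")
        bad = (sub["dna_pos"] < 0) | (sub["dna_pos"] >= genome.length(str(chrom)))
        if bad.any():
            pos = int(sub.loc[bad, "dna_pos"].iloc[0])
            raise ValueError(f"contact position {pos} outside chromosome {chrom!r}")


def write_contacts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CONTACT_COLUMNS)


def read_bed(path, names: bool = True) -> pd.DataFrame:
    """BED3/BED6 -> DataFrame(chrom, start, end[, name, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE loops -> DataFrame(chrom1, start1, end1, chrom2, start2, end2, ...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"][: df.shape[1]]
    df.columns = cols
    df["chrom1"] = df["chrom1"].astype(str)
    df["chrom2"] = df["chrom2"].astype(str)
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"] if c in df.columns]
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


def read_gtf_genes(path) -> pd.DataFrame:
    """Gene records from a GTF -> DataFrame(chrom, start, end, strand, gene_id).

    GTF is 1-based closed; converted to 0-based half-open here.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "gene_id": attrs.get("gene_id", ""),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def read_triplets(path) -> pd.DataFrame:
    """Sparse Hi-C triplets text: chrom_a bin_a chrom_b bin_b count (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    missing = set(TRIPLET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"triplet table missing columns: {sorted(missing)}")
    return df[TRIPLET_COLUMNS].copy()


def write_triplets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TRIPLET_COLUMNS)


def read_fithic(path) -> pd.DataFrame:
    """FitHiC2-style significant-interaction text.

    Columns chr1 fragmentMid1 chr2 fragmentMid2 p q (whitespace separated,
    with or without header). Fragment midpoints are converted to bin
    indices downstream by the caller, which knows the bin size.
    """
    first = open(path).readline().split()
    header = 0 if not _floatable(first[1]) else None
    df = pd.read_csv(path, sep=r"\s+", header=header)
    df.columns = ["chr1", "fragmentMid1", "chr2", "fragmentMid2", "p", "q"][: df.shape[1]]
    df["chr1"] = df["chr1"].astype(str)
    df["chr2"] = df["chr2"].astype(str)
    return df


def _floatable(x) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def read_grouping_map(path) -> dict[str, str]:
    """Two-column raw_label -> grouped_label TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["raw", "grouped"], comment="#")
    return dict(zip(df["raw"].astype(str), df["grouped"].astype(str)))


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column ortholog table: geneA_id, geneB_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"], comment="#")
    return df.astype(str)


def write_result_table(df: pd.DataFrame, path, pvalue_columns=("p", "q")) -> None:
    """Write a result table as TSV; p/q columns in scientific notation."""
    out = df.copy()
    for col in pvalue_columns:
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.6e}" if v == v else "nan")
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_chromsizes(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chromsizes.items():
            fh.write(f"{chrom}\t{length}\n")
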