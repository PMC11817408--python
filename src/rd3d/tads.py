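"""TAD-relative localisation of RNA contacts: parental-TAD assignment,
rescaled TAD metaplots and the OutInDR statistic.

OutInDR is the ratio of the cis-contact density (contacts per bp)
outside an RNA's parental TAD to the density inside it, where the
parental TAD is the TAD overlapping strictly more than half of the
gene and "outside" is the remainder of the gene's chromosome. High
-log10(OutInDR) means the RNA stays near its TAD. The ratio is
expression-independent by construction: scaling every contact count by
a constant leaves it unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contacts import gene_table, split_cis_trans
from .genome import Genome, GenomicInterval
from .stats import bh_adjust, mannwhitney_two_sided, spearman

OUTINDR_COLUMNS = [
    "rna_id",
    "biotype",
    "tad_start",
    "tad_end",
    "n_cis",
    "n_in",
    "n_out",
    "density_in",
    "density_out",
    "outindr",
    "neg_log10_outindr",
]


class TadSet:
    """Sorted non-overlapping TAD intervals per chromosome."""

    def __init__(self, table: pd.DataFrame):
        table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in table.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping TADs on {chrom}")
        self.table = table

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def assign_parental_tad(gene: GenomicInterval, tads: TadSet) -> GenomicInterval | None:
    """The TAD overlapping strictly more than half the gene's length.

    Ties (an exact half split) and genes without a majority TAD return
    None; boundary-spanning genes are thereby left unassigned.
    """
    half = len(gene) / 2.0
    for row in tads.on_chrom(gene.chrom).itertuples():
        overlap = min(gene.end, row.end) - max(gene.start, row.start)
        if overlap > half:
            return GenomicInterval(gene.chrom, int(row.start), int(row.end))
    return None


def compute_outindr(
    n_in: int, n_out: int, tad: GenomicInterval, chrom_length: int, min_cis: int = 10
) -> dict:
    """OutInDR for one gene, or an exclusion record.

    d_in = n_in / len(TAD), d_out = n_out / (chromosome length - len(TAD));
    OutInDR = d_out / d_in. Genes with fewer than *min_cis* cis contacts,
    or with no inside or no outside contacts (degenerate ratio), are
    excluded with a reason code.
    """
    tad_len = len(tad)
    if tad_len >= chrom_length:
        raise ValueError("TAD length must be smaller than the chromosome")
    n_cis = n_in + n_out
    if n_cis < min_cis:
        return {"excluded": "below_min_cis"}
    if n_in == 0:
        return {"excluded": "no_inside_contacts"}
    if n_out == 0:
        return {"excluded": "no_outside_contacts"}
    d_in = n_in / tad_len
    d_out = n_out / (chrom_length - tad_len)
    ratio = d_out / d_in
    return {
        "excluded": None,
        "n_cis": n_cis,
        "n_in": n_in,
        "n_out": n_out,
        "density_in": d_in,
        "density_out": d_out,
        "outindr": ratio,
        "neg_log10_outindr": -float(np.log10(ratio)),
    }


def tad_metaplot(
    contacts: pd.DataFrame,
    tads: TadSet,
    genome: Genome,
    top_n: int = 100,
    n_bins: int = 90,
) -> pd.DataFrame:
    """Rescaled contact profile around parental TADs.

    For each RNA with a parental TAD of length L, cis contacts within
    [start - L, end + L] map to the relative coordinate
    (pos - start) / L in [-1, 2] (the TAD itself is [0, 1]). Per-RNA
    histograms over *n_bins* equal relative bins are normalised to unit
    mean (so heavily contacting RNAs do not dominate) and averaged over
    the top *top_n* RNAs per chromosome ranked by the contact count in
    the window. Run it twice -- on the full contact set and on the
    peak-filtered set -- to contrast raw RD-scaling with the residual
    TAD-boundary signal.
    """
    cis, _ = split_cis_trans(contacts)
    genes = gene_table(contacts)
    edges = np.linspace(-1.0, 2.0, n_bins + 1)
    per_rna = []
    for row in genes.itertuples():
        gene = GenomicInterval(str(row.gene_chrom), int(row.gene_start), int(row.gene_end))
        tad = assign_parental_tad(gene, tads)
        if tad is None:
            continue
        L = len(tad)
        pos = cis.loc[cis["rna_id"] == row.rna_id, "dna_pos"].to_numpy()
        rel = (pos - tad.start) / L
        rel = rel[(rel >= -1.0) & (rel < 2.0)]
        if len(rel) == 0:
            continue
        hist, _ = np.histogram(rel, bins=edges)
        per_rna.append((row.rna_id, gene.chrom, len(rel), hist))
    if not per_rna:
        raise ValueError("no RNAs with an assigned parental TAD and in-window contacts")
    chosen = []
    frame = pd.DataFrame(per_rna, columns=["rna_id", "chrom", "n_window", "hist"])
    for _, sub in frame.groupby("chrom"):
        ranked = sub.sort_values(["n_window", "rna_id"], ascending=[False, True])
        chosen.append(ranked.head(top_n))
    chosen = pd.concat(chosen)
    profiles = np.stack(
        [h / h.mean() if h.mean() > 0 else h for h in chosen["hist"]]
    )
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(
        {"rel_coord": centers, "mean_profile": profiles.mean(axis=0), "n_rnas": len(chosen)}
    )


def compare_biotypes(records: pd.DataFrame, min_group: int = 2) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on -log10(OutInDR) by biotype.

    Biotypes with fewer than *min_group* records are dropped; p-values
    are BH-adjusted across the pairs. Group sizes are reported.
    """
    groups = {
        b: sub["neg_log10_outindr"].to_numpy()
        for b, sub in records.groupby("biotype")
        if len(sub) >= min_group
    }
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two biotypes with enough records")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mannwhitney_two_sided(groups[a], groups[b])
            rows.append(
                {
                    "biotype_a": a,
                    "biotype_b": b,
                    "n_a": len(groups[a]),
                    "n_b": len(groups[b]),
                    "median_a": float(np.median(groups[a])),
                    "median_b": float(np.median(groups[b])),
                    "U": u,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def correlate_experiments(
    records_a: pd.DataFrame, records_b: pd.DataFrame, id_map: pd.DataFrame | None = None
) -> dict:
    """Spearman correlation of -log10(OutInDR) between two experiments.

    With no *id_map* the gene identifiers are matched directly (same
    species); an ortholog table (columns gene_a, gene_b) maps
    experiment A identifiers onto experiment B. Requires >= 3 shared
    genes.
    """
    a = records_a.set_index("rna_id")["neg_log10_outindr"]
    b = records_b.set_index("rna_id")["neg_log10_outindr"]
    if id_map is None:
        shared = a.index.intersection(b.index)
        x, y = a.loc[shared], b.loc[shared]
    else:
        pairs = id_map[id_map["gene_a"].isin(a.index) & id_map["gene_b"].isin(b.index)]
        x = a.loc[pairs["gene_a"]].to_numpy()
        y = b.loc[pairs["gene_b"]].to_numpy()
        shared = pairs["gene_a"]
    if len(x) < 3:
        raise ValueError("fewer than 3 shared genes between experiments")
    rho, p = spearman(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return {"scc": rho, "p": p, "n_shared": int(len(shared))}


class OutInDRModel:
    """OutInDR analysis of one contact table against a TAD annotation.

    ``fit`` assigns parental TADs, applies the >= *min_cis* cis-contact
    filter and computes per-gene densities and ratios; exclusions are
    kept with reason codes.
    """

    def __init__(
        self,
        contacts: pd.DataFrame,
        tads: TadSet,
        genome: Genome,
        config: AnalysisConfig | None = None,
    ):
        self.contacts = contacts
        self.tads = tads
        self.genome = genome
        self.config = config or AnalysisConfig()

    def fit(self) -> "OutInDRResults":
        cis, _ = split_cis_trans(self.contacts)
        genes = gene_table(self.contacts)
        rows, excluded = [], []
        for row in genes.itertuples():
            gene = GenomicInterval(str(row.gene_chrom), int(row.gene_start), int(row.gene_end))
            tad = assign_parental_tad(gene, self.tads)
            if tad is None:
                excluded.append({"rna_id": row.rna_id, "reason": "no_parental_tad"})
                continue
            pos = cis.loc[cis["rna_id"] == row.rna_id, "dna_pos"].to_numpy()
            n_in = int(((pos >= tad.start) & (pos < tad.end)).sum())
            res = compute_outindr(
                n_in, len(pos) - n_in, tad, self.genome.length(gene.chrom), self.config.min_cis_contacts
            )
            if res["excluded"]:
                excluded.append({"rna_id": row.rna_id, "reason": res["excluded"]})
                continue
            res.pop("excluded")
            rows.append({"rna_id": row.rna_id, "biotype": row.biotype,
                         "tad_start": tad.start, "tad_end": tad.end, **res})
        table = pd.DataFrame(rows, columns=OUTINDR_COLUMNS) if rows else pd.DataFrame(columns=OUTINDR_COLUMNS)
        return OutInDRResults(self, table, pd.DataFrame(excluded, columns=["rna_id", "reason"]))


class OutInDRResults:
    """Per-gene OutInDR records plus comparison helpers."""

    def __init__(self, model, table: pd.DataFrame, excluded: pd.DataFrame):
        self.model = model
        self.table = table
        self.excluded = excluded

    def compare_biotypes(self) -> pd.DataFrame:
        return compare_biotypes(self.table)

    def correlate(self, other: "OutInDRResults", id_map: pd.DataFrame | None = None) -> dict:
        return correlate_experiments(self.table, other.table, id_map)

    def metaplot(self, contacts: pd.DataFrame | None = None) -> pd.DataFrame:
        return tad_metaplot(
            self.model.contacts if contacts is None else contacts,
            self.model.tads,
            self.model.genome,
            top_n=self.model.config.metaplot_top_rnas,
        )

    def summary(self) -> str:
        lines = [
            f"OutInDR over {len(self.table)} genes "
            f"({len(self.excluded)} excluded: "
            f"{dict(self.excluded['reason'].value_counts()) if len(self.excluded) else {}})",
        ]
        if len(self.table):
            med = self.table.groupby("biotype")["neg_log10_outindr"].median()
            lines.append("  median -log10(OutInDR) by biotype:")
            lines.extend(f"    {b}: {v:.3f}" for b, v in med.items())
        return "\n".join(lines)
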