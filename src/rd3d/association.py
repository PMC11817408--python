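"""The core statistic: per-RNA structural association of contact pairs
with significant Hi-C interactions, against the shifted background.

For each RNA and each chromosome (intrachromosomal case) or chromosome
pair (interchromosomal case), every pair of occupied contact bins is a
candidate pair; a candidate pair is "paired" (structurally associated)
when the corresponding Hi-C bin pair is a significant interaction. The
same count against the shifted background map gives the 2x2 table

    [[paired_real, N - paired_real], [paired_shifted, N - paired_shifted]]

tested two-sided by Fisher's exact test, Benjamini-Hochberg adjusted
over all (RNA x scope) tests separately for the intra- and
interchromosomal families. An RNA is significantly associated on a
scope when q < 0.05 and the odds ratio exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contacts import bin_contacts, gene_table
from .genome import Genome
from .hic import SignificantInteractionSet
from .stats import bh_adjust, fisher_exact_2x2

RESULT_COLUMNS = [
    "rna_id",
    "biotype",
    "chrom_a",
    "chrom_b",
    "n_pairs",
    "paired_real",
    "paired_shifted",
    "odds_ratio",
    "p",
    "q",
    "significant",
]


@dataclass
class CandidatePairSet:
    """All candidate contact-bin pairs of one RNA on one scope.

    Intra: unordered pairs of distinct occupied bins on one chromosome,
    ``n_pairs = C(k, 2)``. Inter: all cross products of occupied bins on
    the two chromosomes, ``n_pairs = k_a * k_b``. Bins are counted once
    regardless of contact multiplicity (support-based counting).
    """

    rna_id: str
    chrom_a: str
    chrom_b: str
    bins_a: np.ndarray
    bins_b: np.ndarray
    bin_size: int

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def n_pairs(self) -> int:
        k_a = len(self.bins_a)
        if self.is_intra:
            return k_a * (k_a - 1) // 2
        return k_a * len(self.bins_b)

    def pairs(self):
        """Iterate the candidate pairs (order-normalised tuples)."""
        if self.is_intra:
            yield from combinations(sorted(self.bins_a.tolist()), 2)
        else:
            for a in self.bins_a.tolist():
                for b in self.bins_b.tolist():
                    yield (a, b)


def enumerate_candidate_pairs(
    binned: pd.DataFrame, rna_id: str, chrom_a: str, chrom_b: str, bin_size: int
) -> CandidatePairSet | None:
    """Candidate pairs for one RNA on one scope; None below minimum support
    (fewer than 2 occupied bins intra, or an empty side inter)."""
    sub = binned[binned["rna_id"] == rna_id]
    bins_a = np.unique(sub.loc[sub["chrom"] == chrom_a, "bin"].to_numpy())
    if chrom_a == chrom_b:
        if len(bins_a) < 2:
            return None
        return CandidatePairSet(rna_id, chrom_a, chrom_b, bins_a, bins_a, bin_size)
    bins_b = np.unique(sub.loc[sub["chrom"] == chrom_b, "bin"].to_numpy())
    if len(bins_a) < 1 or len(bins_b) < 1:
        return None
    return CandidatePairSet(rna_id, chrom_a, chrom_b, bins_a, bins_b, bin_size)


def count_paired(pairs: CandidatePairSet, peaks: SignificantInteractionSet) -> int:
    """Number of candidate pairs that are significant Hi-C interactions.

    Counted by scanning the (sparse) peak set for pairs whose two anchors
    are both occupied, which avoids enumerating the full candidate set.
    """
    if pairs.bin_size != peaks.bin_size:
        raise ValueError("bin size mismatch between candidate pairs and peak set")
    return len(matching_pairs(pairs, peaks))


def matching_pairs(pairs: CandidatePairSet, peaks: SignificantInteractionSet) -> list[tuple[int, int]]:
    """The candidate pairs present in the peak set (order-insensitive)."""
    peak_pairs = peaks.pair_set(pairs.chrom_a, pairs.chrom_b)
    if pairs.is_intra:
        occ = set(pairs.bins_a.tolist())
        return [(a, b) for a, b in peak_pairs if a != b and a in occ and b in occ]
    occ_a = set(pairs.bins_a.tolist())
    occ_b = set(pairs.bins_b.tolist())
    hits = [(a, b) for a, b in peak_pairs if a in occ_a and b in occ_b]
    # the peak table for an inter scope may record the pair in either
    # chromosome order; check the transpose too if scopes were flipped
    flipped = peaks.pair_set(pairs.chrom_b, pairs.chrom_a)
    hits += [(a, b) for b, a in flipped if a in occ_a and b in occ_b]
    return sorted(set(hits))


def test_association(
    pairs: CandidatePairSet,
    peaks: SignificantInteractionSet,
    shifted: SignificantInteractionSet,
) -> dict:
    """One RNA x scope 2x2 Fisher test (q filled in later by the family BH)."""
    n = pairs.n_pairs
    paired_real = count_paired(pairs, peaks)
    paired_shifted = count_paired(pairs, shifted)
    table = [[paired_real, n - paired_real], [paired_shifted, n - paired_shifted]]
    odds, p = fisher_exact_2x2(table)
    return {
        "rna_id": pairs.rna_id,
        "chrom_a": pairs.chrom_a,
        "chrom_b": pairs.chrom_b,
        "n_pairs": n,
        "paired_real": paired_real,
        "paired_shifted": paired_shifted,
        "odds_ratio": odds,
        "p": p,
    }


class StructuralAssociationModel:
    """Per-RNA association of RD contact pairs with Hi-C structure.

    Parameters
    ----------
    contacts
        RNA-DNA contact table (peak-filtered contacts by convention).
    peaks, shifted_peaks
        The significant Hi-C interactions and their shifted background,
        at the same bin size.
    genome
        Chromosome sizes.
    scope
        "intra" (per chromosome) or "inter" (per chromosome pair);
        the two families are tested and adjusted separately.
    config
        Thresholds; ``rna_q_threshold`` controls significance.
    """

    def __init__(
        self,
        contacts: pd.DataFrame,
        peaks: SignificantInteractionSet,
        shifted_peaks: SignificantInteractionSet,
        genome: Genome,
        scope: str = "intra",
        config: AnalysisConfig | None = None,
    ):
        if scope not in ("intra", "inter"):
            raise ValueError("scope must be 'intra' or 'inter'")
        if peaks.bin_size != shifted_peaks.bin_size:
            raise ValueError("peak sets must share a bin size")
        self.contacts = contacts
        self.peaks = peaks
        self.shifted_peaks = shifted_peaks
        self.genome = genome
        self.scope = scope
        self.config = config or AnalysisConfig()
        self.bin_size = peaks.bin_size

    def _scopes(self, rna_chroms: set[str]) -> list[tuple[str, str]]:
        chroms = sorted(rna_chroms)
        if self.scope == "intra":
            return [(c, c) for c in chroms]
        return [(a, b) for i, a in enumerate(chroms) for b in chroms[i + 1 :]]

    def fit(self) -> "StructuralAssociationResults":
        binned = bin_contacts(self.contacts, self.bin_size, self.genome)
        genes = gene_table(self.contacts).set_index("rna_id")
        rows, skipped, paired_map = [], [], {}
        for rna_id, sub in binned.groupby("rna_id", sort=True):
            for chrom_a, chrom_b in self._scopes(set(sub["chrom"])):
                pairs = enumerate_candidate_pairs(binned=sub.assign(rna_id=rna_id),
                                                  rna_id=rna_id, chrom_a=chrom_a,
                                                  chrom_b=chrom_b, bin_size=self.bin_size)
                if pairs is None:
                    skipped.append((rna_id, chrom_a, chrom_b))
                    continue
                row = test_association(pairs, self.peaks, self.shifted_peaks)
                row["biotype"] = genes.loc[rna_id, "biotype"]
                rows.append(row)
                paired_map[(rna_id, chrom_a, chrom_b)] = matching_pairs(pairs, self.peaks)
        table = pd.DataFrame(rows)
        if len(table):
            table["q"] = bh_adjust(table["p"].to_numpy())
            table["significant"] = (table["q"] < self.config.rna_q_threshold) & (table["odds_ratio"] > 1)
            table = table[RESULT_COLUMNS]
        else:
            table = pd.DataFrame(columns=RESULT_COLUMNS)
        return StructuralAssociationResults(self, table, skipped, paired_map)


class StructuralAssociationResults:
    """Fitted per-(RNA, scope) association tests.

    Attributes
    ----------
    table
        One row per test with counts, odds ratio, p, q, significance.
    skipped
        (rna_id, chrom_a, chrom_b) scopes below minimum support, which
        are excluded from the BH family.
    """

    def __init__(self, model, table: pd.DataFrame, skipped, paired_map):
        self.model = model
        self.table = table
        self.skipped = skipped
        self._paired_map = paired_map

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def significant_rnas(self) -> set[str]:
        """RNAs significantly associated on at least one scope."""
        return set(self.significant["rna_id"])

    def paired_pairs(self, rna_id: str, chrom_a: str, chrom_b: str | None = None) -> list[tuple[int, int]]:
        """The structurally associated (peak-matching) bin pairs of one test."""
        return self._paired_map.get((rna_id, chrom_a, chrom_b or chrom_a), [])

    def paired_pairs_bedpe(self, rna_id: str) -> pd.DataFrame:
        """BEDPE of one RNA's structurally associated pairs (for plotting)."""
        b = self.model.bin_size
        rows = []
        for (rid, ca, cb), prs in self._paired_map.items():
            if rid != rna_id:
                continue
            for a, bb_ in prs:
                rows.append((ca, a * b, (a + 1) * b, cb, bb_ * b, (bb_ + 1) * b, rna_id))
        return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"])

    def summary(self) -> str:
        n_tests = len(self.table)
        n_sig = int(self.table["significant"].sum()) if n_tests else 0
        n_rnas = self.table["rna_id"].nunique() if n_tests else 0
        lines = [
            f"Structural association ({self.model.scope}chromosomal), bin size {self.model.bin_size} bp",
            f"  tests: {n_tests} over {n_rnas} RNAs ({len(self.skipped)} scopes below support)",
            f"  significant (q < {self.model.config.rna_q_threshold}, OR > 1): "
            f"{n_sig} tests, {len(self.significant_rnas())} RNAs",
        ]
        if n_sig:
            top = self.significant.nsmallest(min(n_sig, 10), "q")
            lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)
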