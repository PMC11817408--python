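"""Cross-experiment conservation of structurally associated contact pairs.

For one RNA, the target experiment's candidate contact-bin pairs are
cross-classified by (i) whether the pair is structurally associated
(paired) according to the target Hi-C peaks and (ii) whether the same
unordered bin pair occurs among the reference experiment's candidate
pairs for the same RNA. A two-sided Fisher test per RNA, BH-adjusted
within one direction, asks whether paired pairs are preferentially
preserved. Running both directions and keeping RNAs significant in
both with concordant odds-ratio direction gives the conserved set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .contacts import bin_contacts
from .genome import Genome
from .hic import SignificantInteractionSet
from .stats import bh_adjust, fisher_exact_2x2

RESULT_COLUMNS = [
    "rna_id",
    "direction",
    "paired_present",
    "paired_absent",
    "nonpaired_present",
    "nonpaired_absent",
    "odds_ratio",
    "p",
    "q",
]


def _occupied_by_chrom(binned: pd.DataFrame, rna_id: str) -> dict[str, np.ndarray]:
    sub = binned[binned["rna_id"] == rna_id]
    return {str(c): np.unique(g["bin"].to_numpy()) for c, g in sub.groupby("chrom")}


def conservation_test(
    target_binned: pd.DataFrame,
    target_peaks: SignificantInteractionSet,
    reference_binned: pd.DataFrame,
    rna_id: str,
    direction: str,
    match_tolerance_bins: int = 0,
) -> dict | None:
    """One RNA's conservation 2x2 table and Fisher test (intra pairs pooled
    over chromosomes).

    Cell counts partition the target RNA's candidate pairs: rows are
    paired vs non-paired in the target (by target Hi-C peaks), columns
    are present vs absent among the reference experiment's candidate
    pairs. "Present" means both bins of the pair are occupied by the
    same RNA in the reference at the identical resolution (an optional
    +/- *match_tolerance_bins* fuzz widens the match). Returns None when
    the RNA lacks candidate pairs in the target or is absent from the
    reference.
    """
    occ_t = _occupied_by_chrom(target_binned, rna_id)
    occ_r = _occupied_by_chrom(reference_binned, rna_id)
    if not occ_t or not occ_r:
        return None
    a = b = c = d = 0
    any_pairs = False
    for chrom, bins_t in occ_t.items():
        k = len(bins_t)
        if k < 2:
            continue
        any_pairs = True
        n = k * (k - 1) // 2
        bins_r = occ_r.get(chrom, np.empty(0, dtype=np.int64))
        if match_tolerance_bins:
            widened = np.unique(
                np.concatenate([bins_r + d_ for d_ in range(-match_tolerance_bins, match_tolerance_bins + 1)])
            )
        else:
            widened = bins_r
        present_bins = np.intersect1d(bins_t, widened)
        m = len(present_bins)
        n_present = m * (m - 1) // 2
        occ_set = set(bins_t.tolist())
        present_set = set(present_bins.tolist())
        paired = [
            (x, y)
            for x, y in target_peaks.pair_set(chrom, chrom)
            if x != y and x in occ_set and y in occ_set
        ]
        a_c = sum(1 for x, y in paired if x in present_set and y in present_set)
        a += a_c
        b += len(paired) - a_c
        c += n_present - a_c
        d += n - len(paired) - (n_present - a_c)
    if not any_pairs:
        return None
    odds, p = fisher_exact_2x2([[a, b], [c, d]])
    return {
        "rna_id": rna_id,
        "direction": direction,
        "paired_present": a,
        "paired_absent": b,
        "nonpaired_present": c,
        "nonpaired_absent": d,
        "odds_ratio": odds,
        "p": p,
    }


def reciprocal_filter(forward: pd.DataFrame, backward: pd.DataFrame, q_threshold: float = 0.05) -> set[str]:
    """RNAs significant in both directions with concordant odds-ratio side.

    Keeps RNAs with q < *q_threshold* in both runs whose odds ratios lie
    on the same side of 1 (both enriched or both depleted); undefined
    odds ratios never pass.
    """
    f = forward.set_index("rna_id")
    kept = set()
    for row in backward.itertuples():
        if row.rna_id not in f.index:
            continue
        fr = f.loc[row.rna_id]
        if fr["q"] >= q_threshold or row.q >= q_threshold:
            continue
        or_f, or_b = fr["odds_ratio"], row.odds_ratio
        if math.isnan(or_f) or math.isnan(or_b) or or_f == 1 or or_b == 1:
            continue
        if (or_f > 1) == (or_b > 1):
            kept.add(row.rna_id)
    return kept


def intersect_rna_sets(set_a: set[str], set_b: set[str], universe: set[str] | None = None) -> dict:
    """Venn-style overlap counts, with an optional hypergeometric overlap p.

    The p-value asks how surprising an intersection at least this large
    is when |A| and |B| items are drawn without replacement from the
    stated universe.
    """
    out = {"n_a": len(set_a), "n_b": len(set_b), "n_intersection": len(set_a & set_b)}
    if universe is not None:
        if not universe:
            raise ValueError("empty universe for the overlap p-value")
        from scipy.stats import hypergeom

        n_u = len(universe)
        out["overlap_p"] = float(
            hypergeom.sf(out["n_intersection"] - 1, n_u, out["n_a"], out["n_b"])
        )
    return out


class ConservationModel:
    """Paired-contact conservation between a target and a reference experiment.

    Both experiments are contact tables binned at the same resolution;
    each needs its own significant Hi-C interaction set (the reference
    peaks are used when the direction is reversed). ``fit`` runs both
    directions and applies the reciprocal filter.
    """

    def __init__(
        self,
        target_contacts: pd.DataFrame,
        target_peaks: SignificantInteractionSet,
        reference_contacts: pd.DataFrame,
        reference_peaks: SignificantInteractionSet,
        genome: Genome,
        config: AnalysisConfig | None = None,
        match_tolerance_bins: int = 0,
        names: tuple[str, str] = ("target", "reference"),
    ):
        if target_peaks.bin_size != reference_peaks.bin_size:
            raise ValueError("experiments must be binned at the same resolution")
        self.target_contacts = target_contacts
        self.target_peaks = target_peaks
        self.reference_contacts = reference_contacts
        self.reference_peaks = reference_peaks
        self.genome = genome
        self.config = config or AnalysisConfig()
        self.match_tolerance_bins = match_tolerance_bins
        self.names = names

    def _run_direction(self, binned_t, peaks_t, binned_r, direction) -> pd.DataFrame:
        shared = sorted(set(binned_t["rna_id"]) & set(binned_r["rna_id"]))
        rows = []
        for rna_id in shared:
            res = conservation_test(
                binned_t, peaks_t, binned_r, rna_id, direction, self.match_tolerance_bins
            )
            if res is not None:
                rows.append(res)
        table = pd.DataFrame(rows)
        if len(table):
            table["q"] = bh_adjust(table["p"].to_numpy())
            table = table[RESULT_COLUMNS]
        else:
            table = pd.DataFrame(columns=RESULT_COLUMNS)
        return table

    def fit(self) -> "ConservationResults":
        B = self.target_peaks.bin_size
        binned_t = bin_contacts(self.target_contacts, B, self.genome)
        binned_r = bin_contacts(self.reference_contacts, B, self.genome)
        fwd = self._run_direction(binned_t, self.target_peaks, binned_r, f"{self.names[0]}->{self.names[1]}")
        bwd = self._run_direction(binned_r, self.reference_peaks, binned_t, f"{self.names[1]}->{self.names[0]}")
        conserved = reciprocal_filter(fwd, bwd, self.config.rna_q_threshold)
        return ConservationResults(self, fwd, bwd, conserved)


class ConservationResults:
    """Both-direction conservation tests and the reciprocally filtered set."""

    def __init__(self, model, forward: pd.DataFrame, backward: pd.DataFrame, conserved: set[str]):
        self.model = model
        self.forward = forward
        self.backward = backward
        self.conserved = conserved

    @property
    def table(self) -> pd.DataFrame:
        out = pd.concat([self.forward, self.backward], ignore_index=True)
        out["kept"] = out["rna_id"].isin(self.conserved)
        return out

    def summary(self) -> str:
        return "\n".join(
            [
                f"Conservation {self.model.names[0]} <-> {self.model.names[1]}",
                f"  RNAs tested: {len(self.forward)} forward, {len(self.backward)} backward",
                f"  reciprocally conserved (q < {self.model.config.rna_q_threshold}, "
                f"concordant OR): {len(self.conserved)}",
            ]
        )
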