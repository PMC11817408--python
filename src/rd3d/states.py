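"""Functional-state annotation of structurally associated contact pairs.

Each RNA's paired (peak-matching) contact pairs are annotated with
same-label chromatin-state pairs: a bin belongs to a state when at
least one base pair of a state interval falls within it (so a bin can
carry several states of one annotation), and a pair of bins belongs to
a state when both bins do. Observed in-state paired-contact counts are
compared with the expected fraction -- the share of significant Hi-C
interactions on the same chromosome whose both anchors carry the label
-- by a 1-df chi-square, and summarised as log2 observed/expected
profiles suitable for a t-SNE embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .genome import Genome
from .hic import SignificantInteractionSet
from .stats import chi2_1df

STATS_COLUMNS = [
    "rna_id",
    "chrom",
    "annotation",
    "label",
    "observed",
    "total",
    "expected_fraction",
    "chi2",
    "p",
    "log2_oe",
    "flagged",
]

#: default grouping shipped for SPIN states: Interior_Repr2 aggregates
#: with the nucleolus and is treated as its own NAD-like group.
DEFAULT_SPIN_GROUPING = {"Interior_Repr2": "NAD_like"}


@dataclass
class StateTrack:
    """One chromatin-state annotation with an optional label grouping map."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end, name (raw label)
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        iv = self.intervals.copy()
        iv["label"] = iv["name"].astype(str).map(lambda raw: self.grouping.get(raw, raw))
        self.intervals = iv

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique())


def assign_bins_to_states(genome: Genome, bin_size: int, track: StateTrack) -> dict[str, dict[str, np.ndarray]]:
    """Multi-label bin assignment: chrom -> {label -> boolean bin mask}.

    A bin carries a label when any interval with that label overlaps it
    by at least one base pair; bins with no overlap carry no label.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom in genome:
        n = genome.n_bins(chrom, bin_size)
        masks = {label: np.zeros(n, dtype=bool) for label in track.labels}
        sub = track.intervals[track.intervals["chrom"] == chrom]
        for start, end, label in zip(sub["start"], sub["end"], sub["label"]):
            lo = max(0, start // bin_size)
            hi = min(n - 1, (end - 1) // bin_size)
            if hi >= lo:
                masks[label][lo : hi + 1] = True
        out[chrom] = masks
    return out


def state_pair_enrichment(
    paired_pairs: dict[tuple[str, str], list[tuple[int, int]]],
    peaks: SignificantInteractionSet,
    track: StateTrack,
    genome: Genome,
) -> pd.DataFrame:
    """Per-(RNA, chromosome, label) enrichment of same-state paired contacts.

    Parameters
    ----------
    paired_pairs
        Mapping (rna_id, chrom) -> the RNA's structurally associated
        intrachromosomal bin pairs on that chromosome.
    peaks
        The significant-interaction set the pairs were matched against;
        its per-chromosome composition defines the expected fractions.
    track
        The state annotation (already grouped).

    Only same-label pairs are evaluated. Labels absent from both the
    peaks and the pairs on a chromosome are omitted; an expected
    fraction of zero with observed > 0 yields a flagged row with
    undefined statistics.
    """
    assignment = assign_bins_to_states(genome, peaks.bin_size, track)
    rows = []
    peak_comp: dict[str, dict[str, float]] = {}
    for (rna_id, chrom), pairs in sorted(paired_pairs.items()):
        total = len(pairs)
        if total == 0 or chrom not in assignment:
            continue
        masks = assignment[chrom]
        if chrom not in peak_comp:
            sub = peaks.subset_scope(chrom, chrom)
            ba, bb = sub["bin_a"].to_numpy(), sub["bin_b"].to_numpy()
            peak_comp[chrom] = {
                label: float((mask[ba] & mask[bb]).mean()) if len(ba) else 0.0
                for label, mask in masks.items()
            }
        pa = np.array([p[0] for p in pairs])
        pb = np.array([p[1] for p in pairs])
        for label, mask in masks.items():
            o = int((mask[pa] & mask[pb]).sum())
            e = peak_comp[chrom][label]
            if e == 0.0 and o == 0:
                continue  # label effectively absent from this scope
            flagged = e == 0.0 and o > 0
            if flagged:
                stat = p = log2_oe = float("nan")
            else:
                stat, p = chi2_1df(o, total, e) if e < 1.0 else (float("nan"), float("nan"))
                log2_oe = float(np.log2(o / (e * total))) if (e * total > 0 and o > 0) else float("nan")
            rows.append((rna_id, chrom, track.name, label, o, total, e, stat, p, log2_oe, flagged))
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def build_oe_profiles(stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rectangular per-(RNA, chromosome) log2 O/E profile matrix.

    Columns are (annotation, label) in a fixed sorted order; undefined
    entries are imputed as 0 and reported in the companion boolean mask
    (True = imputed).
    """
    stats = stats.assign(column=stats["annotation"] + ":" + stats["label"])
    profiles = stats.pivot_table(
        index=["rna_id", "chrom"], columns="column", values="log2_oe", aggfunc="first", dropna=False
    ).sort_index(axis=1)
    mask = profiles.isna()
    return profiles.fillna(0.0), mask


def embed_profiles(profiles: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding of the log2 O/E profiles (plotting only).

    Deterministic under *seed*; perplexity adapts to small inputs.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 profiles to embed")
    perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        perplexity=max(1.0, perplexity),
        random_state=seed,
        init="pca",
    ).fit_transform(profiles.to_numpy())
    return pd.DataFrame(coords, index=profiles.index, columns=["tsne1", "tsne2"])


class StateEnrichmentModel:
    """Chromatin-state enrichment of paired contacts for a set of RNAs.

    Parameters
    ----------
    paired_pairs
        (rna_id, chrom) -> structurally associated bin pairs, typically
        from :class:`rd3d.association.StructuralAssociationResults`.
    peaks
        The significant Hi-C interactions (expected-composition source).
    tracks
        The state annotations to evaluate (e.g. grouped ChromHMM, SPIN
        with the NAD-like split, A/B compartments).
    """

    def __init__(
        self,
        paired_pairs: dict[tuple[str, str], list[tuple[int, int]]],
        peaks: SignificantInteractionSet,
        tracks: list[StateTrack],
        genome: Genome,
    ):
        self.paired_pairs = paired_pairs
        self.peaks = peaks
        self.tracks = tracks
        self.genome = genome

    @classmethod
    def from_association(cls, assoc_results, tracks, significant_only: bool = True):
        """Build from fitted intrachromosomal association results."""
        table = assoc_results.significant if significant_only else assoc_results.table
        pairs = {
            (row.rna_id, row.chrom_a): assoc_results.paired_pairs(row.rna_id, row.chrom_a)
            for row in table.itertuples()
            if row.chrom_a == row.chrom_b
        }
        return cls(pairs, assoc_results.model.peaks, tracks, assoc_results.model.genome)

    def fit(self) -> "StateEnrichmentResults":
        frames = [
            state_pair_enrichment(self.paired_pairs, self.peaks, track, self.genome)
            for track in self.tracks
        ]
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=STATS_COLUMNS)
        return StateEnrichmentResults(self, table)


class StateEnrichmentResults:
    """Fitted state-pair enrichment statistics and O/E profiles."""

    def __init__(self, model: StateEnrichmentModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def profiles(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return build_oe_profiles(self.table)

    def embedding(self, seed: int = 0) -> pd.DataFrame:
        profiles, _ = self.profiles()
        return embed_profiles(profiles, seed=seed)

    def summary(self) -> str:
        if not len(self.table):
            return "State enrichment: no evaluable (RNA, chromosome, label) rows"
        lines = [
            f"State enrichment over {self.table['rna_id'].nunique()} RNAs, "
            f"{len(self.model.tracks)} annotations",
        ]
        by_label = (
            self.table.groupby(["annotation", "label"])["log2_oe"].mean().dropna().sort_values()
        )
        lines.append("  mean log2 O/E per label:")
        lines.extend(f"    {ann}:{lab}  {v:+.3f}" for (ann, lab), v in by_label.items())
        return "\n".join(lines)
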