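"""Coupled synthetic Hi-C and RNA-DNA datasets with planted effects.

The generator emulates the features of real data the pipeline depends
on: distance-decaying Hi-C counts with planted TADs, loop dots and an
A/B compartment checkerboard; RNA contact tracks whose density decays
with distance from the source gene (RD-scaling); and planted subsets of
RNAs whose contacts preferentially co-occur at Hi-C-linked bin pairs,
at loop anchors, or within chosen chromatin states. Every planted
effect has a known magnitude, giving each downstream stage a
ground-truth recovery surface. Fixing the seed fixes every output.

Hi-C counts are independent Poisson draws around the structured mean;
RD-scaling uses the parametric law p(x) ~ (1 + |x - gene| / s)^(-gamma).
The ``hic_paired`` effect places a fraction of an RNA's cis contacts as
pairs whose bins are drawn directly from the significant-interaction
list; ``state_pref`` does the same with pair-sampling odds multiplied
for peaks whose both anchors carry the chosen state label, so the
multiplier is interpretable as the expected observed/expected ratio of
the downstream enrichment statistic; ``loop_anchor`` multiplies the
per-base placement density inside expanded loop anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, IntervalIndex
from .hic import HiCMatrix, SignificantInteractionSet
from . import io

#: placement grid resolution in bp for contact sampling
GRID = 1_000

VALID_TAGS = ("none", "hic_paired", "loop_anchor", "state_pref")


@dataclass
class RnaSpec:
    """One simulated RNA: its gene, contact budget and planted effect."""

    rna_id: str
    biotype: str
    gene: GenomicInterval
    n_contacts: int
    scale: float = 200_000.0  # RD-scaling scale s; inf -> uniform cis
    gamma: float = 1.0
    trans_fraction: float = 0.0
    tag: str = "none"
    multiplier: float = 1.0
    paired_fraction: float = 0.9  # used by state_pref pair placement
    state_label: str | None = None
    state_annotation: str = "chromhmm"

    def __post_init__(self):
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown planted-effect tag {self.tag!r}")
        if self.multiplier < 1 and self.tag != "hic_paired":
            raise ValueError("effect multipliers must be >= 1")
        if self.tag == "hic_paired" and not (0 <= self.multiplier <= 1):
            raise ValueError("hic_paired multiplier is the paired fraction in [0, 1]")


@dataclass
class SimulationSpec:
    """Full description of one synthetic study."""

    genome: Genome
    bin_size: int = 10_000
    # Hi-C mean structure: base * (1 + d/d0)^(-alpha) * factors
    hic_base: float = 10.0
    hic_d0: float = 50_000.0
    hic_alpha: float = 1.0
    inter_base: float = 0.2
    tad_size: int = 200_000
    tad_factor: float = 1.0
    n_loops_per_chrom: int = 0
    loop_factor: float = 1.0
    loop_sep_range: tuple[int, int] = (500_000, 5_000_000)
    #: keep loop anchors at least this far from chromosome ends, so a
    #: shifted background image always exists (negligible on real-genome
    #: scales, material on short synthetic chromosomes)
    loop_margin: int = 0
    compartment_block: int = 200_000
    compartment_factor: float = 1.0
    # annotation name -> (labels, block size in bp)
    state_annotations: dict = field(default_factory=dict)
    rnas: list[RnaSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class Annotations:
    """Planted structural annotations shared by the generators."""

    tads: pd.DataFrame
    loops: pd.DataFrame
    compartments: pd.DataFrame
    states: dict[str, pd.DataFrame]


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring downstream."""

    rna_tags: dict[str, dict]
    annotations: Annotations

    def rnas_with_tag(self, tag: str) -> set[str]:
        return {r for r, info in self.rna_tags.items() if info["tag"] == tag}

    def to_jsonable(self) -> dict:
        return {"rna_tags": self.rna_tags}


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def generate_genome_and_annotations(spec: SimulationSpec) -> tuple[Genome, Annotations, GroundTruth]:
    """Plant TADs, loops, compartments and state tracks on the genome.

    TADs tile each chromosome without overlap (a short remainder domain
    closes the chromosome); loop anchors fall on bin boundaries;
    compartment labels alternate in fixed-size blocks; state labels are
    drawn per block, deterministically under the seed.
    """
    rng = _rng(spec, 1)
    genome = spec.genome
    B = spec.bin_size
    tad_rows, comp_rows, loop_rows = [], [], []
    states: dict[str, list] = {name: [] for name in spec.state_annotations}
    for chrom in genome:
        length = genome.length(chrom)
        if spec.tad_size > length:
            raise ValueError(f"TAD size {spec.tad_size} exceeds chromosome {chrom} length")
        for start in range(0, length, spec.tad_size):
            tad_rows.append((chrom, start, min(start + spec.tad_size, length)))
        for i, start in enumerate(range(0, length, spec.compartment_block)):
            comp_rows.append((chrom, start, min(start + spec.compartment_block, length), "AB"[i % 2]))
        for name, (labels, block) in spec.state_annotations.items():
            for start in range(0, length, block):
                states[name].append((chrom, start, min(start + block, length), str(rng.choice(labels))))
        n_bins = genome.n_bins(chrom, B)
        margin = spec.loop_margin // B
        min_sep = max(1, spec.loop_sep_range[0] // B)
        max_sep = min(n_bins - 2 - 2 * margin, spec.loop_sep_range[1] // B)
        placed = set()
        while len(placed) < spec.n_loops_per_chrom and max_sep >= min_sep:
            sep = int(rng.integers(min_sep, max_sep + 1))
            a = int(rng.integers(margin, n_bins - sep - margin))
            if (a, a + sep) not in placed:
                placed.add((a, a + sep))
        for a, b in sorted(placed):
            loop_rows.append((chrom, a * B, (a + 1) * B, chrom, b * B, (b + 1) * B))
    ann = Annotations(
        tads=pd.DataFrame(tad_rows, columns=["chrom", "start", "end"]),
        loops=pd.DataFrame(loop_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]),
        compartments=pd.DataFrame(comp_rows, columns=["chrom", "start", "end", "name"]),
        states={
            name: pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
            for name, rows in states.items()
        },
    )
    truth = GroundTruth(
        rna_tags={
            r.rna_id: {"tag": r.tag, "multiplier": r.multiplier, "state_label": r.state_label}
            for r in spec.rnas
        },
        annotations=ann,
    )
    return genome, ann, truth


def _block_label_per_bin(track: pd.DataFrame, chrom: str, n_bins: int, bin_size: int) -> np.ndarray:
    """Label covering each bin midpoint (for non-overlapping block tracks)."""
    idx = IntervalIndex(track["chrom"], track["start"], track["end"], track["name"])
    mids = np.arange(n_bins) * bin_size + bin_size // 2
    return idx.labels_at(chrom, mids)


def generate_hic_counts(spec: SimulationSpec, ann: Annotations) -> list[HiCMatrix]:
    """Poisson Hi-C counts around the planted mean structure.

    Intra pair (i, j): base * (1 + d/d0)^(-alpha) * TAD factor (both
    bins in one TAD) * loop factor (planted dot) * compartment factor
    (same label). Inter pair: inter_base * compartment factor. Matrices
    are upper-triangular; only non-zero draws are stored.
    """
    if min(spec.hic_base, spec.inter_base) < 0 or min(spec.tad_factor, spec.loop_factor, spec.compartment_factor) < 0:
        raise ValueError("mean parameters must be non-negative")
    rng = _rng(spec, 2)
    genome, B = spec.genome, spec.bin_size
    chroms = list(genome)
    tad_ids, comp = {}, {}
    for chrom in chroms:
        n = genome.n_bins(chrom, B)
        mids = np.arange(n) * B + B // 2
        tad_ids[chrom] = np.minimum(mids // spec.tad_size, genome.length(chrom) // spec.tad_size)
        comp[chrom] = _block_label_per_bin(ann.compartments[ann.compartments["chrom"] == chrom], chrom, n, B)
    matrices = []
    for ci, chrom in enumerate(chroms):
        n = genome.n_bins(chrom, B)
        ii, jj = np.triu_indices(n)
        d = (jj - ii) * B
        mean = spec.hic_base * (1.0 + d / spec.hic_d0) ** (-spec.hic_alpha)
        mean = np.where(tad_ids[chrom][ii] == tad_ids[chrom][jj], mean * spec.tad_factor, mean)
        mean = np.where(comp[chrom][ii] == comp[chrom][jj], mean * spec.compartment_factor, mean)
        dots = ann.loops[ann.loops["chrom1"] == chrom]
        if len(dots) and spec.loop_factor != 1.0:
            codes = ii.astype(np.int64) * n + jj
            dot_codes = (dots["start1"].to_numpy() // B) * n + dots["start2"].to_numpy() // B
            mean = np.where(np.isin(codes, dot_codes), mean * spec.loop_factor, mean)
        counts = rng.poisson(mean)
        nz = counts > 0
        matrices.append(HiCMatrix(chrom, chrom, B, ii[nz], jj[nz], counts[nz], n, n))
        for chrom_b in chroms[ci + 1 :]:
            nb = genome.n_bins(chrom_b, B)
            ia, ib = np.meshgrid(np.arange(n), np.arange(nb), indexing="ij")
            ia, ib = ia.ravel(), ib.ravel()
            mean = np.where(
                comp[chrom][ia] == comp[chrom_b][ib],
                spec.inter_base * spec.compartment_factor,
                spec.inter_base,
            )
            counts = rng.poisson(mean)
            nz = counts > 0
            matrices.append(HiCMatrix(chrom, chrom_b, B, ia[nz], ib[nz], counts[nz], n, nb))
    return matrices


def _rd_weights(spec: SimulationSpec, rna: RnaSpec) -> np.ndarray:
    """RD-scaling placement weight per GRID cell on the gene chromosome."""
    length = spec.genome.length(rna.gene.chrom)
    centers = np.arange(0, length, GRID) + GRID / 2
    if math.isinf(rna.scale):
        return np.ones(len(centers))
    dist = np.abs(centers - rna.gene.midpoint)
    return (1.0 + dist / rna.scale) ** (-rna.gamma)


def _expanded_anchor_cells(spec: SimulationSpec, chrom: str, loops: pd.DataFrame,
                           expansion_bins: int = 5) -> np.ndarray:
    """Boolean GRID-cell mask of expanded loop anchors on *chrom*."""
    length = spec.genome.length(chrom)
    mask = np.zeros(math.ceil(length / GRID), dtype=bool)
    half = (expansion_bins // 2) * spec.bin_size
    sub = loops[loops["chrom1"] == chrom]
    for _, row in sub.iterrows():
        for start, end in ((row["start1"], row["end1"]), (row["start2"], row["end2"])):
            mid = (start + end) // 2
            bin_start = (mid // spec.bin_size) * spec.bin_size
            lo = max(0, (bin_start - half) // GRID)
            hi = min(len(mask), (bin_start + spec.bin_size + half + GRID - 1) // GRID)
            mask[lo:hi] = True
    return mask


def _sample_positions(rng, weights: np.ndarray, n: int, length: int) -> np.ndarray:
    """Draw n positions: GRID cell by weight, uniform within the cell."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    total = weights.sum()
    if total <= 0:
        raise ValueError("empty eligible region: all placement weights are zero")
    cells = rng.choice(len(weights), size=n, p=weights / total)
    pos = cells * GRID + rng.integers(0, GRID, size=n)
    return np.minimum(pos, length - 1).astype(np.int64)


def _uniform_in_bin(rng, bins: np.ndarray, bin_size: int, length: int) -> np.ndarray:
    pos = bins * bin_size + rng.integers(0, bin_size, size=len(bins))
    return np.minimum(pos, length - 1).astype(np.int64)


def _bin_carries_label(spec: SimulationSpec, track: pd.DataFrame, chrom: str, label: str) -> np.ndarray:
    """True for bins sharing >= 1 bp with an interval labelled *label*."""
    n = spec.genome.n_bins(chrom, spec.bin_size)
    mask = np.zeros(n, dtype=bool)
    sub = track[(track["chrom"] == chrom) & (track["name"] == label)]
    for _, row in sub.iterrows():
        lo = row["start"] // spec.bin_size
        hi = (row["end"] - 1) // spec.bin_size
        mask[lo : hi + 1] = True
    return mask


def generate_rna_contacts(
    spec: SimulationSpec,
    ann: Annotations,
    peaks: SignificantInteractionSet | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """RNA-DNA contact records for every RNA in the spec.

    Each RNA receives exactly ``n_contacts`` records. Cis positions
    follow the RD-scaling law (optionally reshaped by a planted effect);
    trans positions are uniform over the other chromosomes. RNAs tagged
    ``hic_paired`` or ``state_pref`` require *peaks*.
    """
    rng = _rng(spec, 3)
    genome, B = spec.genome, spec.bin_size
    rows = []
    for rna in spec.rnas:
        if rna.tag in ("hic_paired", "state_pref") and peaks is None:
            raise ValueError(f"RNA {rna.rna_id}: planted tag {rna.tag} needs a significant-interaction set")
        chrom = rna.gene.chrom
        length = genome.length(chrom)
        n_trans = int(round(rna.trans_fraction * rna.n_contacts))
        n_cis = rna.n_contacts - n_trans
        weights = _rd_weights(spec, rna)
        cis_positions = []
        if rna.tag == "loop_anchor" and rna.multiplier != 1.0:
            mask = _expanded_anchor_cells(spec, chrom, ann.loops)
            weights = np.where(mask, weights * rna.multiplier, weights)
        if rna.tag in ("hic_paired", "state_pref"):
            frac = rna.multiplier if rna.tag == "hic_paired" else rna.paired_fraction
            n_paired = int(round(frac * n_cis)) // 2 * 2
            scope = peaks.subset_scope(chrom, chrom)
            scope = scope[scope["bin_a"] != scope["bin_b"]]
            if len(scope) == 0:
                raise ValueError(f"no intrachromosomal peaks on {chrom} to plant against")
            w = np.ones(len(scope))
            if rna.tag == "state_pref":
                track = ann.states[rna.state_annotation]
                carries = _bin_carries_label(spec, track, chrom, rna.state_label)
                both = carries[scope["bin_a"].to_numpy()] & carries[scope["bin_b"].to_numpy()]
                w = np.where(both, rna.multiplier, 1.0)
            pick = rng.choice(len(scope), size=n_paired // 2, p=w / w.sum())
            ba = scope["bin_a"].to_numpy()[pick]
            bb = scope["bin_b"].to_numpy()[pick]
            cis_positions.append(_uniform_in_bin(rng, ba, B, length))
            cis_positions.append(_uniform_in_bin(rng, bb, B, length))
            n_cis -= n_paired
        cis_positions.append(_sample_positions(rng, weights, n_cis, length))
        cis = np.concatenate(cis_positions)
        for pos in cis:
            rows.append((rna.rna_id, rna.biotype, chrom, rna.gene.start, rna.gene.end,
                         rna.gene.strand or ".", chrom, int(pos)))
        if n_trans:
            others = [c for c in genome if c != chrom]
            if not others:
                raise ValueError("trans contacts requested on a single-chromosome genome")
            lens = np.array([genome.length(c) for c in others], dtype=float)
            t_chroms = rng.choice(len(others), size=n_trans, p=lens / lens.sum())
            for tc in t_chroms:
                pos = int(rng.integers(0, genome.length(others[tc])))
                rows.append((rna.rna_id, rna.biotype, chrom, rna.gene.start, rna.gene.end,
                             rna.gene.strand or ".", others[tc], pos))
    contacts = pd.DataFrame(rows, columns=io.CONTACT_COLUMNS)
    truth = GroundTruth(
        rna_tags={
            r.rna_id: {"tag": r.tag, "multiplier": r.multiplier, "state_label": r.state_label}
            for r in spec.rnas
        },
        annotations=ann,
    )
    return contacts, truth


def write_dataset(
    outdir,
    genome: Genome,
    ann: Annotations,
    contacts: pd.DataFrame,
    matrices: list[HiCMatrix] | None,
    truth: GroundTruth,
) -> None:
    """Write a full synthetic dataset in the pipeline's text dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_chromsizes(genome, outdir / "chrom.sizes")
    io.write_contacts(contacts, outdir / "contacts.tsv")
    io.write_bed(ann.tads, outdir / "tads.bed")
    io.write_bedpe(ann.loops, outdir / "loops.bedpe")
    io.write_bed(ann.compartments, outdir / "compartments.bed")
    for name, track in ann.states.items():
        io.write_bed(track, outdir / f"states.{name}.bed")
    if matrices is not None:
        frames = [
            pd.DataFrame(
                {"chrom_a": m.chrom_a, "bin_a": m.bin_a, "chrom_b": m.chrom_b,
                 "bin_b": m.bin_b, "count": m.count}
            )
            for m in matrices
        ]
        io.write_triplets(pd.concat(frames, ignore_index=True), outdir / "hic.triplets.tsv")
    io.write_json(truth.to_jsonable(), outdir / "truth.json")
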