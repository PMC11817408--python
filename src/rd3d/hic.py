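"""Hi-C matrices, significant-interaction ("Hi-C peak") calling and the
shifted background null.

The caller is a simplified distance-stratified count model: the expected
count of an intrachromosomal bin pair is the mean raw count over all
pairs at the same separation (zeros included), with balancing weights
folded in multiplicatively when present; significance is the upper-tail
Poisson probability of the observed raw count, Benjamini-Hochberg
adjusted within each chromosome (intra) or chromosome pair (inter).
The background null shifts every significant pair along the diagonal
(intra) or along each axis (inter) by a fixed genomic distance while
requiring the shifted anchors to keep their A/B compartment labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, IntervalIndex, bin_midpoint
from .stats import bh_adjust, poisson_upper_tail

PEAK_COLUMNS = ["chrom_a", "bin_a", "chrom_b", "bin_b", "p", "q"]


@dataclass
class HiCMatrix:
    """Sparse binned contact counts for one chromosome pair.

    Intrachromosomal matrices are stored upper-triangular
    (``bin_a <= bin_b``). ``weights`` maps chromosome name to a per-bin
    balancing weight vector (mean-normalised on use); optional.
    """

    chrom_a: str
    chrom_b: str
    bin_size: int
    bin_a: np.ndarray
    bin_b: np.ndarray
    count: np.ndarray
    n_bins_a: int
    n_bins_b: int
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.bin_a = np.asarray(self.bin_a, dtype=np.int64)
        self.bin_b = np.asarray(self.bin_b, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")
        if self.is_intra and np.any(self.bin_a > self.bin_b):
            raise ValueError("intra matrices must be stored upper-triangular")

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def separations(self) -> np.ndarray:
        return self.bin_b - self.bin_a

    @classmethod
    def from_triplets(cls, df: pd.DataFrame, genome: Genome, bin_size: int,
                      chrom_a: str, chrom_b: str, weights=None) -> "HiCMatrix":
        sub = df[(df["chrom_a"] == chrom_a) & (df["chrom_b"] == chrom_b)]
        ba, bb = sub["bin_a"].to_numpy(), sub["bin_b"].to_numpy()
        if chrom_a == chrom_b:
            ba, bb = np.minimum(ba, bb), np.maximum(ba, bb)
        return cls(
            chrom_a, chrom_b, bin_size, ba, bb, sub["count"].to_numpy(),
            genome.n_bins(chrom_a, bin_size), genome.n_bins(chrom_b, bin_size),
            weights or {},
        )


@dataclass
class ExpectedModel:
    """Expected raw count per distance stratum (intra) or globally (inter)."""

    is_intra: bool
    expected_by_sep: np.ndarray | None = None  # indexed by bin separation
    global_expected: float = float("nan")

    def expected_for(self, matrix: HiCMatrix) -> np.ndarray:
        if self.is_intra:
            exp = self.expected_by_sep[matrix.separations]
        else:
            exp = np.full(len(matrix.bin_a), self.global_expected)
        wa = matrix.weights.get(matrix.chrom_a)
        wb = matrix.weights.get(matrix.chrom_b)
        if wa is not None and wb is not None:
            wa = wa / np.nanmean(wa)
            wb = wb / np.nanmean(wb)
            exp = exp * wa[matrix.bin_a] * wb[matrix.bin_b]
        return exp

    @property
    def smallest_positive(self) -> float:
        if self.is_intra:
            pos = self.expected_by_sep[self.expected_by_sep > 0]
            return float(pos.min()) if pos.size else np.nan
        return self.global_expected if self.global_expected > 0 else np.nan


def expected_by_distance(matrix: HiCMatrix, pool: str = "exact", n_strata: int = 50) -> ExpectedModel:
    """Distance-decay expected model for one intrachromosomal matrix.

    expected(d) = (sum of stored counts at separation d) / (number of
    bin pairs at separation d), i.e. the mean over all pairs including
    zero entries. With ``pool='log'`` separations are pooled into
    log-spaced strata (useful for sparse matrices); the default keeps
    one stratum per separation.
    """
    if not matrix.is_intra:
        raise ValueError("expected_by_distance applies to intrachromosomal matrices")
    n = matrix.n_bins_a
    if n == 0 or len(matrix.bin_a) == 0:
        raise ValueError("empty matrix")
    seps = matrix.separations
    sums = np.bincount(seps, weights=matrix.count, minlength=n)
    n_pairs = n - np.arange(n)  # pairs at separation d on an n-bin chromosome
    if pool == "exact":
        expected = sums / n_pairs
    elif pool == "log":
        edges = np.unique(np.geomspace(1, n, num=n_strata).astype(np.int64))
        edges = np.concatenate([[0], edges])
        strat = np.searchsorted(edges, np.arange(n), side="right") - 1
        strat_sum = np.bincount(strat, weights=sums, minlength=len(edges))
        strat_pairs = np.bincount(strat, weights=n_pairs, minlength=len(edges))
        with np.errstate(invalid="ignore"):
            expected = (strat_sum / strat_pairs)[strat]
    else:
        raise ValueError(f"unknown pooling mode {pool!r}")
    return ExpectedModel(is_intra=True, expected_by_sep=expected)


def expected_inter(matrix: HiCMatrix) -> ExpectedModel:
    """Global expected count for an interchromosomal matrix (mean over all pairs)."""
    if matrix.is_intra:
        raise ValueError("expected_inter applies to interchromosomal matrices")
    total_pairs = matrix.n_bins_a * matrix.n_bins_b
    return ExpectedModel(is_intra=False, global_expected=float(matrix.count.sum()) / total_pairs)


class SignificantInteractionSet:
    """Called (or imported) significant Hi-C bin pairs with p and q values.

    The table has columns chrom_a, bin_a, chrom_b, bin_b, p, q; intra
    pairs are normalised to ``bin_a <= bin_b``. Each retained pair has
    q <= the FDR threshold recorded on the set.
    """

    def __init__(self, table: pd.DataFrame, fdr: float, bin_size: int, provenance: str = "called"):
        table = table[PEAK_COLUMNS].copy()
        intra = table["chrom_a"] == table["chrom_b"]
        ba, bb = table["bin_a"].to_numpy().copy(), table["bin_b"].to_numpy().copy()
        swap = intra.to_numpy() & (ba > bb)
        ba[swap], bb[swap] = table["bin_b"].to_numpy()[swap], table["bin_a"].to_numpy()[swap]
        table["bin_a"], table["bin_b"] = ba, bb
        table = table.drop_duplicates(["chrom_a", "bin_a", "chrom_b", "bin_b"]).reset_index(drop=True)
        if (table["q"] > fdr + 1e-12).any():
            raise ValueError("retained pair exceeds the FDR threshold")
        self.table = table
        self.fdr = fdr
        self.bin_size = bin_size
        self.provenance = provenance
        self._cache: dict[tuple[str, str], frozenset] = {}

    def __len__(self) -> int:
        return len(self.table)

    def scopes(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.table["chrom_a"], self.table["chrom_b"])))

    def pair_set(self, chrom_a: str, chrom_b: str) -> frozenset:
        """Unordered bin-pair lookup set for one scope (order-normalised)."""
        key = (chrom_a, chrom_b)
        if key not in self._cache:
            m = (self.table["chrom_a"] == chrom_a) & (self.table["chrom_b"] == chrom_b)
            sub = self.table[m]
            self._cache[key] = frozenset(zip(sub["bin_a"].tolist(), sub["bin_b"].tolist()))
        return self._cache[key]

    def subset_scope(self, chrom_a: str, chrom_b: str) -> pd.DataFrame:
        m = (self.table["chrom_a"] == chrom_a) & (self.table["chrom_b"] == chrom_b)
        return self.table[m]


def call_significant_interactions(
    matrices: list[HiCMatrix],
    models: list[ExpectedModel],
    fdr: float,
) -> SignificantInteractionSet:
    """Upper-tail Poisson test of stored counts against the expected model.

    BH is applied within each matrix (one chromosome intra, one
    chromosome pair inter) over its non-zero entries; pairs with
    q <= *fdr* are retained. An expected value of zero with a positive
    observation is replaced by the model's smallest positive expected
    value to avoid zero p-values.
    """
    frames = []
    bin_size = matrices[0].bin_size if matrices else 0
    for matrix, model in zip(matrices, models):
        mask = matrix.count > 0
        if not mask.any():
            continue
        exp = model.expected_for(matrix)[mask]
        obs = matrix.count[mask]
        exp = np.where(exp <= 0, model.smallest_positive, exp)
        p = poisson_upper_tail(obs, exp)
        q = bh_adjust(p)
        keep = q <= fdr
        if keep.any():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom_a": matrix.chrom_a,
                        "bin_a": matrix.bin_a[mask][keep],
                        "chrom_b": matrix.chrom_b,
                        "bin_b": matrix.bin_b[mask][keep],
                        "p": p[keep],
                        "q": q[keep],
                    }
                )
            )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=PEAK_COLUMNS)
    )
    return SignificantInteractionSet(table, fdr=fdr, bin_size=bin_size)


def import_fithic(df: pd.DataFrame, bin_size: int, fdr: float) -> SignificantInteractionSet:
    """Adopt a FitHiC2-style significant-interaction table verbatim.

    Fragment midpoints are mapped to bin indices; rows with q > *fdr*
    are dropped. Provenance is recorded as "imported".
    """
    out = pd.DataFrame(
        {
            "chrom_a": df["chr1"],
            "bin_a": df["fragmentMid1"].to_numpy() // bin_size,
            "chrom_b": df["chr2"],
            "bin_b": df["fragmentMid2"].to_numpy() // bin_size,
            "p": df["p"],
            "q": df["q"],
        }
    )
    return SignificantInteractionSet(out[out["q"] <= fdr], fdr=fdr, bin_size=bin_size, provenance="imported")


def compartment_bin_labels(compartments: pd.DataFrame | None, genome: Genome, bin_size: int) -> dict[str, np.ndarray]:
    """Per-bin compartment label (label covering the bin midpoint) per chromosome."""
    out = {}
    if compartments is None:
        return out
    index = IntervalIndex(
        compartments["chrom"], compartments["start"], compartments["end"], compartments["name"]
    )
    for chrom in genome:
        n = genome.n_bins(chrom, bin_size)
        mids = np.minimum(bin_midpoint(np.arange(n), bin_size), genome.length(chrom) - 1)
        out[chrom] = index.labels_at(chrom, mids)
    return out


def shift_interactions(
    peaks: SignificantInteractionSet,
    shift: int,
    genome: Genome,
    compartments: pd.DataFrame | None = None,
) -> SignificantInteractionSet:
    """Shifted-map background null for a significant-interaction set.

    Intra pairs move along the main diagonal by ``shift`` (preserving the
    pair separation); inter pairs move by ``shift`` along each axis
    independently. A shifted pair is kept only when both new anchors
    carry the same A/B compartment label as the corresponding original
    anchors; if the +shift image fails (out of range or label mismatch)
    the -shift image is tried, otherwise the pair is dropped. The output
    is never larger than the input.
    """
    bin_size = peaks.bin_size
    if shift % bin_size:
        raise ValueError("shift must be a multiple of the bin size")
    s = shift // bin_size
    if compartments is None:
        warnings.warn("no compartment track supplied; falling back to a pure shift")
    labels = compartment_bin_labels(compartments, genome, bin_size)

    def bin_ok(chrom: str, b: int) -> bool:
        return 0 <= b < genome.n_bins(chrom, bin_size)

    def label_match(chrom: str, orig: int, new: int) -> bool:
        if chrom not in labels:
            return True
        lab = labels[chrom]
        return lab[orig] == lab[new]

    rows = []
    t = peaks.table
    for ca, ba, cb, bb, p, q in zip(t["chrom_a"], t["bin_a"], t["chrom_b"], t["bin_b"], t["p"], t["q"]):
        if ca == cb:
            # along the main diagonal: separation is preserved
            deltas = [(s, s), (-s, -s)]
        else:
            # each axis may take either direction independently
            deltas = [(s, s), (s, -s), (-s, s), (-s, -s)]
        for da, db in deltas:
            na, nb = ba + da, bb + db
            if (
                bin_ok(ca, na)
                and bin_ok(cb, nb)
                and label_match(ca, ba, na)
                and label_match(cb, bb, nb)
            ):
                rows.append((ca, na, cb, nb, p, q))
                break
    table = pd.DataFrame(rows, columns=PEAK_COLUMNS) if rows else pd.DataFrame(columns=PEAK_COLUMNS)
    return SignificantInteractionSet(table, fdr=peaks.fdr, bin_size=bin_size, provenance="shifted")
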