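"""Parental-TAD assignment, OutInDR and TAD metaplots."""

import numpy as np
import pandas as pd
import pytest

from rd3d.genome import Genome, GenomicInterval
from rd3d.tads import (
    OutInDRModel,
    TadSet,
    assign_parental_tad,
    compare_biotypes,
    compute_outindr,
    correlate_experiments,
    tad_metaplot,
)
from tests.conftest import make_contacts


def tads_from(intervals, chrom="chr1"):
    return TadSet(pd.DataFrame([(chrom, s, e) for s, e in intervals], columns=["chrom", "start", "end"]))


def test_parental_tad_majority_rule():
    tads = tads_from([(0, 100_000), (100_000, 200_000)])
    # 15 kb gene, 10 kb overlap with first TAD > half (7.5 kb)
    tad = assign_parental_tad(GenomicInterval("chr1", 90_000, 105_000), tads)
    assert (tad.start, tad.end) == (0, 100_000)
    # exact half split -> unassigned
    assert assign_parental_tad(GenomicInterval("chr1", 95_000, 105_000), tads) is None
    # fully inside
    inside = assign_parental_tad(GenomicInterval("chr1", 120_000, 130_000), tads)
    assert (inside.start, inside.end) == (100_000, 200_000)


def test_tadset_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        tads_from([(0, 100_000), (50_000, 200_000)])


def test_outindr_toy_case():
    tad = GenomicInterval("chr1", 0, 100_000)
    res = compute_outindr(10, 9, tad, 1_000_000)
    assert res["outindr"] == pytest.approx(0.1)
    assert res["neg_log10_outindr"] == pytest.approx(1.0)
    assert res["density_in"] == pytest.approx(1e-4)
    assert res["density_out"] == pytest.approx(1e-5)


def test_outindr_exclusions():
    tad = GenomicInterval("chr1", 0, 100_000)
    assert compute_outindr(5, 4, tad, 1_000_000)["excluded"] == "below_min_cis"
    assert compute_outindr(20, 0, tad, 1_000_000)["excluded"] == "no_outside_contacts"
    assert compute_outindr(0, 20, tad, 1_000_000)["excluded"] == "no_inside_contacts"
    with pytest.raises(ValueError):
        compute_outindr(10, 10, GenomicInterval("chr1", 0, 100_000), 50_000)


def test_outindr_model_counts_cis_only():
    genome = Genome({"chr1": 1_000_000, "chr2": 1_000_000})
    tads = tads_from([(0, 100_000), (100_000, 1_000_000)])
    rows = [("r", "lncRNA", "chr1", 10_000, 20_000, "chr1", p) for p in range(0, 100_000, 10_000)]
    rows += [("r", "lncRNA", "chr1", 10_000, 20_000, "chr1", 500_000 + p) for p in range(0, 90_000, 10_000)]
    rows += [("r", "lncRNA", "chr1", 10_000, 20_000, "chr2", 5_000)]  # trans ignored
    res = OutInDRModel(make_contacts(rows), tads, genome).fit()
    row = res.table.iloc[0]
    assert (row["n_in"], row["n_out"]) == (10, 9)
    assert row["outindr"] == pytest.approx(0.1)


def test_biotype_comparison():
    records = pd.DataFrame(
        {
            "biotype": ["mRNA"] * 3 + ["lncRNA"] * 3,
            "neg_log10_outindr": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    out = compare_biotypes(records)
    assert out.iloc[0]["p"] == pytest.approx(0.1)
    identical = pd.DataFrame(
        {"biotype": ["a"] * 3 + ["b"] * 3, "neg_log10_outindr": [1.0, 2.0, 3.0] * 2}
    )
    assert compare_biotypes(identical).iloc[0]["p"] == 1.0
    with pytest.raises(ValueError):
        compare_biotypes(records.iloc[:3])


def test_correlations_identity_reverse_and_orthologs():
    a = pd.DataFrame({"rna_id": list("abcde"), "neg_log10_outindr": [1, 2, 3, 4, 5.0]})
    b_same = a.copy()
    assert correlate_experiments(a, b_same)["scc"] == pytest.approx(1.0)
    b_rev = a.assign(neg_log10_outindr=[5, 4, 3, 2, 1.0])
    assert correlate_experiments(a, b_rev)["scc"] == pytest.approx(-1.0)
    b_orth = pd.DataFrame({"rna_id": list("vwxyz"), "neg_log10_outindr": [1, 2, 3, 4, 5.0]})
    id_map = pd.DataFrame({"gene_a": list("abcde"), "gene_b": list("vwxyz")})
    out = correlate_experiments(a, b_orth, id_map)
    assert out["scc"] == pytest.approx(1.0) and out["n_shared"] == 5
    with pytest.raises(ValueError, match="shared genes"):
        correlate_experiments(a.iloc[:2], b_same.iloc[:2])


def test_correlation_recovers_planted_signal():
    rng = np.random.default_rng(0)
    sccs = []
    for _ in range(20):
        shared = rng.normal(size=200)
        xa = 0.775 * shared + np.sqrt(1 - 0.775**2) * rng.normal(size=200)
        xb = 0.775 * shared + np.sqrt(1 - 0.775**2) * rng.normal(size=200)
        a = pd.DataFrame({"rna_id": [f"g{i}" for i in range(200)], "neg_log10_outindr": xa})
        b = pd.DataFrame({"rna_id": [f"g{i}" for i in range(200)], "neg_log10_outindr": xb})
        sccs.append(correlate_experiments(a, b)["scc"])
    # Pearson rho 0.6 between the pair; Spearman close to it
    assert abs(np.mean(sccs) - 0.58) < 0.15


def test_tad_metaplot_boundary_recovery():
    """Contacts planted 2x at TAD-boundary bins show up as boundary peaks."""
    genome = Genome({"chr1": 10_000_000})
    tads = tads_from([(s, s + 500_000) for s in range(0, 10_000_000, 500_000)])
    rng = np.random.default_rng(4)
    rows = []
    for g in range(20):
        gene_start = 1_000_000 + g * 400_000
        gene = ("chr1", gene_start, gene_start + 10_000)
        tad_start = (gene_start // 500_000) * 500_000
        for _ in range(300):
            rows.append((f"r{g}", "lncRNA", *gene, "chr1", int(rng.integers(0, 10_000_000))))
        # extra contacts at the parental TAD boundaries (10 kb bins at the edges)
        for _ in range(60):
            edge = tad_start if rng.random() < 0.5 else tad_start + 490_000
            rows.append((f"r{g}", "lncRNA", *gene, "chr1", int(edge + rng.integers(0, 10_000))))
    prof = tad_metaplot(make_contacts(rows), tads, genome, top_n=100)
    rel = prof["rel_coord"].to_numpy()
    profile = prof["mean_profile"].to_numpy()
    at_bounds = profile[(np.abs(rel) < 0.05) | (np.abs(rel - 1) < 0.05)].mean()
    interior = profile[(rel > 0.2) & (rel < 0.8)].mean()
    assert at_bounds / interior > 1.5
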