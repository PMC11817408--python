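"""Synthetic-data generator: determinism, null reductions, planted effects."""

import numpy as np
import pytest
from scipy import stats as sps

from rd3d import io
from rd3d.genome import Genome, GenomicInterval
from rd3d.simulate import (
    RnaSpec,
    SimulationSpec,
    generate_genome_and_annotations,
    generate_hic_counts,
    generate_rna_contacts,
    write_dataset,
)


def basic_spec(seed=0, **overrides):
    genome = Genome({"chr1": 2_000_000, "chr2": 2_000_000})
    defaults = dict(
        genome=genome,
        bin_size=10_000,
        tad_size=200_000,
        compartment_block=200_000,
        rnas=[
            RnaSpec("r1", "lncRNA", GenomicInterval("chr1", 500_000, 510_000), 100, scale=50_000.0),
            RnaSpec("r2", "mRNA", GenomicInterval("chr2", 100_000, 110_000), 100, scale=float("inf"), trans_fraction=0.2),
        ],
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


def test_tads_tile_chromosomes():
    spec = basic_spec()
    _, ann, _ = generate_genome_and_annotations(spec)
    per_chrom = ann.tads.groupby("chrom").size()
    assert per_chrom["chr1"] == 10 and per_chrom["chr2"] == 10
    for _, sub in ann.tads.groupby("chrom"):
        assert sub["start"].iloc[0] == 0
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


def test_tad_longer_than_chromosome_rejected():
    with pytest.raises(ValueError, match="TAD size"):
        generate_genome_and_annotations(basic_spec(tad_size=5_000_000))


def test_loop_anchors_on_bin_boundaries():
    spec = basic_spec(n_loops_per_chrom=15, loop_sep_range=(100_000, 1_000_000))
    _, ann, _ = generate_genome_and_annotations(spec)
    assert (ann.loops["start1"] % spec.bin_size == 0).all()
    assert (ann.loops["start2"] % spec.bin_size == 0).all()
    assert len(ann.loops) == 30


def test_same_seed_identical_outputs(tmp_path):
    outputs = []
    for d in ("a", "b"):
        spec = basic_spec(n_loops_per_chrom=5, seed=42)
        genome, ann, truth = generate_genome_and_annotations(spec)
        matrices = generate_hic_counts(spec, ann)
        contacts, truth = generate_rna_contacts(spec, ann)
        out = tmp_path / d
        write_dataset(out, genome, ann, contacts, matrices, truth)
        outputs.append({p.name: p.read_bytes() for p in sorted(out.iterdir())})
    assert outputs[0] == outputs[1]


def test_roundtrip_through_readers(tmp_path):
    spec = basic_spec(n_loops_per_chrom=5, state_annotations={"chromhmm": (["a", "b"], 50_000)})
    genome, ann, truth = generate_genome_and_annotations(spec)
    matrices = generate_hic_counts(spec, ann)
    contacts, truth = generate_rna_contacts(spec, ann)
    write_dataset(tmp_path, genome, ann, contacts, matrices, truth)
    assert io.read_chromsizes(tmp_path / "chrom.sizes") == genome
    back = io.read_contacts(tmp_path / "contacts.tsv", genome)
    assert len(back) == len(contacts)
    trip = io.read_triplets(tmp_path / "hic.triplets.tsv")
    assert trip["count"].sum() == sum(m.count.sum() for m in matrices)
    assert len(io.read_bed(tmp_path / "states.chromhmm.bed")) == len(ann.states["chromhmm"])


def test_exact_contact_budget_and_trans_fraction():
    spec = basic_spec()
    _, ann, _ = generate_genome_and_annotations(spec)
    contacts, _ = generate_rna_contacts(spec, ann)
    sizes = contacts.groupby("rna_id").size()
    assert sizes["r1"] == 100 and sizes["r2"] == 100
    r2 = contacts[contacts["rna_id"] == "r2"]
    assert (r2["dna_chrom"] == "chr1").sum() == 20  # trans fraction 0.2


def test_infinite_scale_is_uniform():
    genome = Genome({"chr1": 2_000_000})
    spec = basic_spec(
        genome=genome,
        rnas=[RnaSpec("u", "mRNA", GenomicInterval("chr1", 1_000_000, 1_010_000), 5_000, scale=float("inf"))],
    )
    _, ann, _ = generate_genome_and_annotations(spec)
    contacts, _ = generate_rna_contacts(spec, ann)
    pos = contacts["dna_pos"].to_numpy()
    assert sps.kstest(pos / 2_000_000, "uniform").pvalue > 0.01


def test_rd_scaling_concentrates_near_gene():
    genome = Genome({"chr1": 2_000_000})
    spec = basic_spec(
        genome=genome,
        rnas=[RnaSpec("r", "mRNA", GenomicInterval("chr1", 1_000_000, 1_010_000), 5_000, scale=30_000.0, gamma=2.0)],
    )
    _, ann, _ = generate_genome_and_annotations(spec)
    contacts, _ = generate_rna_contacts(spec, ann)
    dist = np.abs(contacts["dna_pos"] - 1_005_000)
    assert np.median(dist) < 200_000


def test_hic_counts_follow_decay_law():
    genome = Genome({"chr1": 3_000_000})
    spec = basic_spec(genome=genome, rnas=[], hic_base=20.0, hic_d0=50_000.0, hic_alpha=1.0)
    _, ann, _ = generate_genome_and_annotations(spec)
    (m,) = [x for x in generate_hic_counts(spec, ann) if x.is_intra]
    # no TAD/loop/compartment factors: empirical mean at each separation
    # matches the stated law within sampling error
    seps = m.bin_b - m.bin_a
    n = m.n_bins_a
    for d in (0, 5, 20, 100):
        expected = 20.0 * (1 + d * 10_000 / 50_000.0) ** -1.0
        total = m.count[seps == d].sum()
        n_pairs = n - d
        se = np.sqrt(expected / n_pairs)
        assert abs(total / n_pairs - expected) < 5 * se


def test_zero_base_rate_gives_empty_matrix():
    spec = basic_spec(hic_base=0.0, inter_base=0.0, rnas=[])
    _, ann, _ = generate_genome_and_annotations(spec)
    for m in generate_hic_counts(spec, ann):
        assert len(m.count) == 0


def test_loop_dot_enrichment_factor():
    genome = Genome({"chr1": 2_000_000})
    spec = basic_spec(
        genome=genome, rnas=[], n_loops_per_chrom=10, loop_factor=3.0,
        loop_sep_range=(200_000, 1_000_000), hic_base=50.0, hic_alpha=0.0,
    )
    ratios = []
    for seed in range(25):
        spec.seed = seed
        _, ann, _ = generate_genome_and_annotations(spec)
        (m,) = [x for x in generate_hic_counts(spec, ann) if x.is_intra]
        pair_counts = {(a, b): c for a, b, c in zip(m.bin_a, m.bin_b, m.count)}
        background = np.mean(m.count)  # flat law: every pair has mean 50
        for _, row in ann.loops.iterrows():
            dot = pair_counts.get((row["start1"] // 10_000, row["start2"] // 10_000), 0)
            ratios.append(dot / background)
    assert np.mean(ratios) == pytest.approx(3.0, rel=0.25)


def test_planted_tags_need_peaks():
    spec = basic_spec(
        rnas=[RnaSpec("p", "lncRNA", GenomicInterval("chr1", 0, 10_000), 50, tag="hic_paired", multiplier=0.5)]
    )
    _, ann, _ = generate_genome_and_annotations(spec)
    with pytest.raises(ValueError, match="significant-interaction"):
        generate_rna_contacts(spec, ann, peaks=None)


def test_multiplier_one_matches_null_distribution():
    """loop_anchor with multiplier 1 is indistinguishable from tag=none."""
    genome = Genome({"chr1": 2_000_000})

    def contacts_for(tag, mult, seed):
        spec = basic_spec(
            genome=genome,
            n_loops_per_chrom=10,
            loop_sep_range=(200_000, 1_000_000),
            seed=seed,
            rnas=[RnaSpec("x", "mRNA", GenomicInterval("chr1", 1_000_000, 1_010_000),
                          5_000, scale=100_000.0, tag=tag, multiplier=mult)],
        )
        _, ann, _ = generate_genome_and_annotations(spec)
        c, _ = generate_rna_contacts(spec, ann)
        return c["dna_pos"].to_numpy()

    a = contacts_for("loop_anchor", 1.0, 5)
    b = contacts_for("none", 1.0, 6)
    assert sps.ks_2samp(a, b).pvalue > 0.01


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="tag"):
        RnaSpec("x", "mRNA", GenomicInterval("chr1", 0, 10), 10, tag="bogus")
    with pytest.raises(ValueError, match="multiplier"):
        RnaSpec("x", "mRNA", GenomicInterval("chr1", 0, 10), 10, tag="loop_anchor", multiplier=0.5)
    with pytest.raises(ValueError, match="paired fraction"):
        RnaSpec("x", "mRNA", GenomicInterval("chr1", 0, 10), 10, tag="hic_paired", multiplier=2.0)
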