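"""Loop anchors: shifting, metaplots, per-RNA tests, RBD classification."""

import numpy as np
import pandas as pd
import pytest

from rd3d.genome import Genome
from rd3d.loops import (
    LoopSet,
    anchor_contact_counts,
    anchor_metaplot,
    classify_loops_rbd,
    compare_anchor_contact_distributions,
    expanded_anchor_mask,
    rna_loop_association_test,
    shift_anchors,
)
from tests.conftest import make_contacts


def loopset(pairs, chrom="chr1", width=10_000):
    rows = [
        (chrom, a, a + width, chrom, b, b + width) for a, b in pairs
    ]
    return LoopSet(pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]))


def comp_track(blocks):
    rows = [("chr1", s, e, lab) for s, e, lab in blocks]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def test_loopset_derives_two_anchors_per_loop():
    ls = loopset([(1_000_000, 1_500_000)])
    assert len(ls.anchors) == 2
    assert ls.anchors["midpoint"].tolist() == [1_005_000, 1_505_000]


def test_shift_anchors_compartment_rules():
    genome = Genome({"chr1": 10_000_000})
    anchors = pd.DataFrame({"chrom": ["chr1"], "midpoint": [3_000_000], "loop_id": [0]})
    # uniform A: +2 Mb kept
    comp = comp_track([(0, 10_000_000, "A")])
    out = shift_anchors(anchors, 2_000_000, genome, comp)
    assert out["midpoint"].tolist() == [5_000_000]
    # +2 Mb lands in B, -2 Mb in A -> -2 Mb taken
    comp2 = comp_track([(0, 4_000_000, "A"), (4_000_000, 6_000_000, "B"), (6_000_000, 10_000_000, "A")])
    out2 = shift_anchors(anchors, 2_000_000, genome, comp2)
    assert out2["midpoint"].tolist() == [1_000_000]
    # both shifts land in B -> dropped
    comp3 = comp_track([(0, 2_000_000, "B"), (2_000_000, 4_000_000, "A"), (4_000_000, 10_000_000, "B")])
    out3 = shift_anchors(anchors, 2_000_000, genome, comp3)
    assert len(out3) == 0
    with pytest.raises(ValueError, match="compartment"):
        shift_anchors(anchors, 2_000_000, genome, None)


def test_shift_anchors_preserve_labels_by_construction():
    genome = Genome({"chr1": 10_000_000})
    rng = np.random.default_rng(0)
    blocks = [(i * 500_000, (i + 1) * 500_000, rng.choice(["A", "B"])) for i in range(20)]
    comp = comp_track(blocks)
    from rd3d.genome import IntervalIndex

    idx = IntervalIndex(comp["chrom"], comp["start"], comp["end"], comp["name"])
    anchors = pd.DataFrame(
        {"chrom": "chr1", "midpoint": rng.integers(0, 10_000_000, 40), "loop_id": range(40)}
    )
    out = shift_anchors(anchors, 2_000_000, genome, comp)
    assert len(out) <= len(anchors)
    merged = out.merge(anchors, on="loop_id", suffixes=("_new", "_old"))
    for row in merged.itertuples():
        assert idx.label_at("chr1", row.midpoint_new) == idx.label_at("chr1", row.midpoint_old)


def test_metaplot_has_101_offsets_and_flat_null():
    genome = Genome({"chr1": 20_000_000})
    rng = np.random.default_rng(1)
    contacts = make_contacts(
        [("r", "mRNA", "chr1", 0, 10_000, "chr1", int(p)) for p in rng.integers(0, 20_000_000, 30_000)]
    )
    anchors = pd.DataFrame(
        {"chrom": "chr1", "midpoint": np.arange(1, 25) * 700_000 + 5_000, "loop_id": range(24)}
    )
    bg = anchors.assign(midpoint=anchors["midpoint"] + 2_000_000)
    prof = anchor_metaplot(contacts, anchors, bg, window=500_000, bin_size=10_000)
    assert len(prof) == 101
    assert prof.loc[50, "offset"] == 0
    assert abs(prof["ratio"].mean() - 1) < 0.05


def test_metaplot_window_must_align():
    with pytest.raises(ValueError):
        anchor_metaplot(make_contacts([]), pd.DataFrame({"chrom": [], "midpoint": [], "loop_id": []}),
                        pd.DataFrame({"chrom": [], "midpoint": [], "loop_id": []}),
                        window=505_000, bin_size=10_000)


def test_expanded_anchor_mask_width():
    genome = Genome({"chr1": 1_000_000})
    anchors = pd.DataFrame({"chrom": ["chr1"], "midpoint": [505_000], "loop_id": [0]})
    mask = expanded_anchor_mask(anchors, genome, 10_000, expansion_bins=5)["chr1"]
    assert mask.sum() == 5
    assert mask[48:53].all()


def test_rna_loop_association_counts():
    genome = Genome({"chr1": 10_000_000})
    rows = []
    # 50 contacts inside the expanded anchor at bin 50, 150 elsewhere
    for i in range(50):
        rows.append(("r", "lncRNA", "chr1", 0, 10_000, "chr1", 500_000 + (i % 5) * 6_000))
    for i in range(150):
        rows.append(("r", "lncRNA", "chr1", 0, 10_000, "chr1", 2_000_000 + i * 10_000))
    contacts = make_contacts(rows)
    anchors = pd.DataFrame({"chrom": ["chr1"], "midpoint": [505_000], "loop_id": [0]})
    bg = pd.DataFrame({"chrom": ["chr1"], "midpoint": [8_000_000], "loop_id": [0]})
    table = rna_loop_association_test(contacts, anchors, bg, genome)
    row = table.iloc[0]
    assert row["in_anchor"] == 50 and row["in_background"] == 0
    assert row["odds_ratio"] != row["odds_ratio"] or row["odds_ratio"] > 1  # NaN or > 1


def test_classify_loops_rbd_rules():
    wt = loopset([(1_000_000, 1_500_000), (3_000_000, 4_000_000)])
    mutant = loopset([(1_010_000, 1_490_000)])
    classes = classify_loops_rbd(wt, mutant, tolerance=20_000)
    assert classes.tolist() == ["common", "differential"]
    # nearest mutant anchor 30 kb away -> differential
    mutant2 = loopset([(1_030_000, 1_500_000)])
    assert classify_loops_rbd(wt, mutant2, 20_000).tolist()[0] == "differential"
    # empty mutant set -> all differential
    empty = LoopSet(pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]))
    assert classify_loops_rbd(wt, empty, 20_000).tolist() == ["differential", "differential"]


def test_compare_anchor_distributions():
    out = compare_anchor_contact_distributions([1, 2, 3], [4, 5, 6])
    assert out["p"] == pytest.approx(0.1)
    assert out["direction"] == 1
    same = compare_anchor_contact_distributions([1, 2, 3], [3, 2, 1])
    assert same["p"] == 1.0


def test_anchor_contact_counts():
    genome = Genome({"chr1": 1_000_000})
    contacts = make_contacts(
        [("r", "mRNA", "chr1", 0, 10_000, "chr1", p) for p in (500_001, 505_000, 529_999, 700_000)]
    )
    anchors = pd.DataFrame({"chrom": ["chr1"], "midpoint": [505_000], "loop_id": [0]})
    counts = anchor_contact_counts(contacts, anchors, genome, 10_000, 5)
    assert counts.tolist() == [3]
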