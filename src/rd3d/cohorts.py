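"""Standard synthetic study conditions ("cohorts") with planted effects.

Each cohort function builds one self-contained synthetic study --
genome, annotations, Hi-C, called peaks, shifted background and RNA
contacts -- at a scale a desktop run completes in seconds, and returns
everything a downstream recovery analysis needs. The cohorts define
the package's ground-truth validation surface; the same conditions are
used by the test suite and by the acceptance script.

Scale conventions (documented in the methods note): chromosomes are a
few tens of megabases at most, and the background shift is scaled with
them (400 kb on the 2 Mb association chromosome, the standard 2 Mb on
the 40 Mb state and 20 Mb loop chromosomes). Shifts are even multiples
of the planted TAD and compartment periods so the shifted map is
statistically exchangeable with the original.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genome import Genome, GenomicInterval
from .hic import (
    SignificantInteractionSet,
    call_significant_interactions,
    expected_by_distance,
    shift_interactions,
)
from .simulate import (
    Annotations,
    GroundTruth,
    RnaSpec,
    SimulationSpec,
    generate_genome_and_annotations,
    generate_hic_counts,
    generate_rna_contacts,
)

CHROMHMM_LABELS = [
    "promoter",
    "enhancer",
    "transcription",
    "insulator",
    "repressed",
    "heterochromatin",
]
SPIN_LABELS = ["speckle", "interior_active", "interior_repressed", "NAD_like", "lamina"]


@dataclass
class Cohort:
    """One generated synthetic study plus its processed Hi-C products."""

    genome: Genome
    annotations: Annotations
    truth: GroundTruth
    contacts: pd.DataFrame
    peaks: SignificantInteractionSet | None = None
    shifted_peaks: SignificantInteractionSet | None = None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    spec: SimulationSpec | None = None


def _spread_genes(rng, length: int, n: int, gene_len: int = 10_000,
                  margin: int = 0) -> list[GenomicInterval]:
    starts = rng.integers(margin, length - gene_len - margin, size=n)
    return [GenomicInterval("chr1", int(s), int(s) + gene_len) for s in np.sort(starts)]


def _call_and_shift(spec: SimulationSpec, ann: Annotations, fdr: float, shift: int):
    matrices = [m for m in generate_hic_counts(spec, ann) if m.is_intra]
    models = [expected_by_distance(m) for m in matrices]
    peaks = call_significant_interactions(matrices, models, fdr)
    shifted = shift_interactions(peaks, shift, spec.genome, ann.compartments)
    return peaks, shifted


def association_cohort(seed: int, n_rnas: int = 200, n_planted: int = 20,
                       paired_fraction: float = 0.5) -> Cohort:
    """Structural-association power/FDR cohort.

    One 2 Mb chromosome at 10 kb bins with 40 planted Hi-C dots;
    *n_planted* of *n_rnas* RNAs place half their contacts (by default)
    in significant Hi-C bin pairs, the rest follow plain RD-scaling.
    The background shift is 400 kb (two TAD periods). Dot separations
    are capped at 1.2 Mb and study genes kept 400 kb from chromosome
    ends so every significant pair has a valid shift image and no
    RNA's neighbourhood straddles a shift-edge zone -- on real-genome
    scales both conditions hold automatically.
    """
    shift = 400_000
    genome = Genome({"chr1": 2_000_000})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    genes = _spread_genes(rng, 2_000_000, n_rnas, margin=400_000)
    rnas = [
        RnaSpec(
            rna_id=f"rna{i:04d}",
            biotype="lncRNA" if i % 2 else "mRNA",
            gene=genes[i],
            n_contacts=200,
            scale=30_000.0,
            gamma=2.0,
            tag="hic_paired" if i < n_planted else "none",
            multiplier=paired_fraction if i < n_planted else 1.0,
        )
        for i in range(n_rnas)
    ]
    spec = SimulationSpec(
        genome=genome,
        bin_size=10_000,
        hic_base=10.0,
        hic_d0=50_000.0,
        hic_alpha=0.5,
        tad_size=200_000,
        tad_factor=1.5,
        n_loops_per_chrom=40,
        loop_factor=8.0,
        loop_sep_range=(50_000, 1_200_000),
        compartment_block=200_000,
        compartment_factor=1.1,
        rnas=rnas,
        seed=seed,
    )
    config = AnalysisConfig(shift_distance=shift)
    _, ann, truth = generate_genome_and_annotations(spec)
    peaks, shifted = _call_and_shift(spec, ann, config.hic_fdr_intra, shift)
    contacts, truth = generate_rna_contacts(spec, ann, peaks)
    return Cohort(genome, ann, truth, contacts, peaks, shifted, config, spec)


def null_cohort(seed: int, n_rnas: int = 200) -> Cohort:
    """Association cohort with no planted effects (null calibration)."""
    return association_cohort(seed, n_rnas=n_rnas, n_planted=0)


def loop_cohort(seed: int, n_planted: int = 50, n_null: int = 50, multiplier: float = 3.0) -> Cohort:
    """Loop-anchor enrichment cohort.

    One 20 Mb chromosome with 12 planted loops; planted RNAs place
    contacts with a 3x density multiplier inside the 5-bin expanded
    anchors, null RNAs are uniform (infinite RD scale). No Hi-C matrix
    is needed: the loop annotation itself is the input.
    """
    genome = Genome({"chr1": 20_000_000})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    genes = _spread_genes(rng, 20_000_000, n_planted + n_null)
    rnas = [
        RnaSpec(
            rna_id=f"rna{i:04d}",
            biotype="lncRNA" if i % 2 else "mRNA",
            gene=genes[i],
            n_contacts=300,
            scale=float("inf"),
            tag="loop_anchor" if i < n_planted else "none",
            multiplier=multiplier if i < n_planted else 1.0,
        )
        for i in range(n_planted + n_null)
    ]
    spec = SimulationSpec(
        genome=genome,
        bin_size=10_000,
        tad_size=500_000,
        n_loops_per_chrom=12,
        loop_sep_range=(1_000_000, 8_000_000),
        compartment_block=200_000,
        rnas=rnas,
        seed=seed,
    )
    _, ann, truth = generate_genome_and_annotations(spec)
    contacts, truth = generate_rna_contacts(spec, ann)
    return Cohort(genome, ann, truth, contacts, config=AnalysisConfig(), spec=spec)


def state_cohort(seed: int, n_planted: int = 20, label: str = "enhancer",
                 multiplier: float = 2.0) -> Cohort:
    """State-preference cohort.

    One 40 Mb chromosome with 3000 strong planted Hi-C dots; planted
    RNAs place all their contacts as significant bin pairs sampled with
    odds multiplied by 2 when both peak anchors carry the chosen
    ChromHMM-style label. Labels are drawn in 50 kb blocks from six
    grouped states, giving a per-label same-state peak share near 5%.
    """
    shift = 400_000
    genome = Genome({"chr1": 40_000_000})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    genes = _spread_genes(rng, 40_000_000, n_planted)
    rnas = [
        RnaSpec(
            rna_id=f"rna{i:04d}",
            biotype="lncRNA",
            gene=genes[i],
            n_contacts=600,
            scale=500_000.0,
            tag="state_pref",
            multiplier=multiplier,
            paired_fraction=1.0,
            state_label=label,
            state_annotation="chromhmm",
        )
        for i in range(n_planted)
    ]
    spec = SimulationSpec(
        genome=genome,
        bin_size=10_000,
        hic_base=15.0,
        hic_d0=50_000.0,
        hic_alpha=0.3,
        tad_size=500_000,
        tad_factor=1.0,
        n_loops_per_chrom=3000,
        loop_factor=6.0,
        loop_sep_range=(50_000, 3_500_000),
        compartment_block=200_000,
        compartment_factor=1.0,
        state_annotations={
            "chromhmm": (CHROMHMM_LABELS, 50_000),
            "spin": (SPIN_LABELS, 80_000),
        },
        rnas=rnas,
        seed=seed,
    )
    config = AnalysisConfig(shift_distance=shift)
    _, ann, truth = generate_genome_and_annotations(spec)
    peaks, shifted = _call_and_shift(spec, ann, config.hic_fdr_intra, shift)
    contacts, truth = generate_rna_contacts(spec, ann, peaks)
    return Cohort(genome, ann, truth, contacts, peaks, shifted, config, spec)


def conservation_cohort(seed: int, n_rnas: int = 100, n_planted: int = 20,
                        twins: bool = True) -> tuple[Cohort, pd.DataFrame]:
    """Twin-experiment conservation cohort.

    Returns the base cohort (experiment A) and an independently drawn
    contact table for experiment B over the same RNAs and the same Hi-C
    structure, on a 10 Mb chromosome with 120 planted dots (occupancy
    low enough that coincidental bin sharing stays small relative to
    direct peak sharing). With ``twins=True`` the planted Hi-C-paired
    RNAs are shared; with ``twins=False`` no RNA carries a planted
    effect and RD-scaling is diffuse, the independent-experiments null.
    """
    shift = 400_000
    genome = Genome({"chr1": 10_000_000})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    genes = _spread_genes(rng, 10_000_000, n_rnas, margin=400_000)
    rnas = [
        RnaSpec(
            rna_id=f"rna{i:04d}",
            biotype="lncRNA" if i % 2 else "mRNA",
            gene=genes[i],
            n_contacts=400,
            scale=5_000_000.0 if not twins else 30_000.0,
            gamma=2.0,
            tag="hic_paired" if (twins and i < n_planted) else "none",
            multiplier=0.5 if (twins and i < n_planted) else 1.0,
        )
        for i in range(n_rnas)
    ]
    spec = SimulationSpec(
        genome=genome,
        bin_size=10_000,
        hic_base=10.0,
        hic_d0=50_000.0,
        hic_alpha=0.5,
        tad_size=200_000,
        tad_factor=1.5,
        n_loops_per_chrom=120,
        loop_factor=8.0,
        loop_sep_range=(50_000, 1_200_000),
        compartment_block=200_000,
        compartment_factor=1.1,
        rnas=rnas,
        seed=seed,
    )
    config = AnalysisConfig(shift_distance=shift)
    _, ann, truth = generate_genome_and_annotations(spec)
    peaks, shifted = _call_and_shift(spec, ann, config.hic_fdr_intra, shift)
    contacts_a, truth = generate_rna_contacts(spec, ann, peaks)
    spec_b = SimulationSpec(**{**spec.__dict__, "seed": spec.seed + 1_000_003})
    # experiment B: same genome, annotations and peak structure;
    # an independent draw of every RNA's contacts
    contacts_b, _ = generate_rna_contacts(spec_b, ann, peaks)
    cohort = Cohort(genome, ann, truth, contacts_a, peaks, shifted, config, spec)
    return cohort, contacts_b


def outindr_cohort(seed: int, n_rnas: int = 60) -> Cohort:
    """TAD-localisation cohort: RNAs with contrasting RD scales.

    One 10 Mb chromosome tiled by 500 kb TADs; mRNAs are given a short
    RD scale (stay near the gene, low OutInDR), lncRNAs a long one
    (leave the TAD, higher OutInDR).
    """
    genome = Genome({"chr1": 10_000_000})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 14]))
    genes = _spread_genes(rng, 10_000_000, n_rnas)
    rnas = []
    for i in range(n_rnas):
        is_lnc = i % 2 == 1
        rnas.append(
            RnaSpec(
                rna_id=f"rna{i:04d}",
                biotype="lncRNA" if is_lnc else "mRNA",
                gene=genes[i],
                n_contacts=200,
                scale=2_000_000.0 if is_lnc else 50_000.0,
                tag="none",
            )
        )
    spec = SimulationSpec(
        genome=genome,
        bin_size=10_000,
        tad_size=500_000,
        compartment_block=200_000,
        rnas=rnas,
        seed=seed,
    )
    _, ann, truth = generate_genome_and_annotations(spec)
    contacts, truth = generate_rna_contacts(spec, ann)
    return Cohort(genome, ann, truth, contacts, config=AnalysisConfig(), spec=spec)
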