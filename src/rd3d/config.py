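"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    """Tunable thresholds and scales of the joint RD/Hi-C analysis.

    Defaults follow the published conventions for mammalian genomes:
    10 kb intra- / 50 kb interchromosomal Hi-C bins, FDR 0.05 / 0.2 for
    Hi-C peak calling, a 2 Mb compartment-aware shift for background
    maps and loop anchors, q < 0.05 for per-RNA calls, 5-bin expanded
    loop anchors, +/-500 kb anchor metaplot windows, a 20 Mb close/distant
    split for cis contacts, 20 kb loop-matching tolerance, the top 6000
    RNAs by peak count, top 100 RNAs for TAD metaplots, >= 10 cis
    contacts per gene for OutInDR, and a 10% peak-contact fraction.
    """

    intra_bin_size: int = 10_000
    inter_bin_size: int = 50_000
    shift_distance: int = 2_000_000
    hic_fdr_intra: float = 0.05
    hic_fdr_inter: float = 0.2
    rna_q_threshold: float = 0.05
    anchor_expansion_bins: int = 5
    metaplot_window: int = 500_000
    close_distance: int = 20_000_000
    loop_match_tolerance: int = 20_000
    top_n_rnas: int = 6000
    metaplot_top_rnas: int = 100
    min_cis_contacts: int = 10
    peak_contact_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in (
            "intra_bin_size",
            "inter_bin_size",
            "shift_distance",
            "metaplot_window",
            "close_distance",
            "loop_match_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hic_fdr_intra", "hic_fdr_inter", "rna_q_threshold", "peak_contact_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.anchor_expansion_bins < 1 or self.anchor_expansion_bins % 2 == 0:
            raise ValueError("anchor_expansion_bins must be a positive odd integer")
        if self.shift_distance % self.intra_bin_size:
            raise ValueError("shift_distance must be a multiple of intra_bin_size")

    @classmethod
    def from_toml(cls, path, **overrides) -> "AnalysisConfig":
        """Load from a TOML file; keyword overrides win over file values."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
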