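"""Pipeline-wide tunable thresholds.

All defaults are the operating point of the marker-gene mOTU workflow:
near-species clustering at 94.8% nucleotide identity, read-mapping filters
of 95% identity / 45 nt (60 nt for partial alignments), and removal of
clusters at 0.5x mean coverage or less.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds shared by clustering, mapping and abundance estimation.

    Parameters
    ----------
    identity_cutoff
        Nucleotide identity at which marker genes are merged into one mOTU.
    min_aligned_bases
        Pairwise gene alignments spanning fewer columns are masked
        (treated as maximally distant).
    min_mapping_identity
        Read alignments below this identity are discarded.
    min_alignment_length
        Minimum aligned length (nt) for a full read alignment.
    min_partial_alignment_length
        Minimum aligned length (nt) when the alignment does not span the
        whole read.
    min_avg_coverage
        mOTUs whose mean per-sample coverage is at or below this multiple
        are removed (strict "or less").
    rarefaction_seed
        Seed for the single rarefaction draw per sample.
    """

    identity_cutoff: float = 0.948
    min_aligned_bases: int = 20
    min_mapping_identity: float = 0.95
    min_alignment_length: int = 45
    min_partial_alignment_length: int = 60
    min_avg_coverage: float = 0.5
    rarefaction_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("identity_cutoff", "min_mapping_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "min_aligned_bases",
            "min_alignment_length",
            "min_partial_alignment_length",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.min_avg_coverage < 0:
            raise ValueError(
                f"min_avg_coverage must be nonnegative, got {self.min_avg_coverage}"
            )


DEFAULT_CONFIG = PipelineConfig()
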