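"""Pipeline-wide parameters, serialized into every run's provenance record.

Defaults: 16-nt cell barcodes matched
exactly in the first and last 200 nt of reads longer than 250 nt, a 13-nt trim
downstream of the barcode (10-nt UMI + 3-nt buffer), a 200-nt minimum read
length and 100-nt minimum overlap for consensus building, four polish rounds,
V-mutation filters of >5 (TCR) / >40 (BCR), constant-region calling at >95%
coverage and >90% identity, a 90% CDR3-nucleotide rule for B-cell clones, and
stepwise subsampling depths 1000/500/250/100/50.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .align import ScoringParams


@dataclass
class PipelineParams:
    barcode_length: int = 16
    umi_length: int = 10
    trim_downstream: int = 13  # UMI + 3-nt buffer removed after the barcode
    demux_min_read_length: int = 250  # strictly-greater rule: >=251 kept
    scan_window: int = 200
    consensus_min_read_length: int = 200
    min_overlap_length: int = 100
    kmer_size: int = 13
    # k-mer containment threshold for joining a cluster: sits between the
    # unrelated-transcript noise floor (~0.005) and the expected sharing of two
    # same-transcript reads at the default 10% total error, (1-0.1)^(2k) ~ 0.065
    kmer_containment: float = 0.03
    polish_rounds: int = 4
    min_v_score: int = 50
    min_j_score: int = 30
    min_c_score: int = 50
    c_min_coverage: float = 0.95  # strict: coverage must exceed this
    c_min_identity: float = 0.90  # strict: identity must exceed this
    bcr_max_v_mutations: int = 40  # strict: >40 removed, 40 kept
    tcr_max_v_mutations: int = 5  # strict: >5 removed, 5 kept
    bcr_cdr3_identity: float = 0.90  # inclusive: >=0.90 co-clusters
    top_n_genes: int = 250
    subsample_depths: tuple[int, ...] = (1000, 500, 250, 100, 50)
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if isinstance(self.scoring, dict):
            self.scoring = ScoringParams(**self.scoring)
        if isinstance(self.subsample_depths, list):
            self.subsample_depths = tuple(self.subsample_depths)
        if not 0 < self.c_min_coverage <= 1 or not 0 < self.c_min_identity <= 1:
            raise ValueError("constant-region thresholds must be in (0, 1]")
        if not 0 <= self.kmer_containment <= 1:
            raise ValueError("kmer_containment must be in [0, 1]")
        if self.barcode_length < 1 or self.umi_length < 0:
            raise ValueError("bad barcode/UMI lengths")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {**self.to_dict(), "subsample_depths": list(self.subsample_depths)},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
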