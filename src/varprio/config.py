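"""Flat key/value pipeline configuration with documented defaults.

All thresholds of the cascade live here: quality > 20, coverage > 5x,
MAF < 0.1 %, deleteriousness score > 10, conservation > 2.0 (rejected
substitutions) / > 0.3 (element probability), 3-of-4 predictor vote,
miRNA target score < -0.1.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .io import DEFAULT_KEY_MAP
from .model import ValidationError


@dataclass
class PipelineConfig:
    # inputs (CLI flags may override)
    vcf: Optional[str] = None
    ped: Optional[str] = None
    statuses: Optional[str] = None
    annotations: Optional[str] = None  # optional TSV annotation sidecar
    out_dir: str = "varprio_out"
    family: Optional[str] = None       # required when the PED holds several families
    key_map: dict = field(default_factory=lambda: dict(DEFAULT_KEY_MAP))

    # technical QC
    min_qual: float = 20.0
    min_depth: int = 5
    qc_strict: bool = True             # strict > on both cutoffs
    depth_scope: str = "carriers"      # carriers | all | site_mean
    require_strand_bias: bool = True
    indel_missing_filter_fails: bool = True

    # rarity
    maf_cutoff: float = 0.001

    # relatedness QC (advisory unless strict_relatedness)
    relatedness_rank_tolerance: float = 0.25
    relatedness_zero_kinship_max_sharing: float = 0.1
    relatedness_min_pair_union: int = 50
    strict_relatedness: bool = False

    # segregation
    seg_model: str = "dominant"
    max_missing_definite_cases: int = 0
    max_missing_phenocopy_cases: Optional[int] = None   # None = unlimited
    max_carrier_noncarrier_controls: int = 0
    max_carrier_possible_controls: Optional[int] = None
    missing_genotype_rule: str = "noninformative"

    # score gate
    cadd_threshold: float = 10.0
    cadd_missing_passes: bool = False
    cadd_region_thresholds: dict = field(default_factory=dict)  # region -> threshold

    # conservation
    conservation_mode: str = "either"  # either | both
    conservation_gate: str = "none"    # none (flag/rank only) | noncoding | all
    gerp_threshold: float = 2.0
    phastcons_threshold: float = 0.3

    # coding branch
    vote_threshold: int = 3
    intolerance_mode: str = "flag"     # flag | filter | off
    intolerance_max_pct: float = 25.0
    intolerance_min_sources: int = 1
    nonmissense_policy: str = "retain_flagged"

    # non-coding branches
    mirsvr_threshold: float = -0.1
    mirna_hard: bool = False
    min_evidence_ordinal: int = 0
    min_evidence_flags: int = 0

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.intolerance_min_sources not in (1, 2, 3):
            raise ValidationError(
                f"intolerance_min_sources must be 1..3, got {self.intolerance_min_sources}"
            )
        if not (0 <= self.intolerance_max_pct <= 100):
            raise ValidationError("intolerance_max_pct must be in [0,100]")
        if self.vote_threshold < 0 or self.vote_threshold > 4:
            raise ValidationError("vote_threshold must be 0..4")
        if self.conservation_mode not in ("either", "both"):
            raise ValidationError(f"unknown conservation_mode: {self.conservation_mode!r}")
        if self.conservation_gate not in ("none", "noncoding", "all"):
            raise ValidationError(f"unknown conservation_gate: {self.conservation_gate!r}")
        if self.intolerance_mode not in ("flag", "filter", "off"):
            raise ValidationError(f"unknown intolerance_mode: {self.intolerance_mode!r}")
        if self.depth_scope not in ("carriers", "all", "site_mean"):
            raise ValidationError(f"unknown depth_scope: {self.depth_scope!r}")
        if not (0.0 <= self.maf_cutoff <= 1.0):
            raise ValidationError("maf_cutoff must be in [0,1]")
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(CONFIG_TEMPLATE_HEADER)
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


CONFIG_TEMPLATE_HEADER = """\
# Pipeline configuration (flat key/value).
#
# Default thresholds of the cascade, all strict inequalities:
#   min_qual 20 / min_depth 5      variant quality > 20, carrier coverage > 5x
#   maf_cutoff 0.001               rare = MAF < 0.1 % in every resource with data
#   cadd_threshold 10              scaled deleteriousness score > 10 (top 10 %)
#   gerp_threshold 2.0             conservation: rejected substitutions > 2.0
#   phastcons_threshold 0.3        conservation: element probability > 0.3
#   vote_threshold 3               >= 3 of 4 predictors call deleterious
#   mirsvr_threshold -0.1          good miRNA target: score < -0.1
#
# key_map maps canonical annotation-field names to the INFO/FORMAT keys of
# your annotated VCF.  MAF fields are consumed as provided by the upstream
# annotator; no alt-vs-minor allele folding is performed.
"""
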