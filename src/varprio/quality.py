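"""Technical QC stage: site quality, carrier coverage, strand bias for
SNVs, upstream caller FILTER status for indels."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import (
    Genotype,
    ValidationError,
    VariantClass,
    VariantRecord,
    count_by_region,
)


@dataclass(frozen=True)
class QcThresholds:
    """Technical QC thresholds.

    By default both cutoffs are strict inequalities (qual > 20, depth > 5);
    set ``strict=False`` for >=.  ``depth_scope`` selects which samples the
    coverage rule applies to: ``carriers`` (default; only samples whose
    genotype contains the alt allele), ``all`` (every genotyped sample) or
    ``site_mean`` (mean depth across genotyped samples).
    """

    min_qual: float = 20.0
    min_depth: int = 5
    strict: bool = True
    depth_scope: str = "carriers"
    require_biallelic_strand: bool = True
    indel_missing_filter_fails: bool = True

    def __post_init__(self) -> None:
        if self.min_qual < 0:
            raise ValidationError(f"min_qual must be >= 0, got {self.min_qual}")
        if self.min_depth < 0:
            raise ValidationError(f"min_depth must be >= 0, got {self.min_depth}")
        if self.depth_scope not in ("carriers", "all", "site_mean"):
            raise ValidationError(f"unknown depth_scope: {self.depth_scope!r}")

    def _gt(self, value: float, threshold: float) -> bool:
        return value > threshold if self.strict else value >= threshold


def passes_site_quality(record: VariantRecord, thr: QcThresholds) -> bool:
    """True iff variant quality and coverage clear the thresholds.

    A missing qual, or a missing depth in a sample the coverage rule
    applies to, fails the check.
    """
    if record.qual is None or not thr._gt(record.qual, thr.min_qual):
        return False
    if thr.depth_scope == "carriers":
        scope = [c for c in record.per_sample.values() if c.genotype.carries_alt]
    else:
        scope = [c for c in record.per_sample.values() if c.genotype != Genotype.MISSING]
    if thr.depth_scope == "site_mean":
        if not scope:
            return True
        depths = [c.depth for c in scope]
        if any(d is None for d in depths):
            return False
        return thr._gt(sum(depths) / len(depths), thr.min_depth)
    for call in scope:
        if call.depth is None or not thr._gt(call.depth, thr.min_depth):
            return False
    return True


def passes_strand_bias(record: VariantRecord) -> bool:
    """True iff, pooled over carrier samples, at least one alt-supporting
    read exists on each strand.  SNVs only."""
    if record.vclass is not VariantClass.SNV:
        raise ValidationError("strand-bias rule applies to SNVs only")
    fwd = rev = 0
    for call in record.per_sample.values():
        if call.genotype.carries_alt:
            fwd += call.alt_fwd or 0
            rev += call.alt_rev or 0
    return fwd >= 1 and rev >= 1


def passes_upstream_filters(record: VariantRecord, missing_fails: bool = True) -> bool:
    """True iff the caller FILTER column is PASS.

    A missing FILTER ('.') fails by default; relax with
    ``missing_fails=False``.
    """
    if record.upstream_filter is None or record.upstream_filter == ".":
        return not missing_fails
    return record.upstream_filter == "PASS"


def passes_technical_qc(record: VariantRecord, thr: QcThresholds) -> bool:
    """Combined per-record QC predicate (SNV and indel routes)."""
    if not passes_site_quality(record, thr):
        return False
    if record.vclass is VariantClass.SNV:
        return (not thr.require_biallelic_strand) or passes_strand_bias(record)
    return passes_upstream_filters(record, missing_fails=thr.indel_missing_filter_fails)


def apply_technical_qc(
    records: Sequence[VariantRecord], thr: QcThresholds
) -> tuple[list[VariantRecord], tuple[str, dict[str, int]]]:
    """Filter a record list; returns survivors and the funnel stage entry."""
    survivors = [r for r in records if passes_technical_qc(r, thr)]
    return survivors, ("technical_qc", count_by_region(survivors))
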