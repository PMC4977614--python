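"""Deleteriousness-score tiering, conservation gating, and routing of
survivors into the four distal branches (coding, 5'UTR, 3'UTR,
intergenic/intronic)."""
from __future__ import annotations

import enum
from typing import Optional

from .model import AnnotationBundle, RegionClass, ValidationError, VariantRecord


class CaddTier(str, enum.Enum):
    BELOW = "below"
    TOP10 = "top10"   # scaled score > 10: top 10 % of possible substitutions
    TOP1 = "top1"     # > 20
    TOP01 = "top01"   # > 30
    MISSING = "missing"


class Branch(str, enum.Enum):
    CODING = "coding"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTERGENIC = "intergenic"
    OTHER = "other"


def cadd_tier(cadd_phred: Optional[float]) -> CaddTier:
    """Monotone step tiering of the scaled score; boundaries are strict."""
    if cadd_phred is None:
        return CaddTier.MISSING
    if cadd_phred < 0:
        raise ValidationError(f"scaled score must be >= 0, got {cadd_phred}")
    if cadd_phred > 30:
        return CaddTier.TOP01
    if cadd_phred > 20:
        return CaddTier.TOP1
    if cadd_phred > 10:
        return CaddTier.TOP10
    return CaddTier.BELOW


def passes_cadd_gate(
    annot: AnnotationBundle,
    threshold: float = 10.0,
    missing_passes: bool = False,
) -> bool:
    """True iff the scaled score is strictly above ``threshold``.

    With the default threshold this is exactly "tier is top10 or better".
    A missing score fails by default (a variant cannot be ranked without
    its ranking score); override with ``missing_passes``.
    """
    if annot.cadd_phred is None:
        return missing_passes
    if annot.cadd_phred < 0:
        raise ValidationError(f"scaled score must be >= 0, got {annot.cadd_phred}")
    return annot.cadd_phred > threshold


def passes_conservation(
    annot: AnnotationBundle,
    mode: str = "either",
    gerp_threshold: float = 2.0,
    phastcons_threshold: float = 0.3,
) -> bool:
    """Conservation check; strict inequalities on both sub-tests.

    ``mode='either'``: one passing sub-test suffices; ``mode='both'``:
    both must pass.  A missing score fails its own sub-test.
    """
    if mode not in ("either", "both"):
        raise ValidationError(f"unknown conservation mode: {mode!r}")
    if annot.phastcons is not None and not (0.0 <= annot.phastcons <= 1.0):
        raise ValidationError(f"phastcons out of [0,1]: {annot.phastcons}")
    gerp_ok = annot.gerp is not None and annot.gerp > gerp_threshold
    pc_ok = annot.phastcons is not None and annot.phastcons > phastcons_threshold
    return (gerp_ok or pc_ok) if mode == "either" else (gerp_ok and pc_ok)


_ROUTES = {
    RegionClass.MISSENSE: Branch.CODING,
    RegionClass.OTHER_CODING: Branch.CODING,
    RegionClass.SPLICING: Branch.CODING,
    RegionClass.UTR5: Branch.UTR5,
    RegionClass.UTR3: Branch.UTR3,
    RegionClass.INTRONIC: Branch.INTERGENIC,  # regulatory evaluation route
    RegionClass.INTERGENIC: Branch.INTERGENIC,
    RegionClass.OTHER: Branch.OTHER,
}


def route_region(record: VariantRecord) -> Branch:
    """Total routing of a record into exactly one distal branch."""
    return _ROUTES[record.region]
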