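"""Rarity filtering against population allele-frequency resources.

A variant is rare when its frequency is below the cutoff in *every*
resource that has data for it; a missing frequency counts as rare (novel
variants absent from the catalogs are the prime candidates).
"""
from __future__ import annotations

from typing import Sequence

from .model import AnnotationBundle, ValidationError, VariantRecord, count_by_region

DEFAULT_MAF_CUTOFF = 0.001  # 0.1 %


def is_rare(annot: AnnotationBundle, cutoff: float = DEFAULT_MAF_CUTOFF) -> bool:
    """True iff every available MAF is strictly below ``cutoff``.

    Resources checked: 1000 Genomes, non-TCGA ExAC, and (when present) an
    in-house control frequency under the same rule.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"MAF cutoff must be in [0,1], got {cutoff}")
    for maf in (annot.maf_1kg, annot.maf_exac_nontcga, annot.maf_inhouse):
        if maf is None:
            continue
        if not (0.0 <= maf <= 1.0):
            raise ValidationError(f"MAF out of [0,1]: {maf}")
        if maf >= cutoff:
            return False
    return True


def apply_rarity_filter(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    cutoff: float = DEFAULT_MAF_CUTOFF,
) -> tuple[list[tuple[VariantRecord, AnnotationBundle]], tuple[str, dict[str, int]]]:
    """Keep exactly the rare records; returns survivors + funnel entry."""
    survivors = [(rec, ann) for rec, ann in pairs if is_rare(ann, cutoff)]
    return survivors, ("rarity", count_by_region(rec for rec, _ in survivors))
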