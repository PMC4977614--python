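"""Non-coding branch evaluation: regulatory-evidence ordinal from
RegulomeDB-style categories plus enhancer/promoter/TFBS/eQTL flag counts,
and miRNA-target promotion for 3'UTR variants."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    AnnotationBundle,
    REGULOME_CATEGORIES,
    ValidationError,
    VariantRecord,
    count_by_region,
)
from .ranking import Branch, passes_conservation

MIRSVR_THRESHOLD = -0.1

#: category -> ordinal; strongest category gets the largest ordinal, a
#: missing category gets 0.
REGULOME_ORDINAL = {
    cat: len(REGULOME_CATEGORIES) - i for i, cat in enumerate(REGULOME_CATEGORIES)
}


def good_mirna_target(mirsvr: Optional[float], threshold: float = MIRSVR_THRESHOLD) -> bool:
    """True iff the score is present and strictly below ``threshold``."""
    return mirsvr is not None and mirsvr < threshold


@dataclass(frozen=True, order=True)
class EvidenceScore:
    """Ordinal regulatory-evidence level.

    Ordering is lexicographic: category ordinal first, then the number of
    regulatory evidence flags.  ``evidence`` lists the contributing tags.
    """

    regulome_ordinal: int
    flag_count: int
    evidence: tuple[str, ...] = field(compare=False, default=())

    @property
    def level(self) -> tuple[int, int]:
        return (self.regulome_ordinal, self.flag_count)


def regulatory_evidence_score(annot: AnnotationBundle) -> EvidenceScore:
    """Combine the category rank and evidence flags into an ordinal score.

    All-missing annotations yield the lowest level with empty evidence.
    """
    evidence: list[str] = []
    if annot.regulome_rank is not None:
        ordinal = REGULOME_ORDINAL.get(annot.regulome_rank)
        if ordinal is None:
            raise ValidationError(f"unknown RegulomeDB category: {annot.regulome_rank!r}")
        evidence.append(f"regulome:{annot.regulome_rank}")
    else:
        ordinal = 0
    flags = sorted(annot.haploreg_flags)
    evidence.extend(f"haploreg:{f}" for f in flags)
    return EvidenceScore(
        regulome_ordinal=ordinal, flag_count=len(flags), evidence=tuple(evidence)
    )


def evaluate_noncoding(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    branch: Branch,
    min_level: tuple[int, int] = (0, 0),
    mirna_hard: bool = False,
    mirsvr_threshold: float = MIRSVR_THRESHOLD,
    conservation_mode: str = "either",
) -> tuple[
    list[tuple[VariantRecord, AnnotationBundle]],
    tuple[str, dict[str, int]],
    dict[str, list[str]],
]:
    """Evaluate records routed to one non-coding branch.

    Survivors are records at or above ``min_level`` of regulatory evidence
    (default: lowest — report-all, rank-only).  The 3'UTR branch
    additionally annotates miRNA-target status and promotes good targets
    in the ranking; with ``mirna_hard`` the target call becomes a filter.
    Ranking is a stable sort: ties keep input order.
    """
    if branch not in (Branch.UTR5, Branch.UTR3, Branch.INTERGENIC):
        raise ValidationError(f"not a non-coding branch: {branch!r}")

    flags: dict[str, list[str]] = {}
    kept: list[tuple[int, tuple, VariantRecord, AnnotationBundle]] = []
    for idx, (rec, ann) in enumerate(pairs):
        score = regulatory_evidence_score(ann)
        conserved = passes_conservation(ann, mode=conservation_mode)
        if conserved:
            flags.setdefault(rec.key, []).append("conserved")
        for tag in score.evidence:
            flags.setdefault(rec.key, []).append(tag)
        mirna = False
        if branch is Branch.UTR3:
            mirna = good_mirna_target(ann.mirsvr, mirsvr_threshold)
            if mirna:
                flags.setdefault(rec.key, []).append("mirna_target")
            elif ann.mirna_secondary:
                flags.setdefault(rec.key, []).append("mirna_secondary_evidence")
            if mirna_hard and not mirna:
                continue
        if score.level < tuple(min_level):
            continue
        sort_key = (
            (0 if mirna else 1) if branch is Branch.UTR3 else 0,
            -score.regulome_ordinal,
            -score.flag_count,
            0 if conserved else 1,
        )
        kept.append((idx, sort_key, rec, ann))

    kept.sort(key=lambda t: t[1])  # stable: input order preserved on ties
    survivors = [(rec, ann) for _, _, rec, ann in kept]
    entry = (f"branch_{branch.value}", count_by_region(rec for rec, _ in survivors))
    return survivors, entry, flags
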