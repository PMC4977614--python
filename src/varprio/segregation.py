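"""Per-family segregation filtering under a dominant model with five-level
member statuses and numeric tolerances.

The rule of thumb being encoded: (almost) all cases must carry the variant
and (almost) no control may carry it, where "almost" is parameterized per
status level — definite cases and non-carrier controls are strict by
default, possible phenocopies and possible carriers are tolerated without
limit by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    Pedigree,
    Status,
    ValidationError,
    VariantRecord,
    count_by_region,
)

#: tolerance value meaning "no limit"
UNLIMITED: Optional[int] = None


@dataclass(frozen=True)
class SegregationPolicy:
    model: str = "dominant"
    max_missing_definite_cases: int = 0
    max_missing_phenocopy_cases: Optional[int] = UNLIMITED
    max_carrier_noncarrier_controls: int = 0
    max_carrier_possible_controls: Optional[int] = UNLIMITED
    missing_genotype_rule: str = "noninformative"  # or "strict"

    def __post_init__(self) -> None:
        if self.model != "dominant":
            raise ValidationError(
                f"unsupported inheritance model {self.model!r}; only 'dominant' is implemented"
            )
        for name in (
            "max_missing_definite_cases",
            "max_missing_phenocopy_cases",
            "max_carrier_noncarrier_controls",
            "max_carrier_possible_controls",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.missing_genotype_rule not in ("noninformative", "strict"):
            raise ValidationError(
                f"unknown missing_genotype_rule: {self.missing_genotype_rule!r}"
            )


@dataclass
class CarrierSet:
    """Dominant-model carriers of a variant, with missing genotypes tracked
    separately (they never enter the carrier set)."""

    carriers: set[str] = field(default_factory=set)
    unknown: set[str] = field(default_factory=set)


@dataclass
class SegregationVerdict:
    passes: bool
    violated_constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passes != (not self.violated_constraints):
            raise ValidationError("passes must mirror emptiness of violated_constraints")


def carrier_set(record: VariantRecord, model: str = "dominant") -> CarrierSet:
    if model != "dominant":
        raise ValidationError(f"unsupported model {model!r}")
    cs = CarrierSet()
    for sid, call in record.per_sample.items():
        if call.genotype.carries_alt:
            cs.carriers.add(sid)
        elif call.genotype.value == "missing":
            cs.unknown.add(sid)
    return cs


def _exceeds(offenders: list[str], limit: Optional[int]) -> bool:
    return limit is not None and len(offenders) > limit


def segregates(
    record: VariantRecord,
    ped: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
    family_id: Optional[str] = None,
) -> SegregationVerdict:
    """Evaluate one variant against one family's statuses.

    Members with status UNINFORMATIVE never constrain.  Under
    ``missing_genotype_rule='noninformative'`` a missing genotype counts
    toward no constraint; under ``'strict'`` a missing genotype in a
    CASE_DEFINITE or CONTROL_NONCARRIER fails that member's constraint.
    """
    cs = carrier_set(record, policy.model)
    strict = policy.missing_genotype_rule == "strict"

    members = [
        m for m in ped.sequenced_members()
        if family_id is None or m.family_id == family_id
    ]
    for m in members:
        if m.member_id not in record.per_sample:
            raise ValidationError(
                f"sequenced member {m.member_id!r} has no genotype column"
            )

    missing_definite: list[str] = []
    missing_phenocopy: list[str] = []
    carrier_noncarrier: list[str] = []
    carrier_possible: list[str] = []
    for m in members:
        mid = m.member_id
        unknown = mid in cs.unknown
        carries = mid in cs.carriers
        if m.status is Status.CASE_DEFINITE:
            if unknown:
                if strict:
                    missing_definite.append(mid)
            elif not carries:
                missing_definite.append(mid)
        elif m.status is Status.CASE_POSSIBLE_PHENOCOPY:
            if not unknown and not carries:
                missing_phenocopy.append(mid)
        elif m.status is Status.CONTROL_NONCARRIER:
            if unknown:
                if strict:
                    carrier_noncarrier.append(mid)
            elif carries:
                carrier_noncarrier.append(mid)
        elif m.status is Status.CONTROL_POSSIBLE_CARRIER:
            if not unknown and carries:
                carrier_possible.append(mid)

    violations: list[tuple[str, str]] = []
    if _exceeds(missing_definite, policy.max_missing_definite_cases):
        violations += [(mid, "definite_case_missing") for mid in missing_definite]
    if _exceeds(missing_phenocopy, policy.max_missing_phenocopy_cases):
        violations += [(mid, "phenocopy_case_missing") for mid in missing_phenocopy]
    if _exceeds(carrier_noncarrier, policy.max_carrier_noncarrier_controls):
        violations += [(mid, "noncarrier_control_carries") for mid in carrier_noncarrier]
    if _exceeds(carrier_possible, policy.max_carrier_possible_controls):
        violations += [(mid, "possible_carrier_control_carries") for mid in carrier_possible]
    return SegregationVerdict(passes=not violations, violated_constraints=violations)


def apply_segregation(
    records: Sequence[VariantRecord],
    ped: Pedigree,
    policy: SegregationPolicy = SegregationPolicy(),
    family_id: Optional[str] = None,
) -> tuple[list[VariantRecord], tuple[str, dict[str, int]]]:
    survivors = [r for r in records if segregates(r, ped, policy, family_id).passes]
    return survivors, ("segregation", count_by_region(survivors))
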