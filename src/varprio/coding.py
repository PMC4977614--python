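"""Coding-branch evaluation: four-predictor consensus vote on missense
variants, plus gene-intolerance percentiles as a separately logged
sub-stage (flag by default, filter optionally)."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import (
    AnnotationBundle,
    PREDICTOR_DELETERIOUS,
    PREDICTORS,
    RegionClass,
    ValidationError,
    VariantRecord,
    count_by_region,
)

VOTE_THRESHOLD = 3


def consensus_deleterious(calls: Mapping[str, Optional[str]], threshold: int = VOTE_THRESHOLD) -> bool:
    """True iff at least ``threshold`` of the four predictors call the
    variant deleterious.  A missing call is not a vote."""
    unknown = set(calls) - set(PREDICTORS)
    if unknown:
        raise ValidationError(f"unknown predictor keys: {sorted(unknown)}")
    votes = sum(1 for v in calls.values() if v == PREDICTOR_DELETERIOUS)
    return votes >= threshold


@dataclass(frozen=True)
class IntoleranceResult:
    passes: bool
    unassessed: bool


def passes_intolerance(
    pcts: Mapping[str, Optional[float]],
    max_pct: float = 25.0,
    min_sources: int = 1,
) -> IntoleranceResult:
    """Gene-intolerance check over up to three percentile sources.

    Lower percentile = more intolerant gene.  Passes when at least
    ``min_sources`` available percentiles are <= ``max_pct``.  When fewer
    than ``min_sources`` percentiles are available at all, the variant is
    passed with ``unassessed=True`` — intolerance is supplementary, not
    exclusionary.
    """
    if not (0.0 <= max_pct <= 100.0):
        raise ValidationError(f"max_pct must be in [0,100], got {max_pct}")
    if min_sources not in (1, 2, 3):
        raise ValidationError(f"min_sources must be 1..3, got {min_sources}")
    available = [v for v in pcts.values() if v is not None]
    for v in available:
        if not (0.0 <= v <= 100.0):
            raise ValidationError(f"percentile out of [0,100]: {v}")
    if len(available) < min_sources:
        return IntoleranceResult(passes=True, unassessed=True)
    qualifying = sum(1 for v in available if v <= max_pct)
    return IntoleranceResult(passes=qualifying >= min_sources, unassessed=False)


def evaluate_coding(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    vote_threshold: int = VOTE_THRESHOLD,
    intolerance_mode: str = "flag",  # "flag" | "filter" | "off"
    max_pct: float = 25.0,
    min_sources: int = 1,
    nonmissense_policy: str = "retain_flagged",  # or "reject"
) -> tuple[
    list[tuple[VariantRecord, AnnotationBundle]],
    list[tuple[str, dict[str, int]]],
    dict[str, list[str]],
]:
    """Evaluate records routed to the coding branch.

    Missense records face the consensus vote.  Non-missense coding classes
    (nonsense/frameshift-style and splicing) cannot be scored by missense
    predictors: by default they are retained with a manual-review flag,
    or rejected outright under ``nonmissense_policy='reject'``.

    Returns (survivors, [vote funnel entry, intolerance funnel entry],
    per-variant-key flag lists).  Both with- and without-intolerance counts
    are thereby reported.
    """
    if intolerance_mode not in ("flag", "filter", "off"):
        raise ValidationError(f"unknown intolerance_mode: {intolerance_mode!r}")
    if nonmissense_policy not in ("retain_flagged", "reject"):
        raise ValidationError(f"unknown nonmissense_policy: {nonmissense_policy!r}")

    flags: dict[str, list[str]] = {}
    post_vote: list[tuple[VariantRecord, AnnotationBundle]] = []
    for rec, ann in pairs:
        if rec.region is RegionClass.MISSENSE:
            if consensus_deleterious(ann.predictor_calls, vote_threshold):
                post_vote.append((rec, ann))
        else:
            if nonmissense_policy == "retain_flagged":
                flags.setdefault(rec.key, []).append("nonmissense_manual_review")
                post_vote.append((rec, ann))
            else:
                flags.setdefault(rec.key, []).append("nonmissense_rejected")
    vote_entry = ("coding_vote", count_by_region(rec for rec, _ in post_vote))

    survivors: list[tuple[VariantRecord, AnnotationBundle]] = []
    for rec, ann in post_vote:
        if intolerance_mode == "off" or rec.region is not RegionClass.MISSENSE:
            survivors.append((rec, ann))
            continue
        pcts = {s: ann.intolerance_pct.get(s) for s in ("inhouse", "esp", "exac")}
        result = passes_intolerance(pcts, max_pct=max_pct, min_sources=min_sources)
        if result.unassessed:
            flags.setdefault(rec.key, []).append("intolerance_unassessed")
        if not result.passes:
            flags.setdefault(rec.key, []).append("intolerance_fail")
            if intolerance_mode == "filter":
                continue
        survivors.append((rec, ann))
    intol_entry = ("intolerance", count_by_region(rec for rec, _ in survivors))
    return survivors, [vote_entry, intol_entry], flags
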