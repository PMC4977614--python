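"""Relatedness QC: compare pairwise rare-variant sharing against
pedigree-expected kinship to catch sample swaps and mislabeled relatives.

The sharing statistic is the Jaccard index over per-sample rare-carrier
sets.  Because rare-variant Jaccard has no closed-form mapping to kinship,
concordance is judged by rank: within the cohort, a pair's observed-sharing
rank must fall inside the rank band its expected-kinship class occupies
(plus a configurable slack).  Additionally, any pair expected to be
unrelated whose observed sharing exceeds an absolute ceiling is flagged.
The check is advisory by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .model import Pedigree, ValidationError

DEFAULT_RANK_TOLERANCE = 0.25
DEFAULT_ZERO_KINSHIP_MAX_SHARING = 0.1
DEFAULT_MIN_PAIR_UNION = 50


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Recursive pedigree kinship phi(i, j); founders unrelated."""
    return ped.kinship(i, j)


def observed_sharing(
    rare_carrier_sets: Mapping[str, set],
    i: str,
    j: str,
) -> Optional[float]:
    """Jaccard index of two samples' rare-variant carrier sets.

    Returns None (missing) when both sets are empty.
    """
    try:
        a, b = rare_carrier_sets[i], rare_carrier_sets[j]
    except KeyError as exc:
        raise ValidationError(f"no rare-carrier set for sample {exc.args[0]!r}") from exc
    union = len(a | b)
    if union == 0:
        return None
    return len(a & b) / union


@dataclass
class PairResult:
    pair: tuple[str, str]
    expected_kinship: float
    observed_sharing: Optional[float]
    concordant: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class RelatednessReport:
    pairs: list[PairResult]

    @property
    def flagged(self) -> list[tuple[str, str]]:
        return [p.pair for p in self.pairs if not p.concordant]

    def to_tsv(self) -> str:
        lines = ["sample_i\tsample_j\texpected_kinship\tobserved_sharing\tconcordant\treasons"]
        for p in self.pairs:
            obs = "." if p.observed_sharing is None else format(p.observed_sharing, "g")
            reasons = "|".join(p.reasons) if p.reasons else "."
            lines.append(
                f"{p.pair[0]}\t{p.pair[1]}\t{format(p.expected_kinship, 'g')}\t"
                f"{obs}\t{int(p.concordant)}\t{reasons}"
            )
        return "\n".join(lines) + "\n"


def relatedness_check(
    ped: Pedigree,
    rare_carrier_sets: Mapping[str, set],
    rank_tolerance: float = DEFAULT_RANK_TOLERANCE,
    zero_kinship_max_sharing: float = DEFAULT_ZERO_KINSHIP_MAX_SHARING,
    min_pair_union: int = DEFAULT_MIN_PAIR_UNION,
) -> RelatednessReport:
    """Flag sample pairs whose observed sharing contradicts the pedigree.

    ``rank_tolerance`` is the slack, as a fraction of the number of pairs,
    allowed between a pair's observed-sharing rank and the rank band of its
    expected-kinship class.  Ranking needs >= 2 pairs; a single pair is
    judged on the absolute rule only.  Pairs whose carrier-set union holds
    fewer than ``min_pair_union`` rare variants give too noisy a Jaccard
    estimate; they are reported but exempt from both rules
    (reason ``insufficient_data``).
    """
    samples = sorted(
        m.member_id for m in ped.sequenced_members() if m.member_id in rare_carrier_sets
    )
    if len(samples) < 2:
        raise ValidationError("relatedness check needs at least 2 sequenced samples")

    results: list[PairResult] = []
    assessable: list[PairResult] = []
    for a_idx in range(len(samples)):
        for b_idx in range(a_idx + 1, len(samples)):
            i, j = samples[a_idx], samples[b_idx]
            union = len(rare_carrier_sets[i] | rare_carrier_sets[j])
            p = PairResult(
                pair=(i, j),
                expected_kinship=ped.kinship(i, j),
                observed_sharing=observed_sharing(rare_carrier_sets, i, j),
                concordant=True,
            )
            results.append(p)
            if union < min_pair_union:
                p.reasons.append("insufficient_data")
            else:
                assessable.append(p)

    # absolute rule: expected-unrelated pairs with high sharing
    for p in assessable:
        if (
            p.expected_kinship == 0.0
            and p.observed_sharing is not None
            and p.observed_sharing > zero_kinship_max_sharing
        ):
            p.concordant = False
            p.reasons.append("unrelated_pair_high_sharing")

    # rank rule over pairs with an observed value
    ranked = [p for p in assessable if p.observed_sharing is not None]
    if len(ranked) >= 2:
        n = len(ranked)
        slack = rank_tolerance * n
        exp = np.array([p.expected_kinship for p in ranked])
        obs = np.array([p.observed_sharing for p in ranked])
        obs_rank = rankdata(obs, method="average")
        order = np.argsort(exp, kind="stable")
        # rank band occupied by each expected-kinship class
        band: dict[float, tuple[float, float]] = {}
        pos = 1
        for value in sorted(set(exp)):
            count = int(np.sum(exp == value))
            band[float(value)] = (pos, pos + count - 1)
            pos += count
        for p, r in zip(ranked, obs_rank):
            lo, hi = band[float(p.expected_kinship)]
            if r < lo - slack or r > hi + slack:
                p.concordant = False
                p.reasons.append("rank_discordant")

    return RelatednessReport(pairs=results)


def rare_carrier_sets_from_records(
    pairs: Sequence,
) -> dict[str, set[str]]:
    """Build per-sample carrier sets from (record, annotation) pairs."""
    out: dict[str, set[str]] = {}
    for rec, _ in pairs:
        for sid, call in rec.per_sample.items():
            out.setdefault(sid, set())
            if call.genotype.carries_alt:
                out[sid].add(rec.key)
    return out
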