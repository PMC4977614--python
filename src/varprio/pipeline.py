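"""Stage orchestration: technical QC -> rarity -> relatedness QC
(advisory) -> segregation -> score gate -> conservation -> region routing
-> branch evaluation, with per-variant provenance and the survivor funnel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import coding as coding_mod
from . import noncoding as noncoding_mod
from .config import PipelineConfig
from .frequency import is_rare
from .model import (
    AnnotationBundle,
    FilterFunnel,
    Pedigree,
    RegionClass,
    ValidationError,
    VariantRecord,
)
from .quality import QcThresholds, passes_technical_qc
from .ranking import Branch, CaddTier, cadd_tier, passes_cadd_gate, passes_conservation, route_region
from .relatedness import RelatednessReport, rare_carrier_sets_from_records, relatedness_check
from .segregation import SegregationPolicy, segregates

log = logging.getLogger("varprio")


class RelatednessAbort(RuntimeError):
    """Raised in strict mode when the relatedness QC flags pairs."""


@dataclass
class VariantTrace:
    """One variant's journey through the cascade."""

    record: VariantRecord
    annot: AnnotationBundle
    verdicts: list[tuple[str, bool, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    branch: Optional[Branch] = None
    tier: Optional[CaddTier] = None
    conservation_pass: Optional[bool] = None
    mirna_target: Optional[bool] = None
    rank: Optional[int] = None

    def mark(self, stage: str, passed: bool, detail: str = "") -> bool:
        self.verdicts.append((stage, passed, detail))
        return passed

    @property
    def alive(self) -> bool:
        return all(ok for _, ok, _ in self.verdicts)

    @property
    def first_failing_stage(self) -> Optional[str]:
        for stage, ok, _ in self.verdicts:
            if not ok:
                return stage
        return None

    def as_row(self) -> list:
        rec, ann = self.record, self.annot
        calls = ann.predictor_calls
        return [
            self.rank, rec.chrom, rec.pos, rec.ref, rec.alt,
            rec.vclass.value, rec.region.value,
            self.branch.value if self.branch else None,
            rec.qual, rec.upstream_filter,
            ann.maf_1kg, ann.maf_exac_nontcga, ann.maf_inhouse,
            ann.cadd_phred, self.tier.value if self.tier else None,
            ann.gerp, ann.phastcons, self.conservation_pass,
            calls.get("mutation_taster"), calls.get("polyphen2"),
            calls.get("provean"), calls.get("sift"),
            ann.intolerance_pct.get("inhouse"), ann.intolerance_pct.get("esp"),
            ann.intolerance_pct.get("exac"),
            ann.regulome_rank, ann.haploreg_flags, ann.mirsvr, self.mirna_target,
            self.flags,
            ";".join(f"{s}={'pass' if ok else 'FAIL'}" for s, ok, _ in self.verdicts),
        ]


@dataclass
class PipelineResult:
    candidates: list[VariantTrace]
    traces: list[VariantTrace]
    funnel: FilterFunnel
    relatedness: Optional[RelatednessReport]

    def candidate_keys(self) -> set[str]:
        return {t.record.key for t in self.candidates}


def _count_alive(traces: Sequence[VariantTrace]) -> dict[str, int]:
    counts = {r.value: 0 for r in RegionClass}
    for t in traces:
        if t.alive:
            counts[t.record.region.value] += 1
    return counts


def run_pipeline(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    ped: Pedigree,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full cascade in memory.

    Every input variant gets a trace with one verdict per stage it reached,
    so the first failing stage of every eliminated variant is recoverable.
    Relatedness QC is advisory: it warns and continues unless
    ``strict_relatedness`` is set.
    """
    config = (config or PipelineConfig()).validate()
    if config.family is None:
        fams = ped.family_ids
        if len(fams) > 1:
            raise ValidationError(
                f"PED holds several families {fams}; select one via config.family"
            )
        family = fams[0] if fams else None
    else:
        family = config.family

    traces = [VariantTrace(rec, ann) for rec, ann in pairs]
    funnel = FilterFunnel()
    funnel.add_stage("input", _count_alive(traces))

    # --- technical QC -----------------------------------------------------
    thr = QcThresholds(
        min_qual=config.min_qual,
        min_depth=config.min_depth,
        strict=config.qc_strict,
        depth_scope=config.depth_scope,
        require_biallelic_strand=config.require_strand_bias,
        indel_missing_filter_fails=config.indel_missing_filter_fails,
    )
    for t in traces:
        t.mark("technical_qc", passes_technical_qc(t.record, thr))
    funnel.add_stage("technical_qc", _count_alive(traces))

    # --- rarity -----------------------------------------------------------
    for t in traces:
        if t.alive:
            t.mark("rarity", is_rare(t.annot, config.maf_cutoff))
    funnel.add_stage("rarity", _count_alive(traces))

    # --- relatedness QC (advisory, not a variant filter) ------------------
    relatedness: Optional[RelatednessReport] = None
    rare_pairs = [(t.record, t.annot) for t in traces if t.alive]
    sequenced = [m for m in ped.sequenced_members() if family is None or m.family_id == family]
    if len(sequenced) >= 2 and rare_pairs:
        carrier_sets = rare_carrier_sets_from_records(rare_pairs)
        relatedness = relatedness_check(
            ped,
            carrier_sets,
            rank_tolerance=config.relatedness_rank_tolerance,
            zero_kinship_max_sharing=config.relatedness_zero_kinship_max_sharing,
            min_pair_union=config.relatedness_min_pair_union,
        )
        if relatedness.flagged:
            log.warning("relatedness QC flagged pairs: %s", relatedness.flagged)
            if config.strict_relatedness:
                raise RelatednessAbort(
                    f"relatedness QC flagged sample pairs: {relatedness.flagged}"
                )

    # --- segregation ------------------------------------------------------
    policy = SegregationPolicy(
        model=config.seg_model,
        max_missing_definite_cases=config.max_missing_definite_cases,
        max_missing_phenocopy_cases=config.max_missing_phenocopy_cases,
        max_carrier_noncarrier_controls=config.max_carrier_noncarrier_controls,
        max_carrier_possible_controls=config.max_carrier_possible_controls,
        missing_genotype_rule=config.missing_genotype_rule,
    )
    for t in traces:
        if t.alive:
            verdict = segregates(t.record, ped, policy, family)
            detail = ",".join(f"{m}:{c}" for m, c in verdict.violated_constraints)
            t.mark("segregation", verdict.passes, detail)
    funnel.add_stage("segregation", _count_alive(traces))

    # --- score gate -------------------------------------------------------
    for t in traces:
        t.tier = cadd_tier(t.annot.cadd_phred)
        if t.alive:
            threshold = config.cadd_region_thresholds.get(
                t.record.region.value, config.cadd_threshold
            )
            t.mark(
                "cadd_gate",
                passes_cadd_gate(t.annot, threshold, config.cadd_missing_passes),
            )
    funnel.add_stage("cadd_gate", _count_alive(traces))

    # --- conservation -----------------------------------------------------
    for t in traces:
        t.conservation_pass = passes_conservation(
            t.annot,
            mode=config.conservation_mode,
            gerp_threshold=config.gerp_threshold,
            phastcons_threshold=config.phastcons_threshold,
        )
        if t.conservation_pass:
            t.flags.append("conserved")
        if t.alive:
            gate = config.conservation_gate
            if gate == "all" or (
                gate == "noncoding" and route_region(t.record) is not Branch.CODING
            ):
                t.mark("conservation", bool(t.conservation_pass))
            else:
                t.mark("conservation", True)
    funnel.add_stage("conservation", _count_alive(traces))

    # --- routing + branch evaluation -------------------------------------
    by_branch: dict[Branch, list[VariantTrace]] = {b: [] for b in Branch}
    for t in traces:
        t.branch = route_region(t.record)
        if t.alive:
            by_branch[t.branch].append(t)

    trace_by_key = {t.record.key: t for t in traces}

    # coding: consensus vote, then intolerance as a separately logged sub-stage
    coding_pairs = [(t.record, t.annot) for t in by_branch[Branch.CODING]]
    _, _, cflags = coding_mod.evaluate_coding(
        coding_pairs,
        vote_threshold=config.vote_threshold,
        intolerance_mode=config.intolerance_mode,
        max_pct=config.intolerance_max_pct,
        min_sources=config.intolerance_min_sources,
        nonmissense_policy=config.nonmissense_policy,
    )
    for key, fl in cflags.items():
        trace_by_key[key].flags.extend(fl)
    for t in by_branch[Branch.CODING]:
        voted_out = (
            t.record.region is RegionClass.MISSENSE
            and not coding_mod.consensus_deleterious(
                t.annot.predictor_calls, config.vote_threshold
            )
        ) or (
            t.record.region is not RegionClass.MISSENSE
            and config.nonmissense_policy == "reject"
        )
        t.mark("branch", not voted_out, "coding_vote")

    # non-coding branches
    noncoding_flags: dict[str, list[str]] = {}
    for branch in (Branch.UTR5, Branch.UTR3, Branch.INTERGENIC):
        bpairs = [(t.record, t.annot) for t in by_branch[branch]]
        bsurv, _, bflags = noncoding_mod.evaluate_noncoding(
            bpairs,
            branch,
            min_level=(config.min_evidence_ordinal, config.min_evidence_flags),
            mirna_hard=config.mirna_hard,
            mirsvr_threshold=config.mirsvr_threshold,
            conservation_mode=config.conservation_mode,
        )
        keys = {rec.key for rec, _ in bsurv}
        for key, fl in bflags.items():
            noncoding_flags.setdefault(key, []).extend(fl)
        for t in by_branch[branch]:
            t.mark("branch", t.record.key in keys, f"branch_{branch.value}")
            if branch is Branch.UTR3:
                t.mirna_target = noncoding_mod.good_mirna_target(
                    t.annot.mirsvr, config.mirsvr_threshold
                )
    for key, fl in noncoding_flags.items():
        for f in fl:
            if f not in trace_by_key[key].flags:
                trace_by_key[key].flags.append(f)

    # routed "other": reported, never silently dropped
    for t in by_branch[Branch.OTHER]:
        t.flags.append("unrouted_region")
        t.mark("branch", True, "unrouted")

    # branch stage entry (post-vote, pre-intolerance)
    funnel.add_stage("branch", _count_alive(traces))

    # intolerance sub-stage (eliminates only in filter mode)
    intol_fail = {
        key for key, fl in cflags.items() if "intolerance_fail" in fl
    }
    for t in by_branch[Branch.CODING]:
        if t.alive and t.record.region is RegionClass.MISSENSE:
            failed = t.record.key in intol_fail
            if config.intolerance_mode == "filter":
                t.mark("intolerance", not failed)
            else:
                t.mark("intolerance", True)
    funnel.add_stage("intolerance", _count_alive(traces))

    # --- final ranking ----------------------------------------------------
    candidates = [t for t in traces if t.alive]

    def sort_key(t: VariantTrace):
        cadd = t.annot.cadd_phred
        ev = noncoding_mod.regulatory_evidence_score(t.annot)
        return (
            0 if cadd is not None else 1,
            -(cadd or 0.0),
            0 if t.mirna_target else 1,
            -ev.regulome_ordinal,
            -ev.flag_count,
        )

    candidates.sort(key=sort_key)  # stable: input order breaks ties
    for i, t in enumerate(candidates, start=1):
        t.rank = i
    return PipelineResult(
        candidates=candidates, traces=traces, funnel=funnel, relatedness=relatedness
    )


def summarize_funnel(funnel: FilterFunnel) -> str:
    """Human-readable funnel table: rows = stages, columns = region classes.

    When both the branch-vote and intolerance stages are present, the
    intolerance row shows ``with (without)`` counts per the reporting
    convention for supplementary intolerance screening.
    """
    classes = funnel.region_classes() or [r.value for r in RegionClass]
    rows = [["stage"] + classes + ["total"]]
    counts_by_stage = dict(funnel.stages)
    for name, counts in funnel.stages:
        if name == "intolerance" and "branch" in counts_by_stage:
            vote = counts_by_stage["branch"]
            cells = [
                f"{counts.get(c, 0)} ({vote.get(c, 0)})" for c in classes
            ]
            total = f"{sum(counts.values())} ({sum(vote.values())})"
        else:
            cells = [str(counts.get(c, 0)) for c in classes]
            total = str(sum(counts.values()))
        rows.append([name] + cells + [total])
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows
    ]
    return "\n".join(lines) + "\n"
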