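"""Synthetic-cohort generator: multi-generation pedigrees, gene-dropped
genotypes, one injected dominant causal variant with incomplete penetrance
and phenocopies, background decoy variants, and simulated annotation
scores.  Everything is reproducible from a single seed and writes the same
standard formats (VCF + PED + status sidecar + annotation TSV) that the
real readers consume.

Member statuses are assigned from observable phenotype and age only —
never from hidden carrier truth — so segregation tests on simulated data
are not circular.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import DEFAULT_KEY_MAP, write_pedigree
from .model import (
    AnnotationBundle,
    Genotype,
    Pedigree,
    PedigreeMember,
    REGULOME_CATEGORIES,
    RegionClass,
    SampleCall,
    Sex,
    Status,
    ValidationError,
    VariantRecord,
)

_BASES = ("A", "C", "G", "T")

_DECOY_REGION_WEIGHTS = {
    RegionClass.MISSENSE: 0.25,
    RegionClass.OTHER_CODING: 0.05,
    RegionClass.UTR5: 0.10,
    RegionClass.UTR3: 0.20,
    RegionClass.INTRONIC: 0.18,
    RegionClass.INTERGENIC: 0.15,
    RegionClass.SPLICING: 0.04,
    RegionClass.OTHER: 0.03,
}

_HAPLOREG_TAGS = ("enhancer", "promoter", "TFBS", "eQTL", "DNase")


def _r6(v: float) -> float:
    """Quantize to 6 significant digits so values survive a VCF round trip
    (htslib stores INFO floats in 32 bits)."""
    return float(format(v, ".6g"))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort."""

    # pedigree template
    generations: int = 3           # descendant generations below the top couple
    sibship_size: int = 3
    reproducing_per_sibship: int = 2
    sequencing_subset: Sequence[str] | str = "all"

    # variants
    n_decoy_variants: int = 60
    decoy_founder_freq_beta: tuple[float, float] = (0.5, 20.0)
    p_decoy_common: float = 0.2        # decoy catalog MAF pushed above the cutoff
    p_decoy_maf_missing: float = 0.25
    p_decoy_indel: float = 0.12
    p_decoy_qc_fail: float = 0.10
    p_boundary_decoy: float = 0.05     # exact-threshold annotation values
    p_missing_genotype: float = 0.02
    maf_cutoff: float = 0.001

    # causal variant
    causal_penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    causal_region: RegionClass = RegionClass.MISSENSE
    causal_cadd_range: tuple[float, float] = (32.0, 40.0)
    decoy_cadd_max: float = 30.0

    # phenotype / status model
    current_year: int = 2015
    founder_birth_year: int = 1920
    generation_gap: int = 28
    phenocopy_age: int = 75
    noncarrier_age: int = 60

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("causal_penetrance", "phenocopy_rate", "p_decoy_common",
                     "p_decoy_maf_missing", "p_decoy_indel", "p_decoy_qc_fail",
                     "p_boundary_decoy", "p_missing_genotype"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.n_decoy_variants < 0:
            raise ValidationError("n_decoy_variants must be >= 0")
        if self.generations < 1 or self.sibship_size < 1:
            raise ValidationError("need >= 1 generation and sibship size >= 1")
        if self.reproducing_per_sibship > self.sibship_size:
            raise ValidationError("reproducing_per_sibship exceeds sibship_size")


def simulate_pedigree(spec: SimulationSpec) -> Pedigree:
    """Build the template pedigree: a top founder couple, fixed-size
    sibships, and married-in founder spouses for reproducing children."""
    members: list[PedigreeMember] = []

    def year(gen: int) -> int:
        return spec.founder_birth_year + gen * spec.generation_gap

    top_f = PedigreeMember("g0p1", sex=Sex.MALE, birth_year=year(0))
    top_m = PedigreeMember("g0p2", sex=Sex.FEMALE, birth_year=year(0))
    members += [top_f, top_m]

    couples = [(top_f.member_id, top_m.member_id, 0)]
    child_counter = {g: 0 for g in range(1, spec.generations + 1)}
    while couples:
        father, mother, gen = couples.pop(0)
        child_gen = gen + 1
        if child_gen > spec.generations:
            continue
        for k in range(spec.sibship_size):
            child_counter[child_gen] += 1
            cid = f"g{child_gen}i{child_counter[child_gen]}"
            sex = Sex.MALE if child_counter[child_gen] % 2 == 1 else Sex.FEMALE
            members.append(
                PedigreeMember(
                    cid, father_id=father, mother_id=mother, sex=sex,
                    birth_year=year(child_gen),
                )
            )
            if k < spec.reproducing_per_sibship and child_gen < spec.generations:
                sp_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                spouse = PedigreeMember(
                    f"{cid}sp", sex=sp_sex, birth_year=year(child_gen)
                )
                members.append(spouse)
                if sex is Sex.MALE:
                    couples.append((cid, spouse.member_id, child_gen))
                else:
                    couples.append((spouse.member_id, cid, child_gen))
    return Pedigree(members)


# ---------------------------------------------------------------------------
# gene drop


def gene_drop_matrix(
    ped: Pedigree,
    founder_freqs: np.ndarray,
    rng: np.random.Generator,
    founder_counts: Optional[dict[str, np.ndarray]] = None,
) -> tuple[list[str], np.ndarray]:
    """Drop ``len(founder_freqs)`` independent variants through the pedigree.

    Founder alt-allele counts are Binomial(2, freq) unless fixed via
    ``founder_counts``; each child inherits one allele from each parent
    uniformly at random.  Returns (member order, alt-allele count matrix of
    shape (n_members, n_variants)).
    """
    freqs = np.asarray(founder_freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("founder allele frequencies must be in [0,1]")
    n = freqs.shape[0]
    order = ped.topological_order()
    index = {mid: k for k, mid in enumerate(order)}
    counts = np.zeros((len(order), n), dtype=np.int8)
    for mid in order:
        m = ped.members[mid]
        if m.is_founder:
            if founder_counts is not None and mid in founder_counts:
                counts[index[mid]] = founder_counts[mid]
            else:
                counts[index[mid]] = rng.binomial(2, freqs)
        else:
            got = np.zeros(n, dtype=np.int8)
            for pid in (m.father_id, m.mother_id):
                # transmit alt with probability (parent count)/2, exactly Mendelian
                g = counts[index[pid]] if pid is not None else np.zeros(n, dtype=np.int8)
                got += (rng.random(n) < g / 2.0).astype(np.int8)
            counts[index[mid]] = got
    return order, counts


def gene_drop(
    ped: Pedigree, founder_allele_freq: float, seed: int | np.random.Generator
) -> dict[str, Genotype]:
    """Drop a single variant; returns member -> genotype."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order, counts = gene_drop_matrix(ped, np.array([founder_allele_freq]), rng)
    lut = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
    return {mid: lut[int(counts[k, 0])] for k, mid in enumerate(order)}


def transmit_from_founder(
    ped: Pedigree,
    origin: str,
    rng: np.random.Generator,
    n: int = 1,
) -> tuple[list[str], np.ndarray]:
    """Drop ``n`` variants that are heterozygous in one founder and absent
    from every other founder (family-private alleles)."""
    if origin not in ped:
        raise ValidationError(f"unknown origin founder: {origin!r}")
    if not ped.members[origin].is_founder:
        raise ValidationError(f"causal origin {origin!r} is not a founder")
    fixed = {f: np.zeros(n, dtype=np.int8) for f in ped.founders()}
    fixed[origin] = np.ones(n, dtype=np.int8)
    return gene_drop_matrix(ped, np.zeros(n), rng, founder_counts=fixed)


# ---------------------------------------------------------------------------
# causal injection and status assignment


@dataclass
class CausalInjection:
    origin: str
    carrier_counts: dict[str, int]
    affected: dict[str, bool]
    statuses: dict[str, Status]
    diagnosis_age: dict[str, int]


def inject_causal(
    ped: Pedigree,
    spec: SimulationSpec,
    rng: np.random.Generator,
    origin: str = "g0p1",
) -> CausalInjection:
    """Transmit the causal allele from ``origin``, draw affection from
    penetrance/phenocopy probabilities, then assign five-level statuses
    from observable phenotype and age alone.

    Status rules (age = years at ``current_year``):
      affected, onset age <  ``phenocopy_age``  -> CASE_DEFINITE
      affected, onset age >= ``phenocopy_age``  -> CASE_POSSIBLE_PHENOCOPY
      unaffected, age >= ``noncarrier_age``     -> CONTROL_NONCARRIER
      unaffected, younger                       -> CONTROL_POSSIBLE_CARRIER
    Phenocopies only arise in members old enough to be sporadic cases, so
    their onset is always late.
    """
    order, counts = transmit_from_founder(ped, origin, rng, n=1)
    carrier_counts = {mid: int(counts[k, 0]) for k, mid in enumerate(order)}

    affected: dict[str, bool] = {}
    statuses: dict[str, Status] = {}
    diagnosis_age: dict[str, int] = {}
    for mid in order:
        m = ped.members[mid]
        age_now = spec.current_year - (m.birth_year or spec.founder_birth_year)
        if carrier_counts[mid] > 0:
            is_affected = bool(rng.random() < spec.causal_penetrance)
            onset = int(np.clip(rng.normal(55, 8), 30, spec.phenocopy_age - 1))
        else:
            can_be_phenocopy = age_now > spec.phenocopy_age
            is_affected = bool(
                can_be_phenocopy and rng.random() < spec.phenocopy_rate
            )
            onset = int(rng.uniform(spec.phenocopy_age, max(age_now, spec.phenocopy_age + 1)))
        affected[mid] = is_affected
        if is_affected:
            onset = min(onset, age_now)
            diagnosis_age[mid] = onset
            statuses[mid] = (
                Status.CASE_POSSIBLE_PHENOCOPY
                if onset >= spec.phenocopy_age
                else Status.CASE_DEFINITE
            )
        else:
            statuses[mid] = (
                Status.CONTROL_NONCARRIER
                if age_now >= spec.noncarrier_age
                else Status.CONTROL_POSSIBLE_CARRIER
            )
    return CausalInjection(
        origin=origin,
        carrier_counts=carrier_counts,
        affected=affected,
        statuses=statuses,
        diagnosis_age=diagnosis_age,
    )


# ---------------------------------------------------------------------------
# annotations


def _decoy_bundle(spec: SimulationSpec, region: RegionClass, rng: np.random.Generator) -> AnnotationBundle:
    def maybe_boundary(value: float, boundary: float) -> float:
        return boundary if rng.random() < spec.p_boundary_decoy else value

    if rng.random() < spec.p_decoy_common:
        maf = float(rng.uniform(spec.maf_cutoff, 0.05))
    else:
        maf = float(rng.beta(0.4, 400))
    maf_1kg = None if rng.random() < spec.p_decoy_maf_missing else _r6(
        min(maybe_boundary(maf, spec.maf_cutoff), 1.0)
    )
    maf_exac = None if rng.random() < spec.p_decoy_maf_missing else _r6(
        min(float(maf * rng.uniform(0.5, 1.5)), 1.0)
    )

    cadd = None
    if rng.random() > 0.08:
        cadd = float(rng.uniform(0.0, spec.decoy_cadd_max))
        cadd = _r6(maybe_boundary(cadd, float(rng.choice([10.0, 20.0, 30.0]))))
    gerp = None if rng.random() < 0.2 else _r6(maybe_boundary(float(rng.normal(0.5, 2.0)), 2.0))
    phast = None if rng.random() < 0.2 else _r6(maybe_boundary(float(rng.beta(0.4, 1.2)), 0.3))

    preds = {}
    if region is RegionClass.MISSENSE:
        for p in ("mutation_taster", "polyphen2", "provean", "sift"):
            if rng.random() < 0.9:
                preds[p] = "deleterious" if rng.random() < 0.35 else "tolerated"
    intol = {}
    for s in ("inhouse", "esp", "exac"):
        if rng.random() < 0.7:
            intol[s] = _r6(float(rng.uniform(0, 100)))
    regulome = (
        str(rng.choice(REGULOME_CATEGORIES)) if rng.random() < 0.6 else None
    )
    flags = frozenset(t for t in _HAPLOREG_TAGS if rng.random() < 0.2)
    mirsvr = None
    if region is RegionClass.UTR3 and rng.random() < 0.8:
        mirsvr = _r6(maybe_boundary(float(rng.normal(-0.1, 0.2)), -0.1))
    return AnnotationBundle(
        maf_1kg=maf_1kg,
        maf_exac_nontcga=maf_exac,
        cadd_phred=cadd,
        gerp=gerp,
        phastcons=phast,
        predictor_calls=preds,
        intolerance_pct=intol,
        regulome_rank=regulome,
        haploreg_flags=flags,
        mirsvr=mirsvr,
    )


def _causal_bundle(spec: SimulationSpec, rng: np.random.Generator) -> AnnotationBundle:
    """Deleterious parameter set: clears rarity, the score gate,
    conservation, and the branch-specific checks by construction."""
    region = spec.causal_region
    preds = {}
    if region is RegionClass.MISSENSE:
        n_del = 4 if rng.random() < 0.5 else 3
        keys = ["mutation_taster", "polyphen2", "provean", "sift"]
        del_keys = list(rng.permutation(keys))[:n_del]
        preds = {k: ("deleterious" if k in del_keys else "tolerated") for k in keys}
    mirsvr = _r6(rng.uniform(-1.2, -0.3)) if region is RegionClass.UTR3 else None
    return AnnotationBundle(
        maf_1kg=None,  # novel: absent from the catalogs
        maf_exac_nontcga=None,
        cadd_phred=_r6(rng.uniform(*spec.causal_cadd_range)),
        gerp=_r6(rng.uniform(3.0, 6.0)),
        phastcons=_r6(rng.uniform(0.6, 1.0)),
        predictor_calls=preds,
        intolerance_pct={s: _r6(rng.uniform(1, 20)) for s in ("inhouse", "esp", "exac")},
        regulome_rank="1a" if region is not RegionClass.MISSENSE else None,
        haploreg_flags=(
            frozenset({"enhancer", "TFBS", "eQTL"})
            if region is not RegionClass.MISSENSE
            else frozenset()
        ),
        mirsvr=mirsvr,
    )


def simulate_annotations(
    n_variants: int,
    causal_index: Optional[int],
    spec: SimulationSpec,
    rng: np.random.Generator,
    regions: Sequence[RegionClass],
) -> list[AnnotationBundle]:
    """Per-variant annotation bundles; the causal index draws from the
    deleterious parameter set, decoys from background distributions that
    deliberately include exact-threshold values."""
    out = []
    for i in range(n_variants):
        if causal_index is not None and i == causal_index:
            out.append(_causal_bundle(spec, rng))
        else:
            out.append(_decoy_bundle(spec, regions[i], rng))
    return out


# ---------------------------------------------------------------------------
# whole cohorts


@dataclass
class Cohort:
    spec: SimulationSpec
    pedigree: Pedigree
    pairs: list[tuple[VariantRecord, AnnotationBundle]]
    causal_key: str
    injection: CausalInjection
    decoy_carrier_counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return sorted(m.member_id for m in self.pedigree.sequenced_members())


def _read_evidence(
    genotype: Genotype,
    rng: np.random.Generator,
    deep: bool,
) -> tuple[int, int, int]:
    """Depth and per-strand alt read counts consistent with the genotype."""
    depth = int(20 + rng.poisson(20)) if deep else int(max(8, rng.poisson(30)))
    if not genotype.carries_alt:
        return depth, 0, 0
    vaf = 0.5 if genotype is Genotype.HET else 0.95
    alt = int(np.clip(rng.binomial(depth, vaf), 2, depth))
    fwd = int(np.clip(rng.binomial(alt, 0.5), 1, alt - 1))
    return depth, fwd, alt - fwd


def simulate_cohort(spec: SimulationSpec) -> Cohort:
    """Generate a full cohort: pedigree + statuses, one causal variant,
    gene-dropped decoys, read evidence, and annotations."""
    rng = np.random.default_rng(spec.seed)
    ped = simulate_pedigree(spec)
    injection = inject_causal(ped, spec, rng)

    # apply statuses/affection to the pedigree; sequencing subset
    if spec.sequencing_subset == "all":
        sequenced = set(ped.members)
    else:
        sequenced = set(spec.sequencing_subset)
        unknown = sequenced - set(ped.members)
        if unknown:
            raise ValidationError(f"sequencing subset names unknown members: {sorted(unknown)}")
    for mid, m in ped.members.items():
        m.affected = injection.affected[mid]
        if mid in injection.diagnosis_age and m.birth_year is not None:
            m.diagnosis_year = m.birth_year + injection.diagnosis_age[mid]
        if mid in sequenced:
            m.sequenced = True
            m.status = injection.statuses[mid]

    samples = sorted(sequenced)
    n_dec = spec.n_decoy_variants
    founder_freqs = rng.beta(*spec.decoy_founder_freq_beta, size=n_dec)
    order, decoy_counts = gene_drop_matrix(ped, founder_freqs, rng)
    index = {mid: k for k, mid in enumerate(order)}

    # condition decoys on being polymorphic in the sequenced cohort — a
    # multi-sample VCF only carries sites with alt evidence in the cohort
    seq_rows = np.array([index[mid] for mid in samples])
    for _ in range(25):
        absent = np.flatnonzero(decoy_counts[seq_rows].sum(axis=0) == 0)
        if absent.size == 0:
            break
        forced_founder = rng.choice(ped.founders(), size=absent.size)
        redraw_freqs = founder_freqs[absent]
        fixed: dict[str, np.ndarray] = {}
        for f in ped.founders():
            base = rng.binomial(2, redraw_freqs)
            base[forced_founder == f] = np.maximum(base[forced_founder == f], 1)
            fixed[f] = base.astype(np.int8)
        _, redrawn = gene_drop_matrix(ped, redraw_freqs, rng, founder_counts=fixed)
        decoy_counts[:, absent] = redrawn

    n_total = n_dec + 1
    causal_index = int(rng.integers(0, n_total))
    regions: list[RegionClass] = []
    region_values = list(_DECOY_REGION_WEIGHTS)
    region_p = np.array(list(_DECOY_REGION_WEIGHTS.values()))
    region_p = region_p / region_p.sum()
    region_draws = rng.choice(len(region_values), size=n_total, p=region_p)
    for i in range(n_total):
        regions.append(
            spec.causal_region if i == causal_index else region_values[int(region_draws[i])]
        )

    bundles = simulate_annotations(n_total, causal_index, spec, rng, regions)

    chroms = np.sort(rng.integers(1, 23, size=n_total))
    positions = rng.integers(10_000, 50_000_000, size=n_total)

    pairs: list[tuple[VariantRecord, AnnotationBundle]] = []
    causal_key = ""
    decoy_j = 0
    for i in range(n_total):
        is_causal = i == causal_index
        region = regions[i]
        if is_causal:
            counts_i = {mid: injection.carrier_counts[mid] for mid in samples}
            is_indel = False
        else:
            counts_i = {mid: int(decoy_counts[index[mid], decoy_j]) for mid in samples}
            is_indel = bool(rng.random() < spec.p_decoy_indel)
            decoy_j += 1

        ref = str(rng.choice(_BASES))
        if is_indel:
            alt_base = str(rng.choice([b for b in _BASES if b != ref]))
            ref, alt = ref + alt_base, ref
        else:
            alt = str(rng.choice([b for b in _BASES if b != ref]))

        qual = float(rng.uniform(50, 90)) if is_causal else float(rng.uniform(25, 90))
        upstream = "PASS"
        qc_fail_mode = None
        if not is_causal and rng.random() < spec.p_decoy_qc_fail:
            qc_fail_mode = str(
                rng.choice(["low_qual", "low_depth", "strand", "filter"])
            )
            if qc_fail_mode == "low_qual":
                qual = float(rng.uniform(2, 20))
            elif qc_fail_mode == "filter":
                upstream = "badReads" if is_indel else upstream

        per_sample: dict[str, SampleCall] = {}
        for mid in samples:
            geno = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[counts_i[mid]]
            if not is_causal and rng.random() < spec.p_missing_genotype:
                per_sample[mid] = SampleCall(Genotype.MISSING, depth=None)
                continue
            depth, fwd, rev = _read_evidence(geno, rng, deep=is_causal)
            if qc_fail_mode == "low_depth" and geno.carries_alt:
                depth = int(rng.integers(0, 6))
                fwd = min(fwd, depth)
                rev = min(rev, depth - fwd)
            elif qc_fail_mode == "strand" and geno.carries_alt:
                fwd, rev = fwd + rev, 0
            per_sample[mid] = SampleCall(geno, depth=depth, alt_fwd=fwd, alt_rev=rev)

        record = VariantRecord(
            chrom=str(int(chroms[i])),
            pos=int(positions[i]) + i,  # avoid collisions
            ref=ref,
            alt=alt,
            region=region,
            qual=round(qual, 2),
            upstream_filter=upstream,
            per_sample=per_sample,
        )
        if is_causal:
            causal_key = record.key
        pairs.append((record, bundles[i]))

    pairs.sort(key=lambda p: (int(p[0].chrom), p[0].pos, p[0].ref, p[0].alt))
    decoy_carriers = {mid: decoy_counts[index[mid]] for mid in order}
    return Cohort(
        spec=spec,
        pedigree=ped,
        pairs=pairs,
        causal_key=causal_key,
        injection=injection,
        decoy_carrier_counts=decoy_carriers,
    )


# ---------------------------------------------------------------------------
# writers (fixtures exercise the real readers)

_VCF_INFO_HEADER = """\
##INFO=<ID={maf_1kg},Number=A,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID={maf_exac_nontcga},Number=A,Type=Float,Description="non-TCGA ExAC allele frequency">
##INFO=<ID={maf_inhouse},Number=A,Type=Float,Description="in-house control allele frequency">
##INFO=<ID={cadd_phred},Number=A,Type=Float,Description="scaled deleteriousness score">
##INFO=<ID={gerp},Number=A,Type=Float,Description="rejected-substitution conservation score">
##INFO=<ID={phastcons},Number=A,Type=Float,Description="conserved-element probability">
##INFO=<ID={mutation_taster},Number=A,Type=String,Description="predictor call (D/T)">
##INFO=<ID={polyphen2},Number=A,Type=String,Description="predictor call (D/T)">
##INFO=<ID={provean},Number=A,Type=String,Description="predictor call (D/T)">
##INFO=<ID={sift},Number=A,Type=String,Description="predictor call (D/T)">
##INFO=<ID={intolerance_inhouse},Number=A,Type=Float,Description="gene intolerance percentile (in-house)">
##INFO=<ID={intolerance_esp},Number=A,Type=Float,Description="gene intolerance percentile (ESP)">
##INFO=<ID={intolerance_exac},Number=A,Type=Float,Description="gene intolerance percentile (ExAC)">
##INFO=<ID={regulome_rank},Number=A,Type=String,Description="regulatory evidence category">
##INFO=<ID={haploreg_flags},Number=A,Type=String,Description="pipe-joined regulatory flags">
##INFO=<ID={mirsvr},Number=A,Type=Float,Description="miRNA target score">
##INFO=<ID={mirna_secondary},Number=A,Type=String,Description="secondary miRNA evidence (0/1)">
##INFO=<ID={region},Number=A,Type=String,Description="region class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID={depth},Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID={alt_fwd},Number=A,Type=Integer,Description="Alt-supporting forward reads">
##FORMAT=<ID={alt_rev},Number=A,Type=Integer,Description="Alt-supporting reverse reads">
"""

_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _info_value(v) -> Optional[str]:
    if v is None:
        return None
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return format(v, ".6g")
    if isinstance(v, frozenset):
        return "|".join(sorted(v)) if v else None
    return str(v)


def write_vcf(
    pairs: Sequence[tuple[VariantRecord, AnnotationBundle]],
    samples: Sequence[str],
    path: str | os.PathLike,
    key_map: Optional[dict[str, str]] = None,
) -> None:
    """Write (record, annotations) pairs as an uncompressed VCF v4.2."""
    km = dict(DEFAULT_KEY_MAP if key_map is None else key_map)
    chroms: list[str] = []
    for rec, _ in pairs:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("##FILTER=<ID=badReads,Description=\"Failed upstream caller filters\">\n")
        fh.write(_VCF_INFO_HEADER.format(**km))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for rec, ann in pairs:
            info_fields = []
            values = {
                "maf_1kg": ann.maf_1kg,
                "maf_exac_nontcga": ann.maf_exac_nontcga,
                "maf_inhouse": ann.maf_inhouse,
                "cadd_phred": ann.cadd_phred,
                "gerp": ann.gerp,
                "phastcons": ann.phastcons,
                "mutation_taster": {"deleterious": "D", "tolerated": "T"}.get(
                    ann.predictor_calls.get("mutation_taster")
                ),
                "polyphen2": {"deleterious": "D", "tolerated": "T"}.get(
                    ann.predictor_calls.get("polyphen2")
                ),
                "provean": {"deleterious": "D", "tolerated": "T"}.get(
                    ann.predictor_calls.get("provean")
                ),
                "sift": {"deleterious": "D", "tolerated": "T"}.get(
                    ann.predictor_calls.get("sift")
                ),
                "intolerance_inhouse": ann.intolerance_pct.get("inhouse"),
                "intolerance_esp": ann.intolerance_pct.get("esp"),
                "intolerance_exac": ann.intolerance_pct.get("exac"),
                "regulome_rank": ann.regulome_rank,
                "haploreg_flags": ann.haploreg_flags,
                "mirsvr": ann.mirsvr,
                "mirna_secondary": ann.mirna_secondary,
                "region": rec.region.value,
            }
            for name, value in values.items():
                s = _info_value(value)
                if s is not None and name in km:
                    info_fields.append(f"{km[name]}={s}")
            info = ";".join(info_fields) if info_fields else "."
            fmt = f"GT:{km['depth']}:{km['alt_fwd']}:{km['alt_rev']}"
            cols = [
                rec.chrom, str(rec.pos), ".", rec.ref, rec.alt,
                format(rec.qual, ".2f") if rec.qual is not None else ".",
                rec.upstream_filter or ".",
                info, fmt,
            ]
            for sid in samples:
                call = rec.per_sample.get(sid)
                if call is None:
                    cols.append("./.:.:.:.")
                    continue
                cols.append(
                    ":".join(
                        [
                            _GT_STRING[call.genotype],
                            "." if call.depth is None else str(call.depth),
                            "." if call.alt_fwd is None else str(call.alt_fwd),
                            "." if call.alt_rev is None else str(call.alt_rev),
                        ]
                    )
                )
            fh.write("\t".join(cols) + "\n")


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write VCF + PED + status sidecar (+ truth JSON lives with the caller)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "ped": os.path.join(out_dir, "cohort.ped"),
        "statuses": os.path.join(out_dir, "cohort.statuses.tsv"),
    }
    write_vcf(cohort.pairs, cohort.samples, paths["vcf"])
    write_pedigree(cohort.pedigree, paths["ped"], paths["statuses"])
    return paths
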