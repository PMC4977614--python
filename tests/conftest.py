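from __future__ import annotations

from typing import Mapping, Optional

import pytest

from varprio.model import (
    AnnotationBundle,
    Genotype,
    Pedigree,
    PedigreeMember,
    RegionClass,
    SampleCall,
    Sex,
    Status,
    VariantRecord,
)


def make_call(
    genotype: Genotype | str,
    depth: Optional[int] = 30,
    alt_fwd: Optional[int] = None,
    alt_rev: Optional[int] = None,
) -> SampleCall:
    g = Genotype(genotype)
    if g.carries_alt and alt_fwd is None and alt_rev is None:
        if depth is None:
            alt_fwd, alt_rev = 1, 1
        else:
            alt_fwd = min(7, max(depth // 2, 0))
            alt_rev = min(8, max(depth - alt_fwd, 0))
    return SampleCall(g, depth=depth, alt_fwd=alt_fwd, alt_rev=alt_rev)


def make_record(
    genotypes: Mapping[str, SampleCall | Genotype | str],
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    region: RegionClass = RegionClass.MISSENSE,
    qual: Optional[float] = 60.0,
    upstream_filter: Optional[str] = "PASS",
) -> VariantRecord:
    per_sample = {
        sid: call if isinstance(call, SampleCall) else make_call(call)
        for sid, call in genotypes.items()
    }
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, region=region,
        qual=qual, upstream_filter=upstream_filter, per_sample=per_sample,
    )


def member(mid, father=None, mother=None, sex=Sex.UNKNOWN, status=None, **kw):
    sequenced = status is not None
    return PedigreeMember(
        member_id=mid, father_id=father, mother_id=mother, sex=sex,
        status=status or Status.UNINFORMATIVE, sequenced=sequenced, **kw
    )


@pytest.fixture
def fig_family() -> Pedigree:
    """A three-generation high-risk family: two sibling cases plus their
    paternal aunt (possible phenocopy, late onset); among the healthy,
    one possible carrier and two non-carriers.  Six sequenced members."""
    return Pedigree([
        member("GF", sex=Sex.MALE),
        member("GM", sex=Sex.FEMALE),
        member("AUNT", "GF", "GM", Sex.FEMALE, Status.CASE_POSSIBLE_PHENOCOPY),
        member("DAD", "GF", "GM", Sex.MALE),
        member("MOM", sex=Sex.FEMALE),
        member("C1", "DAD", "MOM", Sex.MALE, Status.CASE_DEFINITE),
        member("C2", "DAD", "MOM", Sex.FEMALE, Status.CASE_DEFINITE),
        member("S5", "DAD", "MOM", Sex.FEMALE, Status.CONTROL_POSSIBLE_CARRIER),
        member("S2", "DAD", "MOM", Sex.MALE, Status.CONTROL_NONCARRIER),
        member("S6", "DAD", "MOM", Sex.FEMALE, Status.CONTROL_NONCARRIER),
    ])


@pytest.fixture
def six_member_family() -> Pedigree:
    """Flat sibship used for enumerable segregation tests: definite cases
    A, B; possible phenocopy C; non-carrier controls D, E; possible
    carrier F."""
    return Pedigree([
        member("P1", sex=Sex.MALE),
        member("P2", sex=Sex.FEMALE),
        member("A", "P1", "P2", Sex.MALE, Status.CASE_DEFINITE),
        member("B", "P1", "P2", Sex.FEMALE, Status.CASE_DEFINITE),
        member("C", "P1", "P2", Sex.MALE, Status.CASE_POSSIBLE_PHENOCOPY),
        member("D", "P1", "P2", Sex.FEMALE, Status.CONTROL_NONCARRIER),
        member("E", "P1", "P2", Sex.MALE, Status.CONTROL_NONCARRIER),
        member("F", "P1", "P2", Sex.FEMALE, Status.CONTROL_POSSIBLE_CARRIER),
    ])


def record_with_carriers(ped: Pedigree, carriers: set[str], missing: set[str] = frozenset(), **kw):
    genotypes = {}
    for m in ped.sequenced_members():
        mid = m.member_id
        if mid in missing:
            genotypes[mid] = make_call(Genotype.MISSING, depth=None)
        elif mid in carriers:
            genotypes[mid] = make_call(Genotype.HET)
        else:
            genotypes[mid] = make_call(Genotype.HOM_REF)
    return make_record(genotypes, **kw)
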