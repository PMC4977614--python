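"""Core domain types for the prioritization cascade.

Everything downstream operates on these types: variants with per-sample
genotype/read evidence, external annotation bundles (any field may be
missing), the pedigree graph with per-member analysis statuses, and the
per-stage survivor funnel.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class RegionClass(str, enum.Enum):
    MISSENSE = "missense"
    OTHER_CODING = "other_coding"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    SPLICING = "splicing"
    OTHER = "other"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Status(str, enum.Enum):
    """Five-level analysis status of a sequenced pedigree member.

    The two middle levels encode the uncertainty of real counseling data:
    a late-onset case may be a phenocopy, and a young unaffected relative
    may still be a carrier.
    """

    CASE_DEFINITE = "CASE_DEFINITE"
    CASE_POSSIBLE_PHENOCOPY = "CASE_POSSIBLE_PHENOCOPY"
    CONTROL_NONCARRIER = "CONTROL_NONCARRIER"
    CONTROL_POSSIBLE_CARRIER = "CONTROL_POSSIBLE_CARRIER"
    UNINFORMATIVE = "UNINFORMATIVE"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


PREDICTORS = ("mutation_taster", "polyphen2", "provean", "sift")
INTOLERANCE_SOURCES = ("inhouse", "esp", "exac")

#: RegulomeDB-style evidence categories, strongest evidence first.
REGULOME_CATEGORIES = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6", "7",
)

PREDICTOR_DELETERIOUS = "deleterious"
PREDICTOR_TOLERATED = "tolerated"


@dataclass(frozen=True)
class SampleCall:
    """Genotype plus read evidence for one sample at one site."""

    genotype: Genotype
    depth: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValidationError(f"negative depth: {self.depth}")
        for name in ("alt_fwd", "alt_rev"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"negative {name}: {v}")
        if (
            self.depth is not None
            and self.alt_fwd is not None
            and self.alt_rev is not None
            and self.alt_fwd + self.alt_rev > self.depth
        ):
            raise ValidationError(
                f"alt reads ({self.alt_fwd}+{self.alt_rev}) exceed depth {self.depth}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic variant (multi-allelic sites are decomposed upstream)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region: RegionClass
    qual: Optional[float]
    upstream_filter: Optional[str]
    per_sample: Mapping[str, SampleCall]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carrier_samples(self) -> list[str]:
        """Samples whose genotype contains the alt allele, in input order."""
        return [s for s, c in self.per_sample.items() if c.genotype.carries_alt]


def _check_fraction(name: str, v: Optional[float]) -> None:
    if v is not None and not (0.0 <= v <= 1.0):
        raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class AnnotationBundle:
    """External per-variant scores; any field may be missing (None/empty).

    Missing means missing — no field is ever imputed to a default; each
    downstream gate documents its own missing-value rule.
    """

    maf_1kg: Optional[float] = None
    maf_exac_nontcga: Optional[float] = None
    maf_inhouse: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    intolerance_pct: Mapping[str, float] = field(default_factory=dict)
    regulome_rank: Optional[str] = None
    haploreg_flags: frozenset[str] = frozenset()
    mirsvr: Optional[float] = None
    mirna_secondary: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("maf_1kg", "maf_exac_nontcga", "maf_inhouse", "phastcons"):
            _check_fraction(name, getattr(self, name))
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"scaled CADD must be >= 0, got {self.cadd_phred}")
        for k, v in self.predictor_calls.items():
            if k not in PREDICTORS:
                raise ValidationError(f"unknown predictor key: {k!r}")
            if v not in (PREDICTOR_DELETERIOUS, PREDICTOR_TOLERATED):
                raise ValidationError(f"bad predictor call {v!r} for {k}")
        for k, v in self.intolerance_pct.items():
            if k not in INTOLERANCE_SOURCES:
                raise ValidationError(f"unknown intolerance source: {k!r}")
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"intolerance percentile out of [0,100]: {v}")
        if self.regulome_rank is not None and self.regulome_rank not in REGULOME_CATEGORIES:
            raise ValidationError(f"unknown RegulomeDB category: {self.regulome_rank!r}")
        object.__setattr__(self, "haploreg_flags", frozenset(self.haploreg_flags))


@dataclass
class PedigreeMember:
    member_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Optional[bool] = None
    status: Status = Status.UNINFORMATIVE
    sequenced: bool = False
    birth_year: Optional[int] = None
    diagnosis_year: Optional[int] = None
    family_id: str = "FAM"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Validated family graph with kinship support.

    Validation: parent links resolve, fathers are male and mothers female,
    and the ancestry relation is acyclic.
    """

    def __init__(self, members: Iterable[PedigreeMember]):
        self.members: dict[str, PedigreeMember] = {}
        for m in members:
            if m.member_id in self.members:
                raise ValidationError(f"duplicate member id: {m.member_id}")
            self.members[m.member_id] = m
        self._validate()
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def _validate(self) -> None:
        for m in self.members.values():
            for pid, want_sex, label in (
                (m.father_id, Sex.FEMALE, "father"),
                (m.mother_id, Sex.MALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = self.members.get(pid)
                if parent is None:
                    raise ValidationError(
                        f"{label} {pid!r} of {m.member_id!r} not in pedigree"
                    )
                if parent.sex == want_sex:
                    raise ValidationError(
                        f"{label} {pid!r} of {m.member_id!r} has wrong sex"
                    )
            if m.sequenced and m.status is None:
                raise ValidationError(f"sequenced member {m.member_id} lacks a status")
        # cycle detection via iterative DFS over parent links
        state: dict[str, int] = {}  # 0 in-progress, 1 done
        for start in self.members:
            if start in state:
                continue
            stack = [(start, iter(self._parent_ids(start)))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise ValidationError(f"cyclic ancestry involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parent_ids(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _parent_ids(self, member_id: str) -> list[str]:
        m = self.members[member_id]
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    def __contains__(self, member_id: str) -> bool:
        return member_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, member_id: str) -> PedigreeMember:
        try:
            return self.members[member_id]
        except KeyError:
            raise ValidationError(f"unknown pedigree member: {member_id!r}") from None

    @property
    def family_ids(self) -> list[str]:
        return sorted({m.family_id for m in self.members.values()})

    def sequenced_members(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.sequenced]

    def ancestors(self, member_id: str) -> frozenset[str]:
        cached = self._ancestors_cache.get(member_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self._parent_ids(member_id))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self._parent_ids(p))
        result = frozenset(out)
        self._ancestors_cache[member_id] = result
        return result

    def founders(self) -> list[str]:
        return [m.member_id for m in self.members.values() if m.is_founder]

    def topological_order(self) -> list[str]:
        """Members ordered parents-before-children."""
        order: list[str] = []
        done: set[str] = set()
        pending = sorted(self.members)
        while pending:
            remaining = []
            for mid in pending:
                if all(p in done for p in self._parent_ids(mid)):
                    order.append(mid)
                    done.add(mid)
                else:
                    remaining.append(mid)
            if len(remaining) == len(pending):  # pragma: no cover - guarded by _validate
                raise ValidationError("pedigree is not acyclic")
            pending = remaining
        return order

    def kinship(self, i: str, j: str) -> float:
        """Recursive kinship coefficient phi(i, j); founders are unrelated."""
        if i not in self.members:
            raise ValidationError(f"unknown pedigree member: {i!r}")
        if j not in self.members:
            raise ValidationError(f"unknown pedigree member: {j!r}")
        return self._phi(i, j)

    def _phi(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        mi, mj = self.members[i], self.members[j]
        if i == j:
            fm = (
                self._phi(mi.father_id, mi.mother_id)
                if mi.father_id is not None and mi.mother_id is not None
                else 0.0
            )
            val = 0.5 * (1.0 + fm)
        else:
            # recurse on the member that is not an ancestor of the other
            if i in self.ancestors(j):
                pivot, other = mj, i
            elif j in self.ancestors(i):
                pivot, other = mi, j
            elif not mi.is_founder:
                pivot, other = mi, j
            elif not mj.is_founder:
                pivot, other = mj, i
            else:
                val = 0.0
                self._kinship_cache[key] = val
                return val
            val = 0.5 * (
                (self._phi(pivot.father_id, other) if pivot.father_id else 0.0)
                + (self._phi(pivot.mother_id, other) if pivot.mother_id else 0.0)
            )
        self._kinship_cache[key] = val
        return val


class FilterFunnel:
    """Ordered per-stage, per-region-class survivor counts.

    Counts are validated to be non-negative and non-increasing along the
    stage order for every region class.
    """

    def __init__(self) -> None:
        self.stages: list[tuple[str, dict[str, int]]] = []

    def add_stage(self, name: str, counts: Mapping[str, int]) -> None:
        counts = {str(k): int(v) for k, v in counts.items()}
        for k, v in counts.items():
            if v < 0:
                raise ValidationError(f"negative funnel count for {k!r} at {name!r}")
        if any(name == existing for existing, _ in self.stages):
            raise ValidationError(f"duplicate funnel stage name: {name!r}")
        if self.stages:
            _, prev = self.stages[-1]
            for k in set(prev) | set(counts):
                if counts.get(k, 0) > prev.get(k, 0):
                    raise ValidationError(
                        f"funnel count for {k!r} increased at stage {name!r}"
                    )
        self.stages.append((name, counts))

    @property
    def stage_names(self) -> list[str]:
        return [n for n, _ in self.stages]

    def region_classes(self) -> list[str]:
        seen: list[str] = []
        for _, counts in self.stages:
            for k in counts:
                if k not in seen:
                    seen.append(k)
        return seen

    def to_dict(self) -> dict:
        return {"stages": [{"name": n, "counts": c} for n, c in self.stages]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterFunnel":
        f = cls()
        for st in d["stages"]:
            f.add_stage(st["name"], st["counts"])
        return f


def count_by_region(records: Iterable[VariantRecord]) -> dict[str, int]:
    out: dict[str, int] = {r.value: 0 for r in RegionClass}
    for rec in records:
        out[rec.region.value] += 1
    return out
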