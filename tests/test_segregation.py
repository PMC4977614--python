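import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprio.model import Genotype, Status, ValidationError
from varprio.segregation import (
    SegregationPolicy,
    SegregationVerdict,
    apply_segregation,
    carrier_set,
    segregates,
)

from .conftest import make_call, make_record, member, record_with_carriers
from varprio.model import Pedigree, Sex


def _family() -> Pedigree:
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


_HYPO_FAMILY = _family()

MEMBERS = ["A", "B", "C", "D", "E", "F"]
STATUS_OF = {
    "A": Status.CASE_DEFINITE,
    "B": Status.CASE_DEFINITE,
    "C": Status.CASE_POSSIBLE_PHENOCOPY,
    "D": Status.CONTROL_NONCARRIER,
    "E": Status.CONTROL_NONCARRIER,
    "F": Status.CONTROL_POSSIBLE_CARRIER,
}


def oracle(carriers: set, policy: SegregationPolicy) -> bool:
    """Direct constraint counting, written independently of the engine."""
    def within(n, limit):
        return limit is None or n <= limit

    return (
        within(sum(1 for m in MEMBERS if STATUS_OF[m] is Status.CASE_DEFINITE and m not in carriers),
               policy.max_missing_definite_cases)
        and within(sum(1 for m in MEMBERS if STATUS_OF[m] is Status.CASE_POSSIBLE_PHENOCOPY and m not in carriers),
                   policy.max_missing_phenocopy_cases)
        and within(sum(1 for m in MEMBERS if STATUS_OF[m] is Status.CONTROL_NONCARRIER and m in carriers),
                   policy.max_carrier_noncarrier_controls)
        and within(sum(1 for m in MEMBERS if STATUS_OF[m] is Status.CONTROL_POSSIBLE_CARRIER and m in carriers),
                   policy.max_carrier_possible_controls)
    )


class TestCarrierSet:
    def test_dominant_definition(self):
        rec = make_record({"A": "het", "B": "hom_ref", "C": "hom_alt"})
        cs = carrier_set(rec)
        assert cs.carriers == {"A", "C"} and cs.unknown == set()

    def test_all_hom_ref(self):
        rec = make_record({"A": "hom_ref", "B": "hom_ref"})
        assert carrier_set(rec).carriers == set()

    def test_missing_tracked_separately(self):
        rec = make_record({"A": make_call(Genotype.MISSING, depth=None), "B": "het"})
        cs = carrier_set(rec)
        assert cs.carriers == {"B"} and cs.unknown == {"A"}

    def test_unsupported_model(self):
        with pytest.raises(ValidationError):
            carrier_set(make_record({"A": "het"}), model="recessive")


class TestSegregates:
    def test_default_policy_tolerates_phenocopy_and_possible_carrier(self, six_member_family):
        rec = record_with_carriers(six_member_family, {"A", "B", "F"})
        verdict = segregates(rec, six_member_family)
        assert verdict.passes and verdict.violated_constraints == []

    def test_noncarrier_control_carrying_fails(self, six_member_family):
        rec = record_with_carriers(six_member_family, {"A", "B", "C", "D"})
        verdict = segregates(rec, six_member_family)
        assert not verdict.passes
        assert ("D", "noncarrier_control_carries") in verdict.violated_constraints

    def test_definite_case_missing_fails(self, six_member_family):
        verdict = segregates(record_with_carriers(six_member_family, {"A"}), six_member_family)
        assert not verdict.passes
        assert ("B", "definite_case_missing") in verdict.violated_constraints

    def test_verdict_mirrors_violations(self):
        with pytest.raises(ValidationError):
            SegregationVerdict(passes=True, violated_constraints=[("A", "x")])

    def test_missing_genotype_noninformative_vs_strict(self, six_member_family):
        rec = record_with_carriers(six_member_family, {"B"}, missing={"A"})
        assert segregates(rec, six_member_family).passes
        strict = SegregationPolicy(missing_genotype_rule="strict")
        verdict = segregates(rec, six_member_family, strict)
        assert not verdict.passes
        assert ("A", "definite_case_missing") in verdict.violated_constraints

    def test_uninformative_members_never_constrain(self, six_member_family):
        rec = record_with_carriers(six_member_family, {"A", "B"})
        base = segregates(rec, six_member_family)
        # give the record an extra genotype for an uninformative, unsequenced member
        rec2 = make_record({**dict(rec.per_sample), "GHOSTLIKE": make_call("het")})
        assert segregates(rec2, six_member_family).passes == base.passes

    def test_unsequenced_member_without_genotype_is_fine(self, fig_family):
        rec = record_with_carriers(fig_family, {"C1", "C2", "AUNT"})
        assert segregates(rec, fig_family).passes

    def test_sequenced_member_without_genotype_errors(self, six_member_family):
        rec = make_record({"A": "het"})  # only one of six columns
        with pytest.raises(ValidationError, match="no genotype column"):
            segregates(rec, six_member_family)

    def test_tolerances_allow_slack(self, six_member_family):
        rec = record_with_carriers(six_member_family, {"A", "D"})
        relaxed = SegregationPolicy(
            max_missing_definite_cases=1, max_carrier_noncarrier_controls=1
        )
        assert segregates(rec, six_member_family, relaxed).passes


class TestOracleEquivalence:
    def test_all_carrier_patterns_default_policy(self, six_member_family):
        policy = SegregationPolicy()
        for bits in itertools.product([0, 1], repeat=6):
            carriers = {m for m, b in zip(MEMBERS, bits) if b}
            rec = record_with_carriers(six_member_family, carriers)
            assert segregates(rec, six_member_family, policy).passes == oracle(carriers, policy)

    @settings(max_examples=40, deadline=None)
    @given(
        bits=st.tuples(*[st.booleans()] * 6),
        t1=st.integers(0, 3), t2=st.none() | st.integers(0, 3),
        t3=st.integers(0, 3), t4=st.none() | st.integers(0, 3),
    )
    def test_random_policies(self, bits, t1, t2, t3, t4):
        six_member_family = _HYPO_FAMILY
        policy = SegregationPolicy(
            max_missing_definite_cases=t1,
            max_missing_phenocopy_cases=t2,
            max_carrier_noncarrier_controls=t3,
            max_carrier_possible_controls=t4,
        )
        carriers = {m for m, b in zip(MEMBERS, bits) if b}
        rec = record_with_carriers(six_member_family, carriers)
        assert segregates(rec, six_member_family, policy).passes == oracle(carriers, policy)


@settings(max_examples=40, deadline=None)
@given(
    bits=st.tuples(*[st.booleans()] * 6),
    base=st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)),
    bump=st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)),
)
def test_relaxation_monotonicity(bits, base, bump):
    """Increasing any tolerance never removes a survivor."""
    six_member_family = _HYPO_FAMILY
    carriers = {m for m, b in zip(MEMBERS, bits) if b}
    rec = record_with_carriers(six_member_family, carriers)
    tight = SegregationPolicy(
        max_missing_definite_cases=base[0],
        max_missing_phenocopy_cases=base[1],
        max_carrier_noncarrier_controls=base[2],
        max_carrier_possible_controls=base[3],
    )
    loose = SegregationPolicy(
        max_missing_definite_cases=base[0] + bump[0],
        max_missing_phenocopy_cases=base[1] + bump[1],
        max_carrier_noncarrier_controls=base[2] + bump[2],
        max_carrier_possible_controls=base[3] + bump[3],
    )
    if segregates(rec, six_member_family, tight).passes:
        assert segregates(rec, six_member_family, loose).passes


class TestApplySegregation:
    def test_empty_input(self, six_member_family):
        survivors, (name, counts) = apply_segregation([], six_member_family)
        assert survivors == [] and name == "segregation"

    def test_order_independence(self, six_member_family):
        recs = [
            record_with_carriers(six_member_family, {"A", "B"}, pos=100 + i)
            for i in range(5)
        ] + [record_with_carriers(six_member_family, {"A"}, pos=900)]
        fwd, _ = apply_segregation(recs, six_member_family)
        rev, _ = apply_segregation(list(reversed(recs)), six_member_family)
        assert {r.key for r in fwd} == {r.key for r in rev}
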