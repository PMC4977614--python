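import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprio.model import ValidationError
from varprio.quality import (
    QcThresholds,
    apply_technical_qc,
    passes_site_quality,
    passes_strand_bias,
    passes_technical_qc,
    passes_upstream_filters,
)

from .conftest import make_call, make_record

THR = QcThresholds()


class TestSiteQuality:
    def test_good_qual_and_carrier_depths(self):
        rec = make_record({
            "A": make_call("het", depth=12),
            "B": make_call("het", depth=9),
            "C": make_call("hom_ref", depth=2),  # non-carrier depth ignored
        }, qual=35.0)
        assert passes_site_quality(rec, THR)

    def test_qual_exactly_20_fails_strict(self):
        rec = make_record({"A": make_call("het", depth=12)}, qual=20.0)
        assert not passes_site_quality(rec, THR)
        assert passes_site_quality(rec, QcThresholds(strict=False))

    def test_carrier_depth_exactly_5_fails_strict(self):
        rec = make_record({
            "A": make_call("het", depth=12),
            "B": make_call("het", depth=5, alt_fwd=2, alt_rev=2),
        }, qual=50.0)
        assert not passes_site_quality(rec, THR)

    def test_missing_carrier_depth_fails(self):
        rec = make_record({"A": make_call("het", depth=None)}, qual=50.0)
        assert not passes_site_quality(rec, THR)

    def test_missing_qual_fails(self):
        rec = make_record({"A": make_call("het", depth=30)}, qual=None)
        assert not passes_site_quality(rec, THR)

    def test_all_scope_vetoes_on_noncarrier(self):
        rec = make_record({
            "A": make_call("het", depth=12),
            "B": make_call("hom_ref", depth=2),
        }, qual=50.0)
        assert passes_site_quality(rec, THR)
        assert not passes_site_quality(rec, QcThresholds(depth_scope="all"))

    def test_site_mean_scope(self):
        rec = make_record({
            "A": make_call("het", depth=10),
            "B": make_call("hom_ref", depth=2),
        }, qual=50.0)
        assert passes_site_quality(rec, QcThresholds(depth_scope="site_mean"))

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            QcThresholds(min_qual=-1)
        with pytest.raises(ValidationError):
            QcThresholds(depth_scope="per_chromosome")


class TestStrandBias:
    def test_one_read_each_strand_passes(self):
        rec = make_record({"A": make_call("het", depth=30, alt_fwd=1, alt_rev=1)})
        assert passes_strand_bias(rec)

    def test_single_strand_fails(self):
        rec = make_record({"A": make_call("het", depth=30, alt_fwd=7, alt_rev=0)})
        assert not passes_strand_bias(rec)

    def test_no_alt_evidence_fails(self):
        rec = make_record({"A": make_call("het", depth=30, alt_fwd=0, alt_rev=0)})
        assert not passes_strand_bias(rec)

    def test_pooled_across_carriers(self):
        rec = make_record({
            "A": make_call("het", depth=30, alt_fwd=3, alt_rev=0),
            "B": make_call("het", depth=30, alt_fwd=0, alt_rev=2),
        })
        assert passes_strand_bias(rec)

    def test_indel_is_contract_violation(self):
        rec = make_record({"A": make_call("het")}, ref="AT", alt="A")
        with pytest.raises(ValidationError):
            passes_strand_bias(rec)


class TestUpstreamFilters:
    @pytest.mark.parametrize("filt,expected", [("PASS", True), ("badReads", False)])
    def test_filter_values(self, filt, expected):
        rec = make_record({"A": make_call("het")}, ref="AT", alt="A", upstream_filter=filt)
        assert passes_upstream_filters(rec) is expected

    def test_missing_filter_default_fails_but_configurable(self):
        rec = make_record({"A": make_call("het")}, ref="AT", alt="A", upstream_filter=None)
        assert not passes_upstream_filters(rec)
        assert passes_upstream_filters(rec, missing_fails=False)


def _designed_fixture():
    """10 records with 3 designed failures (low qual, one-strand SNV,
    filtered indel)."""
    ok_snv = lambda pos: make_record(
        {"A": make_call("het", depth=20, alt_fwd=5, alt_rev=5)}, pos=pos
    )
    records = [ok_snv(p) for p in range(100, 700, 100)]          # 6 good SNVs
    records.append(make_record({"A": make_call("het")}, pos=700, ref="AT", alt="A"))  # good indel
    records.append(make_record({"A": make_call("het", depth=20)}, pos=800, qual=7.0))    # low qual
    records.append(make_record(
        {"A": make_call("het", depth=20, alt_fwd=9, alt_rev=0)}, pos=900))               # strand
    records.append(make_record(
        {"A": make_call("het")}, pos=1000, ref="AT", alt="A", upstream_filter="badReads"))
    return records


class TestApplyTechnicalQc:
    def test_empty_input(self):
        survivors, (name, counts) = apply_technical_qc([], THR)
        assert survivors == [] and name == "technical_qc"
        assert all(v == 0 for v in counts.values())

    def test_designed_failures_match_per_record_oracle(self):
        records = _designed_fixture()
        survivors, _ = apply_technical_qc(records, THR)
        assert len(survivors) == 7
        # independent per-record oracle
        for rec in records:
            expect = rec.qual is not None and rec.qual > 20
            if expect:
                for call in rec.per_sample.values():
                    if call.genotype.carries_alt:
                        expect = expect and call.depth is not None and call.depth > 5
                if rec.vclass.value == "SNV":
                    fwd = sum(c.alt_fwd or 0 for c in rec.per_sample.values() if c.genotype.carries_alt)
                    rev = sum(c.alt_rev or 0 for c in rec.per_sample.values() if c.genotype.carries_alt)
                    expect = expect and fwd >= 1 and rev >= 1
                else:
                    expect = expect and rec.upstream_filter == "PASS"
            assert (rec in survivors) is expect

    def test_survivors_subset_and_idempotent(self):
        records = _designed_fixture()
        once, entry1 = apply_technical_qc(records, THR)
        twice, entry2 = apply_technical_qc(once, THR)
        assert twice == once
        assert set(r.key for r in once) <= set(r.key for r in records)
        assert entry1 == entry2


@settings(max_examples=60, deadline=None)
@given(
    qual=st.floats(0, 100, allow_nan=False),
    depth=st.integers(0, 60),
    min_qual_lo=st.floats(0, 50),
    bump_qual=st.floats(0, 50),
    min_depth_lo=st.integers(0, 30),
    bump_depth=st.integers(0, 30),
)
def test_threshold_monotonicity(qual, depth, min_qual_lo, bump_qual, min_depth_lo, bump_depth):
    """Raising min_qual or min_depth never turns a failing record into a pass."""
    rec = make_record(
        {"A": make_call("het", depth=depth, alt_fwd=min(1, depth), alt_rev=min(1, max(depth - 1, 0)))},
        qual=qual,
    )
    lo = QcThresholds(min_qual=min_qual_lo, min_depth=min_depth_lo)
    hi = QcThresholds(min_qual=min_qual_lo + bump_qual, min_depth=min_depth_lo + bump_depth)
    if passes_technical_qc(rec, hi):
        assert passes_technical_qc(rec, lo)
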