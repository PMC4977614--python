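import numpy as np
import pytest
from scipy.stats import binomtest

from varprio.coding import consensus_deleterious
from varprio.frequency import is_rare
from varprio.model import Genotype, Pedigree, Status, ValidationError
from varprio.ranking import passes_cadd_gate, passes_conservation
from varprio.simulate import (
    SimulationSpec,
    gene_drop,
    gene_drop_matrix,
    inject_causal,
    simulate_cohort,
    simulate_pedigree,
    transmit_from_founder,
)


class TestSimulationSpec:
    def test_probability_validation(self):
        with pytest.raises(ValidationError):
            SimulationSpec(causal_penetrance=1.5)

    def test_template_validation(self):
        with pytest.raises(ValidationError):
            SimulationSpec(sibship_size=2, reproducing_per_sibship=3)


class TestSimulatePedigree:
    def test_valid_by_construction(self):
        ped = simulate_pedigree(SimulationSpec(generations=3, sibship_size=3))
        assert isinstance(ped, Pedigree)  # Pedigree() validates on build
        assert len(ped.founders()) >= 2

    def test_deterministic_structure(self):
        spec = SimulationSpec(seed=1)
        p1 = simulate_pedigree(spec)
        p2 = simulate_pedigree(spec)
        assert sorted(p1.members) == sorted(p2.members)

    def test_sibship_and_generations(self):
        ped = simulate_pedigree(SimulationSpec(generations=2, sibship_size=4,
                                               reproducing_per_sibship=1))
        gen1 = [m for m in ped.members if m.startswith("g1i") and not m.endswith("sp")]
        assert len(gen1) == 4
        gen2 = [m for m in ped.members if m.startswith("g2i")]
        assert len(gen2) == 4  # one reproducing child -> one sibship of 4

    def test_parent_sexes_consistent(self):
        ped = simulate_pedigree(SimulationSpec(generations=3))
        for m in ped.members.values():
            if m.father_id:
                assert ped[m.father_id].sex.value == "male"
            if m.mother_id:
                assert ped[m.mother_id].sex.value == "female"


class TestGeneDrop:
    def test_freq_zero_all_hom_ref(self):
        ped = simulate_pedigree(SimulationSpec())
        assert set(gene_drop(ped, 0.0, 1).values()) == {Genotype.HOM_REF}

    def test_freq_one_all_hom_alt(self):
        ped = simulate_pedigree(SimulationSpec())
        assert set(gene_drop(ped, 1.0, 1).values()) == {Genotype.HOM_ALT}

    def test_bad_freq_rejected(self):
        ped = simulate_pedigree(SimulationSpec())
        with pytest.raises(ValidationError):
            gene_drop(ped, 1.5, 1)

    def test_het_by_hom_ref_cross_transmits_half(self):
        """Mendel's law oracle: carrier fraction among offspring of a
        het x hom_ref cross is 1/2 (99.9 % binomial CI at 10^4 drops)."""
        ped = simulate_pedigree(SimulationSpec(generations=1, sibship_size=1,
                                               reproducing_per_sibship=1))
        child = "g1i1"
        rng = np.random.default_rng(5)
        n = 10_000
        _, counts = transmit_from_founder(ped, "g0p1", rng, n=n)
        order = ped.topological_order()
        carried = int((counts[order.index(child)] > 0).sum())
        ci = binomtest(carried, n).proportion_ci(confidence_level=0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_transmit_origin_must_be_founder(self):
        ped = simulate_pedigree(SimulationSpec())
        with pytest.raises(ValidationError):
            transmit_from_founder(ped, "g1i1", np.random.default_rng(0))


class TestInjectCausal:
    def test_full_penetrance_no_phenocopy_affected_equals_carriers(self):
        spec = SimulationSpec(causal_penetrance=1.0, phenocopy_rate=0.0, seed=3)
        ped = simulate_pedigree(spec)
        inj = inject_causal(ped, spec, np.random.default_rng(3))
        carriers = {m for m, c in inj.carrier_counts.items() if c > 0}
        affected = {m for m, a in inj.affected.items() if a}
        assert affected == carriers

    def test_statuses_follow_observable_rule_table(self):
        spec = SimulationSpec(causal_penetrance=0.6, phenocopy_rate=0.1, seed=11)
        ped = simulate_pedigree(spec)
        inj = inject_causal(ped, spec, np.random.default_rng(11))
        for mid, status in inj.statuses.items():
            age = spec.current_year - ped[mid].birth_year
            if inj.affected[mid]:
                onset = inj.diagnosis_age[mid]
                expected = (
                    Status.CASE_POSSIBLE_PHENOCOPY
                    if onset >= spec.phenocopy_age
                    else Status.CASE_DEFINITE
                )
            else:
                expected = (
                    Status.CONTROL_NONCARRIER
                    if age >= spec.noncarrier_age
                    else Status.CONTROL_POSSIBLE_CARRIER
                )
            assert status is expected

    def test_phenocopies_always_possible_phenocopy_status(self):
        spec = SimulationSpec(causal_penetrance=1.0, phenocopy_rate=0.8, seed=2)
        ped = simulate_pedigree(spec)
        inj = inject_causal(ped, spec, np.random.default_rng(2))
        phenocopies = [
            m for m in inj.affected
            if inj.affected[m] and inj.carrier_counts[m] == 0
        ]
        assert phenocopies, "seed chosen to exhibit a phenocopy"
        for m in phenocopies:
            assert inj.statuses[m] is Status.CASE_POSSIBLE_PHENOCOPY

    def test_young_unaffected_carrier_is_possible_carrier(self):
        spec = SimulationSpec(causal_penetrance=0.0, phenocopy_rate=0.0, seed=0)
        ped = simulate_pedigree(spec)
        inj = inject_causal(ped, spec, np.random.default_rng(0))
        young_carriers = [
            m for m, c in inj.carrier_counts.items()
            if c > 0 and spec.current_year - ped[m].birth_year < spec.noncarrier_age
        ]
        assert young_carriers
        for m in young_carriers:
            assert inj.statuses[m] is Status.CONTROL_POSSIBLE_CARRIER


class TestSimulateCohort:
    def test_deterministic(self):
        spec = SimulationSpec(seed=13, n_decoy_variants=25)
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        assert c1.causal_key == c2.causal_key
        assert [r.key for r, _ in c1.pairs] == [r.key for r, _ in c2.pairs]
        assert all(a1 == a2 for (_, a1), (_, a2) in zip(c1.pairs, c2.pairs))

    def test_causal_bundle_clears_gates_by_construction(self):
        for seed in range(5):
            c = simulate_cohort(SimulationSpec(seed=seed, n_decoy_variants=10))
            ann = dict((r.key, a) for r, a in c.pairs)[c.causal_key]
            assert is_rare(ann)
            assert passes_cadd_gate(ann)
            assert passes_conservation(ann, "both")
            assert consensus_deleterious(ann.predictor_calls)

    def test_every_variant_polymorphic_in_cohort(self):
        c = simulate_cohort(SimulationSpec(seed=21, n_decoy_variants=60))
        for rec, _ in c.pairs:
            assert any(call.genotype.carries_alt for call in rec.per_sample.values())

    def test_boundary_decoys_present_and_excluded(self):
        # aggregate across seeds: exact-threshold values must appear
        cadd_boundary = maf_boundary = 0
        for seed in range(8):
            c = simulate_cohort(SimulationSpec(
                seed=seed, n_decoy_variants=80, p_boundary_decoy=0.4
            ))
            for rec, ann in c.pairs:
                if ann.cadd_phred in (10.0, 20.0, 30.0):
                    cadd_boundary += 1
                    assert not passes_cadd_gate(ann) or ann.cadd_phred > 10.0
                if ann.maf_1kg == 0.001:
                    maf_boundary += 1
                    assert not is_rare(ann)
        assert cadd_boundary > 0 and maf_boundary > 0

    def test_sequencing_subset(self):
        ped = simulate_pedigree(SimulationSpec())
        subset = sorted(ped.members)[:6]
        c = simulate_cohort(SimulationSpec(seed=1, sequencing_subset=tuple(subset)))
        assert c.samples == sorted(subset)
        for rec, _ in c.pairs:
            assert set(rec.per_sample) == set(subset)

    def test_unknown_subset_member_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(SimulationSpec(sequencing_subset=("nobody",)))


class TestGeneDropMatrix:
    def test_shape_and_range(self):
        ped = simulate_pedigree(SimulationSpec())
        order, counts = gene_drop_matrix(ped, np.full(50, 0.3), np.random.default_rng(0))
        assert counts.shape == (len(ped), 50)
        assert counts.min() >= 0 and counts.max() <= 2

    def test_children_only_inherit_parental_alleles(self):
        ped = simulate_pedigree(SimulationSpec())
        order, counts = gene_drop_matrix(ped, np.full(200, 0.2), np.random.default_rng(1))
        idx = {m: i for i, m in enumerate(order)}
        for mid, m in ped.members.items():
            if m.is_founder:
                continue
            parent_total = counts[idx[m.father_id]] + counts[idx[m.mother_id]]
            # a child cannot carry more alt alleles than its parents offer
            assert np.all(counts[idx[mid]] <= parent_total)
            assert np.all((parent_total > 0) | (counts[idx[mid]] == 0))
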