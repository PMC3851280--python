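"""Unit and property tests for the prioritization rule engine."""

import dataclasses
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exotriage.model import Consequence, GeneTier, PredictorCall
from exotriage.prioritize import (
    Consensus,
    ImpactClass,
    TriageConfig,
    classify_impact,
    evaluate_sample,
    frequency_pass,
    predictor_consensus,
    prioritize_cohort,
    prioritize_sample,
    read_support_pass,
    summarize_classes,
    unanimous_damaging,
)
from exotriage.synth import SyntheticSpec, generate_sample


class TestFrequencyRule:
    def test_common_variant_fails(self, make_variant):
        v = make_variant(af_by_db={"EVS6500": 0.427, "TGP": 0.234}, dbsnp_id="rs4504469")
        check = frequency_pass(v, 0.003)
        assert not check.passed
        assert check.max_frequency == pytest.approx(0.427)
        assert check.database == "EVS6500"

    def test_absent_everywhere_is_novel_and_passes(self, make_variant):
        check = frequency_pass(make_variant(af_by_db={}), 0.003)
        assert check.passed
        assert check.max_frequency is None

    def test_max_across_databases(self, make_variant):
        # EVS below threshold but TGP above: the maximum decides
        v = make_variant(af_by_db={"EVS6500": 0.0009, "TGP": 0.0096})
        check = frequency_pass(v, 0.003)
        assert not check.passed
        assert check.database == "TGP"
        assert check.max_frequency == pytest.approx(0.0096)

    def test_boundary_equality_passes(self, make_variant):
        assert frequency_pass(make_variant(af_by_db={"TGP": 0.003}), 0.003).passed

    def test_unknown_database_rejected(self, make_variant):
        with pytest.raises(KeyError):
            frequency_pass(make_variant(), 0.003, databases=("gnomAD",))

    def test_restricted_database_list(self, make_variant):
        v = make_variant(af_by_db={"TGP": 0.5})
        assert frequency_pass(v, 0.003, databases=("EVS6500",)).passed
        assert not frequency_pass(v, 0.003, databases=("TGP",)).passed


class TestReadSupportRule:
    @pytest.mark.parametrize(
        "pct,expected", [(38.46, True), (10.0, True), (9.99, False), (0.0, False), (100.0, True)]
    )
    def test_boundaries(self, make_variant, pct, expected):
        assert read_support_pass(make_variant(reads_pct=pct)) is expected


class TestPredictorConsensus:
    def test_unanimous_damaging(self, make_variant):
        v = make_variant(damaging=5)
        assert predictor_consensus(v) is Consensus.DAMAGING
        assert unanimous_damaging(v)

    def test_two_damaging_three_neutral_is_neutral(self, make_variant):
        v = make_variant(damaging=2, neutral=3)
        assert predictor_consensus(v) is Consensus.NEUTRAL

    def test_majority_damaging(self, make_variant):
        v = make_variant(damaging=3, neutral=2)
        assert predictor_consensus(v) is Consensus.DAMAGING
        assert not unanimous_damaging(v)

    def test_all_unknown(self, make_variant):
        assert predictor_consensus(make_variant(damaging=0, neutral=0)) is Consensus.UNKNOWN

    def test_discordant(self, make_variant):
        assert predictor_consensus(make_variant(damaging=2, neutral=2)) is Consensus.DISCORDANT
        assert predictor_consensus(make_variant(damaging=1, neutral=0)) is Consensus.DISCORDANT


class TestImpactClassification:
    @pytest.mark.parametrize(
        "consequence",
        [
            Consequence.PREMATURE_STOP,
            Consequence.START_LOSS,
            Consequence.CANONICAL_SPLICE,
            Consequence.STOP_READTHROUGH,
            Consequence.FRAMESHIFT_INSERTION,
            Consequence.FRAMESHIFT_DELETION,
        ],
    )
    def test_truncating_types_are_class2(self, make_variant, consequence):
        v = make_variant(consequence=consequence, damaging=0)
        assert classify_impact(v, Consensus.UNKNOWN) is ImpactClass.CLASS2_LIKELY_DELETERIOUS

    def test_known_functional_is_class1(self, make_variant):
        v = make_variant(consequence=Consequence.KNOWN_FUNCTIONAL)
        assert classify_impact(v, Consensus.UNKNOWN) is ImpactClass.CLASS1_KNOWN_FUNCTIONAL

    def test_damaging_ns_is_class3(self, make_variant):
        v = make_variant(damaging=5)
        assert classify_impact(v, Consensus.DAMAGING) is ImpactClass.CLASS3_POSSIBLY_DELETERIOUS

    def test_neutral_ns_is_unprioritized(self, make_variant):
        v = make_variant(damaging=0, neutral=5)
        assert classify_impact(v, Consensus.NEUTRAL) is ImpactClass.UNPRIORITIZED

    def test_near_splice_window(self, make_variant):
        inside = make_variant(consequence=Consequence.NEAR_SPLICE, splice_distance=10)
        outside = make_variant(consequence=Consequence.NEAR_SPLICE, splice_distance=11)
        assert classify_impact(inside, Consensus.UNKNOWN) is ImpactClass.CLASS3_POSSIBLY_DELETERIOUS
        assert classify_impact(outside, Consensus.UNKNOWN) is ImpactClass.UNPRIORITIZED

    def test_near_splice_without_distance_is_an_error(self, make_variant):
        v = make_variant(consequence=Consequence.NEAR_SPLICE)
        with pytest.raises(ValueError, match="splice_distance"):
            classify_impact(v, Consensus.UNKNOWN)

    def test_inframe_indels_are_class3(self, make_variant):
        for c in (Consequence.INFRAME_INSERTION, Consequence.INFRAME_DELETION):
            v = make_variant(consequence=c, damaging=0)
            assert classify_impact(v, Consensus.UNKNOWN) is ImpactClass.CLASS3_POSSIBLY_DELETERIOUS


class TestPrioritizeSample:
    def test_frequency_failure_rescued_by_gene_knowledge(self, make_variant, knowledge, config):
        v = make_variant(
            gene="KIAA0319",
            af_by_db={"EVS6500": 0.427, "TGP": 0.234},
            dbsnp_id="rs4504469",
            protein_change="p.Ala311Thr",
        )
        ((_, prov),) = prioritize_sample([v], knowledge, config)
        assert not prov.frequency_pass
        assert prov.rescued_by_gene
        assert prov.rescue_tier is GeneTier.TIER_OVERLAP
        assert prov.admitted

    def test_prior_variant_evidence_rescues_gus_gene(self, make_variant, knowledge, config):
        v = make_variant(
            gene="SETX",
            af_by_db={"TGP": 0.0096},
            protein_change="p.Lys992Arg",
        )
        ((_, prov),) = prioritize_sample([v], knowledge, config)
        assert prov.rescued_by_prior_variant
        assert prov.admitted

    def test_known_neutral_excluded_even_in_cas_gene(self, make_variant, knowledge, config):
        v = make_variant(gene="CNTNAP2", known_neutral=True)
        assert prioritize_sample([v], knowledge, config) == []

    def test_low_read_support_dominates(self, make_variant, knowledge, config):
        v = make_variant(gene="CNTNAP2", reads_pct=5.0)
        assert prioritize_sample([v], knowledge, config) == []

    def test_zygosity_never_filters(self, make_variant, knowledge, config):
        from exotriage.model import Zygosity

        for zygosity in Zygosity:
            v = make_variant(zygosity=zygosity)
            assert len(prioritize_sample([v], knowledge, config)) == 1

    def test_mixed_sample_ids_rejected(self, make_variant, knowledge, config):
        with pytest.raises(ValueError, match="multiple samples"):
            prioritize_sample(
                [make_variant(sample_id="A"), make_variant(sample_id="B")], knowledge, config
            )

    def test_order_independence(self, make_variant, knowledge, config):
        variants = [make_variant() for _ in range(20)]
        shuffled = variants[:]
        random.Random(7).shuffle(shuffled)
        a = prioritize_sample(variants, knowledge, config)
        b = prioritize_sample(shuffled, knowledge, config)
        assert [v.key for v, _ in a] == [v.key for v, _ in b]

    def test_cohort_pass_rescues_genes_of_interest(self, make_variant, knowledge, config):
        # sample A holds a prioritized variant in GENEX; sample B's common
        # GENEX variant is rescued only by the cohort-level second pass
        a = make_variant(sample_id="A", gene="GENEX")
        b = make_variant(sample_id="B", gene="GENEX", af_by_db={"TGP": 0.2})
        without = prioritize_cohort({"A": [a], "B": [b]}, knowledge, config, cross_sample_rescue=False)
        with_pass = prioritize_cohort({"A": [a], "B": [b]}, knowledge, config)
        assert without["B"] == []
        assert len(with_pass["B"]) == 1
        assert with_pass["B"][0][1].rescued_by_cohort_gene


# -- provenance completeness (brute-force cross-check) ----------------------


def _brute_force_failed_rules(v, knowledge, config):
    failed = []
    freq = frequency_pass(v, config.frequency_threshold, config.databases)
    entry = knowledge.get(v.gene)
    rescue = entry.tier in (GeneTier.TIER_CAS, GeneTier.TIER_OVERLAP) or (
        v.protein_change in entry.prior_variant_evidence
        or v.ref_alt_description in entry.prior_variant_evidence
    )
    if not freq.passed and not rescue:
        failed.append("frequency")
    if not read_support_pass(v, config.min_read_support_pct):
        failed.append("read_support")
    if v.known_neutral:
        failed.append("neutral")
    consensus = predictor_consensus(v, config.min_damaging_votes)
    if classify_impact(v, consensus, config.near_splice_window) is ImpactClass.UNPRIORITIZED:
        failed.append("impact")
    return tuple(failed)


def test_provenance_matches_independent_rule_checks(knowledge, config):
    sample = generate_sample(SyntheticSpec(n_variants=3000, seed=11), "S1")
    for v, prov in evaluate_sample(sample.variants, knowledge, config):
        assert prov.failed_rules == _brute_force_failed_rules(v, knowledge, config)
        assert prov.admitted == (not prov.failed_rules)


# -- monotonicity properties -------------------------------------------------


@settings(max_examples=15, deadline=None)
@given(
    t1=st.floats(min_value=1e-5, max_value=0.5, allow_nan=False),
    t2=st.floats(min_value=1e-5, max_value=0.5, allow_nan=False),
)
def test_frequency_threshold_monotonicity(knowledge, t1, t2):
    lo, hi = sorted((t1, t2))
    sample = generate_sample(SyntheticSpec(n_variants=1500, seed=23), "S1")
    keys_lo = {
        v.key
        for v, _ in prioritize_sample(
            sample.variants, knowledge, TriageConfig(frequency_threshold=lo)
        )
    }
    keys_hi = {
        v.key
        for v, _ in prioritize_sample(
            sample.variants, knowledge, TriageConfig(frequency_threshold=hi)
        )
    }
    assert keys_lo <= keys_hi


@settings(max_examples=15, deadline=None)
@given(
    r1=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    r2=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
)
def test_read_support_monotonicity(knowledge, r1, r2):
    lo, hi = sorted((r1, r2))
    sample = generate_sample(SyntheticSpec(n_variants=1500, seed=29), "S1")
    keys_lo = {
        v.key
        for v, _ in prioritize_sample(
            sample.variants, knowledge, TriageConfig(min_read_support_pct=lo)
        )
    }
    keys_hi = {
        v.key
        for v, _ in prioritize_sample(
            sample.variants, knowledge, TriageConfig(min_read_support_pct=hi)
        )
    }
    assert keys_hi <= keys_lo


# -- class-count summary ------------------------------------------------------


class TestSummarizeClasses:
    def test_premature_stops_in_seventeen_genes(self, make_variant, knowledge, config):
        variants = []
        for i in range(20):
            gene = f"G{min(i, 16)}"  # 17 distinct genes, 20 variants
            variants.append(
                make_variant(gene=gene, consequence=Consequence.PREMATURE_STOP, damaging=0)
            )
        summary = summarize_classes([], variants, knowledge, config)
        assert summary.rows["rare_premature_stop"] == (17, 20)
        assert summary.rows["highly_likely_deleterious_rare"] == (17, 20)

    def test_empty_input_gives_all_zero(self, knowledge, config):
        summary = summarize_classes([], [], knowledge, config)
        assert all(row == (0, 0) for row in summary.rows.values())

    def test_single_frameshift_insertion(self, make_variant, knowledge, config):
        v = make_variant(consequence=Consequence.FRAMESHIFT_INSERTION, damaging=0)
        summary = summarize_classes([], [v], knowledge, config)
        assert summary.rows["rare_frameshift_insertion"] == (1, 1)

    def test_variant_count_at_least_gene_count(self, knowledge, config):
        sample = generate_sample(SyntheticSpec(n_variants=3000, seed=31), "S1")
        summary = summarize_classes([], sample.variants, knowledge, config)
        for genes, count in summary.rows.values():
            assert 0 <= genes <= count

    def test_common_variants_not_counted_as_rare(self, make_variant, knowledge, config):
        v = make_variant(consequence=Consequence.PREMATURE_STOP, af_by_db={"TGP": 0.2})
        summary = summarize_classes([], [v], knowledge, config)
        assert summary.rows["rare_premature_stop"] == (0, 0)


class TestTriageConfig:
    def test_yaml_round_trip(self, tmp_path):
        config = TriageConfig(frequency_threshold=0.03, min_read_support_pct=20.0)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert TriageConfig.from_yaml(path) == config

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            TriageConfig(frequency_threshold=1.5)

    def test_unknown_database_rejected(self):
        with pytest.raises(ValueError, match="gnomAD"):
            TriageConfig(databases=("gnomAD",))
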