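"""Quality filtering and novel/rare classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raveburden import (
    AnalysisConfig,
    AnnotatedVariant,
    DataError,
    FunctionalClass,
    Group,
    SiteQuality,
    VariantStatus,
)
from raveburden.classify import (
    apply_quality_filters,
    classify_cohort,
    is_novel,
    is_rare,
    restrict_functional,
)

from conftest import make_cohort
from oracles import brute_force_classify


def _variant(**kwargs):
    defaults = dict(chrom="chr1", pos=100, ref="A", alt="T", gene="G")
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


class TestQualityFilters:
    def test_all_passing(self):
        q = SiteQuality(dp=100, qual=500, qd=20, fs=1, mq=60,
                        mq_rank_sum=0, read_pos_rank_sum=0)
        assert apply_quality_filters(q) == (True, [])

    @pytest.mark.parametrize(
        "field, value, rule",
        [
            ("dp", 4, "DP"),
            ("qual", 29.9, "QUAL"),
            ("qd", 1.9, "QD"),
            ("fs", 50.1, "FS"),
            ("haplotype_score", 13.1, "HaplotypeScore"),
            ("mq", 29.9, "MQ"),
            ("mq_rank_sum", -12.6, "MQRankSum"),
            ("read_pos_rank_sum", -8.1, "ReadPosRankSum"),
        ],
    )
    def test_each_rule_fires(self, field, value, rule):
        q = SiteQuality(**{field: value})
        ok, failed = apply_quality_filters(q)
        assert not ok and failed == [rule]

    @pytest.mark.parametrize(
        "field, value",
        [
            ("dp", 5), ("qual", 30.0), ("qd", 2.0), ("fs", 50.0),
            ("haplotype_score", 13.0), ("mq", 30.0),
            ("mq_rank_sum", -12.5), ("read_pos_rank_sum", -8.0),
        ],
    )
    def test_boundaries_are_strict(self, field, value):
        # thresholds are read literally: a value exactly at the bound passes
        ok, failed = apply_quality_filters(SiteQuality(**{field: value}))
        assert ok and failed == []

    def test_absent_fields_never_fail(self):
        assert apply_quality_filters(SiteQuality()) == (True, [])

    def test_multiple_failures_all_reported(self):
        ok, failed = apply_quality_filters(SiteQuality(dp=1, qual=10.0, fs=99.0))
        assert not ok and failed == ["DP", "QUAL", "FS"]


class TestNovelty:
    def test_absent_from_all_databases_is_novel(self):
        assert is_novel(_variant())

    def test_dbsnp_membership_defeats_novelty(self):
        assert not is_novel(_variant(in_dbsnp=True))

    def test_kg_listing_defeats_novelty(self):
        assert not is_novel(_variant(kg_freq=0.30))

    def test_zero_frequency_listing_is_membership(self):
        # frequency 0 is a database entry, distinct from absence
        assert not is_novel(_variant(esp_freq=0.0))


class TestRarity:
    def test_anchor_frequency_is_rare_inclusive(self):
        # the pathogenic SOD1 p.D91A ESP6500 frequency defines the cutoff
        assert is_rare(_variant(in_dbsnp=True, dbsnp_has_freq=True, esp_freq=0.000538))

    def test_just_above_cutoff_is_not_rare(self):
        assert not is_rare(
            _variant(in_dbsnp=True, dbsnp_has_freq=True, esp_freq=0.000625)
        )

    def test_unfrequencied_dbsnp_with_low_kg_is_rare(self):
        assert is_rare(_variant(in_dbsnp=True, kg_freq=0.009))

    def test_unfrequencied_dbsnp_alone_is_rare(self):
        assert is_rare(_variant(in_dbsnp=True))

    def test_kg_bound_is_exclusive(self):
        assert not is_rare(_variant(in_dbsnp=True, kg_freq=0.01))

    def test_kg_only_without_dbsnp_is_not_rare(self):
        assert not is_rare(_variant(kg_freq=0.005))

    def test_rarity_undefined_for_novel_variants(self):
        with pytest.raises(DataError):
            is_rare(_variant())

    @given(esp=st.floats(0.0, 0.01), cut_lo=st.floats(0.0, 0.005),
           cut_hi=st.floats(0.0, 0.005))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_lowering_cutoff_never_adds_rare_variants(self, esp, cut_lo, cut_hi):
        lo, hi = sorted((cut_lo, cut_hi))
        v = _variant(in_dbsnp=True, dbsnp_has_freq=True, esp_freq=esp)
        if is_rare(v, AnalysisConfig(rarity_cutoff=lo)):
            assert is_rare(v, AnalysisConfig(rarity_cutoff=hi))


class TestFunctionalRestriction:
    def test_stopgain_kept(self):
        v = _variant(functional_class=FunctionalClass.STOPGAIN,
                     protein_change="p.Q541X")
        assert restrict_functional([v]) == [v]

    def test_synonymous_dropped(self):
        v = _variant(functional_class=FunctionalClass.SYNONYMOUS,
                     protein_change="p.G110G")
        assert restrict_functional([v]) == []

    def test_empty_input(self):
        assert restrict_functional([]) == []


class TestClassifyCohort:
    def test_shared_variant_excluded(self):
        # the two-patients-one-control pattern: excluded as likely benign
        data = make_cohort(5, 5, [(dict(), [0, 1], [0])])
        (c,) = classify_cohort(data)
        assert c.status is VariantStatus.EXCLUDED_SHARED
        assert (c.case_carriers, c.control_carriers) == (2, 1)

    def test_case_private_novel_attributed_to_cases(self):
        data = make_cohort(5, 5, [(dict(), [0], [])])
        (c,) = classify_cohort(data)
        assert c.status is VariantStatus.NOVEL
        assert c.attributed_to is Group.CASE

    def test_control_private_rare_attributed_to_controls(self):
        data = make_cohort(
            5, 5,
            [(dict(in_dbsnp=True, dbsnp_has_freq=True, esp_freq=0.0001), [], [0])],
        )
        (c,) = classify_cohort(data)
        assert c.status is VariantStatus.RARE
        assert c.attributed_to is Group.CONTROL

    def test_quality_failure_short_circuits(self):
        data = make_cohort(3, 3, [(dict(), [0], [])])
        data.site_quality = [SiteQuality(dp=2)]
        (c,) = classify_cohort(data)
        assert c.status is VariantStatus.FILTERED_QUALITY
        assert c.reasons == ("DP",)

    def test_every_variant_gets_exactly_one_status(self, default_study):
        cls = classify_cohort(default_study.cohort)
        assert len(cls) == len(default_study.cohort.variants)
        assert all(isinstance(c.status, VariantStatus) for c in cls)

    def test_idempotent(self, default_study):
        first = classify_cohort(default_study.cohort)
        second = classify_cohort(default_study.cohort)
        assert first == second

    def test_order_of_restriction_and_exclusion_is_immaterial(self):
        # shared-exclusion before or after the functional restriction yields
        # the same final qualifying sets
        specs = [
            (dict(), [0, 1], [0]),
            (dict(functional_class=FunctionalClass.SYNONYMOUS), [0], []),
            (dict(), [2], []),
        ]
        data = make_cohort(5, 5, specs)
        cls = classify_cohort(data)
        qual_after = {
            data.variants[j].key
            for j, c in enumerate(cls)
            if c.status in (VariantStatus.NOVEL, VariantStatus.RARE)
        }
        # reversed order: classify without functional restriction, then drop
        cls2 = classify_cohort(data, apply_functional=False)
        functional = set(
            v.key for v in restrict_functional(data.variants)
        )
        qual_before = {
            data.variants[j].key
            for j, c in enumerate(cls2)
            if c.status in (VariantStatus.NOVEL, VariantStatus.RARE)
            and data.variants[j].key in functional
        }
        assert qual_after == qual_before == {("chr1", 1002, "A", "T")}

    def test_agrees_with_brute_force_on_small_cohorts(self):
        rng = np.random.default_rng(7)
        cfg = AnalysisConfig()
        for trial in range(25):
            n_case, n_control = 6, 4
            specs = []
            for k in range(int(rng.integers(1, 20))):
                in_db = bool(rng.random() < 0.5)
                has_freq = in_db and bool(rng.random() < 0.5)
                esp = float(rng.choice([0.0001, 0.000538, 0.002, 0.2])) if (
                    has_freq and rng.random() < 0.7
                ) else None
                kg = float(rng.choice([0.001, 0.05])) if rng.random() < 0.3 else None
                if not in_db and esp is None and rng.random() < 0.5:
                    kg = None
                fc = FunctionalClass.SYNONYMOUS if rng.random() < 0.2 else FunctionalClass.NONSYNONYMOUS
                cases = [int(i) for i in np.flatnonzero(rng.random(n_case) < 0.3)]
                controls = [int(i) for i in np.flatnonzero(rng.random(n_control) < 0.3)]
                specs.append(
                    (
                        dict(pos=1000 + k, in_dbsnp=in_db, dbsnp_has_freq=has_freq,
                             esp_freq=esp, kg_freq=kg, functional_class=fc),
                        cases, controls,
                    )
                )
            data = make_cohort(n_case, n_control, specs)
            expected = brute_force_classify(
                data.variants, data.genotypes,
                range(n_case), range(n_case, n_case + n_control), cfg,
            )
            got = {
                v.key: c.status.value
                for v, c in zip(data.variants, classify_cohort(data, cfg))
            }
            assert got == expected
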