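"""Exact 2x2 engine: p-values, conditional-MLE OR, exact CIs, prevalence."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from raveburden import (
    DataError,
    Group,
    PanelGene,
    adjust_control_count,
    category_enrichment,
    fisher_exact,
    gene_prevalence,
    prevalence_total,
    snp_carrier_test,
)
from raveburden.classify import classify_cohort

from conftest import make_cohort
from oracles import minlike_p, two_sided_ps


class TestFisherExact:
    def test_carrier_configuration_anchor(self):
        # 10 of 242 carriers vs 1 of 129: two-sided exact p rounds to 0.106
        r = fisher_exact([[10, 232], [1, 128]])
        assert round(r.p_two_sided, 3) == 0.106
        assert round(r.or_cmle, 2) == 5.50

    def test_published_stress_granule_statistics(self):
        # the published test's table (244-case denominator) reproduces the
        # reported p/OR/CI triple exactly at printed precision
        r = fisher_exact([[10, 234], [1, 128]])
        assert round(r.p_two_sided, 3) == 0.106
        assert round(r.or_cmle, 2) == 5.45
        assert round(r.ci_low, 2) == 0.77
        assert round(r.ci_high, 2) == 117.92

    def test_balanced_table_is_null(self):
        r = fisher_exact([[5, 5], [5, 5]])
        assert r.p_two_sided == 1.0
        assert r.or_cmle == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separation_small_table(self):
        # margins (2,2)/(2,2): point probabilities {1/6, 2/3, 1/6}
        r = fisher_exact([[2, 0], [0, 2]])
        assert r.p_two_sided == pytest.approx(1 / 3, abs=1e-12)
        assert math.isinf(r.or_cmle)
        assert math.isinf(r.ci_high)

    @pytest.mark.parametrize(
        "table", [[[0, 5], [0, 7]], [[3, 0], [2, 0]], [[0, 0], [3, 4]]]
    )
    def test_zero_margin_is_degenerate_not_an_error(self, table):
        r = fisher_exact(table)
        assert r.degenerate
        assert r.p_two_sided == 1.0
        assert r.or_cmle == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -2], [3, 4]])

    @pytest.mark.parametrize("method", ["minlike", "central"])
    def test_enumeration_oracle_small_tables(self, method):
        """p-values agree with exact integer enumeration for all tables N<=20."""
        worst = 0.0
        for n in range(1, 21):
            for r1 in range(1, n):
                r2 = n - r1
                for c1 in range(1, n):
                    if c1 > n:
                        continue
                    oracle = two_sided_ps(r1, r2, c1)
                    for x, (p_ml, p_c) in oracle.items():
                        t = [[x, r1 - x], [c1 - x, r2 - c1 + x]]
                        if min(t[0][1], t[1][0], t[1][1]) < 0:
                            continue
                        r = fisher_exact(t, method=method, compute_ci=False)
                        expected = p_ml if method == "minlike" else p_c
                        worst = max(worst, abs(r.p_two_sided - expected))
        assert worst < 1e-12

    def test_matches_scipy_minlike_p(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(0, 20, size=(2, 2))
            if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
                continue
            mine = fisher_exact(t.tolist(), compute_ci=False)
            assert mine.p_two_sided == pytest.approx(
                scipy.stats.fisher_exact(t).pvalue, abs=1e-11
            )

    def test_matches_scipy_conditional_or_and_central_ci(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            t = rng.integers(0, 15, size=(2, 2))
            if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
                continue
            mine = fisher_exact(t.tolist(), method="central")
            ref = scipy_odds_ratio(t)
            ci = ref.confidence_interval(0.95)
            if math.isfinite(mine.or_cmle):
                assert mine.or_cmle == pytest.approx(ref.statistic, rel=1e-6)
            assert mine.ci_low == pytest.approx(ci.low, rel=1e-4, abs=1e-6)
            if math.isfinite(mine.ci_high):
                assert mine.ci_high == pytest.approx(ci.high, rel=1e-4)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_symmetries(self, a, b, c, d):
        """Transposing preserves p; swapping rows inverts the odds ratio."""
        t = [[a, b], [c, d]]
        r = fisher_exact(t, compute_ci=False)
        assert 0.0 < r.p_two_sided <= 1.0
        rt = fisher_exact([[a, c], [b, d]], compute_ci=False)
        assert rt.p_two_sided == pytest.approx(r.p_two_sided, abs=1e-11)
        rs = fisher_exact([[c, d], [a, b]], compute_ci=False)
        if not r.degenerate:
            if r.or_cmle == 0.0:
                assert math.isinf(rs.or_cmle)
            elif math.isinf(r.or_cmle):
                assert rs.or_cmle == pytest.approx(0.0, abs=1e-9)
            else:
                assert rs.or_cmle == pytest.approx(1.0 / r.or_cmle, rel=1e-6)

    @pytest.mark.parametrize("method", ["minlike", "central"])
    def test_ci_and_test_agree_on_rejecting_unity(self, method):
        """The 95% CI excludes 1 iff the two-sided test rejects at 0.05."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 60:
            t = rng.integers(0, 16, size=(2, 2))
            if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
                continue
            r = fisher_exact(t.tolist(), method=method)
            excludes_one = (r.ci_low > 1.0) or (r.ci_high < 1.0)
            # boundary tables where p == alpha exactly are ambiguous; skip
            if abs(r.p_two_sided - 0.05) < 1e-9:
                continue
            assert excludes_one == (r.p_two_sided < 0.05), (t, r)
            checked += 1


class TestSnpCarrierTest:
    @pytest.mark.parametrize(
        "case, control", [(17, 4), (26, 16), (8, 1), (59, 32)]
    )
    def test_agrees_with_enumeration(self, case, control):
        # previously-associated SNP carrier configurations at the study's
        # 242/129 denominators
        r = snp_carrier_test(case, control, 242, 129)
        assert r.table == ((case, 242 - case), (control, 129 - control))
        expected = minlike_p(case, 242 - case, control, 129 - control)
        assert r.p_two_sided == pytest.approx(expected, abs=1e-12)

    def test_no_carriers_is_degenerate(self):
        r = snp_carrier_test(0, 0, 242, 129)
        assert r.degenerate and r.p_two_sided == 1.0

    def test_count_exceeding_cohort_rejected(self):
        with pytest.raises(DataError):
            snp_carrier_test(243, 0, 242, 129)


def _prevalence_cohort():
    """242/129 cohort with disjoint qualifying carriers per known gene."""
    specs = [
        # gene, case carriers, control carriers (novel variants, disjoint)
        (dict(gene="ANG"), [0], []),
        (dict(gene="FUS"), [1], []),
        (dict(gene="OPTN"), [], []),
        (dict(gene="SOD1"), [2, 3, 4, 5], []),
        (dict(gene="SPG11"), [], [0, 1, 2, 3]),
    ]
    return make_cohort(242, 129, specs)


class TestPrevalence:
    def test_gene_prevalence_matches_printed_percentages(self):
        data = _prevalence_cohort()
        cls = classify_cohort(data)
        sod1 = gene_prevalence(data, cls, "SOD1", Group.CASE)
        assert (sod1.carriers, round(sod1.prevalence, 2)) == (4, 1.65)
        spg11 = gene_prevalence(data, cls, "SPG11", Group.CONTROL)
        assert (spg11.carriers, round(spg11.prevalence, 2)) == (4, 3.10)

    def test_total_is_union_of_carriers(self):
        data = _prevalence_cohort()
        cls = classify_cohort(data)
        tot = prevalence_total(data, cls, ["ANG", "FUS", "OPTN", "SOD1"], Group.CASE)
        assert tot.carriers == 6
        assert round(tot.prevalence, 2) == 2.48

    def test_sample_with_two_genes_counts_once(self):
        specs = [
            (dict(gene="A"), [0], []),
            (dict(gene="B"), [0], []),
        ]
        data = make_cohort(10, 5, specs)
        cls = classify_cohort(data)
        tot = prevalence_total(data, cls, ["A", "B"], Group.CASE)
        assert tot.carriers == 1

    def test_unknown_gene_rejected(self):
        data = _prevalence_cohort()
        with pytest.raises(DataError):
            gene_prevalence(data, classify_cohort(data), "NOPE", Group.CASE)

    def test_zero_carriers_is_zero_percent(self):
        data = _prevalence_cohort()
        row = gene_prevalence(data, classify_cohort(data), "OPTN", Group.CASE)
        assert row.prevalence == 0.0


def test_adjust_control_count():
    assert adjust_control_count(2, 242, 129) == pytest.approx(3.752, abs=5e-4)
    assert adjust_control_count(0, 242, 129) == 0
    assert adjust_control_count(1, 242, 129) == pytest.approx(1.876, abs=5e-4)


class TestCategoryEnrichment:
    def test_stress_granule_carrier_configuration(self):
        panel = [
            PanelGene("SG1", frozenset({"rrm"}), frozenset({"stress_granule"})),
            PanelGene("OTHER", frozenset({"known_als"})),
        ]
        specs = [(dict(gene="SG1", pos=1000 + i), [i], []) for i in range(10)]
        specs.append((dict(gene="SG1", pos=2000), [], [0]))
        data = make_cohort(242, 129, specs)
        fr, pct = category_enrichment(data, classify_cohort(data), panel, "stress_granule")
        assert pct == {"case_pct": 4.13, "control_pct": 0.78}
        assert round(fr.p_two_sided, 3) == 0.106

    def test_unknown_tag_rejected(self):
        panel = [PanelGene("A", frozenset({"rrm"}))]
        data = make_cohort(4, 4, [(dict(gene="A"), [0], [])])
        with pytest.raises(DataError):
            category_enrichment(data, classify_cohort(data), panel, "nope")
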