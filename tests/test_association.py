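"""Association statistics: 2×2 tests, OR/CI, HWE, QC, burden analysis."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar.association import (
    CountTable2x2,
    GenotypeCounts,
    TestMethod,
    allele_table,
    allelic_association_test,
    bonferroni_correct,
    carriers_in_matrix,
    combined_carrier_analysis,
    drop_fully_missing_samples,
    genotype_to_allele_counts,
    hwe_exact_test,
    minor_allele_frequency,
    odds_ratio_2x2,
    single_variant_association,
    variant_call_rate,
    woolf_confidence_interval,
)
from famvar.io import truncate2
from famvar.model import FamvarError, Genotype, GenotypeMatrix, InputError, VariantKey


def gc(hom_ref, het, hom_alt, cohort="x", label="v"):
    return GenotypeCounts(cohort, label, hom_ref, het, hom_alt)


# ---------------------------------------------------------------------------
# Independent oracles (exact integer arithmetic)
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, col1)
    support = range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = {
        k: Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k), denom)
        for k in support
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def hwe_oracle(hom_ref, het, hom_alt):
    """Exact conditional HWE p with rational arithmetic (Levene distribution)."""
    n = hom_ref + het + hom_alt
    n_alt = het + 2 * hom_alt
    m = min(n_alt, 2 * n - n_alt)
    if m == 0:
        return Fraction(1)
    denom = math.comb(2 * n, m)
    probs = {}
    for h in range(m % 2, m + 1, 2):
        rare_hom = (m - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            continue
        probs[h] = Fraction(
            math.comb(n, h) * math.comb(n - h, rare_hom) * 2**h, denom
        )
    p_obs = probs[het]
    return sum(p for p in probs.values() if p <= p_obs)


# ---------------------------------------------------------------------------
# HWE
# ---------------------------------------------------------------------------

class TestHWE:
    def test_rare_all_het_configuration_is_modal(self):
        # 5 minor alleles in 7074 diploids: the all-het state carries nearly
        # all conditional mass, so the two-sided p is 1
        assert hwe_exact_test(gc(7069, 5, 0)) == pytest.approx(1.0)

    def test_balanced_counts_match_oracle(self):
        p = hwe_exact_test(gc(25, 50, 25))
        assert p == pytest.approx(float(hwe_oracle(25, 50, 25)), rel=1e-9)

    def test_extreme_disequilibrium_rejected(self):
        # no heterozygotes at 50% allele frequency: strong HWE violation
        assert hwe_exact_test(gc(10, 0, 10)) < 1e-4

    def test_monomorphic_counts_give_p_one(self):
        assert hwe_exact_test(gc(0, 0, 10)) == 1.0
        assert hwe_exact_test(gc(10, 0, 0)) == 1.0

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 20, 57, 123, 200])
    def test_matches_enumeration_oracle_across_sample_sizes(self, n):
        for m in {1, 2, 3, n // 3, n, 2 * n - 1}:
            m = min(max(m, 0), n)  # keep alt the minor allele
            for h in range(m % 2, m + 1, 2):
                rare_hom = (m - h) // 2
                counts = gc(n - h - rare_hom, h, rare_hom)
                assert hwe_exact_test(counts) == pytest.approx(
                    float(hwe_oracle(counts.n_hom_ref, h, rare_hom)), rel=1e-9
                )


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------

class TestAlleleCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [((2942, 10, 0), (10, 5904)), ((0, 0, 0), (0, 0)), ((1, 1, 1), (3, 6))],
    )
    def test_genotype_to_allele_counts(self, counts, expected):
        assert genotype_to_allele_counts(gc(*counts)) == expected

    def test_maf_matches_printed_control_frequencies(self):
        assert minor_allele_frequency(gc(7069, 5, 0)) * 100 == pytest.approx(
            0.035, abs=5e-4
        )
        assert minor_allele_frequency(gc(5749, 3, 0)) * 100 == pytest.approx(
            0.026, abs=5e-4
        )
        assert minor_allele_frequency(gc(0, 10, 0)) == 0.5

    def test_maf_requires_data(self):
        with pytest.raises(InputError):
            minor_allele_frequency(gc(0, 0, 0))


# ---------------------------------------------------------------------------
# 2×2 machinery
# ---------------------------------------------------------------------------

UC_S361L = CountTable2x2(10, 5894, 5, 14143)


class TestAllelicTest:
    def test_yates_matches_published_uc_pvalue(self):
        p = allelic_association_test(UC_S361L, TestMethod.CHI2_YATES)
        assert p == pytest.approx(0.0040, abs=1e-4)

    def test_balanced_table_shows_no_association(self):
        t = CountTable2x2(5, 95, 5, 95)
        assert allelic_association_test(t, TestMethod.FISHER_EXACT) == 1.0
        assert allelic_association_test(t, TestMethod.CHI2) == pytest.approx(1.0)

    def test_fisher_equals_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 13, size=4)
            if a + b == 0 or c + d == 0:
                continue
            p = allelic_association_test(
                CountTable2x2(int(a), int(b), int(c), int(d)), TestMethod.FISHER_EXACT
            )
            assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), rel=1e-8)

    def test_degenerate_margins_rejected_for_chi2(self):
        with pytest.raises(FamvarError):
            allelic_association_test(CountTable2x2(0, 0, 5, 5), TestMethod.CHI2)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_chi2_dominates_yates_and_swap_invariance(self, cells):
        t = CountTable2x2(*cells)
        chi2 = allelic_association_test(t, TestMethod.CHI2)
        yates = allelic_association_test(t, TestMethod.CHI2_YATES)
        assert yates >= chi2 - 1e-12
        swapped = CountTable2x2(t.d, t.c, t.b, t.a)  # swap rows AND columns
        assert allelic_association_test(swapped, TestMethod.CHI2) == pytest.approx(chi2)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, printed",
        [
            ((10, 5894, 5, 14143), "4.79"),
            ((13, 11589, 5, 14143), "3.17"),
            ((5, 100, 5, 100), "1.00"),
        ],
    )
    def test_cross_product_and_truncation(self, table, printed):
        assert truncate2(odds_ratio_2x2(CountTable2x2(*table))) == printed

    def test_zero_cell_haldane_correction(self):
        t = CountTable2x2(0, 10, 5, 10)
        assert odds_ratio_2x2(t) == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))
        with pytest.raises(FamvarError):
            odds_ratio_2x2(CountTable2x2(5, 0, 5, 10), zero_correction=False)

    @settings(max_examples=100, derandomize=True)
    @given(st.tuples(*[st.integers(1, 1000)] * 4))
    def test_group_swap_reciprocity(self, cells):
        a, b, c, d = cells
        assert odds_ratio_2x2(CountTable2x2(a, b, c, d)) * odds_ratio_2x2(
            CountTable2x2(c, d, a, b)
        ) == pytest.approx(1.0)


class TestWoolfCI:
    def test_uc_interval(self):
        low, high = woolf_confidence_interval(UC_S361L)
        assert (low, high) == (pytest.approx(1.64, abs=5e-3), pytest.approx(14.05, abs=5e-2))
        assert low <= odds_ratio_2x2(UC_S361L) <= high

    def test_symmetric_table_brackets_unity_symmetrically(self):
        low, high = woolf_confidence_interval(CountTable2x2(8, 92, 8, 92))
        assert math.log(low) == pytest.approx(-math.log(high))

    def test_wider_at_higher_level(self):
        low95, high95 = woolf_confidence_interval(UC_S361L, 0.95)
        low99, high99 = woolf_confidence_interval(UC_S361L, 0.99)
        assert low99 < low95 and high99 > high95


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.0039, 6, 0.0234), (0.018, 3, 0.054), (0.5, 6, 1.0)]
    )
    def test_published_corrections(self, p, m, expected):
        assert bonferroni_correct(p, m) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 10), st.integers(1, 10))
    def test_monotone_in_both_arguments(self, p1, p2, m1, m2):
        if p1 <= p2:
            assert bonferroni_correct(p1, m1) <= bonferroni_correct(p2, m1)
        if m1 <= m2:
            assert bonferroni_correct(p1, m1) <= bonferroni_correct(p1, m2)


# ---------------------------------------------------------------------------
# Composite analyses on the published counts
# ---------------------------------------------------------------------------

class TestSingleVariant(object):
    def test_uc_s361l(self, table1_counts):
        res = single_variant_association(
            table1_counts["p.S361L"]["UC"], table1_counts["p.S361L"]["control"]
        )
        assert truncate2(res.odds_ratio) == "4.79"
        assert res.p_corrected <= 0.05
        assert res.n_case == 2952

    def test_cd_s361l(self, table1_counts):
        res = single_variant_association(
            table1_counts["p.S361L"]["CD"], table1_counts["p.S361L"]["control"]
        )
        assert truncate2(res.odds_ratio) == "1.49"

    def test_identical_cohorts_are_null(self):
        res = single_variant_association(
            gc(990, 10, 0), gc(990, 10, 0), TestMethod.FISHER_EXACT
        )
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == 1.0


class TestCombinedCarrier:
    def test_ibd_combined_frequencies_and_or(self, table1_counts):
        res = combined_carrier_analysis(
            [table1_counts[v]["IBD"] for v in ("p.S361L", "p.R801H")],
            [table1_counts[v]["control"] for v in ("p.S361L", "p.R801H")],
        )
        assert res.n_case == 5752 and res.n_control == 6986
        assert res.maf_case * 100 == pytest.approx(0.28, abs=5e-3)
        assert res.maf_control * 100 == pytest.approx(0.10, abs=5e-3)
        assert truncate2(res.odds_ratio) == "2.77"

    def test_uc_combined_or(self, table1_counts):
        res = combined_carrier_analysis(
            [table1_counts[v]["UC"] for v in ("p.S361L", "p.R801H")],
            [table1_counts[v]["control"] for v in ("p.S361L", "p.R801H")],
        )
        assert truncate2(res.odds_ratio) == "3.73"

    def test_single_variant_panel_consistency_identity(self, table1_counts):
        case = table1_counts["p.S361L"]["UC"]
        control = table1_counts["p.S361L"]["control"]
        combined = combined_carrier_analysis(
            [case], [control], basis="carrier", m_tests=6
        )
        direct = CountTable2x2(
            case.n_carriers,
            case.n - case.n_carriers,
            control.n_carriers,
            control.n - control.n_carriers,
        )
        assert combined.odds_ratio == pytest.approx(odds_ratio_2x2(direct))
        assert combined.p == pytest.approx(
            allelic_association_test(direct, TestMethod.CHI2_YATES)
        )
        assert combined.maf_case == case.n_carriers / case.n

    def test_allele_and_carrier_bases_agree_without_hom_alt(self, table1_counts):
        panel = ("p.S361L", "p.R801H")
        for cohort in ("CD", "UC", "IBD"):
            allele = combined_carrier_analysis(
                [table1_counts[v][cohort] for v in panel],
                [table1_counts[v]["control"] for v in panel],
                basis="allele",
            ).odds_ratio
            carrier = combined_carrier_analysis(
                [table1_counts[v][cohort] for v in panel],
                [table1_counts[v]["control"] for v in panel],
                basis="carrier",
            ).odds_ratio
            assert abs(allele - carrier) / allele < 0.005

    def test_mismatched_panels_rejected(self, table1_counts):
        with pytest.raises(InputError, match="panel"):
            combined_carrier_analysis(
                [table1_counts["p.S361L"]["UC"]], [table1_counts["p.R801H"]["control"]]
            )


# ---------------------------------------------------------------------------
# Matrix-level QC
# ---------------------------------------------------------------------------

def panel_matrix():
    v1, v2 = VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "A", "G")
    m = GenotypeMatrix(["s1", "s2", "s3", "s4"], [v1, v2])
    m.set("s1", v1, Genotype.MISSING)
    m.set("s1", v2, Genotype.MISSING)  # fully missing → dropped
    m.set("s2", v1, Genotype.MISSING)
    m.set("s2", v2, Genotype.HET)  # partially missing → kept
    for s in ("s3", "s4"):
        m.set(s, v1, Genotype.HOM_REF)
        m.set(s, v2, Genotype.HET if s == "s3" else Genotype.HOM_ALT)
    return m, v1, v2


class TestMatrixQC:
    def test_drop_fully_missing_samples(self):
        m, v1, v2 = panel_matrix()
        filtered, removed = drop_fully_missing_samples(
            m, cohorts={"s1": "CD", "s2": "CD"}
        )
        assert filtered.individuals == ["s2", "s3", "s4"]
        assert removed == {"CD": 1}

    def test_no_missingness_is_identity(self):
        m, *_ = panel_matrix()
        filtered, _ = drop_fully_missing_samples(m)
        again, removed = drop_fully_missing_samples(filtered)
        assert again.individuals == filtered.individuals
        assert removed == {}

    def test_call_rate(self):
        m, v1, v2 = panel_matrix()
        assert variant_call_rate(m, v1) == 0.5
        assert variant_call_rate(m, v2) == 0.75

    def test_call_rate_gate_at_low_missingness(self):
        v = VariantKey("1", 1, "A", "G")
        codes = np.zeros((1000, 1), dtype=np.int8)
        codes[:5, 0] = -1  # 0.5% missing
        m = GenotypeMatrix([f"s{i}" for i in range(1000)], [v], codes)
        assert variant_call_rate(m, v) > 0.99

    def test_carriers_counted_once_across_panel(self):
        m, v1, v2 = panel_matrix()
        m.set("s3", v1, Genotype.HET)  # s3 now carries both panel variants
        carriers, total = carriers_in_matrix(m, [v1, v2])
        assert (carriers, total) == (3, 4)
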