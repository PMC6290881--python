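"""Case-control association statistics for rare variants.

Implements the allelic single-variant analysis (2×2 cross-product odds
ratio, chi-square with or without Yates continuity correction or Fisher's
exact test, Woolf confidence interval, Bonferroni correction) and the
cumulative-carrier (burden) analysis that pools carriers of a panel of rare
variants, plus the per-variant QC steps: sample missingness removal,
call-rate computation, and the exact conditional Hardy–Weinberg test.

All tests operate on genotype count tables; the allele-level 2×2 is derived
by counting minor alleles (het + 2·hom-alt) against the remaining alleles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .model import (
    FamvarError,
    Genotype,
    GenotypeMatrix,
    InputError,
    VariantKey,
)

__all__ = [
    "GenotypeCounts",
    "CountTable2x2",
    "TestMethod",
    "AssociationResult",
    "drop_fully_missing_samples",
    "variant_call_rate",
    "hwe_exact_test",
    "genotype_to_allele_counts",
    "minor_allele_frequency",
    "allele_table",
    "allelic_association_test",
    "odds_ratio_2x2",
    "woolf_confidence_interval",
    "bonferroni_correct",
    "single_variant_association",
    "combined_carrier_analysis",
    "carriers_in_matrix",
]


class TestMethod(enum.Enum):
    __test__ = False  # not a pytest class, despite the name

    CHI2 = "chi2"
    CHI2_YATES = "chi2_yates"
    FISHER_EXACT = "fisher_exact"


@dataclass
class GenotypeCounts:
    """Genotype tally for one variant in one cohort (hom-ref / het / hom-alt)."""

    cohort: str
    variant_label: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for cell in (self.n_hom_ref, self.n_het, self.n_hom_alt):
            if cell < 0:
                raise InputError(f"negative genotype count in {self}")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_carriers(self) -> int:
        return self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class CountTable2x2:
    """2×2 table: a/b = case minor/major (or carrier/non-carrier), c/d = control."""

    a: int | float
    b: int | float
    c: int | float
    d: int | float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError(f"negative cell in 2x2 table {self}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "CountTable2x2":
        """Haldane–Anscombe: add 0.5 to every cell when any cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return CountTable2x2(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return self


@dataclass
class AssociationResult:
    """One association test: odds ratio with CI, p-values, and frequencies.

    For allele-basis tests ``maf_case``/``maf_control`` are minor allele
    frequencies; for carrier-basis (burden) tests they are carrier
    frequencies per individual.  ``n_case``/``n_control`` count individuals.
    """

    phenotype: str
    basis: str  # "allele" or "carrier"
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_corrected: float
    maf_case: float
    maf_control: float
    n_case: int
    n_control: int


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def drop_fully_missing_samples(
    matrix: GenotypeMatrix,
    cohorts: Mapping[str, str] | None = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove individuals missing at every panel variant.

    Individuals missing at some but not all variants are retained (per-variant
    n may then differ between variants).  Returns the filtered matrix and the
    number removed per cohort ("all" when no cohort map is given).
    """
    if not matrix.variants:
        raise InputError("empty variant panel")
    fully_missing = (matrix.codes == Genotype.MISSING.code).all(axis=1)
    removed: dict[str, int] = {}
    keep = []
    for iid, miss in zip(matrix.individuals, fully_missing):
        if miss:
            cohort = cohorts.get(iid, "unknown") if cohorts is not None else "all"
            removed[cohort] = removed.get(cohort, 0) + 1
        else:
            keep.append(iid)
    return matrix.subset_individuals(keep), removed


def variant_call_rate(matrix: GenotypeMatrix, variant: VariantKey) -> float:
    """Fraction of individuals with a non-missing call at the variant."""
    if variant not in matrix:
        raise InputError(f"variant {variant} not in matrix")
    return matrix.call_rate(variant)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy–Weinberg test (two-sided by probability mass).

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; the p-value is the summed
    probability of all configurations no more probable than the observed
    one.  No mid-p adjustment.
    """
    n = counts.n
    if n <= 0:
        raise InputError("HWE test requires at least one genotyped individual")
    n_alt = counts.n_het + 2 * counts.n_hom_alt
    n_ref = 2 * n - n_alt
    m = min(n_alt, n_ref)  # rarer allele count
    if m == 0:
        return 1.0
    # log P(h hets | n, m) = log n! - log n_aa! - log h! - log n_bb!
    #                        + h log 2 + log m! + log (2n-m)! - log (2n)!
    base = (
        gammaln(n + 1)
        + gammaln(m + 1)
        + gammaln(2 * n - m + 1)
        - gammaln(2 * n + 1)
    )
    hs = np.arange(m % 2, m + 1, 2)
    n_rare_hom = (m - hs) // 2
    n_common_hom = n - hs - n_rare_hom
    valid = n_common_hom >= 0
    hs, n_rare_hom, n_common_hom = hs[valid], n_rare_hom[valid], n_common_hom[valid]
    logp = (
        base
        - gammaln(n_rare_hom + 1)
        - gammaln(hs + 1)
        - gammaln(n_common_hom + 1)
        + hs * math.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    h_obs = counts.n_het
    if h_obs not in set(hs.tolist()):
        raise InputError(
            f"heterozygote count {h_obs} incompatible with allele count {m}"
        )
    p_obs = probs[np.nonzero(hs == h_obs)[0][0]]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Allele counting
# ---------------------------------------------------------------------------

def genotype_to_allele_counts(counts: GenotypeCounts) -> tuple[int, int]:
    """(minor allele count, total allele count) for a genotype tally."""
    n_minor = counts.n_het + 2 * counts.n_hom_alt
    n_total = 2 * counts.n
    return n_minor, n_total


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    n_minor, n_total = genotype_to_allele_counts(counts)
    if n_total == 0:
        raise InputError("cannot compute MAF with zero genotyped individuals")
    return n_minor / n_total


def allele_table(case: GenotypeCounts, control: GenotypeCounts) -> CountTable2x2:
    """Allele-level 2×2: case minor/major vs control minor/major."""
    a, case_total = genotype_to_allele_counts(case)
    c, control_total = genotype_to_allele_counts(control)
    return CountTable2x2(a, case_total - a, c, control_total - c)


# ---------------------------------------------------------------------------
# 2×2 tests, odds ratio, confidence interval
# ---------------------------------------------------------------------------

def _chi2_stat(table: CountTable2x2, yates: bool) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise FamvarError(f"degenerate margins in {table}; chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return n * diff * diff / margins


def allelic_association_test(table: CountTable2x2, method: TestMethod) -> float:
    """Two-sided p-value for a 2×2 association table.

    chi2: Pearson statistic N(ad−bc)²/(r₁r₂c₁c₂), 1 df.
    chi2_yates: continuity-corrected, (|ad−bc|−N/2)² floored at 0.
    fisher_exact: two-sided exact hypergeometric (sum of tables with
    probability ≤ the observed table's).
    """
    if method is TestMethod.FISHER_EXACT:
        _, p = stats.fisher_exact(
            [[round(table.a), round(table.b)], [round(table.c), round(table.d)]],
            alternative="two-sided",
        )
        return float(p)
    stat = _chi2_stat(table, yates=method is TestMethod.CHI2_YATES)
    return float(stats.chi2.sf(stat, df=1))


def odds_ratio_2x2(table: CountTable2x2, zero_correction: bool = True) -> float:
    """Cross-product odds ratio (a·d)/(b·c), Haldane–Anscombe on zero cells."""
    if zero_correction:
        table = table.corrected()
    if table.b * table.c == 0:
        raise FamvarError(f"odds ratio undefined for {table} (zero in b·c)")
    return (table.a * table.d) / (table.b * table.c)


def woolf_confidence_interval(
    table: CountTable2x2, level: float = 0.95
) -> tuple[float, float]:
    """Woolf (log-scale normal) CI: exp(ln OR ± z·√(1/a+1/b+1/c+1/d))."""
    if not (0.0 < level < 1.0):
        raise InputError(f"confidence level outside (0,1): {level}")
    table = table.corrected()
    log_or = math.log(odds_ratio_2x2(table, zero_correction=False))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def bonferroni_correct(p: float, m: int) -> float:
    """min(1, m·p)."""
    if m < 1:
        raise InputError(f"number of tests must be >= 1, got {m}")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# Composite analyses
# ---------------------------------------------------------------------------

def single_variant_association(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    method: TestMethod = TestMethod.CHI2_YATES,
    m_tests: int = 6,
) -> AssociationResult:
    """Allelic case-control test for one variant.

    Builds the allele-level 2×2, tests it with ``method``, and reports the
    cross-product odds ratio, the Woolf 95% CI, per-cohort minor allele
    frequencies and the Bonferroni-corrected p-value (default m = 6: two
    variants × three phenotypes).
    """
    table = allele_table(case_counts, control_counts)
    p = allelic_association_test(table, method)
    return AssociationResult(
        phenotype=case_counts.cohort,
        basis="allele",
        odds_ratio=odds_ratio_2x2(table),
        ci_low=woolf_confidence_interval(table)[0],
        ci_high=woolf_confidence_interval(table)[1],
        p=p,
        p_corrected=bonferroni_correct(p, m_tests),
        maf_case=minor_allele_frequency(case_counts),
        maf_control=minor_allele_frequency(control_counts),
        n_case=case_counts.n,
        n_control=control_counts.n,
    )


def combined_carrier_analysis(
    per_variant_case: Sequence[GenotypeCounts],
    per_variant_control: Sequence[GenotypeCounts],
    method: TestMethod = TestMethod.CHI2_YATES,
    m_tests: int = 3,
    basis: str = "allele",
) -> AssociationResult:
    """Cumulative (burden) analysis pooling carriers of a rare-variant panel.

    Carriers (het + hom-alt) are summed across panel variants per cohort;
    the per-cohort denominator is the minimum per-variant n (individuals
    typed on the complete panel, assuming missingness nests).  With
    ``basis="allele"`` the 2×2 pools minor alleles against the remaining
    alleles; with ``basis="carrier"`` it compares carrier vs non-carrier
    individuals.  Counts-level input assumes carrier sets are disjoint across
    variants (use :func:`carriers_in_matrix` to deduplicate from raw calls).
    ``maf_case``/``maf_control`` in the result hold the combined carrier
    frequency per individual.  Default m = 3 (one combined test per
    phenotype).
    """
    if len(per_variant_case) != len(per_variant_control) or not per_variant_case:
        raise InputError("case and control panels must be non-empty and match")
    case_labels = [c.variant_label for c in per_variant_case]
    control_labels = [c.variant_label for c in per_variant_control]
    if case_labels != control_labels:
        raise InputError(
            f"panel mismatch: cases {case_labels} vs controls {control_labels}"
        )
    if basis not in ("allele", "carrier"):
        raise InputError(f"basis must be 'allele' or 'carrier', got {basis!r}")
    n_case = min(c.n for c in per_variant_case)
    n_control = min(c.n for c in per_variant_control)
    carriers_case = sum(c.n_carriers for c in per_variant_case)
    carriers_control = sum(c.n_carriers for c in per_variant_control)
    if basis == "allele":
        minor_case = sum(genotype_to_allele_counts(c)[0] for c in per_variant_case)
        minor_control = sum(
            genotype_to_allele_counts(c)[0] for c in per_variant_control
        )
        table = CountTable2x2(
            minor_case,
            2 * n_case - minor_case,
            minor_control,
            2 * n_control - minor_control,
        )
    else:
        table = CountTable2x2(
            carriers_case,
            n_case - carriers_case,
            carriers_control,
            n_control - carriers_control,
        )
    p = allelic_association_test(table, method)
    return AssociationResult(
        phenotype=per_variant_case[0].cohort,
        basis=basis,
        odds_ratio=odds_ratio_2x2(table),
        ci_low=woolf_confidence_interval(table)[0],
        ci_high=woolf_confidence_interval(table)[1],
        p=p,
        p_corrected=bonferroni_correct(p, m_tests),
        maf_case=carriers_case / n_case,
        maf_control=carriers_control / n_control,
        n_case=n_case,
        n_control=n_control,
    )


def carriers_in_matrix(
    matrix: GenotypeMatrix, variants: Sequence[VariantKey]
) -> tuple[int, int]:
    """(carrier individuals, total individuals) for a panel, counting an
    individual carrying several panel variants once."""
    cols = [matrix.variant_column(v) for v in variants]
    if not cols:
        raise InputError("empty variant panel")
    codes = np.stack(cols, axis=1)
    carrier = (codes == Genotype.HET.code) | (codes == Genotype.HOM_ALT.code)
    return int(carrier.any(axis=1).sum()), len(matrix.individuals)
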