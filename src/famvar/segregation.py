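"""Co-segregation tables for a candidate variant in an extended pedigree.

Given a pedigree and genotype calls, tabulate carriers (het or hom-alt:
segregation describes whatever is observed, even under a dominant filter)
against affection status, keeping married-in individuals out of the
segregation argument and counting penetrance and phenocopies explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import (
    Genotype,
    GenotypeMatrix,
    InputError,
    Pedigree,
    Phenotype,
    VariantKey,
)

__all__ = ["SegregationSummary", "tabulate_segregation", "penetrance_report"]


@dataclass
class SegregationSummary:
    """Carrier-by-phenotype tally for one variant in one family.

    ``untyped`` counts members of known phenotype without a genotype call;
    members of unknown phenotype are excluded from all four cells and
    reported in ``unknown_phenotype``.  ``carrier_penetrance`` is
    affected carriers / all carriers (None when there are no carriers).
    ``complete_segregation`` requires every affected to be a carrier and
    every unaffected a non-carrier, married-in members excluded.
    """

    variant: VariantKey
    family_id: str
    affected_carriers: int = 0
    affected_noncarriers: int = 0
    unaffected_carriers: int = 0
    unaffected_noncarriers: int = 0
    untyped: int = 0
    unknown_phenotype: int = 0
    married_in_affected_noncarriers: int = 0
    carrier_penetrance: float | None = None
    complete_segregation: bool = False


def tabulate_segregation(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    variant: VariantKey,
) -> SegregationSummary:
    """Tabulate carrier status against affection status for one variant.

    Members absent from the matrix, or with a missing call, count as
    untyped.  Order of members does not affect the result.
    """
    if variant not in matrix:
        raise InputError(f"variant {variant} not present in genotype matrix")
    s = SegregationSummary(variant=variant, family_id=pedigree.family_id)
    blood_affected_noncarriers = 0
    blood_unaffected_carriers = 0
    for ind in pedigree.members:
        if ind.phenotype is Phenotype.UNKNOWN:
            s.unknown_phenotype += 1
            continue
        gt = (
            matrix.get(ind.individual_id, variant)
            if matrix.has_individual(ind.individual_id)
            else Genotype.MISSING
        )
        if gt is Genotype.MISSING:
            s.untyped += 1
            continue
        carrier = gt.is_carrier
        married = pedigree.is_married_in(ind.individual_id)
        if ind.phenotype is Phenotype.AFFECTED:
            if carrier:
                s.affected_carriers += 1
            else:
                s.affected_noncarriers += 1
                if married:
                    s.married_in_affected_noncarriers += 1
                else:
                    blood_affected_noncarriers += 1
        else:
            if carrier:
                s.unaffected_carriers += 1
                if not married:
                    blood_unaffected_carriers += 1
            else:
                s.unaffected_noncarriers += 1
    carriers = s.affected_carriers + s.unaffected_carriers
    if carriers > 0:
        s.carrier_penetrance = s.affected_carriers / carriers
    s.complete_segregation = (
        blood_affected_noncarriers == 0
        and blood_unaffected_carriers == 0
        and s.affected_carriers > 0
    )
    return s


def penetrance_report(summaries: Iterable[SegregationSummary]) -> list[dict]:
    """Per-family penetrance and phenocopy summary.

    A family shows incomplete penetrance when at least one unaffected member
    carries the variant; phenocopies (affected non-carriers) are split into
    married-in individuals and blood relatives.
    """
    report = []
    for s in summaries:
        report.append(
            {
                "family_id": s.family_id,
                "variant": str(s.variant),
                "carrier_penetrance": s.carrier_penetrance,
                "phenocopies_married_in": s.married_in_affected_noncarriers,
                "phenocopies_blood": s.affected_noncarriers
                - s.married_in_affected_noncarriers,
                "incomplete_penetrance": s.unaffected_carriers > 0,
            }
        )
    return report
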