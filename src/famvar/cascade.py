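"""Stepwise rare-variant prioritization cascade for multiplex pedigrees.

The cascade assumes a dominant model of inheritance and keeps, per family,
variants that are (i) heterozygous in every whole-exome-sequenced affected
member, (ii) protein-altering (missense, nonsense, frameshift, or canonical
splice site), (iii) absent or rare (< 1% by default) in every configured
population frequency source, and finally (iv) restricts to genes hit in at
least two distinct families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    PROTEIN_ALTERING,
    AnnotatedVariant,
    Consequence,
    FamvarError,
    Genotype,
    GenotypeMatrix,
    InputError,
    Pedigree,
    VariantKey,
)

__all__ = [
    "FilterConfig",
    "FamilyCandidateSet",
    "GeneHit",
    "CascadeResult",
    "shared_het_in_affecteds",
    "filter_protein_altering",
    "filter_rare",
    "genes_recurrent_across_families",
    "run_cascade",
    "STAGES",
]

#: Cascade stage names, in application order.
STAGES = ("shared_het", "protein_altering", "rare")


@dataclass
class FilterConfig:
    """Tunable thresholds of the prioritization cascade.

    ``source_mode="all"`` requires the frequency criterion to hold in every
    configured source (conservative AND); ``"any"`` accepts a variant rare
    in at least one source.  ``allow_hom_alt`` relaxes the strict
    heterozygous-only dominant filter to carrier status.  With
    ``require_all_sequenced_affected=False`` a missing call in a sequenced
    affected member is tolerated instead of excluding the variant.
    """

    max_frequency: float = 0.01
    frequency_sources: tuple[str, ...] = ("exac", "inhouse")
    qualifying_consequences: frozenset[Consequence] = PROTEIN_ALTERING
    min_families: int = 2
    require_all_sequenced_affected: bool = True
    allow_hom_alt: bool = False
    source_mode: str = "all"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_frequency <= 1.0):
            raise InputError(f"max_frequency outside [0,1]: {self.max_frequency}")
        if self.min_families < 1:
            raise InputError(f"min_families must be >= 1, got {self.min_families}")
        if self.source_mode not in ("all", "any"):
            raise InputError(f"source_mode must be 'all' or 'any', got {self.source_mode!r}")
        self.qualifying_consequences = frozenset(self.qualifying_consequences)


@dataclass
class FamilyCandidateSet:
    """Per-family candidate variants after each cascade stage (descending chain)."""

    family_id: str
    stage_variants: dict[str, list[VariantKey]] = field(default_factory=dict)

    def final(self) -> list[VariantKey]:
        return self.stage_variants.get(STAGES[-1], [])


@dataclass
class GeneHit:
    gene: str
    supporting_families: list[str]
    variants: dict[str, list[VariantKey]]


@dataclass
class CascadeResult:
    per_family: list[FamilyCandidateSet]
    gene_hits: list[GeneHit]
    stage_counts: dict[str, int]
    gene_count: int
    novel_count: int


def shared_het_in_affecteds(
    pedigree: Pedigree,
    matrix: GenotypeMatrix,
    config: FilterConfig | None = None,
) -> list[VariantKey]:
    """Variants heterozygous in every sequenced affected family member.

    Any hom-ref, hom-alt or missing call in a sequenced affected member
    excludes the variant (strict sharing; see FilterConfig for the
    relaxations).  Affected members without the sequenced flag are ignored:
    they were not part of the exome screen.
    """
    config = config or FilterConfig()
    members = [
        ind
        for ind in pedigree.sequenced_affected()
        if matrix.has_individual(ind.individual_id)
    ]
    if not members:
        raise FamvarError(
            f"family {pedigree.family_id}: no sequenced affected member in the "
            "genotype matrix; family cannot be analysed"
        )
    sub = matrix.subset_individuals([m.individual_id for m in members])
    codes = sub.codes
    het = codes == Genotype.HET.code
    if config.allow_hom_alt:
        het = het | (codes == Genotype.HOM_ALT.code)
    if config.require_all_sequenced_affected:
        mask = het.all(axis=0)
    else:
        missing = codes == Genotype.MISSING.code
        mask = (het | missing).all(axis=0) & het.any(axis=0)
    return [v for v, keep in zip(sub.variants, mask) if keep]


def filter_protein_altering(
    variants: Iterable[VariantKey],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig | None = None,
) -> list[VariantKey]:
    """Keep variants whose consequence class qualifies as protein-altering."""
    config = config or FilterConfig()
    variants = list(variants)
    unannotated = [v for v in variants if v not in annotations]
    if unannotated:
        raise InputError(
            "unannotated variants: " + ", ".join(str(v) for v in unannotated)
        )
    return [
        v
        for v in variants
        if annotations[v].consequence in config.qualifying_consequences
    ]


def _is_rare(
    variant: VariantKey,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig,
) -> bool:
    ann = annotations.get(variant)
    freqs = ann.freq_by_source if ann is not None else {}
    verdicts = []
    for source in config.frequency_sources:
        freq = freqs.get(source)
        verdicts.append(freq is None or freq < config.max_frequency)
    if not verdicts:
        return True
    return all(verdicts) if config.source_mode == "all" else any(verdicts)


def is_novel(
    variant: VariantKey,
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig | None = None,
) -> bool:
    """Absent from every configured frequency source (never observed)."""
    config = config or FilterConfig()
    ann = annotations.get(variant)
    if ann is None:
        return True
    return not any(s in ann.freq_by_source for s in config.frequency_sources)


def filter_rare(
    variants: Iterable[VariantKey],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig | None = None,
) -> list[VariantKey]:
    """Keep variants absent or strictly below ``max_frequency`` per source.

    A variant with no frequency record in a source is treated as absent from
    that source (and counts as novel when absent from all sources).
    """
    config = config or FilterConfig()
    return [v for v in variants if _is_rare(v, annotations, config)]


def genes_recurrent_across_families(
    per_family: Sequence[FamilyCandidateSet],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig | None = None,
) -> list[GeneHit]:
    """Group final-stage variants by gene; keep genes hit in >= min_families.

    The supporting variants may be identical or different between families;
    gene identity comes solely from the annotation table.
    """
    config = config or FilterConfig()
    by_gene: dict[str, dict[str, list[VariantKey]]] = {}
    for fam in per_family:
        for variant in fam.final():
            ann = annotations.get(variant)
            if ann is None:
                raise InputError(f"unannotated variant {variant} in final stage")
            by_gene.setdefault(ann.gene, {}).setdefault(fam.family_id, []).append(variant)
    hits = []
    for gene in sorted(by_gene):
        fam_variants = by_gene[gene]
        if len(fam_variants) >= config.min_families:
            hits.append(
                GeneHit(
                    gene=gene,
                    supporting_families=sorted(fam_variants),
                    variants={f: sorted(vs) for f, vs in fam_variants.items()},
                )
            )
    return hits


def run_cascade(
    families: Sequence[tuple[Pedigree, GenotypeMatrix]],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    config: FilterConfig | None = None,
) -> CascadeResult:
    """Apply the full cascade per family, then the cross-family recurrence step.

    ``stage_counts`` pools distinct (family, variant) pairs per stage;
    ``novel_count`` counts distinct final-stage variants absent from every
    frequency source.
    """
    config = config or FilterConfig()
    per_family: list[FamilyCandidateSet] = []
    stage_counts = {stage: 0 for stage in STAGES}
    novel: set[VariantKey] = set()
    for pedigree, matrix in families:
        shared = shared_het_in_affecteds(pedigree, matrix, config)
        altering = filter_protein_altering(shared, annotations, config)
        rare = filter_rare(altering, annotations, config)
        per_family.append(
            FamilyCandidateSet(
                family_id=pedigree.family_id,
                stage_variants={
                    "shared_het": shared,
                    "protein_altering": altering,
                    "rare": rare,
                },
            )
        )
        stage_counts["shared_het"] += len(shared)
        stage_counts["protein_altering"] += len(altering)
        stage_counts["rare"] += len(rare)
        novel.update(v for v in rare if is_novel(v, annotations, config))
    gene_hits = genes_recurrent_across_families(per_family, annotations, config)
    return CascadeResult(
        per_family=per_family,
        gene_hits=gene_hits,
        stage_counts=stage_counts,
        gene_count=len(gene_hits),
        novel_count=len(novel),
    )
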