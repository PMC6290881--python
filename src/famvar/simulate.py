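"""Synthetic pedigrees, genotypes and case-control cohorts.

The family-mode generator emulates the study design the cascade assumes:
multi-generation multiplex pedigrees ascertained for three or more affected
members, a rare heterozygous risk allele introduced by a founder and
transmitted by Mendelian gene dropping, incomplete penetrance with
phenocopies, and a background of independent variants with a log-uniform
population frequency spectrum.  The cohort-mode generator draws carrier
counts for case-control panels from an odds-ratio-parameterised binomial
model at the scale of the genotyping follow-up (2948 CD, 3077 UC, 7238
controls).  Everything is reproducible bit-for-bit given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AnnotatedVariant,
    Consequence,
    FamvarError,
    Genotype,
    GenotypeMatrix,
    Individual,
    InputError,
    Pedigree,
    Phenotype,
    Sex,
    VariantKey,
)
from .association import GenotypeCounts

__all__ = [
    "PenetranceModel",
    "FamilySimConfig",
    "CohortSimConfig",
    "VariantEffect",
    "simulate_pedigree",
    "gene_drop",
    "assign_phenotypes",
    "simulate_family_dataset",
    "simulate_casecontrol_counts",
    "write_family_dataset",
    "write_cohort_dataset",
]

# Integer tags for independent, order-insensitive random substreams.
_S_PEDIGREE, _S_DROP, _S_PHENO, _S_BACKGROUND, _S_COHORT = 0, 1, 2, 3, 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class PenetranceModel:
    """Dominant-model penetrance: carriers affected with probability
    ``carrier_penetrance``, non-carriers with the phenocopy rate."""

    carrier_penetrance: float = 0.6
    phenocopy_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.phenocopy_rate < self.carrier_penetrance <= 1.0):
            raise InputError(
                f"need 0 <= phenocopy_rate < carrier_penetrance <= 1, got "
                f"{self.phenocopy_rate}, {self.carrier_penetrance}"
            )


_DEFAULT_MIX = {
    Consequence.MISSENSE: 0.50,
    Consequence.SYNONYMOUS: 0.30,
    Consequence.OTHER: 0.10,
    Consequence.NONSENSE: 0.04,
    Consequence.FRAMESHIFT: 0.03,
    Consequence.SPLICE_CANONICAL: 0.03,
}


@dataclass
class FamilySimConfig:
    """Family-mode generator settings.

    Defaults mirror the study conditions: 10 multiplex families with >= 3
    affected members over 3 generations, a causal missense allele of
    population frequency 4e-4 planted in 2 families, penetrance 0.6 with a
    5% phenocopy rate, and 200 background variants with log-uniform allele
    frequencies on [1e-5, 0.5].
    """

    n_families: int = 10
    generations: int = 3
    mean_sibship: float = 2.5
    causal_gene: str = "GENE_CAUSAL"
    causal_allele_frequency: float = 0.0004
    n_causal_families: int = 2
    background_variants: int = 200
    background_af_range: tuple[float, float] = (1e-5, 0.5)
    consequence_mix: dict[Consequence, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    min_affected: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_families > self.n_families:
            raise InputError("n_causal_families cannot exceed n_families")
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"consequence_mix must sum to 1, sums to {total}")
        if self.generations < 2:
            raise InputError("need at least 2 generations")


@dataclass(frozen=True)
class VariantEffect:
    """One panel variant for cohort simulation: control carrier frequency
    plus per-phenotype odds ratios."""

    label: str
    control_carrier_frequency: float
    odds_ratio_cd: float
    odds_ratio_uc: float


@dataclass
class CohortSimConfig:
    """Cohort-mode generator settings, defaulting to the follow-up panel's
    scale and the published effect sizes (control carrier frequencies of the
    two NLRP7 variants; UC odds ratio 4.8 for the first)."""

    n_cd: int = 2948
    n_uc: int = 3077
    n_control: int = 7238
    variants: tuple[VariantEffect, ...] = (
        VariantEffect("var1", 0.0007, 1.5, 4.8),
        VariantEffect("var2", 0.0003, 2.5, 1.2),
    )
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cd, self.n_uc, self.n_control) <= 0:
            raise InputError("cohort sizes must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InputError(f"missing_rate outside [0,1): {self.missing_rate}")
        for v in self.variants:
            if not (0.0 <= v.control_carrier_frequency <= 1.0):
                raise InputError(f"carrier frequency outside [0,1] for {v.label}")


# ---------------------------------------------------------------------------
# Pedigree structure
# ---------------------------------------------------------------------------

def simulate_pedigree(config: FamilySimConfig, family_index: int) -> Pedigree:
    """Build one multi-generation pedigree, deterministic given (seed, index).

    A founding couple heads the family; in every non-final generation each
    child marries a married-in spouse and has a sibship of size
    max(1, Poisson(mean_sibship)).  Phenotypes are left unknown here; they
    are drawn by :func:`assign_phenotypes` after gene dropping.
    """
    rng = _rng(config.seed, _S_PEDIGREE, family_index)
    family_id = f"F{family_index:03d}"
    counter = 0

    def new_individual(father=None, mother=None, sex=None) -> Individual:
        nonlocal counter
        counter += 1
        if sex is None:
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        return Individual(
            individual_id=f"{family_id}_I{counter:03d}",
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
        )

    father0 = new_individual(sex=Sex.MALE)
    mother0 = new_individual(sex=Sex.FEMALE)
    members = [father0, mother0]
    couples = [(father0, mother0)]
    for generation in range(2, config.generations + 1):
        next_couples = []
        for father, mother in couples:
            n_children = max(1, int(rng.poisson(config.mean_sibship)))
            for _ in range(n_children):
                child = new_individual(
                    father=father.individual_id, mother=mother.individual_id
                )
                members.append(child)
                if generation < config.generations:
                    spouse_sex = (
                        Sex.FEMALE if child.sex is Sex.MALE else Sex.MALE
                    )
                    spouse = new_individual(sex=spouse_sex)
                    members.append(spouse)
                    if child.sex is Sex.MALE:
                        next_couples.append((child, spouse))
                    else:
                        next_couples.append((spouse, child))
        couples = next_couples
    return Pedigree(family_id=family_id, members=members)


# ---------------------------------------------------------------------------
# Gene dropping and phenotypes
# ---------------------------------------------------------------------------

def gene_drop(
    pedigree: Pedigree,
    founder_genotypes: Mapping[str, Genotype],
    seed: int | np.random.Generator,
    variant: VariantKey | None = None,
) -> GenotypeMatrix:
    """Mendelian transmission of a single biallelic variant.

    Every founder must have a genotype; each non-founder inherits one allele
    from each parent uniformly at random.  Returns a one-variant matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if variant is None:
        variant = VariantKey("1", 1000, "A", "G")
    missing_founders = [
        f.individual_id for f in pedigree.founders()
        if f.individual_id not in founder_genotypes
    ]
    if missing_founders:
        raise InputError(
            "no founder genotype for: " + ", ".join(missing_founders)
        )
    dosage: dict[str, int] = {}
    index = pedigree.by_id()

    def resolve(iid: str) -> int:
        if iid in dosage:
            return dosage[iid]
        ind = index[iid]
        if ind.is_founder:
            d = {Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2}[
                founder_genotypes[iid]
            ]
        else:
            d = 0
            for parent in (ind.father_id, ind.mother_id):
                pd = resolve(parent)
                # transmit the alt allele with probability dosage/2
                d += int(rng.random() < pd / 2.0)
        dosage[iid] = d
        return d

    # Resolve in member order so the draw sequence is reproducible.
    for ind in pedigree.members:
        resolve(ind.individual_id)
    matrix = GenotypeMatrix(pedigree.member_ids, [variant])
    for iid, d in dosage.items():
        matrix.set(iid, variant, (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[d])
    return matrix


def assign_phenotypes(
    pedigree: Pedigree,
    causal_calls: Mapping[str, Genotype],
    model: PenetranceModel,
    seed: int | np.random.Generator,
) -> Pedigree:
    """Draw affection status: carriers affected with probability f,
    non-carriers with the phenocopy rate.  Returns a new pedigree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = []
    for ind in pedigree.members:
        call = causal_calls.get(ind.individual_id)
        if call is None:
            raise InputError(f"no causal call for member {ind.individual_id}")
        p_affected = (
            model.carrier_penetrance if call.is_carrier else model.phenocopy_rate
        )
        phenotype = (
            Phenotype.AFFECTED if rng.random() < p_affected else Phenotype.UNAFFECTED
        )
        members.append(dataclasses.replace(ind, phenotype=phenotype))
    return Pedigree(family_id=pedigree.family_id, members=members)


# ---------------------------------------------------------------------------
# Family-mode dataset
# ---------------------------------------------------------------------------

_CAUSAL_VARIANT = VariantKey("19", 55_440_000, "C", "T")

_MAX_ASCERTAINMENT_ATTEMPTS = 20_000


def _ascertain_family(
    config: FamilySimConfig,
    pedigree: Pedigree,
    family_index: int,
    causal: bool,
) -> tuple[Pedigree, dict[str, Genotype]]:
    """Redraw gene drop and phenotypes until the family meets ascertainment.

    Ascertainment mirrors the study's family selection: at least
    ``min_affected`` affected members; causal families additionally need at
    least two affected carriers (otherwise the family would never have
    entered a shared-variant screen).
    """
    drop_rng = _rng(config.seed, _S_DROP, family_index)
    pheno_rng = _rng(config.seed, _S_PHENO, family_index)
    founders = pedigree.founders()
    for _ in range(_MAX_ASCERTAINMENT_ATTEMPTS):
        founder_genotypes = {f.individual_id: Genotype.HOM_REF for f in founders}
        if causal:
            # The risk allele enters through one member of the founding couple.
            founder_genotypes[pedigree.members[0].individual_id] = Genotype.HET
        matrix = gene_drop(pedigree, founder_genotypes, drop_rng, _CAUSAL_VARIANT)
        calls = {
            iid: matrix.get(iid, _CAUSAL_VARIANT) for iid in pedigree.member_ids
        }
        assigned = assign_phenotypes(pedigree, calls, config.penetrance, pheno_rng)
        n_affected = len(assigned.affected_members())
        affected_carriers = [
            ind
            for ind in assigned.affected_members()
            if calls[ind.individual_id].is_carrier
        ]
        if n_affected < config.min_affected:
            continue
        if causal and len(affected_carriers) < 2:
            continue
        # Exome-sequenced members: affected carriers in causal families
        # (the screen's shared-variant selection, validated post hoc in the
        # study), all affected members otherwise.
        selected = (
            {i.individual_id for i in affected_carriers}
            if causal
            else {i.individual_id for i in assigned.affected_members()}
        )
        for ind in assigned.members:
            ind.sequenced = ind.individual_id in selected
        return assigned, calls
    raise FamvarError(
        f"family {pedigree.family_id}: ascertainment not met in "
        f"{_MAX_ASCERTAINMENT_ATTEMPTS} attempts; relax min_affected or penetrance"
    )


def _background_variant_key(i: int) -> VariantKey:
    chrom = str(1 + (i % 22))
    return VariantKey(chrom, 1_000_000 + 1_000 * i, "A", "G")


def simulate_family_dataset(
    config: FamilySimConfig,
) -> tuple[
    list[tuple[Pedigree, GenotypeMatrix]],
    dict[VariantKey, AnnotatedVariant],
    dict,
]:
    """Generate the full family-mode dataset plus its ground truth.

    The causal missense variant is planted in the first ``n_causal_families``
    families through a het founder; background variants are drawn per family
    from their population frequency.  The truth record names the causal
    gene/variant, the causal families, and the per-family carrier sets.
    """
    causal_indices = set(range(config.n_causal_families))
    lo, hi = config.background_af_range
    af_rng = _rng(config.seed, _S_BACKGROUND, 0)
    background_afs = np.exp(
        af_rng.uniform(np.log(lo), np.log(hi), size=config.background_variants)
    )
    consequences = list(config.consequence_mix)
    probs = np.array([config.consequence_mix[c] for c in consequences])
    csq_draws = af_rng.choice(len(consequences), size=config.background_variants, p=probs)

    annotations: dict[VariantKey, AnnotatedVariant] = {
        _CAUSAL_VARIANT: AnnotatedVariant(
            key=_CAUSAL_VARIANT,
            gene=config.causal_gene,
            consequence=Consequence.MISSENSE,
            freq_by_source={"exac": config.causal_allele_frequency},
        )
    }
    for i in range(config.background_variants):
        key = _background_variant_key(i)
        annotations[key] = AnnotatedVariant(
            key=key,
            gene=f"GENE{i:04d}",
            consequence=consequences[csq_draws[i]],
            freq_by_source={"exac": float(background_afs[i])},
        )

    families: list[tuple[Pedigree, GenotypeMatrix]] = []
    truth: dict = {
        "causal_gene": config.causal_gene,
        "causal_variant": str(_CAUSAL_VARIANT),
        "causal_families": [],
        "carriers": {},
        "n_affected": {},
    }
    variant_order = [_CAUSAL_VARIANT] + [
        _background_variant_key(i) for i in range(config.background_variants)
    ]
    for idx in range(config.n_families):
        structure = simulate_pedigree(config, idx)
        causal = idx in causal_indices
        pedigree, causal_calls = _ascertain_family(config, structure, idx, causal)
        matrix = GenotypeMatrix(pedigree.member_ids, variant_order)
        for iid, call in causal_calls.items():
            matrix.set(iid, _CAUSAL_VARIANT, call)
        bg_rng = _rng(config.seed, _S_BACKGROUND, idx + 1)
        founders = pedigree.founders()
        for i in range(config.background_variants):
            key = variant_order[i + 1]
            af = background_afs[i]
            founder_genotypes = {}
            for f in founders:
                n_alt = int(bg_rng.random() < af) + int(bg_rng.random() < af)
                founder_genotypes[f.individual_id] = (
                    Genotype.HOM_REF,
                    Genotype.HET,
                    Genotype.HOM_ALT,
                )[n_alt]
            col = gene_drop(pedigree, founder_genotypes, bg_rng, key)
            for iid in pedigree.member_ids:
                matrix.set(iid, key, col.get(iid, key))
        families.append((pedigree, matrix))
        if causal:
            truth["causal_families"].append(pedigree.family_id)
        truth["carriers"][pedigree.family_id] = sorted(
            iid for iid, call in causal_calls.items() if call.is_carrier
        )
        truth["n_affected"][pedigree.family_id] = len(pedigree.affected_members())
    return families, annotations, truth


# ---------------------------------------------------------------------------
# Cohort-mode dataset
# ---------------------------------------------------------------------------

def _case_carrier_probability(q: float, odds_ratio: float) -> float:
    """Odds transform: case carrier odds = OR × control carrier odds."""
    odds = odds_ratio * q / (1.0 - q)
    return odds / (1.0 + odds)


def simulate_casecontrol_counts(
    config: CohortSimConfig,
) -> dict[str, dict[str, GenotypeCounts]]:
    """Draw per-variant genotype counts for CD, UC, IBD and control cohorts.

    Control carriers ~ Binomial(n_control, q); case carrier probabilities
    come from the odds transform of the per-phenotype odds ratio.  Carriers
    are simulated as heterozygous only (rare-variant regime); genotypes go
    missing independently at ``missing_rate``.  The IBD cohort is the union
    of the CD and UC draws.  Returns variant label → cohort → counts.
    """
    out: dict[str, dict[str, GenotypeCounts]] = {}
    for vi, effect in enumerate(config.variants):
        rng = _rng(config.seed, _S_COHORT, vi)
        q = effect.control_carrier_frequency
        cohort_specs = [
            ("CD", config.n_cd, _case_carrier_probability(q, effect.odds_ratio_cd)),
            ("UC", config.n_uc, _case_carrier_probability(q, effect.odds_ratio_uc)),
            ("control", config.n_control, q),
        ]
        per_cohort: dict[str, GenotypeCounts] = {}
        for cohort, n, p in cohort_specs:
            carriers = rng.binomial(n, p)
            called_carriers = rng.binomial(carriers, 1.0 - config.missing_rate)
            called_noncarriers = rng.binomial(n - carriers, 1.0 - config.missing_rate)
            per_cohort[cohort] = GenotypeCounts(
                cohort=cohort,
                variant_label=effect.label,
                n_hom_ref=int(called_noncarriers),
                n_het=int(called_carriers),
                n_hom_alt=0,
            )
        per_cohort["IBD"] = GenotypeCounts(
            cohort="IBD",
            variant_label=effect.label,
            n_hom_ref=per_cohort["CD"].n_hom_ref + per_cohort["UC"].n_hom_ref,
            n_het=per_cohort["CD"].n_het + per_cohort["UC"].n_het,
            n_hom_alt=0,
        )
        out[effect.label] = per_cohort
    return out


# ---------------------------------------------------------------------------
# File emission (used by the CLI's simulate subcommand)
# ---------------------------------------------------------------------------

def write_family_dataset(
    families: Sequence[tuple[Pedigree, GenotypeMatrix]],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    truth: Mapping,
    outdir: str | Path,
) -> None:
    """Emit PED + VCF + annotation TSV + truth JSON for a family dataset."""
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_ped(
        [ped for ped, _ in families], outdir / "families.ped",
        write_sequenced_column=True,
    )
    if families:
        all_ids = [iid for ped, _ in families for iid in ped.member_ids]
        variants = families[0][1].variants
        combined = GenotypeMatrix(all_ids, variants)
        for _, matrix in families:
            for iid in matrix.individuals:
                for v in variants:
                    combined.set(iid, v, matrix.get(iid, v))
        fio.write_vcf_genotypes(combined, outdir / "genotypes.vcf")
    fio.write_annotation_table(
        annotations, outdir / "annotations.tsv", source_names=["exac"]
    )
    with open(outdir / "truth.json", "wt") as fh:
        json.dump(dict(truth), fh, indent=2, sort_keys=True)


def write_cohort_dataset(
    counts: Mapping[str, Mapping[str, GenotypeCounts]],
    outdir: str | Path,
) -> None:
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flat = [
        counts[label][cohort]
        for label in counts
        for cohort in ("CD", "UC", "IBD", "control")
    ]
    fio.write_genotype_counts(flat, outdir / "cohort_counts.tsv")
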