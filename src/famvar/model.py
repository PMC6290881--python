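"""Shared data model for pedigrees, variants and genotype matrices.

The objects here are deliberately small and explicit: a pedigree is a named
collection of individuals with parent pointers, a variant is a normalized
(chrom, pos, ref, alt) key, and genotypes live in a dense individuals ×
variants matrix with an explicit missing state.  Everything downstream
(filter cascade, segregation tables, association statistics) consumes these
containers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Sex",
    "Phenotype",
    "Consequence",
    "Genotype",
    "VariantKey",
    "AnnotatedVariant",
    "Individual",
    "Pedigree",
    "GenotypeMatrix",
    "FamvarError",
    "InputError",
    "PedigreeError",
]


class FamvarError(Exception):
    """Base class for errors raised by this package."""


class InputError(FamvarError):
    """Malformed or inconsistent user input (files, tables, configs)."""


class PedigreeError(FamvarError):
    """Structurally invalid pedigree (broken parent pointers, cycles...)."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Consequence(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_CANONICAL = "splice_canonical"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences treated as protein-altering under the dominant-model cascade.
PROTEIN_ALTERING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_CANONICAL,
    }
)


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def code(self) -> int:
        return _GT_CODE[self]

    @classmethod
    def from_code(cls, code: int) -> "Genotype":
        return _CODE_GT[int(code)]

    @property
    def is_carrier(self) -> bool:
        """Carries at least one copy of the alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


_GT_CODE = {
    Genotype.HOM_REF: 0,
    Genotype.HET: 1,
    Genotype.HOM_ALT: 2,
    Genotype.MISSING: -1,
}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}

MISSING_CODE = -1


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic variant identifier (1-based VCF coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise InputError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise InputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Uppercase alleles and trim shared padding to the minimal representation.

        Shared trailing bases are removed first, then shared leading bases
        (advancing ``pos``), always leaving at least one base per allele.
        """
        ref, alt = ref.upper(), alt.upper()
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return cls(str(chrom), int(pos), ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        parts = text.split(":")
        if len(parts) != 4:
            raise InputError(f"expected chrom:pos:ref:alt, got {text!r}")
        return cls.normalized(parts[0], int(parts[1]), parts[2], parts[3])


@dataclass
class AnnotatedVariant:
    """A variant plus the annotation the cascade filters on.

    ``freq_by_source`` maps a population panel name (e.g. ``exac``,
    ``inhouse``) to an allele frequency; a source absent from the map means
    the variant was not observed in that panel.  ``scores`` (e.g. CADD) are
    pass-through only and never filtered on.
    """

    key: VariantKey
    gene: str
    consequence: Consequence
    freq_by_source: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for source, freq in self.freq_by_source.items():
            if not (0.0 <= freq <= 1.0):
                raise InputError(
                    f"frequency for {self.key} in source {source!r} outside [0,1]: {freq}"
                )

    def is_novel(self) -> bool:
        """Absent from every configured frequency source."""
        return not self.freq_by_source


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN
    diagnosis: str | None = None
    sequenced: bool = False
    #: None = infer married-in status structurally from the pedigree.
    married_in: bool | None = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def affected(self) -> bool:
        return self.phenotype is Phenotype.AFFECTED


@dataclass
class Pedigree:
    """One family: an ordered collection of individuals with parent pointers."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        if not self.members:
            raise PedigreeError(f"family {self.family_id}: no members")
        seen: set[str] = set()
        for ind in self.members:
            if ind.individual_id in seen:
                raise PedigreeError(
                    f"family {self.family_id}: duplicate member id {ind.individual_id!r}"
                )
            seen.add(ind.individual_id)
        for ind in self.members:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {parent!r} of "
                        f"{ind.individual_id!r} not present in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        index = self.by_id()
        state: dict[str, int] = {}  # 0 = visiting, 1 = done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(
                    f"family {self.family_id}: ancestry cycle through {iid!r}"
                )
            state[iid] = 0
            ind = index[iid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for ind in self.members:
            visit(ind.individual_id, [])

    def by_id(self) -> dict[str, Individual]:
        return {ind.individual_id: ind for ind in self.members}

    @property
    def member_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.members]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.members if ind.is_founder]

    def affected_members(self) -> list[Individual]:
        return [ind for ind in self.members if ind.affected]

    def sequenced_affected(self) -> list[Individual]:
        return [ind for ind in self.members if ind.affected and ind.sequenced]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            ind
            for ind in self.members
            if individual_id in (ind.father_id, ind.mother_id)
        ]

    def is_married_in(self, individual_id: str) -> bool:
        """Whether an individual joined the family by marriage only.

        Structural rule: a founder (no parents in the pedigree) whose every
        co-parent is a bloodline member (i.e. a non-founder) is married-in;
        founding couples, where both partners are founders, are bloodline.
        The per-individual ``married_in`` attribute overrides the inference.
        """
        index = self.by_id()
        ind = index[individual_id]
        if ind.married_in is not None:
            return ind.married_in
        if not ind.is_founder:
            return False
        coparents: set[str] = set()
        for child in self.children_of(individual_id):
            for parent in (child.father_id, child.mother_id):
                if parent is not None and parent != individual_id:
                    coparents.add(parent)
        if not coparents:
            return False
        return all(not index[p].is_founder for p in coparents)


class GenotypeMatrix:
    """Dense individuals × variants genotype call matrix.

    Every (individual, variant) cell holds exactly one :class:`Genotype`;
    missing calls are explicit.  Internally stored as an int8 array
    (0 = hom_ref, 1 = het, 2 = hom_alt, -1 = missing).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        variants: Sequence[VariantKey],
        codes: np.ndarray | None = None,
    ) -> None:
        self.individuals = list(individuals)
        self.variants = list(variants)
        if len(set(self.individuals)) != len(self.individuals):
            raise InputError("duplicate individual ids in genotype matrix")
        if len(set(self.variants)) != len(self.variants):
            raise InputError("duplicate variant keys in genotype matrix")
        if codes is None:
            codes = np.full((len(self.individuals), len(self.variants)), MISSING_CODE, dtype=np.int8)
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.individuals), len(self.variants)):
            raise InputError(
                f"genotype code array shape {codes.shape} does not match "
                f"{len(self.individuals)} individuals × {len(self.variants)} variants"
            )
        self.codes = codes
        self._ind_idx = {iid: i for i, iid in enumerate(self.individuals)}
        self._var_idx = {v: i for i, v in enumerate(self.variants)}

    @classmethod
    def from_calls(
        cls,
        calls: Mapping[tuple[str, VariantKey], Genotype],
        individuals: Sequence[str],
        variants: Sequence[VariantKey],
    ) -> "GenotypeMatrix":
        m = cls(individuals, variants)
        for (iid, var), gt in calls.items():
            m.set(iid, var, gt)
        return m

    def __contains__(self, variant: VariantKey) -> bool:
        return variant in self._var_idx

    def has_individual(self, individual_id: str) -> bool:
        return individual_id in self._ind_idx

    def get(self, individual_id: str, variant: VariantKey) -> Genotype:
        return Genotype.from_code(
            self.codes[self._ind_idx[individual_id], self._var_idx[variant]]
        )

    def set(self, individual_id: str, variant: VariantKey, genotype: Genotype) -> None:
        self.codes[self._ind_idx[individual_id], self._var_idx[variant]] = genotype.code

    def variant_column(self, variant: VariantKey) -> np.ndarray:
        return self.codes[:, self._var_idx[variant]]

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(ids)
        rows = [self._ind_idx[i] for i in ids]
        return GenotypeMatrix(ids, self.variants, self.codes[rows, :].copy())

    def call_rate(self, variant: VariantKey) -> float:
        col = self.variant_column(variant)
        if col.size == 0:
            return float("nan")
        return float(np.mean(col != MISSING_CODE))

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({len(self.individuals)} individuals × "
            f"{len(self.variants)} variants)"
        )


def _copy_with(ind: Individual, **kwargs) -> Individual:
    """Dataclass-replace helper kept here so callers avoid importing dataclasses."""
    return replace(ind, **kwargs)
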