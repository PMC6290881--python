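"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: 6-column whitespace-delimited PED (optional 7th column as
a sequenced flag), VCF 4.x with GT genotypes (via cyvcf2), tab-separated
annotation tables, and per-cohort genotype-count tables.  All readers accept
gzip-compressed files.  Output is header-first TSV with deterministic column
order; odds ratios are truncated (not rounded) to two decimals and
frequencies are reported as percentages.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
import math
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    GenotypeMatrix,
    Individual,
    InputError,
    Pedigree,
    Phenotype,
    Sex,
    VariantKey,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_ped",
    "write_ped",
    "read_vcf_genotypes",
    "write_vcf_genotypes",
    "read_annotation_table",
    "write_annotation_table",
    "read_genotype_counts",
    "write_genotype_counts",
    "write_results_table",
    "truncate2",
    "percent",
]

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO_CODES = {
    "2": Phenotype.AFFECTED,
    "1": Phenotype.UNAFFECTED,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {Phenotype.AFFECTED: "2", Phenotype.UNAFFECTED: "1", Phenotype.UNKNOWN: "0"}

#: Common annotation-tool consequence terms mapped onto the closed vocabulary.
DEFAULT_CONSEQUENCE_SYNONYMS: dict[str, str] = {
    "missense_variant": "missense",
    "nonsynonymous_snv": "missense",
    "stop_gained": "nonsense",
    "stopgain": "nonsense",
    "frameshift_variant": "frameshift",
    "frameshift_insertion": "frameshift",
    "frameshift_deletion": "frameshift",
    "splice_acceptor_variant": "splice_canonical",
    "splice_donor_variant": "splice_canonical",
    "splicing": "splice_canonical",
    "synonymous_variant": "synonymous",
    "synonymous_snv": "synonymous",
}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(
    path: str | Path,
    sequenced_ids: Iterable[str] | None = None,
    use_seventh_column: bool = True,
) -> list[Pedigree]:
    """Read a whitespace-delimited 6-column PED file into pedigrees.

    Phenotype codes: 2 = affected, 1 = unaffected, 0/-9 = unknown; parent
    code 0 = no parent recorded.  A 7th column of 0/1 flags, when present and
    ``use_seventh_column`` is true, marks which members were whole-exome
    sequenced; a ``sequenced_ids`` sidecar collection overrides it.  With
    neither, every affected member is treated as sequenced.
    """
    sequenced_set = set(sequenced_ids) if sequenced_ids is not None else None
    families: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    any_flag_column = False
    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise InputError(
                    f"{path}:{lineno}: expected at least 6 PED columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex_code, pheno_code = fields[:6]
            if (fam, iid) in seen:
                raise InputError(f"{path}:{lineno}: duplicate individual ({fam}, {iid})")
            seen.add((fam, iid))
            if sex_code not in _SEX_CODES:
                raise InputError(f"{path}:{lineno}: malformed sex code {sex_code!r}")
            if pheno_code not in _PHENO_CODES:
                raise InputError(
                    f"{path}:{lineno}: malformed phenotype code {pheno_code!r}"
                )
            sequenced = False
            if len(fields) >= 7 and use_seventh_column:
                flag = fields[6]
                if flag not in ("0", "1"):
                    raise InputError(
                        f"{path}:{lineno}: sequenced flag must be 0 or 1, got {flag!r}"
                    )
                sequenced = flag == "1"
                any_flag_column = True
            families.setdefault(fam, []).append(
                Individual(
                    individual_id=iid,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex_code],
                    phenotype=_PHENO_CODES[pheno_code],
                    sequenced=sequenced,
                )
            )
    pedigrees = []
    for fam, members in families.items():
        if sequenced_set is not None:
            for ind in members:
                ind.sequenced = ind.individual_id in sequenced_set
        elif not any_flag_column:
            # No explicit flag source: the cascade treats every affected
            # member as whole-exome sequenced.
            for ind in members:
                ind.sequenced = ind.phenotype is Phenotype.AFFECTED
        pedigrees.append(Pedigree(family_id=fam, members=members))
    if not pedigrees:
        raise InputError(f"{path}: no PED records found")
    return pedigrees


def write_ped(
    pedigrees: Iterable[Pedigree],
    path: str | Path,
    write_sequenced_column: bool = False,
) -> None:
    with open(path, "wt") as out:
        for ped in pedigrees:
            for ind in ped.members:
                fields = [
                    ped.family_id,
                    ind.individual_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_OUT[ind.sex],
                    _PHENO_OUT[ind.phenotype],
                ]
                if write_sequenced_column:
                    fields.append("1" if ind.sequenced else "0")
                out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
) -> tuple[list[VariantKey], GenotypeMatrix]:
    """Read GT calls from a VCF into a dense genotype matrix.

    Multiallelic records are split into one variant per alternate allele;
    a genotype containing the target allele index plus any other allele is
    recoded as heterozygous for the target.  Phase separators are ignored.
    """
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise InputError(f"samples not in VCF header: {', '.join(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    for record in vcf:
        if "GT" not in (record.FORMAT or []):
            raise InputError(
                f"record {record.CHROM}:{record.POS} has no GT in FORMAT"
            )
        gts = record.genotypes  # per sample: [allele0, allele1, ..., phased]
        for alt_index, alt in enumerate(record.ALT, start=1):
            key = VariantKey.normalized(record.CHROM, record.POS, record.REF, alt)
            if key in seen:
                raise InputError(f"duplicate variant {key} in {path}")
            seen.add(key)
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    col[i] = Genotype.MISSING.code
                else:
                    n_target = sum(1 for a in alleles if a == alt_index)
                    if n_target == 0:
                        col[i] = Genotype.HOM_REF.code
                    elif n_target == len(alleles):
                        col[i] = Genotype.HOM_ALT.code
                    else:
                        col[i] = Genotype.HET.code
            keys.append(key)
            columns.append(col)
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return keys, GenotypeMatrix(samples, keys, codes)


_GT_VCF = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF 4.2 file (GT only, biallelic rows)."""
    with open(path, "wt") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in matrix.variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for chrom in chroms:
            out.write(f"##contig=<ID={chrom}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        order = sorted(range(len(matrix.variants)), key=lambda i: matrix.variants[i])
        for i in order:
            v = matrix.variants[i]
            gts = "\t".join(
                _GT_VCF[Genotype.from_code(c)] for c in matrix.codes[:, i]
            )
            out.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def read_annotation_table(
    path: str | Path,
    source_names: Sequence[str],
    consequence_synonyms: Mapping[str, str] | None = None,
) -> dict[VariantKey, AnnotatedVariant]:
    """Read a TSV of per-variant annotations into an AnnotatedVariant map.

    Mandatory columns: chrom, pos, ref, alt, gene, consequence, plus one
    frequency column per entry of ``source_names`` (empty cell = variant not
    observed in that panel).  Optional columns: ``rsid`` and
    ``protein_change`` become labels; any column prefixed ``score_`` is kept
    as a pass-through score.  Consequence strings outside the closed
    vocabulary map to "other" with a warning; a synonym map (defaults cover
    common VEP/ANNOVAR terms) is applied first.
    """
    synonyms = dict(DEFAULT_CONSEQUENCE_SYNONYMS)
    if consequence_synonyms:
        synonyms.update(consequence_synonyms)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    mandatory = ["chrom", "pos", "ref", "alt", "gene", "consequence"]
    for col in mandatory + list(source_names):
        if col not in df.columns:
            raise InputError(f"{path}: missing mandatory column {col!r}")
    known = {c.value for c in Consequence}
    score_cols = [c for c in df.columns if c.startswith("score_")]
    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        key = VariantKey.normalized(
            rowd["chrom"], int(rowd["pos"]), rowd["ref"], rowd["alt"]
        )
        raw_csq = str(rowd["consequence"]).strip().lower()
        raw_csq = synonyms.get(raw_csq, raw_csq)
        if raw_csq in known:
            csq = Consequence(raw_csq)
        else:
            logger.warning(
                "unknown consequence %r for %s; mapped to 'other'", raw_csq, key
            )
            csq = Consequence.OTHER
        freqs: dict[str, float] = {}
        for source in source_names:
            value = rowd[source]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            freq = float(value)
            if not (0.0 <= freq <= 1.0):
                raise InputError(
                    f"{path}: frequency {freq} for {key} in {source!r} outside [0,1]"
                )
            freqs[source] = freq
        labels = {}
        for label_col in ("rsid", "protein_change"):
            if label_col in rowd and isinstance(rowd[label_col], str):
                labels[label_col] = rowd[label_col]
        scores = {
            c.removeprefix("score_"): float(rowd[c])
            for c in score_cols
            if not (isinstance(rowd[c], float) and math.isnan(rowd[c]))
        }
        out[key] = AnnotatedVariant(
            key=key,
            gene=str(rowd["gene"]),
            consequence=csq,
            freq_by_source=freqs,
            labels=labels,
            scores=scores,
        )
    return out


def write_annotation_table(
    annotations: Mapping[VariantKey, AnnotatedVariant],
    path: str | Path,
    source_names: Sequence[str],
) -> None:
    header = ["chrom", "pos", "ref", "alt", "gene", "consequence", *source_names]
    with open(path, "wt") as out:
        out.write("\t".join(header) + "\n")
        for key in sorted(annotations):
            ann = annotations[key]
            cells = [
                key.chrom,
                str(key.pos),
                key.ref,
                key.alt,
                ann.gene,
                ann.consequence.value,
            ]
            for source in source_names:
                freq = ann.freq_by_source.get(source)
                cells.append("" if freq is None else repr(freq))
            out.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Genotype counts (cohort mode)
# ---------------------------------------------------------------------------

def read_genotype_counts(path: str | Path):
    """Read a genotype-count TSV (cohort, variant, n_hom_ref, n_het, n_hom_alt)."""
    from .association import GenotypeCounts

    counts = []
    with _open_text(path) as handle:
        header = handle.readline().strip().split("\t")
        expected = ["cohort", "variant", "n_hom_ref", "n_het", "n_hom_alt"]
        if header != expected:
            raise InputError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, raw in enumerate(handle, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            try:
                counts.append(
                    GenotypeCounts(
                        cohort=fields[0],
                        variant_label=fields[1],
                        n_hom_ref=int(fields[2]),
                        n_het=int(fields[3]),
                        n_hom_alt=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return counts


def write_genotype_counts(counts, path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("cohort\tvariant\tn_hom_ref\tn_het\tn_hom_alt\n")
        for c in counts:
            out.write(
                f"{c.cohort}\t{c.variant_label}\t{c.n_hom_ref}\t{c.n_het}\t{c.n_hom_alt}\n"
            )


# ---------------------------------------------------------------------------
# Results tables and number formatting
# ---------------------------------------------------------------------------

def truncate2(x: float) -> str:
    """Truncate (never round) to two decimals, e.g. 4.7991 → "4.79"."""
    sign = "-" if x < 0 else ""
    cents = int(abs(x) * 100 + 1e-9)
    return f"{sign}{cents // 100}.{cents % 100:02d}"


def percent(x: float, decimals: int = 3) -> str:
    """Format a fraction as a rounded percentage, e.g. 0.00035 → "0.035%"."""
    return f"{x * 100:.{decimals}f}%"


_OR_FIELDS = {"odds_ratio", "or", "ci_low", "ci_high"}


def _format_cell(name: str, value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        lname = name.lower()
        if lname in _OR_FIELDS:
            return truncate2(value)
        if "maf" in lname or "freq" in lname:
            return percent(value)
        if lname.startswith("p"):
            return f"{value:.4g}"
        return f"{value:.6g}"
    if dataclasses.is_dataclass(value) or isinstance(value, (VariantKey,)):
        return str(value)
    if isinstance(value, Genotype):
        return value.value
    return str(value)


def write_results_table(rows: Sequence[Any], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or mappings) as a TSV.

    Column order is the field order of the first record (or ``columns``);
    an empty collection yields a header-only file when ``columns`` is given,
    otherwise an empty file with a zero-column header line.
    """
    records: list[dict[str, Any]] = []
    for row in rows:
        if dataclasses.is_dataclass(row) and not isinstance(row, type):
            # shallow, so nested values (e.g. VariantKey) format via str()
            records.append(
                {f.name: getattr(row, f.name) for f in dataclasses.fields(row)}
            )
        elif isinstance(row, Mapping):
            records.append(dict(row))
        else:
            raise InputError(f"unsupported record type {type(row).__name__}")
    if columns is None:
        columns = list(records[0].keys()) if records else []
    with open(path, "wt") as out:
        out.write("\t".join(columns) + "\n")
        for rec in records:
            out.write("\t".join(_format_cell(c, rec.get(c)) for c in columns) + "\n")
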