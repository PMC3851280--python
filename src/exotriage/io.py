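"""Readers and writers for the variant-table dialect and supporting tables.

The canonical on-disk form is a UTF-8, tab-separated table with one row per
called variant per sample. Absent allele frequencies are written ``NA`` and
parsed back to ``None``; they are never silently coerced to 0. An optional
VCF 4.x dialect maps INFO keys onto the same model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .model import (
    DATABASES,
    PREDICTORS,
    PHENOTYPE_TRAITS,
    AnnotatedVariant,
    Consequence,
    GeneKnowledgeEntry,
    GeneKnowledgeTable,
    GeneTier,
    PhenotypeCode,
    PhenotypeRecord,
    PhenotypeTable,
    PredictorCall,
    SchemaError,
    Zygosity,
)

#: Missing-value token used in the TSV dialect for optional fields.
NA = "NA"

#: Documented column order of the canonical variant-table dialect.
VARIANT_COLUMNS = (
    "sample_id",
    "chrom",
    "start",
    "end",
    "gene",
    "consequence",
    "nucleotide_desc",
    "protein_change",
    "zygosity",
    "reads_pct",
    "depth",
    "af_dbsnp",
    "af_evs",
    "af_tgp",
    "af_inhouse",
    "dbsnp_id",
    "provean",
    "sift",
    "mutation_assessor",
    "condel",
    "polyphen2",
    "known_neutral",
    "splice_distance",
)

_AF_COLUMNS = {
    "af_dbsnp": "dbSNP137",
    "af_evs": "EVS6500",
    "af_tgp": "TGP",
    "af_inhouse": "in_house_128",
}

_PREDICTOR_COLUMNS = {
    "provean": "PROVEAN",
    "sift": "SIFT",
    "mutation_assessor": "MutationAssessor",
    "condel": "Condel",
    "polyphen2": "PolyPhen2",
}


class RowParseError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}")


def _parse_float(token: str, line: int, column: str) -> Optional[float]:
    if token == NA or token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise RowParseError(line, f"unparseable number {token!r} in column {column}") from None


def _parse_consequence(token: str, line: int) -> Consequence:
    try:
        return Consequence(token)
    except ValueError:
        accepted = ", ".join(c.value for c in Consequence)
        raise RowParseError(
            line, f"unknown consequence {token!r}; accepted values: {accepted}"
        ) from None


def _row_to_variant(row: dict[str, str], line: int) -> AnnotatedVariant:
    consequence = _parse_consequence(row["consequence"], line)
    try:
        zygosity = Zygosity(row["zygosity"].lower())
    except ValueError:
        raise RowParseError(line, f"unknown zygosity {row['zygosity']!r}") from None

    af_by_db: dict[str, float] = {}
    for column, db in _AF_COLUMNS.items():
        af = _parse_float(row[column], line, column)
        if af is not None:
            af_by_db[db] = af

    predictor_calls: dict[str, PredictorCall] = {}
    for column, predictor in _PREDICTOR_COLUMNS.items():
        token = row[column]
        if token in ("", NA):
            token = "unknown"
        try:
            predictor_calls[predictor] = PredictorCall(token.lower())
        except ValueError:
            raise RowParseError(line, f"unknown predictor call {token!r} in {column}") from None

    known_neutral_token = row["known_neutral"].strip().lower()
    if known_neutral_token not in ("true", "false"):
        raise RowParseError(line, f"known_neutral must be true/false, got {row['known_neutral']!r}")

    splice_token = row.get("splice_distance", NA)
    splice_distance = None
    if splice_token not in ("", NA):
        try:
            splice_distance = int(splice_token)
        except ValueError:
            raise RowParseError(line, f"unparseable splice_distance {splice_token!r}") from None

    reads_pct = _parse_float(row["reads_pct"], line, "reads_pct")
    if reads_pct is None:
        raise RowParseError(line, "reads_pct is mandatory")
    try:
        depth = int(row["depth"])
    except ValueError:
        raise RowParseError(line, f"unparseable depth {row['depth']!r}") from None

    try:
        return AnnotatedVariant(
            sample_id=row["sample_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            gene=row["gene"],
            consequence=consequence,
            ref_alt_description=row["nucleotide_desc"],
            protein_change=row["protein_change"],
            zygosity=zygosity,
            read_support_fraction=reads_pct,
            total_depth=depth,
            af_by_db=af_by_db,
            dbsnp_id=row["dbsnp_id"] if row["dbsnp_id"] not in ("", NA) else None,
            predictor_calls=predictor_calls,
            known_neutral=known_neutral_token == "true",
            splice_distance_bases=splice_distance,
        )
    except ValueError as exc:
        raise RowParseError(line, str(exc)) from None


def parse_variant_table(path, dialect: str = "tsv") -> list[AnnotatedVariant]:
    """Read an annotated variant table in the ``tsv`` or ``vcf`` dialect."""
    if dialect == "tsv":
        return _parse_variant_tsv(path)
    if dialect == "vcf":
        return _parse_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _parse_variant_tsv(path) -> list[AnnotatedVariant]:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected a header row") from None
        missing = [c for c in VARIANT_COLUMNS if c not in header]
        # splice_distance is the one optional schema column
        missing = [c for c in missing if c != "splice_distance"]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        variants = []
        for line_no, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) != len(header):
                raise RowParseError(
                    line_no, f"expected {len(header)} fields, found {len(fields)}"
                )
            variants.append(_row_to_variant(dict(zip(header, fields)), line_no))
    return variants


def write_variant_table(variants: Iterable[AnnotatedVariant], path) -> None:
    """Write variants in the canonical TSV dialect (lossless round-trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            row = {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "start": str(v.start),
                "end": str(v.end),
                "gene": v.gene,
                "consequence": v.consequence.value,
                "nucleotide_desc": v.ref_alt_description,
                "protein_change": v.protein_change,
                "zygosity": v.zygosity.value,
                "reads_pct": repr(v.read_support_fraction),
                "depth": str(v.total_depth),
                "dbsnp_id": v.dbsnp_id if v.dbsnp_id is not None else NA,
                "known_neutral": "true" if v.known_neutral else "false",
                "splice_distance": NA
                if v.splice_distance_bases is None
                else str(v.splice_distance_bases),
            }
            for column, db in _AF_COLUMNS.items():
                af = v.frequency(db)
                row[column] = NA if af is None else repr(af)
            for column, predictor in _PREDICTOR_COLUMNS.items():
                row[column] = v.predictor_call(predictor).value
            writer.writerow([row[c] for c in VARIANT_COLUMNS])


# --- VCF dialect -----------------------------------------------------------

_VCF_INFO_KEYS = {
    "GENE": "gene",
    "CONSEQUENCE": "consequence",
    "READS_PCT": "reads_pct",
}


def _parse_variant_vcf(path) -> list[AnnotatedVariant]:
    """Thin adapter from a VCF 4.x file carrying annotations in INFO keys.

    One AnnotatedVariant is produced per ALT allele; INFO fields declared with
    Number=A are indexed per allele, scalar fields apply to every allele. The
    sample id is the single sample name of the VCF; zygosity derives from GT.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    required = {"GENE", "CONSEQUENCE", "READS_PCT", "DEPTH"}
    declared = set(vcf.header.info.keys())
    missing = required - declared
    if missing:
        raise SchemaError(f"{path}: VCF header missing INFO key(s): {', '.join(sorted(missing))}")
    if len(vcf.header.samples) != 1:
        raise SchemaError(f"{path}: VCF dialect requires exactly one sample column")
    sample_id = vcf.header.samples[0]

    def per_alt(record, key, alt_index, default=None):
        if key not in record.info:
            return default
        value = record.info[key]
        if isinstance(value, tuple):
            number = vcf.header.info[key].number
            if number == "A":
                return value[alt_index]
            return value[0]
        return value

    variants = []
    for record in vcf:
        alts = record.alts or ()
        gt = record.samples[sample_id].get("GT", (None,))
        for alt_index, alt in enumerate(alts):
            called = [a for a in gt if a is not None]
            alt_allele_no = alt_index + 1
            if len(called) <= 1:
                zygosity = Zygosity.HEMIZYGOUS
            elif all(a == alt_allele_no for a in called):
                zygosity = Zygosity.HOMOZYGOUS
            else:
                zygosity = Zygosity.HETEROZYGOUS
            af_by_db = {}
            for key, db in (
                ("AF_DBSNP", "dbSNP137"),
                ("AF_EVS", "EVS6500"),
                ("AF_TGP", "TGP"),
                ("AF_INHOUSE", "in_house_128"),
            ):
                af = per_alt(record, key, alt_index)
                if af is not None:
                    af_by_db[db] = float(af)
            predictor_calls = {}
            for key, predictor in (
                ("PROVEAN", "PROVEAN"),
                ("SIFT", "SIFT"),
                ("MUTATION_ASSESSOR", "MutationAssessor"),
                ("CONDEL", "Condel"),
                ("POLYPHEN2", "PolyPhen2"),
            ):
                call = per_alt(record, key, alt_index)
                if call is not None:
                    predictor_calls[predictor] = PredictorCall(str(call).lower())
            nuc = per_alt(record, "NUC_DESC", alt_index)
            splice = per_alt(record, "SPLICE_DISTANCE", alt_index)
            variants.append(
                AnnotatedVariant(
                    sample_id=sample_id,
                    chrom=record.chrom,
                    start=record.pos,
                    end=record.pos + len(record.ref) - 1,
                    gene=str(per_alt(record, "GENE", alt_index)),
                    consequence=Consequence(str(per_alt(record, "CONSEQUENCE", alt_index))),
                    ref_alt_description=str(nuc)
                    if nuc is not None
                    else f"g.{record.pos}{record.ref}>{alt}",
                    protein_change=str(per_alt(record, "PROTEIN_CHANGE", alt_index, "")),
                    zygosity=zygosity,
                    read_support_fraction=float(per_alt(record, "READS_PCT", alt_index)),
                    total_depth=int(per_alt(record, "DEPTH", alt_index)),
                    af_by_db=af_by_db,
                    dbsnp_id=record.id,
                    predictor_calls=predictor_calls,
                    known_neutral=bool(per_alt(record, "KNOWN_NEUTRAL", alt_index, False)),
                    splice_distance_bases=None if splice is None else int(splice),
                )
            )
    return variants


# --- gene knowledge --------------------------------------------------------


def parse_gene_knowledge(path) -> GeneKnowledgeTable:
    """Read a gene-knowledge table from YAML (list of mappings) or TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with path.open("r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if raw is None:
            raw = []
        if not isinstance(raw, list):
            raise SchemaError(f"{path}: expected a YAML list of gene entries")
        entries = [_knowledge_entry_from_mapping(item, path) for item in raw]
    else:
        entries = []
        with path.open("r", encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None or "gene" not in reader.fieldnames:
                raise SchemaError(f"{path}: expected TSV with a 'gene' column")
            for row in reader:
                prior = row.get("prior_variants") or ""
                entries.append(
                    _knowledge_entry_from_mapping(
                        {
                            "gene": row["gene"],
                            "tier": row.get("tier", "TIER_NONE"),
                            "phenotype_note": row.get("phenotype_note", ""),
                            "prior_variants": [p for p in prior.split(",") if p],
                        },
                        path,
                    )
                )
    return GeneKnowledgeTable(entries)


def _knowledge_entry_from_mapping(item, path) -> GeneKnowledgeEntry:
    try:
        tier = GeneTier(item.get("tier", "TIER_NONE"))
    except ValueError:
        accepted = ", ".join(t.value for t in GeneTier)
        raise SchemaError(
            f"{path}: unknown tier {item.get('tier')!r} for gene {item.get('gene')!r};"
            f" accepted: {accepted}"
        ) from None
    return GeneKnowledgeEntry(
        gene=str(item["gene"]),
        tier=tier,
        phenotype_note=str(item.get("phenotype_note", "") or ""),
        prior_variant_evidence=frozenset(item.get("prior_variants") or ()),
    )


# --- phenotype table -------------------------------------------------------

_PHENOTYPE_CODE_TOKENS = {
    "+": PhenotypeCode.POSITIVE,
    "": PhenotypeCode.NEGATIVE,  # a blank cell encodes a negative finding
    "ND": PhenotypeCode.ND,
}


def parse_phenotype_table(path) -> PhenotypeTable:
    """Read the participant phenotype grid (+ / blank / ND cell codes)."""
    path = Path(path)
    expected = ("participant", "gender", "age_group", "years_of_treatment") + PHENOTYPE_TRAITS
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != expected:
            raise SchemaError(f"{path}: header must be exactly {expected}")
        records = []
        for line_no, fields in enumerate(reader, start=2):
            if not fields:
                continue
            fields += [""] * (len(expected) - len(fields))  # trailing blanks
            row = dict(zip(expected, fields))
            codes = {}
            for trait in PHENOTYPE_TRAITS:
                token = row[trait].strip()
                if token not in _PHENOTYPE_CODE_TOKENS:
                    raise RowParseError(line_no, f"unknown phenotype code {token!r} in {trait}")
                codes[trait] = _PHENOTYPE_CODE_TOKENS[token]
            records.append(
                PhenotypeRecord(
                    participant=row["participant"],
                    gender=row["gender"],
                    age_group=row["age_group"],
                    years_of_treatment=row["years_of_treatment"],
                    codes=codes,
                )
            )
    return PhenotypeTable(records=records)


# --- packaged fixtures -----------------------------------------------------


@dataclass(slots=True)
class CohortFixture:
    """The packaged 10-participant cohort with its expected report categories."""

    variants: list[AnnotatedVariant]
    no_finding_participants: frozenset[str]
    expected_categories: dict[tuple[str, str, str], str]
    cohort_size: int = 10

    @property
    def participants(self) -> list[str]:
        """All cohort participant ids, including those without records."""
        return [str(i) for i in range(1, self.cohort_size + 1)]

    def by_participant(self) -> dict[str, list[AnnotatedVariant]]:
        """Variants grouped per participant; no-finding participants map to []."""
        grouped: dict[str, list[AnnotatedVariant]] = {p: [] for p in self.participants}
        for v in self.variants:
            grouped[v.sample_id].append(v)
        return grouped


#: Printed report category for each fixture record, keyed by
#: (participant, gene, nucleotide description).
_EXPECTED_CATEGORIES = {
    ("1", "ATP13A4", "g.1938A>T"): "VUS",
    ("1", "KIAA0319", "c.931G>A"): "VUS",
    ("2", "ATP13A4", "g.1938A>T"): "VUS",
    ("4", "CNTNAP2", "c.3714-7insTTG"): "VUS",
    ("4", "ATP13A4", "g.1938A>T"): "VUS",
    ("6", "CNTNAP2", "c.511C>T"): "LIKELY_PATHOGENIC",
    ("7", "CNTNAP1", "c.3191G>A"): "VUS_IN_GUS",
    ("8", "FOXP1", "c.320T>C"): "LIKELY_PATHOGENIC",
    ("9", "KIAA0319", "c.931G>A"): "VUS",
    ("9", "SETX", "g.2975A>G"): "VUS_IN_GUS",
    ("10", "CNTNAP2", "c.3714-7insTTG"): "VUS",
    ("10", "KIAA0319", "c.931G>A"): "VUS",
}


def _data_path(name: str):
    return resources.files("exotriage").joinpath("data", name)


def load_cohort_fixture() -> CohortFixture:
    """The packaged 10-record cohort of most highly prioritized variants."""
    with resources.as_file(_data_path("cohort_variants.tsv")) as path:
        variants = parse_variant_table(path, dialect="tsv")
    return CohortFixture(
        variants=variants,
        no_finding_participants=frozenset({"3", "5"}),
        expected_categories=dict(_EXPECTED_CATEGORIES),
    )


def default_gene_knowledge() -> GeneKnowledgeTable:
    """The packaged gene-knowledge table used for default triage runs."""
    with resources.as_file(_data_path("gene_knowledge.yaml")) as path:
        return parse_gene_knowledge(path)


def load_phenotype_fixture() -> PhenotypeTable:
    """The packaged 10-participant phenotype grid."""
    with resources.as_file(_data_path("phenotype_table.tsv")) as path:
        return parse_phenotype_table(path)
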