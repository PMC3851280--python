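"""Domain model for annotated exome variants, gene knowledge and phenotypes.

Coordinates are 1-based and inclusive on both ends. Allele frequencies are
stored per source database on a 0-1 scale; a frequency that was not observed
in a database is represented by the *absence* of that database's entry (or an
explicit ``None``), never by 0. Read support is stored as a percentage on the
0-100 scale exactly as reported by upstream annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Consequence(str, enum.Enum):
    """Transcript-level consequence type of a called variant."""

    KNOWN_FUNCTIONAL = "known_functional"
    PREMATURE_STOP = "premature_stop"
    START_LOSS = "start_loss"
    CANONICAL_SPLICE = "canonical_splice"
    STOP_READTHROUGH = "stop_readthrough"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    NEAR_SPLICE = "near_splice"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    NONSYNONYMOUS = "nonsynonymous"
    OTHER = "other"


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"


class PredictorCall(str, enum.Enum):
    DAMAGING = "damaging"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"


class GeneTier(str, enum.Enum):
    """Strength of a gene's association with the target phenotype."""

    TIER_CAS = "TIER_CAS"  # causally associated with the phenotype itself
    TIER_OVERLAP = "TIER_OVERLAP"  # associated with an overlapping phenotype
    TIER_GUS = "TIER_GUS"  # gene of uncertain significance
    TIER_NONE = "TIER_NONE"  # no recorded association


#: Canonical names of the five in-silico effect predictors.
PREDICTORS = ("PROVEAN", "SIFT", "MutationAssessor", "Condel", "PolyPhen2")

#: Canonical names of the four allele-frequency source databases.
DATABASES = ("dbSNP137", "EVS6500", "TGP", "in_house_128")


class SchemaError(ValueError):
    """A table's header or structure does not match the documented schema."""


class VariantValidationError(ValueError):
    """An AnnotatedVariant violates one of its field invariants."""


@dataclass(slots=True)
class AnnotatedVariant:
    """One called variant for one sample, with all triage-relevant annotations."""

    sample_id: str
    chrom: str
    start: int
    end: int
    gene: str
    consequence: Consequence
    ref_alt_description: str
    protein_change: str = ""
    zygosity: Zygosity = Zygosity.HETEROZYGOUS
    read_support_fraction: float = 100.0
    total_depth: int = 1
    af_by_db: Mapping[str, Optional[float]] = field(default_factory=dict)
    dbsnp_id: Optional[str] = None
    predictor_calls: Mapping[str, PredictorCall] = field(default_factory=dict)
    known_neutral: bool = False
    splice_distance_bases: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.read_support_fraction <= 100.0:
            raise VariantValidationError(
                f"read_support_fraction {self.read_support_fraction} outside [0, 100]"
            )
        if self.total_depth < 1:
            raise VariantValidationError(f"total_depth {self.total_depth} < 1")
        if self.start > self.end:
            raise VariantValidationError(f"start {self.start} > end {self.end}")
        for db, af in self.af_by_db.items():
            if db not in DATABASES:
                raise VariantValidationError(f"unknown frequency database {db!r}")
            if af is not None and not 0.0 <= af <= 1.0:
                raise VariantValidationError(f"frequency {af} for {db} outside [0, 1]")
        for name, call in self.predictor_calls.items():
            if name not in PREDICTORS:
                raise VariantValidationError(f"unknown predictor {name!r}")
            if not isinstance(call, PredictorCall):
                raise VariantValidationError(f"bad predictor call {call!r} for {name}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Stable identity of a record within a cohort table."""
        return (self.sample_id, self.chrom, self.start, self.ref_alt_description)

    def frequency(self, db: str) -> Optional[float]:
        """Frequency in *db*, or ``None`` when the variant is absent there."""
        if db not in DATABASES:
            raise KeyError(f"unknown frequency database {db!r}")
        return self.af_by_db.get(db)

    def present_frequencies(self, databases=DATABASES) -> dict[str, float]:
        """The subset of queried databases in which the variant was observed."""
        out = {}
        for db in databases:
            af = self.frequency(db)
            if af is not None:
                out[db] = af
        return out

    def is_novel(self) -> bool:
        """True when absent from all four sources and carrying no dbSNP id."""
        return not self.present_frequencies() and self.dbsnp_id is None

    def predictor_call(self, name: str) -> PredictorCall:
        if name not in PREDICTORS:
            raise KeyError(f"unknown predictor {name!r}")
        return self.predictor_calls.get(name, PredictorCall.UNKNOWN)


@dataclass(slots=True)
class GeneKnowledgeEntry:
    """Curated association between one gene and the target phenotype."""

    gene: str
    tier: GeneTier
    phenotype_note: str = ""
    prior_variant_evidence: frozenset[str] = frozenset()


_NO_ENTRY_CACHE: dict[str, GeneKnowledgeEntry] = {}


class GeneKnowledgeTable:
    """Gene -> association tier lookup; unlisted genes default to TIER_NONE."""

    def __init__(self, entries=()) -> None:
        self._entries: dict[str, GeneKnowledgeEntry] = {}
        for entry in entries:
            if entry.gene in self._entries:
                raise SchemaError(f"duplicate gene {entry.gene!r} in knowledge table")
            self._entries[entry.gene] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def get(self, gene: str) -> GeneKnowledgeEntry:
        entry = self._entries.get(gene)
        if entry is None:
            entry = _NO_ENTRY_CACHE.get(gene)
            if entry is None:
                entry = GeneKnowledgeEntry(gene=gene, tier=GeneTier.TIER_NONE)
                _NO_ENTRY_CACHE[gene] = entry
        return entry

    def tier(self, gene: str) -> GeneTier:
        return self.get(gene).tier


class PhenotypeCode(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    ND = "ND"  # no data / not determined


#: Trait columns of the participant phenotype grid, in canonical order.
PHENOTYPE_TRAITS = (
    "familial",
    "cognitive",
    "onset_delay",
    "comprehension",
    "expression",
    "gross_motor",
    "oral_nonverbal",
)


@dataclass(slots=True)
class PhenotypeRecord:
    participant: str
    gender: str
    age_group: str
    years_of_treatment: str
    codes: dict[str, PhenotypeCode]

    def __post_init__(self) -> None:
        if self.age_group not in ("A", "B", "C"):
            raise SchemaError(f"age_group must be A/B/C, got {self.age_group!r}")
        for trait in PHENOTYPE_TRAITS:
            if trait not in self.codes:
                raise SchemaError(f"missing trait column {trait!r}")


@dataclass(slots=True)
class PhenotypeTable:
    records: list[PhenotypeRecord]

    def column(self, trait: str) -> list[PhenotypeCode]:
        if trait not in PHENOTYPE_TRAITS:
            raise KeyError(f"unknown trait {trait!r}")
        return [r.codes[trait] for r in self.records]

    def __len__(self) -> int:
        return len(self.records)
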