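"""Rule-based variant prioritization with full filter provenance.

Four rules gate admission of a variant into the prioritized set:

1. frequency  - deprioritize when the maximum allele frequency observed in any
   queried database strictly exceeds the threshold (default 0.3%); a variant
   absent everywhere is novel and passes. A frequency failure can be rescued
   by gene knowledge (phenotype-associated gene or prior variant evidence) or
   by a cohort-level gene-of-interest list.
2. impact     - keep only variants whose consequence type places them in one
   of three impact classes (known functional; likely deleterious truncating /
   splice / start types; possibly deleterious near-splice, in-frame indel or
   damaging-consensus nonsynonymous changes).
3. read support - deprioritize variants supported by fewer than 10% of reads.
4. neutral    - exclude variants previously confirmed to be neutral.

Zygosity is annotated and reported but never filters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .model import (
    DATABASES,
    PREDICTORS,
    AnnotatedVariant,
    Consequence,
    GeneKnowledgeTable,
    GeneTier,
    PredictorCall,
)


class ImpactClass(str, enum.Enum):
    CLASS1_KNOWN_FUNCTIONAL = "CLASS1_KNOWN_FUNCTIONAL"
    CLASS2_LIKELY_DELETERIOUS = "CLASS2_LIKELY_DELETERIOUS"
    CLASS3_POSSIBLY_DELETERIOUS = "CLASS3_POSSIBLY_DELETERIOUS"
    UNPRIORITIZED = "UNPRIORITIZED"


class Consensus(str, enum.Enum):
    DAMAGING = "damaging"
    NEUTRAL = "neutral"
    DISCORDANT = "discordant"
    UNKNOWN = "unknown"


#: Consequence types that define the likely-deleterious impact class.
CLASS2_CONSEQUENCES = frozenset(
    {
        Consequence.PREMATURE_STOP,
        Consequence.START_LOSS,
        Consequence.CANONICAL_SPLICE,
        Consequence.STOP_READTHROUGH,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
    }
)

#: Gene tiers whose variants are reviewed even when too common.
RESCUE_TIERS = frozenset({GeneTier.TIER_CAS, GeneTier.TIER_OVERLAP})


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and source lists driving the prioritization rules."""

    frequency_threshold: float = 0.003
    min_read_support_pct: float = 10.0
    near_splice_window: int = 10
    min_damaging_votes: int = 3
    databases: tuple[str, ...] = DATABASES

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency_threshold < 1.0:
            raise ValueError(f"frequency_threshold {self.frequency_threshold} outside [0, 1)")
        if not 0.0 <= self.min_read_support_pct <= 100.0:
            raise ValueError(f"min_read_support_pct {self.min_read_support_pct} outside [0, 100]")
        unknown = set(self.databases) - set(DATABASES)
        if unknown:
            raise ValueError(f"unknown database name(s): {', '.join(sorted(unknown))}")

    @classmethod
    def from_yaml(cls, path) -> "TriageConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in (
            "frequency_threshold",
            "min_read_support_pct",
            "near_splice_window",
            "min_damaging_votes",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "databases" in raw:
            kwargs["databases"] = tuple(raw["databases"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(
                {
                    "frequency_threshold": self.frequency_threshold,
                    "min_read_support_pct": self.min_read_support_pct,
                    "near_splice_window": self.near_splice_window,
                    "min_damaging_votes": self.min_damaging_votes,
                    "databases": list(self.databases),
                },
                handle,
            )


@dataclass(frozen=True)
class FrequencyCheck:
    passed: bool
    max_frequency: Optional[float] = None
    database: Optional[str] = None


def frequency_pass(
    v: AnnotatedVariant,
    threshold: float = 0.003,
    databases: Sequence[str] = DATABASES,
) -> FrequencyCheck:
    """Fail iff the maximum frequency in any queried database exceeds *threshold*.

    A variant absent from every queried database is novel and passes. Equality
    with the threshold passes (only strictly greater frequencies fail).
    """
    present = v.present_frequencies(databases)
    if not present:
        return FrequencyCheck(passed=True)
    database, max_frequency = max(present.items(), key=lambda item: item[1])
    return FrequencyCheck(
        passed=max_frequency <= threshold,
        max_frequency=max_frequency,
        database=database,
    )


def read_support_pass(v: AnnotatedVariant, min_pct: float = 10.0) -> bool:
    """True iff at least *min_pct* percent of reads support the call."""
    return v.read_support_fraction >= min_pct


def predictor_consensus(v: AnnotatedVariant, min_votes: int = 3) -> Consensus:
    """Majority call over the five effect predictors.

    Damaging (or neutral) requires at least *min_votes* concordant calls with
    no larger opposing bloc; all-unknown is unknown; anything else with at
    least one known call is discordant.
    """
    damaging = neutral = 0
    for name in PREDICTORS:
        call = v.predictor_calls.get(name, PredictorCall.UNKNOWN)
        if call is PredictorCall.DAMAGING:
            damaging += 1
        elif call is PredictorCall.NEUTRAL:
            neutral += 1
    if damaging == 0 and neutral == 0:
        return Consensus.UNKNOWN
    if damaging >= min_votes and damaging >= neutral:
        return Consensus.DAMAGING
    if neutral >= min_votes and neutral >= damaging:
        return Consensus.NEUTRAL
    return Consensus.DISCORDANT


def unanimous_damaging(v: AnnotatedVariant) -> bool:
    """True iff all five predictors call the variant damaging."""
    return all(
        v.predictor_calls.get(name, PredictorCall.UNKNOWN) is PredictorCall.DAMAGING
        for name in PREDICTORS
    )


def classify_impact(
    v: AnnotatedVariant,
    consensus: Consensus,
    near_splice_window: int = 10,
) -> ImpactClass:
    """Map a consequence (plus predictor consensus for NS changes) to a class."""
    c = v.consequence
    if c is Consequence.KNOWN_FUNCTIONAL:
        return ImpactClass.CLASS1_KNOWN_FUNCTIONAL
    if c in CLASS2_CONSEQUENCES:
        return ImpactClass.CLASS2_LIKELY_DELETERIOUS
    if c is Consequence.NEAR_SPLICE:
        if v.splice_distance_bases is None:
            raise ValueError(
                f"near_splice variant {v.ref_alt_description} lacks splice_distance_bases"
            )
        if v.splice_distance_bases <= near_splice_window:
            return ImpactClass.CLASS3_POSSIBLY_DELETERIOUS
        return ImpactClass.UNPRIORITIZED
    if c in (Consequence.INFRAME_INSERTION, Consequence.INFRAME_DELETION):
        return ImpactClass.CLASS3_POSSIBLY_DELETERIOUS
    if c is Consequence.NONSYNONYMOUS and consensus is Consensus.DAMAGING:
        return ImpactClass.CLASS3_POSSIBLY_DELETERIOUS
    return ImpactClass.UNPRIORITIZED


@dataclass(slots=True)
class FilterProvenance:
    """Outcome of every rule for one variant, plus the admission verdict."""

    frequency_pass: bool
    max_frequency: Optional[float]
    frequency_db: Optional[str]
    read_support_pass: bool
    neutral_excluded: bool
    rescued_by_gene: bool
    rescue_tier: Optional[GeneTier]
    rescued_by_prior_variant: bool
    rescued_by_cohort_gene: bool
    impact_class: ImpactClass
    consensus: Consensus
    unanimous_damaging: bool
    admitted: bool

    @property
    def rescued(self) -> bool:
        return self.rescued_by_gene or self.rescued_by_prior_variant or self.rescued_by_cohort_gene

    @property
    def failed_rules(self) -> tuple[str, ...]:
        """Names of the rules this variant failed (empty when admitted)."""
        failed = []
        if not (self.frequency_pass or self.rescued):
            failed.append("frequency")
        if not self.read_support_pass:
            failed.append("read_support")
        if self.neutral_excluded:
            failed.append("neutral")
        if self.impact_class is ImpactClass.UNPRIORITIZED:
            failed.append("impact")
        return tuple(failed)


def _evaluate_one(
    v: AnnotatedVariant,
    knowledge: GeneKnowledgeTable,
    config: TriageConfig,
    extra_rescue_genes: frozenset[str],
) -> FilterProvenance:
    freq = frequency_pass(v, config.frequency_threshold, config.databases)
    read_ok = read_support_pass(v, config.min_read_support_pct)
    consensus = predictor_consensus(v, config.min_damaging_votes)
    impact = classify_impact(v, consensus, config.near_splice_window)

    entry = knowledge.get(v.gene)
    tier_rescue = entry.tier in RESCUE_TIERS
    prior_rescue = bool(
        entry.prior_variant_evidence
        and (
            v.protein_change in entry.prior_variant_evidence
            or v.ref_alt_description in entry.prior_variant_evidence
        )
    )
    cohort_rescue = v.gene in extra_rescue_genes
    rescue_available = tier_rescue or prior_rescue or cohort_rescue

    admitted = (
        read_ok
        and not v.known_neutral
        and impact is not ImpactClass.UNPRIORITIZED
        and (freq.passed or rescue_available)
    )
    rescue_used = not freq.passed and rescue_available
    return FilterProvenance(
        frequency_pass=freq.passed,
        max_frequency=freq.max_frequency,
        frequency_db=freq.database,
        read_support_pass=read_ok,
        neutral_excluded=v.known_neutral,
        rescued_by_gene=rescue_used and tier_rescue,
        rescue_tier=entry.tier if rescue_used and tier_rescue else None,
        rescued_by_prior_variant=rescue_used and prior_rescue,
        rescued_by_cohort_gene=rescue_used and cohort_rescue and not (tier_rescue or prior_rescue),
        impact_class=impact,
        consensus=consensus,
        unanimous_damaging=unanimous_damaging(v),
        admitted=admitted,
    )


def _check_single_sample(variants: Sequence[AnnotatedVariant]) -> None:
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(sample_ids)}")


def evaluate_sample(
    variants: Sequence[AnnotatedVariant],
    knowledge: GeneKnowledgeTable,
    config: TriageConfig = TriageConfig(),
    extra_rescue_genes: frozenset[str] = frozenset(),
) -> list[tuple[AnnotatedVariant, FilterProvenance]]:
    """Apply every rule to every variant of one sample; nothing is dropped."""
    _check_single_sample(variants)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.start, v.ref_alt_description, v.gene))
    return [(v, _evaluate_one(v, knowledge, config, extra_rescue_genes)) for v in ordered]


def prioritize_sample(
    variants: Sequence[AnnotatedVariant],
    knowledge: GeneKnowledgeTable,
    config: TriageConfig = TriageConfig(),
    extra_rescue_genes: frozenset[str] = frozenset(),
) -> list[tuple[AnnotatedVariant, FilterProvenance]]:
    """The admitted subset of one sample's variants, with provenance.

    Output order is deterministic (genomic position) and independent of the
    input row order.
    """
    return [
        (v, prov)
        for v, prov in evaluate_sample(variants, knowledge, config, extra_rescue_genes)
        if prov.admitted
    ]


def prioritize_cohort(
    samples: Mapping[str, Sequence[AnnotatedVariant]],
    knowledge: GeneKnowledgeTable,
    config: TriageConfig = TriageConfig(),
    cross_sample_rescue: bool = True,
) -> dict[str, list[tuple[AnnotatedVariant, FilterProvenance]]]:
    """Per-sample prioritization with an optional cohort-level second pass.

    In the second pass, genes carrying a prioritized variant in any sample
    become genes of interest and rescue frequency failures in every sample.
    """
    first = {
        sample: prioritize_sample(variants, knowledge, config)
        for sample, variants in samples.items()
    }
    if not cross_sample_rescue:
        return first
    genes_of_interest = frozenset(
        v.gene for prioritized in first.values() for v, _ in prioritized
    )
    return {
        sample: prioritize_sample(variants, knowledge, config, genes_of_interest)
        for sample, variants in samples.items()
    }


# --- class-count summary ---------------------------------------------------

#: Row names of the class-count summary, in output order.
SUMMARY_ROWS = (
    "highly_likely_deleterious_rare",
    "rare_premature_stop",
    "rare_readthrough",
    "rare_start_codon",
    "rare_splice",
    "rare_frameshift_insertion",
    "rare_frameshift_deletion",
    "possibly_deleterious_rare",
    "damaging_polyphen_ns",
    "damaging_sift_ns",
    "inframe_insertion",
    "inframe_deletion",
    "intronic_near_splice",
    "clinically_associated_rare",
)


@dataclass(slots=True)
class ClassCountSummary:
    """Per-subcategory (gene count, variant count) pairs for one sample."""

    rows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def gene_count(self, row: str) -> int:
        return self.rows[row][0]

    def variant_count(self, row: str) -> int:
        return self.rows[row][1]


def summarize_classes(
    prioritized: Sequence[tuple[AnnotatedVariant, FilterProvenance]],
    all_variants: Sequence[AnnotatedVariant],
    knowledge: GeneKnowledgeTable,
    config: TriageConfig = TriageConfig(),
) -> ClassCountSummary:
    """Count genes and variants per impact subcategory for one sample.

    Counts are taken over variants that survive the error-exclusion rules
    (read support, known-neutral); rarity means passing the frequency rule at
    the configured threshold. The clinically-associated row additionally
    requires a non-default gene tier.
    """
    buckets: dict[str, set[str]] = {name: set() for name in SUMMARY_ROWS}
    counts: dict[str, int] = {name: 0 for name in SUMMARY_ROWS}

    def hit(row: str, v: AnnotatedVariant) -> None:
        buckets[row].add(v.gene)
        counts[row] += 1

    for v in all_variants:
        if v.known_neutral or not read_support_pass(v, config.min_read_support_pct):
            continue
        rare = frequency_pass(v, config.frequency_threshold, config.databases).passed
        if not rare:
            continue
        consensus = predictor_consensus(v, config.min_damaging_votes)
        impact = classify_impact(v, consensus, config.near_splice_window)
        c = v.consequence
        if impact is ImpactClass.CLASS2_LIKELY_DELETERIOUS:
            hit("highly_likely_deleterious_rare", v)
            if c is Consequence.PREMATURE_STOP:
                hit("rare_premature_stop", v)
            elif c is Consequence.STOP_READTHROUGH:
                hit("rare_readthrough", v)
            elif c is Consequence.START_LOSS:
                hit("rare_start_codon", v)
            elif c is Consequence.CANONICAL_SPLICE:
                hit("rare_splice", v)
            elif c is Consequence.FRAMESHIFT_INSERTION:
                hit("rare_frameshift_insertion", v)
            elif c is Consequence.FRAMESHIFT_DELETION:
                hit("rare_frameshift_deletion", v)
        elif impact is ImpactClass.CLASS3_POSSIBLY_DELETERIOUS:
            hit("possibly_deleterious_rare", v)
            if c is Consequence.NONSYNONYMOUS:
                if v.predictor_call("PolyPhen2") is PredictorCall.DAMAGING:
                    hit("damaging_polyphen_ns", v)
                if v.predictor_call("SIFT") is PredictorCall.DAMAGING:
                    hit("damaging_sift_ns", v)
            elif c is Consequence.INFRAME_INSERTION:
                hit("inframe_insertion", v)
            elif c is Consequence.INFRAME_DELETION:
                hit("inframe_deletion", v)
            elif c is Consequence.NEAR_SPLICE:
                hit("intronic_near_splice", v)
        if impact is not ImpactClass.UNPRIORITIZED and knowledge.tier(v.gene) is not GeneTier.TIER_NONE:
            hit("clinically_associated_rare", v)

    return ClassCountSummary(
        rows={name: (len(buckets[name]), counts[name]) for name in SUMMARY_ROWS}
    )
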