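"""Clinical report-category assignment and cohort-level summaries.

Category rules are reverse-engineered from per-gene clinical narratives and
kept deliberately simple:

* LIKELY_PATHOGENIC - novel (absent from every frequency source, no dbSNP id)
  nonsynonymous change with unanimous damaging predictor calls in a gene
  causally associated with the phenotype.
* VUS - a variant in a causally-associated or overlapping-phenotype gene with
  uncertain functional impact (near-splice, in-frame indel, discordant or
  unknown predictor consensus), or one admitted only through gene/prior
  variant rescue after failing the frequency rule, or a damaging change not
  meeting the likely-pathogenic bar.
* VUS_IN_GUS - damaging-consensus variant in a gene of uncertain significance.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import (
    AnnotatedVariant,
    Consequence,
    GeneKnowledgeEntry,
    GeneKnowledgeTable,
    GeneTier,
)
from .prioritize import (
    Consensus,
    FilterProvenance,
    RESCUE_TIERS,
    TriageConfig,
    prioritize_cohort,
)


class ReportCategory(str, enum.Enum):
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    VUS_IN_GUS = "VUS_IN_GUS"
    NOT_REPORTABLE = "NOT_REPORTABLE"


#: Severity order used for participant-level rollups.
_SEVERITY = {
    ReportCategory.LIKELY_PATHOGENIC: 3,
    ReportCategory.VUS: 2,
    ReportCategory.VUS_IN_GUS: 1,
    ReportCategory.NOT_REPORTABLE: 0,
}

#: Categories that count toward multi-gene ("two-hit") tallies. Findings in
#: genes of uncertain significance are reported but do not make a gene pair.
ESTABLISHED_GENE_CATEGORIES = frozenset(
    {ReportCategory.LIKELY_PATHOGENIC, ReportCategory.VUS}
)

_UNCERTAIN_CONSEQUENCES = frozenset(
    {Consequence.NEAR_SPLICE, Consequence.INFRAME_INSERTION, Consequence.INFRAME_DELETION}
)


def assign_report_category(
    v: AnnotatedVariant,
    provenance: FilterProvenance,
    entry: GeneKnowledgeEntry,
) -> ReportCategory:
    """Category for one prioritized variant; a pure function of its inputs."""
    tier = entry.tier
    damaging = provenance.consensus is Consensus.DAMAGING
    if tier is GeneTier.TIER_GUS:
        return ReportCategory.VUS_IN_GUS if damaging else ReportCategory.NOT_REPORTABLE
    if tier in RESCUE_TIERS:
        if (
            tier is GeneTier.TIER_CAS
            and v.is_novel()
            and v.consequence is Consequence.NONSYNONYMOUS
            and provenance.unanimous_damaging
        ):
            return ReportCategory.LIKELY_PATHOGENIC
        if v.consequence in _UNCERTAIN_CONSEQUENCES:
            return ReportCategory.VUS
        if provenance.consensus in (Consensus.DISCORDANT, Consensus.UNKNOWN):
            return ReportCategory.VUS
        if provenance.rescued or damaging:
            return ReportCategory.VUS
    return ReportCategory.NOT_REPORTABLE


@dataclass(slots=True)
class Finding:
    """One categorized variant for one participant."""

    variant: AnnotatedVariant
    category: ReportCategory
    provenance: FilterProvenance

    def to_dict(self) -> dict:
        v = self.variant
        return {
            "participant": v.sample_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "start": v.start,
            "end": v.end,
            "nucleotide_desc": v.ref_alt_description,
            "protein_change": v.protein_change,
            "zygosity": v.zygosity.value,
            "reads_pct": v.read_support_fraction,
            "depth": v.total_depth,
            "category": self.category.value,
            "impact_class": self.provenance.impact_class.value,
            "consensus": self.provenance.consensus.value,
            "rescued": self.provenance.rescued,
            "max_frequency": self.provenance.max_frequency,
        }


@dataclass(slots=True)
class CohortReport:
    """Per-participant findings plus the cohort-level tallies."""

    cohort_size: int
    findings: dict[str, list[Finding]]
    participants_with_reportable: int
    participants_likely_pathogenic: int
    participants_with_two_gene_findings: int
    shared_variant_groups: dict[tuple[str, str], tuple[str, ...]]
    two_gene_participants: dict[str, tuple[str, ...]]
    distinct_genes: frozenset[str]
    distinct_chromosomes: frozenset[str]
    notes: list[str] = field(default_factory=list)

    def reportable(self, participant: str) -> list[Finding]:
        return [
            f
            for f in self.findings.get(participant, [])
            if f.category is not ReportCategory.NOT_REPORTABLE
        ]

    def participant_severity(self, participant: str) -> ReportCategory:
        """Most severe category among a participant's findings."""
        best = ReportCategory.NOT_REPORTABLE
        for f in self.findings.get(participant, []):
            if _SEVERITY[f.category] > _SEVERITY[best]:
                best = f.category
        return best

    def to_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "participants": {
                participant: [f.to_dict() for f in findings]
                for participant, findings in self.findings.items()
            },
            "participants_with_reportable": self.participants_with_reportable,
            "participants_likely_pathogenic": self.participants_likely_pathogenic,
            "participants_with_two_gene_findings": self.participants_with_two_gene_findings,
            "shared_variant_groups": [
                {"gene": gene, "nucleotide_desc": nuc, "participants": list(participants)}
                for (gene, nuc), participants in sorted(self.shared_variant_groups.items())
            ],
            "two_gene_participants": {
                participant: list(genes)
                for participant, genes in self.two_gene_participants.items()
            },
            "distinct_genes": sorted(self.distinct_genes),
            "distinct_chromosomes": sorted(self.distinct_chromosomes),
            "notes": list(self.notes),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _participant_sort_key(participant: str):
    return (0, int(participant)) if participant.isdigit() else (1, participant)


def build_cohort_report(
    cohort: Mapping[str, Sequence[Finding]] | Iterable[tuple[str, Sequence[Finding]]],
    cohort_size: int,
) -> CohortReport:
    """Aggregate categorized findings into the cohort-level report.

    Participants with no findings must appear with empty lists so that the
    cohort denominator is explicit. A participant appearing twice is an error.
    """
    pairs = cohort.items() if isinstance(cohort, Mapping) else cohort
    findings: dict[str, list[Finding]] = {}
    for participant, participant_findings in pairs:
        if participant in findings:
            raise ValueError(f"participant {participant!r} appears twice")
        findings[participant] = list(participant_findings)
    if len(findings) > cohort_size:
        raise ValueError(f"{len(findings)} participants exceed cohort size {cohort_size}")

    reportable_by_participant = {
        participant: [f for f in fs if f.category is not ReportCategory.NOT_REPORTABLE]
        for participant, fs in findings.items()
    }

    shared: dict[tuple[str, str], list[str]] = {}
    for participant in sorted(reportable_by_participant, key=_participant_sort_key):
        for f in reportable_by_participant[participant]:
            shared.setdefault((f.variant.gene, f.variant.ref_alt_description), []).append(
                participant
            )
    shared_groups = {
        key: tuple(dict.fromkeys(participants))
        for key, participants in shared.items()
        if len(set(participants)) >= 2
    }

    two_gene: dict[str, tuple[str, ...]] = {}
    for participant in sorted(reportable_by_participant, key=_participant_sort_key):
        genes = sorted(
            {
                f.variant.gene
                for f in reportable_by_participant[participant]
                if f.category in ESTABLISHED_GENE_CATEGORIES
            }
        )
        if len(genes) >= 2:
            two_gene[participant] = tuple(genes)

    all_reportable = [f for fs in reportable_by_participant.values() for f in fs]
    return CohortReport(
        cohort_size=cohort_size,
        findings=findings,
        participants_with_reportable=sum(
            1 for fs in reportable_by_participant.values() if fs
        ),
        participants_likely_pathogenic=sum(
            1
            for fs in reportable_by_participant.values()
            if any(f.category is ReportCategory.LIKELY_PATHOGENIC for f in fs)
        ),
        participants_with_two_gene_findings=len(two_gene),
        shared_variant_groups=shared_groups,
        two_gene_participants=two_gene,
        distinct_genes=frozenset(f.variant.gene for f in all_reportable),
        distinct_chromosomes=frozenset(f.variant.chrom for f in all_reportable),
    )


def two_hit_candidates(report: CohortReport) -> list[tuple[str, tuple[str, ...]]]:
    """Participants with reportable findings in >=2 distinct established genes."""
    return [
        (participant, report.two_gene_participants[participant])
        for participant in sorted(report.two_gene_participants, key=_participant_sort_key)
    ]


def run_triage(
    samples: Mapping[str, Sequence[AnnotatedVariant]],
    knowledge: GeneKnowledgeTable,
    config: TriageConfig = TriageConfig(),
    cohort_size: int | None = None,
    cross_sample_rescue: bool = True,
) -> CohortReport:
    """Prioritize every sample and assemble the categorized cohort report."""
    prioritized = prioritize_cohort(samples, knowledge, config, cross_sample_rescue)
    cohort = {
        participant: [
            Finding(
                variant=v,
                category=assign_report_category(v, prov, knowledge.get(v.gene)),
                provenance=prov,
            )
            for v, prov in admitted
        ]
        for participant, admitted in prioritized.items()
    }
    return build_cohort_report(cohort, cohort_size if cohort_size is not None else len(samples))
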