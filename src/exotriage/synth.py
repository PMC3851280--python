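"""Synthetic annotated-exome generator with planted ground truth.

Every generated sample carries a per-variant truth table stating whether the
prioritization rules should admit the variant and which report category (if
any) it should receive. Background variants are generated to fail at least
one named rule; planted class variants satisfy every rule but sit in genes
with no phenotype association; planted reportable variants satisfy the rules
of their intended category by construction. The generator and the rule engine
are therefore two independent encodings of the same contract, and exact
agreement between them is a meaningful oracle.

Per-class default counts are drawn uniformly within published per-sample
ranges for an exome of ~117k called variants (e.g. rare premature stops in
[19, 27]); the combined likely-deleterious classes are constrained to
[53, 66] variants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AnnotatedVariant,
    Consequence,
    GeneTier,
    PredictorCall,
    Zygosity,
)
from .interpret import ReportCategory

#: Published per-sample variant-count ranges per rare impact subcategory.
TABLE_RANGES: dict[str, tuple[int, int]] = {
    "premature_stop": (19, 27),
    "stop_readthrough": (0, 1),
    "start_loss": (0, 1),
    "canonical_splice": (3, 8),
    "frameshift_insertion": (13, 22),
    "frameshift_deletion": (6, 17),
    "damaging_ns": (120, 152),
    "inframe_insertion": (0, 6),
    "inframe_deletion": (0, 6),
    "near_splice": (78, 101),
}

#: Combined range for the six likely-deleterious (class 2) subcategories.
CLASS2_TOTAL_RANGE = (53, 66)

_CLASS2_KEYS = (
    "premature_stop",
    "stop_readthrough",
    "start_loss",
    "canonical_splice",
    "frameshift_insertion",
    "frameshift_deletion",
)

_CLASS_CONSEQUENCE = {
    "premature_stop": Consequence.PREMATURE_STOP,
    "stop_readthrough": Consequence.STOP_READTHROUGH,
    "start_loss": Consequence.START_LOSS,
    "canonical_splice": Consequence.CANONICAL_SPLICE,
    "frameshift_insertion": Consequence.FRAMESHIFT_INSERTION,
    "frameshift_deletion": Consequence.FRAMESHIFT_DELETION,
    "damaging_ns": Consequence.NONSYNONYMOUS,
    "inframe_insertion": Consequence.INFRAME_INSERTION,
    "inframe_deletion": Consequence.INFRAME_DELETION,
    "near_splice": Consequence.NEAR_SPLICE,
}

_ALL_DAMAGING = {
    "PROVEAN": PredictorCall.DAMAGING,
    "SIFT": PredictorCall.DAMAGING,
    "MutationAssessor": PredictorCall.DAMAGING,
    "Condel": PredictorCall.DAMAGING,
    "PolyPhen2": PredictorCall.DAMAGING,
}
# 4/5 damaging: a majority call that is deliberately not unanimous.
_MAJORITY_DAMAGING = {
    "PROVEAN": PredictorCall.NEUTRAL,
    "SIFT": PredictorCall.DAMAGING,
    "MutationAssessor": PredictorCall.DAMAGING,
    "Condel": PredictorCall.DAMAGING,
    "PolyPhen2": PredictorCall.DAMAGING,
}
_EMPTY_CALLS: dict[str, PredictorCall] = {}


class InfeasibleSpecError(ValueError):
    """Requested counts cannot fit into n_variants."""


@dataclass(frozen=True)
class PlantedReportable:
    """One reportable variant to plant, with its intended category.

    ``route`` selects how a VUS is realized: ``near_splice`` (uncertain
    functional impact in an associated gene) or ``rescued`` (frequency
    failure re-admitted through gene knowledge). The gene must carry the
    matching tier in the knowledge table used for triage.
    """

    gene: str
    tier: GeneTier
    category: ReportCategory
    route: str = "auto"

    def resolved_route(self) -> str:
        if self.route != "auto":
            return self.route
        if self.category is ReportCategory.VUS:
            return "near_splice"
        return "novel_ns"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic exome sample."""

    n_variants: int = 120_000
    class_counts: Optional[dict[str, int]] = None
    planted_reportable: tuple[PlantedReportable, ...] = ()
    af_rare_max: float = 0.003
    novel_fraction: float = 0.5
    frac_neutral_ns: float = 0.02
    frac_common_ns: float = 0.02
    frac_low_support: float = 0.005
    frac_known_neutral: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_counts is not None:
            unknown = set(self.class_counts) - set(TABLE_RANGES)
            if unknown:
                raise InfeasibleSpecError(
                    f"unknown class count key(s): {', '.join(sorted(unknown))}"
                )
            for key, count in self.class_counts.items():
                if count < 0:
                    raise InfeasibleSpecError(f"negative count for {key}: {count}")


@dataclass(frozen=True)
class VariantTruth:
    should_prioritize: bool
    intended_category: ReportCategory
    failing_rules: tuple[str, ...] = ()


@dataclass(slots=True)
class SyntheticSample:
    sample_id: str
    spec: SyntheticSpec
    variants: list[AnnotatedVariant]
    truth: dict[tuple[str, str, int, str], VariantTruth]

    def planted_prioritized_keys(self) -> frozenset[tuple[str, str, int, str]]:
        return frozenset(k for k, t in self.truth.items() if t.should_prioritize)


def draw_class_counts(rng: np.random.Generator) -> dict[str, int]:
    """Uniform counts within each published range, class-2 total constrained."""
    counts = {
        key: int(rng.integers(lo, hi + 1))
        for key, (lo, hi) in TABLE_RANGES.items()
        if key not in _CLASS2_KEYS
    }
    for _ in range(10_000):
        class2 = {
            key: int(rng.integers(*[TABLE_RANGES[key][0], TABLE_RANGES[key][1] + 1]))
            for key in _CLASS2_KEYS
        }
        total = sum(class2.values())
        if CLASS2_TOTAL_RANGE[0] <= total <= CLASS2_TOTAL_RANGE[1]:
            counts.update(class2)
            return counts
    raise RuntimeError("could not draw class-2 counts inside the combined range")


def _rare_af(rng, novel_fraction: float, af_max: float) -> dict[str, float]:
    """Absent everywhere (novel) or present below/at the rarity bound."""
    if rng.random() < novel_fraction:
        return {}
    dbs = ("EVS6500", "TGP", "in_house_128")
    n_dbs = int(rng.integers(1, 3))
    chosen = rng.choice(len(dbs), size=n_dbs, replace=False)
    out = {}
    for idx in chosen:
        if rng.random() < 0.05:
            af = af_max  # boundary-equal frequency still passes
        else:
            af = float(10 ** rng.uniform(-5, np.log10(af_max)))
            af = min(af, af_max)
        out[dbs[idx]] = af
    return out


def _support(rng) -> float:
    # occasionally sit exactly on the 10% boundary, which passes
    if rng.random() < 0.02:
        return 10.0
    return float(rng.uniform(10.0, 100.0))


def generate_sample(
    spec: SyntheticSpec, sample_id: str = "S1"
) -> SyntheticSample:
    """Deterministically generate one annotated sample with planted truth."""
    rng = np.random.default_rng(spec.seed)
    counts = dict(spec.class_counts) if spec.class_counts is not None else draw_class_counts(rng)

    # planted rare reportables occupy part of their class-count budget
    planted_ns = sum(
        1 for p in spec.planted_reportable if p.resolved_route() in ("novel_ns",)
    )
    planted_splice = sum(
        1 for p in spec.planted_reportable if p.resolved_route() == "near_splice"
    )
    counts["damaging_ns"] = max(0, counts.get("damaging_ns", 0) - planted_ns)
    counts["near_splice"] = max(0, counts.get("near_splice", 0) - planted_splice)

    n_class = sum(counts.values())
    n_planted = len(spec.planted_reportable)
    n_background = spec.n_variants - n_class - n_planted
    if n_background < 0:
        raise InfeasibleSpecError(
            f"class counts ({n_class}) plus planted variants ({n_planted})"
            f" exceed n_variants ({spec.n_variants})"
        )

    variants: list[AnnotatedVariant] = []
    truth: dict[tuple[str, str, int, str], VariantTruth] = {}
    index = 0

    def add(v: AnnotatedVariant, t: VariantTruth) -> None:
        variants.append(v)
        truth[v.key] = t

    def locus(i: int) -> tuple[str, int]:
        return f"chr{(i % 22) + 1}", 100_000 + i

    def make(
        gene: str,
        consequence: Consequence,
        af_by_db: dict[str, float],
        predictor_calls: dict[str, PredictorCall],
        *,
        reads_pct: Optional[float] = None,
        dbsnp_id: Optional[str] = None,
        known_neutral: bool = False,
        splice_distance: Optional[int] = None,
        protein_change: str = "",
    ) -> AnnotatedVariant:
        nonlocal index
        chrom, pos = locus(index)
        v = AnnotatedVariant(
            sample_id=sample_id,
            chrom=chrom,
            start=pos,
            end=pos,
            gene=gene,
            consequence=consequence,
            ref_alt_description=f"c.{index + 1}A>G",
            protein_change=protein_change,
            zygosity=Zygosity.HOMOZYGOUS if rng.random() < 0.1 else Zygosity.HETEROZYGOUS,
            read_support_fraction=reads_pct if reads_pct is not None else _support(rng),
            total_depth=int(rng.integers(10, 250)),
            af_by_db=af_by_db,
            dbsnp_id=dbsnp_id,
            predictor_calls=predictor_calls,
            known_neutral=known_neutral,
            splice_distance_bases=splice_distance,
        )
        index += 1
        return v

    # --- planted rare class variants (prioritized, but in unassociated genes)
    for key, count in counts.items():
        if count == 0:
            continue
        consequence = _CLASS_CONSEQUENCE[key]
        pool_size = max(1, count - int(rng.binomial(count, 0.15)))
        pool = [f"SYN_{key.upper()}_{j}" for j in range(pool_size)]
        for i in range(count):
            gene = pool[i] if i < pool_size else pool[int(rng.integers(0, pool_size))]
            calls = _ALL_DAMAGING if key == "damaging_ns" else _EMPTY_CALLS
            v = make(
                gene,
                consequence,
                _rare_af(rng, spec.novel_fraction, spec.af_rare_max),
                calls,
                splice_distance=int(rng.integers(1, 11)) if key == "near_splice" else None,
            )
            add(v, VariantTruth(True, ReportCategory.NOT_REPORTABLE))

    # --- planted reportable variants
    for i, plant in enumerate(spec.planted_reportable):
        route = plant.resolved_route()
        protein = f"p.Planted{i}"
        if plant.category is ReportCategory.LIKELY_PATHOGENIC:
            v = make(
                plant.gene,
                Consequence.NONSYNONYMOUS,
                {},
                _ALL_DAMAGING,
                reads_pct=float(rng.uniform(30, 95)),
                protein_change=protein,
            )
        elif plant.category is ReportCategory.VUS_IN_GUS:
            v = make(
                plant.gene,
                Consequence.NONSYNONYMOUS,
                {},
                _MAJORITY_DAMAGING,
                reads_pct=float(rng.uniform(30, 95)),
                protein_change=protein,
            )
        elif plant.category is ReportCategory.VUS and route == "near_splice":
            v = make(
                plant.gene,
                Consequence.NEAR_SPLICE,
                {},
                _EMPTY_CALLS,
                reads_pct=float(rng.uniform(30, 95)),
                splice_distance=int(rng.integers(1, 11)),
            )
        elif plant.category is ReportCategory.VUS and route == "rescued":
            v = make(
                plant.gene,
                Consequence.NONSYNONYMOUS,
                {"EVS6500": float(rng.uniform(0.004, 0.1))},
                _ALL_DAMAGING,
                reads_pct=float(rng.uniform(30, 95)),
                dbsnp_id=f"rs{900000 + i}",
                protein_change=protein,
            )
        else:
            raise InfeasibleSpecError(
                f"cannot plant category {plant.category} via route {route!r}"
            )
        add(v, VariantTruth(True, plant.category))

    # --- background variants, each failing at least one named rule
    modes = rng.choice(
        5,
        size=n_background,
        p=[
            1.0
            - spec.frac_neutral_ns
            - spec.frac_common_ns
            - spec.frac_low_support
            - spec.frac_known_neutral,
            spec.frac_neutral_ns,
            spec.frac_common_ns,
            spec.frac_low_support,
            spec.frac_known_neutral,
        ],
    )
    neutral_templates = (
        {name: PredictorCall.NEUTRAL for name in _ALL_DAMAGING},
        {**{name: PredictorCall.NEUTRAL for name in _ALL_DAMAGING}, "SIFT": PredictorCall.UNKNOWN},
    )
    for mode in modes:
        if mode == 0:
            # consequence gives no impact-class assignment
            if rng.random() < 0.02:
                v = make(
                    f"BG{index}",
                    Consequence.NEAR_SPLICE,
                    _rare_af(rng, 0.3, 0.5),
                    _EMPTY_CALLS,
                    splice_distance=int(rng.integers(11, 60)),
                )
            else:
                v = make(f"BG{index}", Consequence.OTHER, _rare_af(rng, 0.3, 0.5), _EMPTY_CALLS)
            add(v, VariantTruth(False, ReportCategory.NOT_REPORTABLE, ("impact",)))
        elif mode == 1:
            # nonsynonymous with a neutral predictor consensus
            calls = neutral_templates[int(rng.integers(0, 2))]
            v = make(
                f"BG{index}",
                Consequence.NONSYNONYMOUS,
                _rare_af(rng, spec.novel_fraction, spec.af_rare_max),
                calls,
            )
            add(v, VariantTruth(False, ReportCategory.NOT_REPORTABLE, ("impact",)))
        elif mode == 2:
            # too common, damaging, no rescue route (unassociated gene)
            v = make(
                f"CMN{index}",
                Consequence.NONSYNONYMOUS,
                {"TGP": float(rng.uniform(0.0031, 0.5))},
                _ALL_DAMAGING,
                dbsnp_id=f"rs{100000 + index}",
            )
            add(v, VariantTruth(False, ReportCategory.NOT_REPORTABLE, ("frequency",)))
        elif mode == 3:
            # supported by fewer than 10% of reads
            v = make(
                f"BG{index}",
                Consequence.PREMATURE_STOP,
                _rare_af(rng, spec.novel_fraction, spec.af_rare_max),
                _EMPTY_CALLS,
                reads_pct=float(rng.uniform(0.5, 9.9)),
            )
            add(v, VariantTruth(False, ReportCategory.NOT_REPORTABLE, ("read_support",)))
        else:
            # previously confirmed neutral polymorphism
            v = make(
                f"BG{index}",
                Consequence.NONSYNONYMOUS,
                _rare_af(rng, spec.novel_fraction, spec.af_rare_max),
                _ALL_DAMAGING,
                known_neutral=True,
            )
            add(v, VariantTruth(False, ReportCategory.NOT_REPORTABLE, ("neutral",)))

    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    return SyntheticSample(sample_id=sample_id, spec=spec, variants=variants, truth=truth)


#: Default reportable variants planted into reportable cohort samples.
DEFAULT_PLANT = (
    PlantedReportable("CNTNAP2", GeneTier.TIER_CAS, ReportCategory.LIKELY_PATHOGENIC),
    PlantedReportable("CNTNAP1", GeneTier.TIER_GUS, ReportCategory.VUS_IN_GUS),
    PlantedReportable("KIAA0319", GeneTier.TIER_OVERLAP, ReportCategory.VUS, route="rescued"),
)


def generate_cohort(
    n_samples: int,
    spec_template: SyntheticSpec = SyntheticSpec(),
    reportable_fraction: float = 0.8,
    seed: int = 0,
) -> list[SyntheticSample]:
    """A cohort of samples; a controlled fraction carries planted findings."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= reportable_fraction <= 1.0:
        raise ValueError("reportable_fraction must be in [0, 1]")
    n_reportable = round(reportable_fraction * n_samples)
    plant = spec_template.planted_reportable or DEFAULT_PLANT
    children = np.random.SeedSequence(seed).spawn(n_samples)
    samples = []
    for i in range(n_samples):
        child_seed = int(children[i].generate_state(1)[0])
        spec = dataclasses.replace(
            spec_template,
            seed=child_seed,
            planted_reportable=plant if i < n_reportable else (),
        )
        samples.append(generate_sample(spec, sample_id=f"S{i + 1}"))
    return samples


def write_truth_table(sample: SyntheticSample, path) -> None:
    """Write the per-variant truth labels as a TSV keyed like the variant table."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(
            "sample_id\tchrom\tstart\tnucleotide_desc\tshould_prioritize"
            "\tintended_category\tfailing_rules\n"
        )
        for v in sample.variants:
            t = sample.truth[v.key]
            handle.write(
                f"{v.sample_id}\t{v.chrom}\t{v.start}\t{v.ref_alt_description}"
                f"\t{str(t.should_prioritize).lower()}\t{t.intended_category.value}"
                f"\t{','.join(t.failing_rules)}\n"
            )
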