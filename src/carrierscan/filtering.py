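"""Variant filtering and candidate prioritization.

Implements the discovery-phase cascade used for rare RAD51C/RAD51D
variants: genotype-level quality filters (read depth, variant allele
fraction), variant-level class and population-frequency filters, and
prioritization of loss-of-function variants plus missense variants with
a supportive clinical classification and in-silico predictor evidence.

Every rule is a pure predicate, so the final kept set does not depend
on the order in which rules are applied; the per-variant trace records
which rule fired first for excluded items.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .types import (
    CONSERVATION_TOOLS,
    DAMAGE_TOOLS,
    LOF_CONSEQUENCES,
    AnnotatedVariant,
    ClinicalClass,
    Consequence,
    GenotypeCall,
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering and prioritization cascade.

    Defaults match the published discovery criteria: MAF < 0.01,
    depth >= 10 reads, VAF within [0.20, 0.80] (the bounds themselves
    are kept, since only calls strictly outside are excluded),
    conservation thresholds GERP >= 2.0, PhyloP >= 0.2,
    PhastCons >= 0.4; damage thresholds REVEL/MetaLR/CONDEL >= 0.4,
    MetaSVM >= 0.0, CADD (Phred) >= 20; and the splice consensus rule
    (both dbscSNV scores >= 0.4, or MaxEntScan and HSF both calling the
    change splice-affecting).

    PROVEAN is a special case: the conventional direction of the tool
    is damaging when the score is at or below -2.5, and that is the
    default here (``provean_damaging_low=True``); the opposite
    direction (>= -2.5) is available for sensitivity analyses.
    """

    maf_max: float = 0.01
    depth_min: int = 10
    vaf_min: float = 0.20
    vaf_max: float = 0.80
    conservation_thresholds: dict[str, float] = field(
        default_factory=lambda: {"GERP": 2.0, "PhyloP": 0.2, "PhastCons": 0.4}
    )
    damage_thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "REVEL": 0.4,
            "MetaLR": 0.4,
            "MetaSVM": 0.0,
            "CONDEL": 0.4,
            "CADD_phred": 20.0,
        }
    )
    provean_threshold: float = -2.5
    provean_damaging_low: bool = True
    dbscsnv_threshold: float = 0.4
    aggregation_mode: str = "any_tool"  # or "all_categories"
    accepted_classes: frozenset[ClinicalClass] = frozenset(
        {
            ClinicalClass.PATHOGENIC,
            ClinicalClass.LIKELY_PATHOGENIC,
            ClinicalClass.VUS,
            ClinicalClass.CONFLICTING,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError("require 0 <= vaf_min < vaf_max <= 1")
        if self.aggregation_mode not in {"any_tool", "all_categories"}:
            raise ValueError(f"unknown aggregation_mode {self.aggregation_mode!r}")


class FilterStatus(str, Enum):
    CANDIDATE = "candidate"
    EXCLUDED = "excluded"


@dataclass
class FilterTrace:
    """Audit trail for one variant (or one genotype call) through the cascade."""

    variant_id: str
    verdicts: dict[str, str] = field(default_factory=dict)  # rule -> pass/fail/not_applicable
    first_failure: str | None = None
    status: FilterStatus = FilterStatus.CANDIDATE

    def record(self, rule: str, passed: bool | None) -> None:
        self.verdicts[rule] = (
            "not_applicable" if passed is None else ("pass" if passed else "fail")
        )
        if passed is False:
            if self.first_failure is None:
                self.first_failure = rule
            self.status = FilterStatus.EXCLUDED


def apply_quality_filters(
    calls: list[GenotypeCall], cfg: FilterConfig | None = None
) -> tuple[list[GenotypeCall], list[FilterTrace]]:
    """Keep calls with depth >= depth_min, VAF in [vaf_min, vaf_max], base quality pass.

    Both VAF bounds are inclusive: a call at exactly 0.20 or 0.80 is kept.
    """
    cfg = cfg or FilterConfig()
    kept: list[GenotypeCall] = []
    traces: list[FilterTrace] = []
    for call in calls:
        trace = FilterTrace(variant_id=f"{call.sample_id}:{call.variant_id}")
        trace.record("depth", call.depth >= cfg.depth_min)
        trace.record("vaf", cfg.vaf_min <= call.vaf <= cfg.vaf_max)
        trace.record("base_quality", call.base_quality_pass)
        if trace.status is FilterStatus.CANDIDATE:
            kept.append(call)
        traces.append(trace)
    return kept, traces


def apply_class_and_frequency_filters(
    variants: list[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], list[FilterTrace]]:
    """Remove silent/intronic variants and those with reference MAF >= maf_max.

    A missing MAF is kept: absence from the reference database is
    evidence of rarity for a founder-population variant, not of
    commonness.
    """
    cfg = cfg or FilterConfig()
    kept: list[AnnotatedVariant] = []
    traces: list[FilterTrace] = []
    for v in variants:
        trace = FilterTrace(variant_id=v.variant_id)
        trace.record(
            "consequence_class",
            v.consequence not in {Consequence.SILENT, Consequence.INTRONIC},
        )
        if v.maf_reference is None:
            trace.record("maf", None)
        else:
            trace.record("maf", v.maf_reference < cfg.maf_max)
        if trace.status is FilterStatus.CANDIDATE:
            kept.append(v)
        traces.append(trace)
    return kept, traces


def _score_passes(score: float | None, threshold: float, low_is_bad: bool = False) -> bool | None:
    if score is None:
        return None
    return score <= threshold if low_is_bad else score >= threshold


def _tool_passes(v: AnnotatedVariant, tool: str, cfg: FilterConfig) -> bool | None:
    """Pass/fail for one tool; categorical labels take precedence over scores.

    Returns None when the tool was not run for this variant.
    """
    panel = v.predictor_panel
    entry = panel.get(tool)
    if entry.missing:
        return None
    label_verdict = panel.label_passes(tool)
    if label_verdict is not None:
        return label_verdict
    if tool in CONSERVATION_TOOLS:
        return _score_passes(entry.score, cfg.conservation_thresholds[tool])
    if tool == "PROVEAN":
        return _score_passes(entry.score, cfg.provean_threshold, cfg.provean_damaging_low)
    if tool in cfg.damage_thresholds:
        return _score_passes(entry.score, cfg.damage_thresholds[tool])
    if tool in ("dbscSNV_ADA", "dbscSNV_RF"):
        return _score_passes(entry.score, cfg.dbscsnv_threshold)
    return None


def evaluate_insilico_support(
    v: AnnotatedVariant, cfg: FilterConfig | None = None
) -> tuple[bool, set[str]]:
    """Decide whether the in-silico predictor panel supports the variant.

    Under the default ``any_tool`` aggregation, support means: at least
    one conservation tool at threshold, OR at least one damage tool at
    threshold, OR the splice consensus rule fires. The splice rule
    fires when both dbscSNV scores reach 0.4, or when MaxEntScan and
    HSF both classify the change as splice-affecting. Missing tools
    contribute nothing. ``all_categories`` additionally requires every
    non-missing category (conservation, damage, splice) that has any
    passing evidence ... to pass, i.e. evidence from each available
    category; it is provided for sensitivity analyses.
    """
    cfg = cfg or FilterConfig()
    evidence: set[str] = set()

    conservation_hits = [t for t in CONSERVATION_TOOLS if _tool_passes(v, t, cfg)]
    damage_hits = [t for t in DAMAGE_TOOLS if _tool_passes(v, t, cfg)]
    evidence.update(conservation_hits)
    evidence.update(damage_hits)

    ada = _tool_passes(v, "dbscSNV_ADA", cfg)
    rf = _tool_passes(v, "dbscSNV_RF", cfg)
    maxent = v.predictor_panel.label_passes("MaxEntScan_class")
    hsf = v.predictor_panel.label_passes("HSF_class")
    splice_fires = bool(ada and rf) or bool(maxent and hsf)
    if splice_fires:
        evidence.add("splice_consensus")

    if cfg.aggregation_mode == "any_tool":
        supported = bool(conservation_hits) or bool(damage_hits) or splice_fires
    else:  # all_categories: every category with any non-missing tool must support
        categories: list[bool] = []
        if any(_tool_passes(v, t, cfg) is not None for t in CONSERVATION_TOOLS):
            categories.append(bool(conservation_hits))
        if any(_tool_passes(v, t, cfg) is not None for t in DAMAGE_TOOLS):
            categories.append(bool(damage_hits))
        if ada is not None or rf is not None or maxent is not None or hsf is not None:
            categories.append(splice_fires)
        supported = bool(categories) and all(categories)
    return supported, evidence


def _clinical_class_accepted(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return v.clinvar_class in cfg.accepted_classes or v.acmg_class in cfg.accepted_classes


def prioritize_candidates(
    variants: list[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], list[FilterTrace]]:
    """Select candidates among variants that passed the class/frequency filters.

    A variant is a candidate when it is loss-of-function (nonsense,
    frameshift, canonical splice), or when it is missense with a
    ClinVar or ACMG classification among the accepted classes
    (pathogenic, likely pathogenic, VUS, or conflicting — conflicting
    reports are treated as VUS-equivalent) and the in-silico panel
    supports it.
    """
    cfg = cfg or FilterConfig()
    candidates: list[AnnotatedVariant] = []
    traces: list[FilterTrace] = []
    for v in variants:
        trace = FilterTrace(variant_id=v.variant_id)
        if v.consequence in LOF_CONSEQUENCES:
            trace.record("lof", True)
            candidates.append(v)
        elif v.consequence is Consequence.MISSENSE:
            trace.record("lof", None)
            trace.record("clinical_class", _clinical_class_accepted(v, cfg))
            supported, evidence = evaluate_insilico_support(v, cfg)
            trace.record("insilico_support", supported)
            trace.verdicts["insilico_evidence"] = ",".join(sorted(evidence))
            if trace.status is FilterStatus.CANDIDATE:
                candidates.append(v)
        else:
            trace.record("consequence_eligible", False)
        traces.append(trace)
    return candidates, traces


def run_filter_cascade(
    variants: list[AnnotatedVariant], cfg: FilterConfig | None = None
) -> tuple[list[AnnotatedVariant], list[FilterTrace]]:
    """Class/frequency filters followed by prioritization, with a merged trace."""
    cfg = cfg or FilterConfig()
    kept, stage1 = apply_class_and_frequency_filters(variants, cfg)
    candidates, stage2 = prioritize_candidates(kept, cfg)
    stage2_by_id = {t.variant_id: t for t in stage2}
    merged: list[FilterTrace] = []
    for trace in stage1:
        later = stage2_by_id.get(trace.variant_id)
        if trace.status is FilterStatus.CANDIDATE and later is not None:
            combined = replace(later)
            combined.verdicts = {**trace.verdicts, **later.verdicts}
            merged.append(combined)
        else:
            merged.append(trace)
    return candidates, merged
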