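"""The quality/class/frequency filters and the prioritization rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierscan import study
from carrierscan.filtering import (
    FilterConfig,
    FilterStatus,
    apply_class_and_frequency_filters,
    apply_quality_filters,
    evaluate_insilico_support,
    prioritize_candidates,
    run_filter_cascade,
)
from carrierscan.types import (
    AnnotatedVariant,
    ClinicalClass,
    Consequence,
    GenotypeCall,
    PredictorLabel,
    PredictorPanel,
    PredictorValue,
)


# ---------------------------------------------------------------- quality

@pytest.mark.parametrize(
    "depth,vaf,bq,kept",
    [
        (9, 0.5, True, False),    # below the 10-read coverage floor
        (10, 0.5, True, True),
        (30, 0.20, True, True),   # VAF bounds are inclusive
        (30, 0.80, True, True),
        (30, 0.19, True, False),
        (30, 0.81, True, False),
        (30, 0.5, False, False),  # base-quality failure
    ],
)
def test_quality_filter_boundaries(depth, vaf, bq, kept):
    call = GenotypeCall("s", "v", depth=depth, vaf=vaf, base_quality_pass=bq)
    result, traces = apply_quality_filters([call])
    assert (len(result) == 1) is kept
    if not kept:
        assert traces[0].first_failure is not None


calls_strategy = st.lists(
    st.builds(
        GenotypeCall,
        sample_id=st.sampled_from(["s1", "s2"]),
        variant_id=st.sampled_from(["v1", "v2", "v3"]),
        depth=st.integers(min_value=0, max_value=40),
        vaf=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        base_quality_pass=st.booleans(),
    ),
    max_size=30,
)


@settings(deadline=None, derandomize=True)
@given(calls=calls_strategy)
def test_quality_filter_matches_direct_predicate(calls):
    """Brute-force reapplication of the stated predicate gives the same kept set."""
    cfg = FilterConfig()
    kept, _ = apply_quality_filters(calls, cfg)
    expected = [
        c for c in calls
        if c.depth >= 10 and 0.20 <= c.vaf <= 0.80 and c.base_quality_pass
    ]
    assert kept == expected


# -------------------------------------------------- class / frequency

def _variant(consequence=Consequence.MISSENSE, maf=None, clinvar=ClinicalClass.VUS,
             acmg=ClinicalClass.VUS, panel=None, vid="G:c.1A>G"):
    return AnnotatedVariant(
        variant_id=vid, gene="G", genomic_change="g.1A>G", protein_change="",
        consequence=consequence, maf_reference=maf,
        predictor_panel=panel or PredictorPanel(),
        clinvar_class=clinvar, acmg_class=acmg,
    )


@pytest.mark.parametrize(
    "consequence,maf,kept",
    [
        (Consequence.MISSENSE, 0.02, False),   # common variant removed
        (Consequence.MISSENSE, 0.01, False),   # MAF >= 0.01 removed (boundary)
        (Consequence.MISSENSE, 0.009, True),
        (Consequence.MISSENSE, None, True),    # absent from reference db => rare
        (Consequence.SILENT, 0.0001, False),
        (Consequence.INTRONIC, None, False),
        (Consequence.NONSENSE, 0.0001, True),
    ],
)
def test_class_and_frequency_rules(consequence, maf, kept):
    result, traces = apply_class_and_frequency_filters(
        [_variant(consequence=consequence, maf=maf)]
    )
    assert (len(result) == 1) is kept


def test_reference_panel_survives_frequency_filter(reference_panel):
    kept, _ = apply_class_and_frequency_filters(reference_panel)
    assert kept == reference_panel


# ------------------------------------------------------- in-silico panel

def test_splice_donor_profile_supported(reference_panel):
    """The splice-site missense profile (conserved x3, REVEL benign,
    CADD damaging, four splice tools affecting) is supported, with both
    CADD and the splice consensus as evidence."""
    v = next(v for v in reference_panel if v.variant_id == study.RAD51C_705)
    supported, evidence = evaluate_insilico_support(v)
    assert supported
    assert "CADD_phred" in evidence
    assert "splice_consensus" in evidence


def test_all_tools_missing_or_failing_not_supported():
    bare = _variant(panel=PredictorPanel())
    assert evaluate_insilico_support(bare)[0] is False
    failing = _variant(
        panel=PredictorPanel(entries={
            "GERP": PredictorValue(score=1.0),
            "REVEL": PredictorValue(label=PredictorLabel.BENIGN),
        })
    )
    assert evaluate_insilico_support(failing)[0] is False


def test_damage_threshold_is_inclusive():
    """A REVEL score of exactly 0.4 counts as damaging."""
    v = _variant(panel=PredictorPanel(entries={"REVEL": PredictorValue(score=0.4)}))
    supported, evidence = evaluate_insilico_support(v)
    assert supported and evidence == {"REVEL"}


def test_splice_rule_needs_both_consensus_tools():
    one_only = _variant(panel=PredictorPanel(entries={
        "dbscSNV_ADA": PredictorValue(score=0.9),
        "dbscSNV_RF": PredictorValue(score=0.1),
    }))
    assert evaluate_insilico_support(one_only)[0] is False
    both = _variant(panel=PredictorPanel(entries={
        "dbscSNV_ADA": PredictorValue(score=0.9),
        "dbscSNV_RF": PredictorValue(score=0.4),
    }))
    supported, evidence = evaluate_insilico_support(both)
    assert supported and "splice_consensus" in evidence


def test_provean_direction_is_configurable():
    v = _variant(panel=PredictorPanel(entries={"PROVEAN": PredictorValue(score=-3.0)}))
    assert evaluate_insilico_support(v, FilterConfig())[0] is True  # <= -2.5 damaging
    flipped = FilterConfig(provean_damaging_low=False)
    assert evaluate_insilico_support(v, flipped)[0] is False


def test_label_takes_precedence_over_score():
    v = _variant(panel=PredictorPanel(entries={
        "REVEL": PredictorValue(score=0.9, label=PredictorLabel.BENIGN),
    }))
    assert evaluate_insilico_support(v)[0] is False


# -------------------------------------------------------- prioritization

def test_reference_panel_yields_exactly_five_candidates(reference_panel):
    candidates, trace = prioritize_candidates(reference_panel)
    assert [c.variant_id for c in candidates] == list(study.VARIANT_IDS)


def test_benign_missense_excluded_despite_damaging_predictors():
    v = _variant(
        clinvar=ClinicalClass.BENIGN, acmg=ClinicalClass.BENIGN,
        panel=PredictorPanel(entries={"REVEL": PredictorValue(score=0.99)}),
    )
    candidates, trace = prioritize_candidates([v])
    assert candidates == []
    assert trace[0].first_failure == "clinical_class"


def test_conflicting_classification_is_accepted():
    v = _variant(
        clinvar=ClinicalClass.CONFLICTING, acmg=ClinicalClass.LIKELY_BENIGN,
        panel=PredictorPanel(entries={"GERP": PredictorValue(score=3.0)}),
    )
    candidates, _ = prioritize_candidates([v])
    assert len(candidates) == 1


# independent re-implementation of the candidate rule, used as an oracle
def _is_candidate_oracle(v: AnnotatedVariant) -> bool:
    if v.consequence.value in {"nonsense", "frameshift", "canonical_splice"}:
        return True
    if v.consequence.value != "missense":
        return False
    accepted = {"pathogenic", "likely_pathogenic", "vus", "conflicting"}
    if v.clinvar_class.value not in accepted and v.acmg_class.value not in accepted:
        return False
    thresholds = {"GERP": 2.0, "PhyloP": 0.2, "PhastCons": 0.4, "REVEL": 0.4,
                  "MetaLR": 0.4, "MetaSVM": 0.0, "CONDEL": 0.4, "CADD_phred": 20.0}
    good = {"conserved", "damaging", "pathogenic", "affecting_splicing"}

    def tool_ok(tool):
        entry = v.predictor_panel.get(tool)
        if entry.label is not None:
            return entry.label.value in good
        if entry.score is None:
            return None
        if tool == "PROVEAN":
            return entry.score <= -2.5
        if tool in ("dbscSNV_ADA", "dbscSNV_RF"):
            return entry.score >= 0.4
        return entry.score >= thresholds[tool]

    any_hit = any(tool_ok(t) for t in thresholds)
    splice = bool(tool_ok("dbscSNV_ADA")) and bool(tool_ok("dbscSNV_RF"))
    splice = splice or (
        bool(tool_ok("MaxEntScan_class")) and bool(tool_ok("HSF_class"))
    )
    return bool(any_hit or splice)


score_tool = st.sampled_from(
    ["GERP", "PhyloP", "PhastCons", "REVEL", "MetaLR", "MetaSVM", "CONDEL",
     "PROVEAN", "CADD_phred", "dbscSNV_ADA", "dbscSNV_RF"]
)
label_tool = st.sampled_from(["MaxEntScan_class", "HSF_class"])


@st.composite
def random_variant(draw, index):
    entries = {}
    for tool in draw(st.sets(score_tool, max_size=6)):
        entries[tool] = PredictorValue(
            score=draw(st.floats(min_value=-30, max_value=40, allow_nan=False))
        )
    for tool in draw(st.sets(label_tool, max_size=2)):
        entries[tool] = PredictorValue(
            label=draw(st.sampled_from(
                [PredictorLabel.AFFECTING_SPLICING, PredictorLabel.NOT_AFFECTING]
            ))
        )
    return AnnotatedVariant(
        variant_id=f"G:c.{index}A>G", gene="G", genomic_change=f"g.{index}A>G",
        protein_change="",
        consequence=draw(st.sampled_from(list(Consequence))),
        maf_reference=draw(st.one_of(st.none(), st.floats(0, 0.009))),
        predictor_panel=PredictorPanel(entries=entries),
        clinvar_class=draw(st.sampled_from(list(ClinicalClass))),
        acmg_class=draw(st.sampled_from(list(ClinicalClass))),
    )


@settings(deadline=None, derandomize=True, max_examples=60)
@given(data=st.data(), n=st.integers(min_value=0, max_value=12))
def test_prioritization_matches_independent_oracle(data, n):
    """Randomized panels: candidate set equals an independently coded rule."""
    variants = [data.draw(random_variant(index=i)) for i in range(n)]
    candidates, trace = prioritize_candidates(variants)
    expected = [v for v in variants if _is_candidate_oracle(v)]
    assert candidates == expected
    assert len(candidates) + sum(
        t.status is FilterStatus.EXCLUDED for t in trace
    ) == len(variants)
    for t in trace:
        if t.status is FilterStatus.EXCLUDED:
            assert t.first_failure is not None


def test_cascade_counts_partition_input(reference_panel):
    from carrierscan.synthetic import PanelSpec, generate_variant_panel

    panel = generate_variant_panel(
        PanelSpec(planted=tuple(reference_panel), n_decoys=50, decoy_mode="straddling",
                  seed=5)
    )
    candidates, trace = run_filter_cascade(panel)
    excluded = [t for t in trace if t.status is FilterStatus.EXCLUDED]
    assert len(candidates) + len(excluded) == len(panel)
    for t in excluded:
        assert t.first_failure is not None
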