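"""Reference study profiles: the rare RAD51C/RAD51D founder-population design.

This module packages, as plain Python constructors, the published
characteristics of the five candidate RAD51C/RAD51D variants found in
French Canadian ovarian-cancer cases (in-silico predictor labels,
reference-population allele frequencies, clinical classifications),
the study-group structure (ovarian-cancer families counted by family,
hereditary breast-and-ovarian-cancer families, sporadic cases, and two
control series), the per-group carrier counts, the discovery-phase
yield, and tumour/normal allele-fraction observations encoded from the
reported loss-of-heterozygosity states.

The allele fractions attached to LOH states are representative
synthetic values (the original readout was visual chromatogram
inspection, which reports states, not fractions).
"""

from __future__ import annotations

from .loh import LOHObservation, Preservation
from .permutation import PermutationTest
from .stats import CarrierFrequency, carrier_frequency
from .synthetic import CohortSpec, GroupSpec
from .types import (
    AnnotatedVariant,
    ClinicalClass,
    Consequence,
    CountingUnit,
    PredictorLabel,
    PredictorPanel,
    PredictorValue,
    Role,
)

RAD51C_414 = "RAD51C:c.414G>C"
RAD51C_705 = "RAD51C:c.705G>T"
RAD51D_137 = "RAD51D:c.137C>G"
RAD51D_620 = "RAD51D:c.620C>T"
RAD51D_694 = "RAD51D:c.694C>T"

VARIANT_IDS = (RAD51C_414, RAD51C_705, RAD51D_137, RAD51D_620, RAD51D_694)

OC_FAMILIES = "oc_families"
HBOC_FAMILIES = "hboc_families"
SPORADIC = "sporadic_oc"
SEQ_CONTROLS = "seq_controls"
GENO_CONTROLS = "geno_controls"

_L = PredictorLabel


def _panel(**labels: PredictorLabel) -> PredictorPanel:
    return PredictorPanel(
        entries={tool: PredictorValue(label=label) for tool, label in labels.items()}
    )


def candidate_variant_panel() -> list[AnnotatedVariant]:
    """The five candidate variants with their reported annotation."""
    conserved = dict(GERP=_L.CONSERVED, PhyloP=_L.CONSERVED, PhastCons=_L.CONSERVED)
    return [
        AnnotatedVariant(
            variant_id=RAD51C_414,
            gene="RAD51C",
            genomic_change="g.56774063G>C",
            protein_change="p.Leu138Phe",
            consequence=Consequence.MISSENSE,
            maf_reference=0.00001,
            predictor_panel=_panel(
                **conserved,
                REVEL=_L.PATHOGENIC,
                MetaLR=_L.TOLERATED,
                MetaSVM=_L.TOLERATED,
                CONDEL=_L.DAMAGING,
                PROVEAN=_L.DAMAGING,
                CADD_phred=_L.DAMAGING,
            ),
            clinvar_class=ClinicalClass.PATHOGENIC,
            acmg_class=ClinicalClass.LIKELY_PATHOGENIC,
        ),
        AnnotatedVariant(
            variant_id=RAD51C_705,
            gene="RAD51C",
            genomic_change="g.56780690G>T",
            protein_change="p.Lys235Asn",
            consequence=Consequence.MISSENSE,
            maf_reference=0.00001,
            predictor_panel=_panel(
                **conserved,
                REVEL=_L.BENIGN,
                MetaLR=_L.TOLERATED,
                MetaSVM=_L.TOLERATED,
                CONDEL=_L.TOLERATED,
                PROVEAN=_L.TOLERATED,
                CADD_phred=_L.DAMAGING,
                dbscSNV_ADA=_L.AFFECTING_SPLICING,
                dbscSNV_RF=_L.AFFECTING_SPLICING,
                MaxEntScan_class=_L.AFFECTING_SPLICING,
                HSF_class=_L.AFFECTING_SPLICING,
            ),
            clinvar_class=ClinicalClass.CONFLICTING,
            acmg_class=ClinicalClass.PATHOGENIC,
        ),
        AnnotatedVariant(
            variant_id=RAD51D_137,
            gene="RAD51D",
            genomic_change="g.33446137G>C",
            protein_change="p.Ser46Cys",
            consequence=Consequence.MISSENSE,
            maf_reference=0.0001,
            predictor_panel=_panel(
                **conserved,
                REVEL=_L.PATHOGENIC,
                MetaLR=_L.TOLERATED,
                MetaSVM=_L.TOLERATED,
                CONDEL=_L.DAMAGING,
                PROVEAN=_L.DAMAGING,
                CADD_phred=_L.DAMAGING,
            ),
            clinvar_class=ClinicalClass.CONFLICTING,
            acmg_class=ClinicalClass.VUS,
        ),
        AnnotatedVariant(
            variant_id=RAD51D_620,
            gene="RAD51D",
            genomic_change="g.33430520G>A",
            protein_change="p.Ser207Leu",
            consequence=Consequence.MISSENSE,
            maf_reference=0.0001,
            predictor_panel=_panel(
                **conserved,
                REVEL=_L.PATHOGENIC,
                MetaLR=_L.DAMAGING,
                MetaSVM=_L.DAMAGING,
                CONDEL=_L.DAMAGING,
                PROVEAN=_L.DAMAGING,
                CADD_phred=_L.DAMAGING,
            ),
            clinvar_class=ClinicalClass.CONFLICTING,
            acmg_class=ClinicalClass.VUS,
        ),
        AnnotatedVariant(
            variant_id=RAD51D_694,
            gene="RAD51D",
            genomic_change="g.33430317G>A",
            protein_change="p.Arg232Ter",
            consequence=Consequence.NONSENSE,
            maf_reference=0.00003,
            predictor_panel=_panel(**conserved, CADD_phred=_L.DAMAGING),
            clinvar_class=ClinicalClass.PATHOGENIC,
            acmg_class=ClinicalClass.PATHOGENIC,
        ),
    ]


# discovery phase: carriers per variant among 20 familial cases (17
# families) and 53 sporadic early-onset cases; each carrier in the
# familial arm came from a distinct family
N_DISCOVERY_FAMILIES = 17
N_DISCOVERY_SPORADIC = 53
DISCOVERY_FAMILIAL_CARRIERS = {
    RAD51C_414: 1, RAD51C_705: 0, RAD51D_137: 0, RAD51D_620: 2, RAD51D_694: 0,
}
DISCOVERY_SPORADIC_CARRIERS = {
    RAD51C_414: 1, RAD51C_705: 1, RAD51D_137: 1, RAD51D_620: 2, RAD51D_694: 1,
}


def discovery_summary() -> dict[str, CarrierFrequency]:
    """Fraction of discovery families / sporadic cases carrying any candidate."""
    return {
        "families": carrier_frequency(
            sum(DISCOVERY_FAMILIAL_CARRIERS.values()), N_DISCOVERY_FAMILIES
        ),
        "sporadic": carrier_frequency(
            sum(DISCOVERY_SPORADIC_CARRIERS.values()), N_DISCOVERY_SPORADIC
        ),
    }


#: replication-phase carrier counts per (variant, group)
CARRIER_COUNTS: dict[str, dict[str, int]] = {
    RAD51C_414: {OC_FAMILIES: 1, HBOC_FAMILIES: 0, SPORADIC: 0, SEQ_CONTROLS: 1, GENO_CONTROLS: 0},
    RAD51C_705: {OC_FAMILIES: 0, HBOC_FAMILIES: 0, SPORADIC: 1, SEQ_CONTROLS: 0, GENO_CONTROLS: 0},
    RAD51D_137: {OC_FAMILIES: 0, HBOC_FAMILIES: 0, SPORADIC: 1, SEQ_CONTROLS: 0, GENO_CONTROLS: 0},
    RAD51D_620: {OC_FAMILIES: 1, HBOC_FAMILIES: 0, SPORADIC: 15, SEQ_CONTROLS: 1, GENO_CONTROLS: 0},
    RAD51D_694: {OC_FAMILIES: 0, HBOC_FAMILIES: 0, SPORADIC: 1, SEQ_CONTROLS: 0, GENO_CONTROLS: 0},
}

#: nine physical persons were recruited into two different case groups
N_DUPLICATE_MEMBERSHIPS = 9


def study_cohort_spec(seed: int = 0) -> CohortSpec:
    """The replication-phase cohort: group sizes, counting units,
    carrier counts and duplicate recruitment."""
    return CohortSpec(
        groups=(
            GroupSpec(OC_FAMILIES, Role.CASE, CountingUnit.FAMILY, 44, 49),
            GroupSpec(HBOC_FAMILIES, Role.CASE, CountingUnit.FAMILY, 56, 56),
            GroupSpec(SPORADIC, Role.CASE, CountingUnit.PARTICIPANT, 438, 438),
            GroupSpec(SEQ_CONTROLS, Role.CONTROL, CountingUnit.PARTICIPANT, 1025, 1025),
            GroupSpec(GENO_CONTROLS, Role.CONTROL, CountingUnit.PARTICIPANT, 8493, 8493),
        ),
        carrier_counts=CARRIER_COUNTS,
        n_duplicate_memberships=N_DUPLICATE_MEMBERSHIPS,
        seed=seed,
    )


def replication_pairs() -> list[tuple[str, str]]:
    """Pairwise comparisons reported in the replication phase: each
    cancer group against the sequencing-based control series."""
    return [
        (OC_FAMILIES, SEQ_CONTROLS),
        (HBOC_FAMILIES, SEQ_CONTROLS),
        (SPORADIC, SEQ_CONTROLS),
    ]


def permutation_tests() -> tuple[PermutationTest, ...]:
    """The five observed comparisons re-examined by the permutation study."""
    cancer = (OC_FAMILIES, HBOC_FAMILIES, SPORADIC)
    both_controls = (SEQ_CONTROLS, GENO_CONTROLS)
    return (
        PermutationTest("all_cases_vs_seq_controls", VARIANT_IDS, cancer, (SEQ_CONTROLS,)),
        PermutationTest("oc_families_vs_seq_controls", VARIANT_IDS, (OC_FAMILIES,), (SEQ_CONTROLS,)),
        PermutationTest(
            "all_families_vs_seq_controls",
            VARIANT_IDS,
            (OC_FAMILIES, HBOC_FAMILIES),
            (SEQ_CONTROLS,),
        ),
        PermutationTest("c620_all_cases_vs_all_controls", (RAD51D_620,), cancer, both_controls),
        PermutationTest(
            "c620_families_vs_all_controls",
            (RAD51D_620,),
            (OC_FAMILIES, HBOC_FAMILIES),
            both_controls,
        ),
    )


# representative tumour VAFs for the reported LOH state vocabulary
_STATE_VAF = {"heterozygous": 0.50, "partial": 0.75, "complete": 0.95}
_FF = Preservation.FRESH_FROZEN
_PE = Preservation.FFPE


def loh_observations() -> list[LOHObservation]:
    """Reported tumour LOH states encoded as synthetic allele fractions.

    Rows follow the published per-carrier states (fresh-frozen and
    FFPE readouts), with tumour VAFs set to representative values per
    state and a heterozygous germline VAF of 0.5.
    """
    rows = [
        ("PT0094", RAD51C_414, "ascites", _FF, "partial"),
        ("PT0124", RAD51C_705, "right_ovary", _FF, "partial"),
        ("PT0125", RAD51C_705, "left_ovary", _FF, "complete"),
        ("PT0126", RAD51C_705, "right_ovary", _FF, "heterozygous"),
        ("PT0058", RAD51D_137, "alternative_tissue", _FF, "heterozygous"),
        ("PT0058", RAD51D_137, "right_ovary", _PE, "partial"),
        ("PT0145", RAD51D_137, "right_ovary", _FF, "partial"),
        ("PT0080", RAD51D_620, "omentum", _FF, "partial"),
        ("PT0071", RAD51D_620, "right_ovary", _FF, "partial"),
        ("PT0071", RAD51D_620, "right_ovary", _PE, "partial"),
        ("PT0059", RAD51D_620, "ovary", _FF, "complete"),
        ("PT0065", RAD51D_620, "ovary", _FF, "heterozygous"),
        ("PT0075", RAD51D_620, "right_ovary", _FF, "partial"),
        ("PT0075", RAD51D_620, "right_ovary", _PE, "complete"),
        ("PT0076", RAD51D_620, "right_ovary", _PE, "complete"),
        ("PT0076", RAD51D_620, "left_ovary", _PE, "partial"),
        ("PT0077", RAD51D_620, "right_ovary", _PE, "complete"),
        ("PT0077", RAD51D_620, "left_ovary", _PE, "complete"),
        ("PT0074", RAD51D_620, "right_ovary", _FF, "partial"),
        ("PT0144", RAD51D_620, "alternative_tissue", _FF, "heterozygous"),
    ]
    return [
        LOHObservation(
            carrier_id=cid,
            variant_id=vid,
            tissue=tissue,
            preservation=pres,
            normal_vaf=0.5,
            tumour_vaf=_STATE_VAF[state],
            tumour_depth=200,
        )
        for cid, vid, tissue, pres, state in rows
    ]
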