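"""Domain types shared by every analysis stage.

The package models a founder-population case-control study of rare
germline variants: an annotated variant panel, per-sample genotype
calls, the recruitment structure (study groups, families, duplicate
recruitment), and per-group carrier counts.

Missing values are represented as ``None`` throughout and are distinct
from zero: a variant absent from a reference frequency database has
``maf_reference is None``, never ``0.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping


class Consequence(str, Enum):
    """Coding consequence of a germline variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    SILENT = "silent"
    INTRONIC = "intronic"
    OTHER = "other"


#: Consequences treated as loss-of-function for prioritization.
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)


class ClinicalClass(str, Enum):
    """ClinVar / ACMG clinical classification."""

    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    CONFLICTING = "conflicting"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    NOT_REPORTED = "not_reported"


class PredictorLabel(str, Enum):
    """Categorical verdict emitted by an in-silico predictor."""

    CONSERVED = "conserved"
    NOT_CONSERVED = "not_conserved"
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    AFFECTING_SPLICING = "affecting_splicing"
    NOT_AFFECTING = "not_affecting"


#: Conservation predictors (nucleotide-level).
CONSERVATION_TOOLS = ("GERP", "PhyloP", "PhastCons")
#: Protein/ensemble damage predictors.
DAMAGE_TOOLS = ("REVEL", "MetaLR", "MetaSVM", "CONDEL", "PROVEAN", "CADD_phred")
#: Splice predictors with numeric consensus scores.
SPLICE_SCORE_TOOLS = ("dbscSNV_ADA", "dbscSNV_RF")
#: Splice predictors that only emit a categorical verdict.
SPLICE_CLASS_TOOLS = ("MaxEntScan_class", "HSF_class")

ALL_TOOLS = CONSERVATION_TOOLS + DAMAGE_TOOLS + SPLICE_SCORE_TOOLS + SPLICE_CLASS_TOOLS

_PASS_LABELS = {
    PredictorLabel.CONSERVED,
    PredictorLabel.DAMAGING,
    PredictorLabel.PATHOGENIC,
    PredictorLabel.AFFECTING_SPLICING,
}


@dataclass(frozen=True)
class PredictorValue:
    """Score and/or categorical label from a single in-silico tool.

    Either field may be missing; a tool with both fields ``None`` is
    treated as not run for this variant.
    """

    score: float | None = None
    label: PredictorLabel | None = None

    @property
    def missing(self) -> bool:
        return self.score is None and self.label is None


@dataclass(frozen=True)
class PredictorPanel:
    """In-silico predictor results for one variant.

    MaxEntScan and HSF are categorical only; providing a numeric score
    for either raises at validation. A fully missing panel is legal
    (e.g. protein-level tools are not applicable to nonsense variants).
    """

    entries: Mapping[str, PredictorValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool in self.entries:
            if tool not in ALL_TOOLS:
                raise ValueError(f"unknown predictor tool: {tool!r}")
        for tool in SPLICE_CLASS_TOOLS:
            entry = self.entries.get(tool)
            if entry is not None and entry.score is not None:
                raise ValueError(f"{tool} is categorical only, got a score")

    def get(self, tool: str) -> PredictorValue:
        return self.entries.get(tool, PredictorValue())

    def label_passes(self, tool: str) -> bool | None:
        """True/False for a categorical verdict, None when no label."""
        label = self.get(tool).label
        if label is None:
            return None
        return label in _PASS_LABELS


@dataclass(frozen=True)
class AnnotatedVariant:
    """One germline variant with annotation used for prioritization.

    ``variant_id`` is "GENE:c.notation" (e.g. ``RAD51C:c.414G>C``);
    ``genomic_change`` is the GRCh37 g. string, kept verbatim.
    ``maf_reference`` is the reference-population allele frequency
    (gnomAD non-cancer NFE in the packaged panel); ``None`` means the
    variant is absent from the reference database.
    """

    variant_id: str
    gene: str
    genomic_change: str
    protein_change: str
    consequence: Consequence
    maf_reference: float | None
    predictor_panel: PredictorPanel = field(default_factory=PredictorPanel)
    clinvar_class: ClinicalClass = ClinicalClass.NOT_REPORTED
    acmg_class: ClinicalClass = ClinicalClass.NOT_REPORTED

    def __post_init__(self) -> None:
        if self.maf_reference is not None and not 0.0 <= self.maf_reference <= 1.0:
            raise ValueError(
                f"{self.variant_id}: maf_reference {self.maf_reference} outside [0, 1]"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x variant sequencing observation."""

    sample_id: str
    variant_id: str
    depth: int
    vaf: float
    base_quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")


class Role(str, Enum):
    CASE = "case"
    CONTROL = "control"


class CountingUnit(str, Enum):
    PARTICIPANT = "participant"
    FAMILY = "family"


@dataclass(frozen=True)
class Participant:
    """A physical study participant.

    ``group_memberships`` with more than one entry encodes duplicate
    recruitment of the same person into several study groups.
    """

    participant_id: str
    group_memberships: frozenset[str]
    role: Role
    family_id: str = ""
    is_index: bool = False

    def __post_init__(self) -> None:
        if not self.group_memberships:
            raise ValueError(f"{self.participant_id}: at least one group membership required")


@dataclass(frozen=True)
class StudyGroup:
    """A recruitment group with its carrier-frequency denominator.

    ``counting_unit`` decides the denominator: familial groups count
    families (``n_units``), sporadic/control groups count participants.
    """

    name: str
    role: Role
    counting_unit: CountingUnit
    n_units: int
    n_participants: int

    def __post_init__(self) -> None:
        if self.n_units <= 0 or self.n_participants <= 0:
            raise ValueError(f"group {self.name}: sizes must be positive")
        if self.n_units > self.n_participants:
            raise ValueError(
                f"group {self.name}: n_units ({self.n_units}) exceeds "
                f"n_participants ({self.n_participants})"
            )
        if (
            self.counting_unit is CountingUnit.PARTICIPANT
            and self.n_units != self.n_participants
        ):
            raise ValueError(
                f"group {self.name}: participant-counted groups need n_units == n_participants"
            )


class CarrierTable:
    """Carrier counts per (group, variant).

    Counts are stored as integers; frequencies and percentages are
    always derived downstream. Absent keys count as zero.
    """

    def __init__(self, counts: Mapping[tuple[str, str], int] | None = None):
        self._counts: dict[tuple[str, str], int] = {}
        if counts:
            for key, value in counts.items():
                self.set_count(key[0], key[1], value)

    def set_count(self, group: str, variant_id: str, count: int) -> None:
        count = int(count)
        if count < 0:
            raise ValueError(f"carrier count for ({group}, {variant_id}) is negative")
        self._counts[(group, variant_id)] = count

    def count(self, group: str, variant_id: str) -> int:
        return self._counts.get((group, variant_id), 0)

    def items(self) -> Iterable[tuple[tuple[str, str], int]]:
        return self._counts.items()

    def variants(self) -> list[str]:
        return sorted({v for (_, v) in self._counts})

    def groups(self) -> list[str]:
        return sorted({g for (g, _) in self._counts})

    def total(self, variant_id: str) -> int:
        return sum(c for (g, v), c in self._counts.items() if v == variant_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CarrierTable):
            return NotImplemented
        return {k: v for k, v in self._counts.items() if v} == {
            k: v for k, v in other._counts.items() if v
        }

    def __repr__(self) -> str:
        return f"CarrierTable({self._counts!r})"


@dataclass(frozen=True)
class Cohort:
    """Validated bundle of groups, participants and carrier counts."""

    groups: tuple[StudyGroup, ...]
    participants: tuple[Participant, ...]
    carrier_table: CarrierTable

    def group(self, name: str) -> StudyGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown study group: {name!r}")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]


def validate_cohort(
    groups: Iterable[StudyGroup],
    participants: Iterable[Participant],
    carrier_table: CarrierTable,
) -> Cohort:
    """Cross-validate the three cohort tables and bundle them.

    Checks: memberships refer to declared groups, per-group membership
    counts match the declared group sizes, roles are consistent with the
    group role, and carrier counts never exceed the group denominator.
    """
    groups = tuple(groups)
    participants = tuple(participants)
    by_name = {g.name: g for g in groups}
    if len(by_name) != len(groups):
        raise ValueError("duplicate study group names")

    membership_counts: dict[str, int] = {name: 0 for name in by_name}
    seen_ids: set[str] = set()
    for p in participants:
        if p.participant_id in seen_ids:
            raise ValueError(f"duplicate participant_id {p.participant_id!r}")
        seen_ids.add(p.participant_id)
        for g in p.group_memberships:
            if g not in by_name:
                raise ValueError(f"{p.participant_id}: unknown group {g!r}")
            if by_name[g].role is not p.role:
                raise ValueError(
                    f"{p.participant_id}: role {p.role.value} inconsistent with group {g!r}"
                )
            membership_counts[g] += 1

    if participants:
        for name, group in by_name.items():
            if membership_counts[name] != group.n_participants:
                raise ValueError(
                    f"group {name}: {membership_counts[name]} member(s) found, "
                    f"declared n_participants is {group.n_participants}"
                )

    for (gname, variant_id), count in carrier_table.items():
        if gname not in by_name:
            raise ValueError(f"carrier table references unknown group {gname!r}")
        if count > by_name[gname].n_units:
            raise ValueError(
                f"carrier count {count} for ({gname}, {variant_id}) exceeds "
                f"group denominator {by_name[gname].n_units}"
            )
        if count > 0 and not participants:
            raise ValueError("nonzero carrier counts with an empty participant list")

    return Cohort(groups=groups, participants=participants, carrier_table=carrier_table)
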