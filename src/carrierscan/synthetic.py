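"""Synthetic cohorts, variant panels, LOH observations and clinical tables.

The study data this package analyses live in restricted biobanks, so
every stage is exercised on synthetic inputs that reproduce the
statistical structure the analysis assumes: study groups with family
or participant counting units, duplicate recruitment of the same
person into two case groups, exact or probabilistic carrier placement,
decoy variants with predictor scores drawn below (or straddling) the
prioritization thresholds, purity-mixed tumour allele fractions with
binomial sequencing noise, and truncated-normal clinical ages.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clinical import ClinicalRecord, VitalStatus
from .loh import LOHObservation, LOHState, Preservation, expected_variant_fraction
from .types import (
    AnnotatedVariant,
    CarrierTable,
    ClinicalClass,
    Cohort,
    Consequence,
    CountingUnit,
    Participant,
    PredictorLabel,
    PredictorPanel,
    PredictorValue,
    Role,
    StudyGroup,
    validate_cohort,
)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    role: Role
    counting_unit: CountingUnit
    n_units: int
    n_participants: int


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    Exactly one of ``carrier_counts`` (exact without-replacement
    placement, deterministic counts) or ``carrier_probs`` (independent
    per-unit Bernoulli draws) drives carrier placement per
    (variant, group). ``n_duplicate_memberships`` physical persons are
    each given a second membership in another case group.
    """

    groups: tuple[GroupSpec, ...]
    carrier_counts: dict[str, dict[str, int]] | None = None
    carrier_probs: dict[str, dict[str, float]] | None = None
    n_duplicate_memberships: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.carrier_counts is not None and self.carrier_probs is not None:
            raise ValueError("give carrier_counts or carrier_probs, not both")


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Build a validated cohort from a spec.

    In exact-count mode carriers are placed on single-membership
    participants (one per counting unit, units disjoint across
    variants), so the resulting carrier table reproduces the spec with
    probability 1 and no carrier is double-counted across groups.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    group_by_name = {g.name: g for g in spec.groups}

    # one slot per declared membership
    slot_person: dict[tuple[str, int], dict] = {}
    for g in spec.groups:
        if g.counting_unit is CountingUnit.FAMILY:
            family_of_slot = list(range(g.n_units)) + [
                int(x) for x in rng.integers(0, g.n_units, size=g.n_participants - g.n_units)
            ]
        else:
            family_of_slot = [None] * g.n_participants
        for j in range(g.n_participants):
            fam = family_of_slot[j]
            slot_person[(g.name, j)] = {
                "groups": {g.name},
                "family": f"{g.name}-F{fam:03d}" if fam is not None else "",
            }

    # merge duplicate memberships across case groups
    case_groups = [g for g in spec.groups if g.role is Role.CASE]
    if spec.n_duplicate_memberships:
        if len(case_groups) < 2:
            raise ValueError("duplicate memberships need at least two case groups")
        used: set[tuple[str, int]] = set()
        merged: list[tuple[tuple[str, int], tuple[str, int]]] = []
        for _ in range(spec.n_duplicate_memberships):
            gi, gj = rng.choice(len(case_groups), size=2, replace=False)
            ga, gb = case_groups[gi], case_groups[gj]
            free_a = [(ga.name, j) for j in range(ga.n_participants) if (ga.name, j) not in used]
            free_b = [(gb.name, j) for j in range(gb.n_participants) if (gb.name, j) not in used]
            if not free_a or not free_b:
                raise ValueError("infeasible spec: not enough pairable participants")
            sa = free_a[int(rng.integers(len(free_a)))]
            sb = free_b[int(rng.integers(len(free_b)))]
            used.update({sa, sb})
            merged.append((sa, sb))
        for sa, sb in merged:
            person = slot_person[sa]
            person["groups"] = person["groups"] | slot_person[sb]["groups"]
            if not person["family"]:
                person["family"] = slot_person[sb]["family"]
            slot_person[sb] = person

    # unique physical persons, stable order
    persons: list[dict] = []
    seen: set[int] = set()
    for key in sorted(slot_person):
        person = slot_person[key]
        if id(person) not in seen:
            seen.add(id(person))
            persons.append(person)
    for i, person in enumerate(persons):
        person["id"] = f"P{i:05d}"

    # carrier placement
    table = CarrierTable()
    carrier_of: dict[str, str] = {}  # person id -> variant
    if spec.carrier_counts is not None:
        used_units: dict[str, set] = {g.name: set() for g in spec.groups}
        for variant_id in sorted(spec.carrier_counts):
            for gname in sorted(spec.carrier_counts[variant_id]):
                count = spec.carrier_counts[variant_id][gname]
                if count == 0:
                    table.set_count(gname, variant_id, 0)
                    continue
                group = group_by_name[gname]
                # units whose members all belong only to this group and carry nothing yet
                unit_members: dict[str, list[dict]] = {}
                for person in persons:
                    if person["groups"] != {gname} or person["id"] in carrier_of:
                        continue
                    unit = (
                        person["family"]
                        if group.counting_unit is CountingUnit.FAMILY
                        else person["id"]
                    )
                    unit_members.setdefault(unit, []).append(person)
                eligible = sorted(set(unit_members) - used_units[gname])
                if count > len(eligible):
                    raise ValueError(
                        f"infeasible spec: {count} carriers requested for "
                        f"({gname}, {variant_id}) but only {len(eligible)} free units"
                    )
                chosen = rng.choice(len(eligible), size=count, replace=False)
                for ci in chosen:
                    unit = eligible[int(ci)]
                    used_units[gname].add(unit)
                    carrier_of[unit_members[unit][0]["id"]] = variant_id
                table.set_count(gname, variant_id, count)
    elif spec.carrier_probs is not None:
        for variant_id in sorted(spec.carrier_probs):
            for gname in sorted(spec.carrier_probs[variant_id]):
                prob = spec.carrier_probs[variant_id][gname]
                group = group_by_name[gname]
                units: dict[str, list[dict]] = {}
                for person in persons:
                    if gname not in person["groups"]:
                        continue
                    unit = (
                        person["family"]
                        if group.counting_unit is CountingUnit.FAMILY
                        else person["id"]
                    )
                    units.setdefault(unit, []).append(person)
                hits = 0
                for unit in sorted(units):
                    if rng.random() < prob:
                        hits += 1
                        carrier_of.setdefault(units[unit][0]["id"], variant_id)
                table.set_count(gname, variant_id, hits)

    participants = tuple(
        Participant(
            participant_id=person["id"],
            group_memberships=frozenset(person["groups"]),
            role=group_by_name[next(iter(person["groups"]))].role,
            family_id=person["family"],
        )
        for person in persons
    )
    groups = tuple(
        StudyGroup(
            name=g.name,
            role=g.role,
            counting_unit=g.counting_unit,
            n_units=g.n_units,
            n_participants=g.n_participants,
        )
        for g in spec.groups
    )
    return validate_cohort(groups, participants, table)


# strictly-below-threshold sampling ranges for decoy predictor scores;
# PROVEAN's range is benign under the tool-conventional direction (<= -2.5 damaging)
_SUBTHRESHOLD_RANGES = {
    "GERP": (-5.0, 1.9),
    "PhyloP": (-2.0, 0.19),
    "PhastCons": (0.0, 0.39),
    "REVEL": (0.0, 0.39),
    "MetaLR": (0.0, 0.39),
    "MetaSVM": (-2.0, -0.01),
    "CONDEL": (0.0, 0.39),
    "CADD_phred": (0.0, 19.9),
    "PROVEAN": (-2.4, 4.0),
    "dbscSNV_ADA": (0.0, 0.39),
    "dbscSNV_RF": (0.0, 0.39),
}

_STRADDLING_RANGES = {
    "GERP": (-5.0, 6.0),
    "PhyloP": (-2.0, 2.0),
    "PhastCons": (0.0, 1.0),
    "REVEL": (0.0, 1.0),
    "MetaLR": (0.0, 1.0),
    "MetaSVM": (-2.0, 2.0),
    "CONDEL": (0.0, 1.0),
    "CADD_phred": (0.0, 40.0),
    "PROVEAN": (-6.0, 4.0),
    "dbscSNV_ADA": (0.0, 1.0),
    "dbscSNV_RF": (0.0, 1.0),
}


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic variant panel: planted true candidates
    plus decoys drawn from benign score distributions.

    ``decoy_mode="subthreshold"`` draws every decoy score strictly
    below its prioritization threshold, so filtering recovers exactly
    the planted set; ``"straddling"`` draws over ranges crossing the
    thresholds, so some decoys survive by design. Decoy MAFs are a
    mixture with mass above and below the 0.01 rarity cut-off plus a
    fraction missing from the reference database entirely.
    """

    planted: tuple[AnnotatedVariant, ...] = ()
    n_decoys: int = 200
    decoy_mode: str = "subthreshold"
    decoy_maf_above_frac: float = 0.4
    decoy_maf_missing_frac: float = 0.1
    decoy_consequences: tuple[tuple[Consequence, float], ...] = (
        (Consequence.MISSENSE, 0.6),
        (Consequence.SILENT, 0.2),
        (Consequence.INTRONIC, 0.2),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoy_mode not in {"subthreshold", "straddling"}:
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")


def generate_variant_panel(spec: PanelSpec, seed: int | None = None) -> list[AnnotatedVariant]:
    """Planted candidates plus ``n_decoys`` decoys, shuffled deterministically."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ranges = (
        _SUBTHRESHOLD_RANGES if spec.decoy_mode == "subthreshold" else _STRADDLING_RANGES
    )
    consequences, weights = zip(*spec.decoy_consequences)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    benign_classes = [
        ClinicalClass.BENIGN,
        ClinicalClass.LIKELY_BENIGN,
        ClinicalClass.VUS,
        ClinicalClass.NOT_REPORTED,
    ]

    decoys: list[AnnotatedVariant] = []
    for i in range(spec.n_decoys):
        gene = "RAD51C" if i % 2 == 0 else "RAD51D"
        consequence = consequences[int(rng.choice(len(consequences), p=weights))]
        u = rng.random()
        if u < spec.decoy_maf_missing_frac:
            maf = None
        elif u < spec.decoy_maf_missing_frac + spec.decoy_maf_above_frac:
            maf = float(rng.uniform(0.01, 0.3))
        else:
            maf = float(rng.uniform(0.0, 0.009))
        entries = {
            tool: PredictorValue(score=float(rng.uniform(lo, hi)))
            for tool, (lo, hi) in ranges.items()
        }
        entries["MaxEntScan_class"] = PredictorValue(label=PredictorLabel.NOT_AFFECTING)
        entries["HSF_class"] = PredictorValue(label=PredictorLabel.NOT_AFFECTING)
        decoys.append(
            AnnotatedVariant(
                variant_id=f"{gene}:c.{9000 + i}A>G",
                gene=gene,
                genomic_change=f"g.{50_000_000 + i}A>G",
                protein_change="",
                consequence=consequence,
                maf_reference=maf,
                predictor_panel=PredictorPanel(entries=entries),
                clinvar_class=benign_classes[int(rng.integers(len(benign_classes)))],
                acmg_class=benign_classes[int(rng.integers(len(benign_classes)))],
            )
        )

    panel = list(spec.planted) + decoys
    order = rng.permutation(len(panel))
    return [panel[int(i)] for i in order]


def generate_loh_observations(
    purities,
    states,
    depth: int = 100,
    normal_depth: int = 100,
    seed: int = 0,
    preservation: Preservation = Preservation.FRESH_FROZEN,
) -> list[LOHObservation]:
    """Purity-mixed tumour allele fractions with binomial read noise.

    For each (purity, state) pair, the tumour VAF is a binomial draw at
    ``depth`` around the closed-form expectation (1/(2-p) for
    wild-type loss, 0.5 for retained heterozygosity), and the normal
    VAF a binomial draw around 0.5.
    """
    rng = np.random.default_rng(seed)
    observations = []
    for i, (purity, state) in enumerate(zip(purities, states)):
        state = LOHState(state)
        expected = expected_variant_fraction(purity, state)
        tumour_vaf = rng.binomial(depth, expected) / depth if depth > 0 else expected
        normal_vaf = rng.binomial(normal_depth, 0.5) / normal_depth if normal_depth > 0 else 0.5
        observations.append(
            LOHObservation(
                carrier_id=f"SIM{i:04d}",
                variant_id="RAD51D:c.620C>T",
                tissue="ovary",
                preservation=preservation,
                normal_vaf=float(normal_vaf),
                tumour_vaf=float(tumour_vaf),
                tumour_depth=depth,
            )
        )
    return observations


def generate_clinical_table(
    n: int,
    age_mean: float,
    age_sd: float,
    seed: int = 0,
    variant_id: str = "RAD51D:c.620C>T",
    survival_mean: float | None = None,
    survival_sd: float | None = None,
    age_bounds: tuple[float, float] = (25.0, 90.0),
) -> list[ClinicalRecord]:
    """Truncated-normal ages at diagnosis (resampled into bounds) and
    optional non-negative survival months."""
    rng = np.random.default_rng(seed)
    lo, hi = age_bounds
    records = []
    for i in range(n):
        age = rng.normal(age_mean, age_sd)
        while not lo <= age <= hi:
            age = rng.normal(age_mean, age_sd)
        survival = None
        if survival_mean is not None:
            survival = max(0.0, rng.normal(survival_mean, survival_sd or survival_mean / 2))
        records.append(
            ClinicalRecord(
                carrier_id=f"CL{i:04d}",
                variant_id=variant_id,
                age_at_diagnosis=float(age),
                survival_months=survival,
                vital_status=VitalStatus.MISSING,
                histopathology="HGSC",
            )
        )
    return records


def permutation_null_calibration(
    n_replicates: int = 200,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Replicate permutation studies on a null cohort; return per-test
    rejection rates.

    The calibration design mirrors the study structure at a reduced
    scale: three case groups (50 participants each), two control
    groups (100 each), two variants with 12 and 8 carriers allocated
    uniformly over the pooled roster (the null), and five comparisons
    ranging from one case group vs one control group to all cases vs
    all controls. Each replicate draws a fresh uniform allocation as
    the "observed" data and runs a full permutation study on it; the
    returned vector is the fraction of replicates in which each test's
    permutation p-value falls below ``alpha``. Under the null this
    should sit near ``alpha`` (slightly below, since the carrier
    statistic is discrete).
    """
    from .permutation import (
        PermutationConfig,
        PermutationTest,
        permute_once,
        pool_participants,
        run_permutation_study,
    )

    spec = CohortSpec(
        groups=(
            GroupSpec("caseA", Role.CASE, CountingUnit.PARTICIPANT, 50, 50),
            GroupSpec("caseB", Role.CASE, CountingUnit.PARTICIPANT, 50, 50),
            GroupSpec("caseC", Role.CASE, CountingUnit.PARTICIPANT, 50, 50),
            GroupSpec("ctrlA", Role.CONTROL, CountingUnit.PARTICIPANT, 100, 100),
            GroupSpec("ctrlB", Role.CONTROL, CountingUnit.PARTICIPANT, 100, 100),
        ),
        carrier_counts={"v1": {}, "v2": {}},
        seed=seed,
    )
    cohort = generate_cohort(spec)
    roster = pool_participants(cohort)
    totals = {"v1": 12, "v2": 8}
    tests = (
        PermutationTest("all_cases_vs_ctrlA", ("v1", "v2"), ("caseA", "caseB", "caseC"), ("ctrlA",)),
        PermutationTest("caseA_vs_ctrlA", ("v1", "v2"), ("caseA",), ("ctrlA",)),
        PermutationTest("caseAB_vs_ctrlA", ("v1", "v2"), ("caseA", "caseB"), ("ctrlA",)),
        PermutationTest("v1_all_cases_vs_all_ctrls", ("v1",), ("caseA", "caseB", "caseC"), ("ctrlA", "ctrlB")),
        PermutationTest("v1_caseAB_vs_all_ctrls", ("v1",), ("caseA", "caseB"), ("ctrlA", "ctrlB")),
    )

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    rejections = np.zeros(len(tests))
    for child in children:
        rng = np.random.Generator(np.random.PCG64(child))
        observed = permute_once(roster, totals, rng)
        cfg = PermutationConfig(
            seed=int(rng.integers(2**31 - 1)),
            tests=tests,
            n_permutations=n_permutations,
            alpha=alpha,
        )
        null_cohort = Cohort(
            groups=cohort.groups, participants=cohort.participants, carrier_table=observed
        )
        result = run_permutation_study(null_cohort, None, cfg)
        rejections += np.asarray(result.perm_p) < alpha
    return rejections / n_replicates


def enrichment_detection_rate(
    n_case: int,
    n_control: int,
    p_case: float,
    p_control: float,
    n_sims: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts where the carrier-enrichment
    Fisher test is significant; carriers drawn binomially per arm."""
    from .stats import fisher_exact_two_sided

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = int(rng.binomial(n_case, p_case))
        c = int(rng.binomial(n_control, p_control))
        p = fisher_exact_two_sided(((a, n_case - a), (c, n_control - c)))
        if p < alpha:
            hits += 1
    return hits / n_sims
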