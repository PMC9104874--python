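"""Permutation study of carrier enrichment across study groups.

Recruitment of the same person into more than one study group breaks
the independence that a naive Fisher test assumes. The permutation
study addresses this: the observed carriers of each variant are
randomly re-allocated across the pooled, de-duplicated roster of
physical participants; group counts are recomputed through the actual
membership structure (a duplicated participant propagates carrier
status to every group they belong to, and a carrier landing anywhere
in a family marks that family once); and each comparison's naive
Fisher p is recomputed on every permuted table. This yields per-test
permutation p-values, the family-wise error rate of running all k
naive tests at a given alpha, and the probability that all k tests
would be simultaneously significant by chance.

Permutation p-values use the add-one estimator (r + 1) / (B + 1), so
they are never reported as zero; with exhaustive enumeration the exact
tail probability r / n_allocations is returned instead (the observed
allocation is itself a member of the enumeration, so r >= 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .stats import fisher_exact_two_sided
from .types import CarrierTable, Cohort, CountingUnit, StudyGroup

_TIE_REL = 1e-12


@dataclass(frozen=True)
class PermutationTest:
    """One observed comparison: carriers of the listed variants, summed
    over the case groups, versus the control groups."""

    name: str
    variant_ids: tuple[str, ...]
    case_groups: tuple[str, ...]
    control_groups: tuple[str, ...]


@dataclass(frozen=True)
class PermutationConfig:
    seed: int
    tests: tuple[PermutationTest, ...]
    n_permutations: int = 5000
    alpha: float = 0.05
    allocation_unit: str = "carrier"  # or "variant_block"
    statistic: str = "fisher_p"  # or "rate_diff"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.allocation_unit not in {"carrier", "variant_block"}:
            raise ValueError(f"unknown allocation_unit {self.allocation_unit!r}")
        if self.statistic not in {"fisher_p", "rate_diff"}:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if not self.tests:
            raise ValueError("test set must be non-empty")


@dataclass
class PooledRoster:
    """De-duplicated roster: each physical participant exactly once.

    ``unit_index[group]`` maps pool position -> counting-unit index
    within the group (family index for family-counted groups, a unique
    per-participant index otherwise), or -1 for non-members.
    """

    participant_ids: list[str]
    groups: tuple[StudyGroup, ...]
    unit_index: dict[str, np.ndarray]

    @property
    def size(self) -> int:
        return len(self.participant_ids)

    def group_count(self, group: str, carrier_positions: np.ndarray) -> int:
        """Number of distinct carrier-positive units of a group."""
        units = self.unit_index[group][carrier_positions]
        units = units[units >= 0]
        if units.size == 0:
            return 0
        return int(np.unique(units).size)


def pool_participants(cohort: Cohort) -> PooledRoster:
    """Collapse the cohort to one entry per physical participant.

    Group memberships are retained as tags; a participant recruited to
    two groups contributes to both groups' counts but is permuted as a
    single person. In family-counted groups, participants sharing a
    family_id share a counting unit; participants without a family_id
    each form their own unit.
    """
    ids = [p.participant_id for p in cohort.participants]
    n = len(ids)
    unit_index: dict[str, np.ndarray] = {}
    for group in cohort.groups:
        idx = np.full(n, -1, dtype=np.int64)
        unit_of: dict[str, int] = {}
        for pos, p in enumerate(cohort.participants):
            if group.name not in p.group_memberships:
                continue
            if group.counting_unit is CountingUnit.FAMILY and p.family_id:
                key = f"fam:{p.family_id}"
            else:
                key = f"ind:{p.participant_id}"
            idx[pos] = unit_of.setdefault(key, len(unit_of))
        unit_index[group.name] = idx
    return PooledRoster(participant_ids=ids, groups=cohort.groups, unit_index=unit_index)


def permute_once(
    roster: PooledRoster,
    carrier_totals: dict[str, int],
    rng: np.random.Generator,
    allocation_unit: str = "carrier",
) -> CarrierTable:
    """Randomly re-allocate each variant's carriers over the pool.

    ``carrier``: each variant's carriers are a uniform simple random
    sample without replacement from the pool, independent across
    variants. ``variant_block``: the whole carrier set of a variant is
    placed inside one group chosen with probability proportional to
    membership size, then sampled uniformly within that group.
    """
    table = CarrierTable()
    n = roster.size
    group_members = None
    if allocation_unit == "variant_block":
        group_members = {
            g.name: np.flatnonzero(roster.unit_index[g.name] >= 0) for g in roster.groups
        }
        sizes = np.array([group_members[g.name].size for g in roster.groups], dtype=float)
        probs = sizes / sizes.sum()

    for variant_id in sorted(carrier_totals):
        m = carrier_totals[variant_id]
        if m > n:
            raise ValueError(f"{variant_id}: {m} carriers exceed pool size {n}")
        if m == 0:
            continue
        if allocation_unit == "carrier":
            positions = rng.choice(n, size=m, replace=False)
        else:
            gi = rng.choice(len(roster.groups), p=probs)
            members = group_members[roster.groups[gi].name]
            if m > members.size:
                raise ValueError(f"{variant_id}: block of {m} exceeds group size")
            positions = members[rng.choice(members.size, size=m, replace=False)]
        for group in roster.groups:
            count = roster.group_count(group.name, positions)
            if count:
                table.set_count(group.name, variant_id, count)
    return table


def _test_margins(cohort: Cohort, test: PermutationTest) -> tuple[int, int]:
    n_case = sum(cohort.group(g).n_units for g in test.case_groups)
    n_ctrl = sum(cohort.group(g).n_units for g in test.control_groups)
    return n_case, n_ctrl


def _test_counts(table: CarrierTable, test: PermutationTest) -> tuple[int, int]:
    a = sum(table.count(g, v) for g in test.case_groups for v in test.variant_ids)
    c = sum(table.count(g, v) for g in test.control_groups for v in test.variant_ids)
    return a, c


def _test_statistic(
    a: int, c: int, n_case: int, n_ctrl: int, statistic: str
) -> float:
    if statistic == "fisher_p":
        return fisher_exact_two_sided(((a, n_case - a), (c, n_ctrl - c)))
    return a / n_case - c / n_ctrl  # rate_diff


def _more_extreme(perm_stat: float, obs_stat: float, statistic: str) -> bool:
    if statistic == "fisher_p":  # smaller p is more extreme
        return perm_stat <= obs_stat * (1.0 + _TIE_REL)
    return perm_stat >= obs_stat - abs(obs_stat) * _TIE_REL  # larger diff more extreme


@dataclass
class PermutationResult:
    """All estimates from one permutation study."""

    test_names: list[str]
    observed_naive_p: list[float]
    observed_statistic: list[float]
    perm_p: list[float]
    perm_p_se: list[float]
    rejection_rate_at_alpha: list[float]
    fwer_estimate: float
    fwer_se: float
    joint_significance: float
    joint_se: float
    n_permutations: int
    alpha: float
    seed: int
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)


def _enumerate_allocations(n: int, carrier_totals: dict[str, int], limit: int = 300_000):
    """Yield every distinct joint allocation (cartesian over variants)."""
    variants = sorted(v for v, m in carrier_totals.items() if m > 0)
    total = 1
    for v in variants:
        total *= math.comb(n, carrier_totals[v])
    if total > limit:
        raise ValueError(
            f"exhaustive enumeration of {total} allocations exceeds limit {limit}"
        )
    pools = [
        [np.array(combo, dtype=np.int64) for combo in itertools.combinations(range(n), carrier_totals[v])]
        for v in variants
    ]
    for joint in itertools.product(*pools):
        yield dict(zip(variants, joint))


def run_permutation_study(
    cohort: Cohort, carrier_table: CarrierTable | None, cfg: PermutationConfig
) -> PermutationResult:
    """Run the full permutation study.

    Randomness is driven by one seed; each permutation draws from its
    own counter-derived substream, so results do not depend on
    execution order or parallel scheduling.
    """
    observed = carrier_table if carrier_table is not None else cohort.carrier_table
    roster = pool_participants(cohort)
    carrier_totals = {v: observed.total(v) for v in observed.variants()}
    for test in cfg.tests:
        for v in test.variant_ids:
            carrier_totals.setdefault(v, 0)

    margins = [_test_margins(cohort, t) for t in cfg.tests]
    obs_naive_p: list[float] = []
    obs_stat: list[float] = []
    for test, (n_case, n_ctrl) in zip(cfg.tests, margins):
        a, c = _test_counts(observed, test)
        obs_naive_p.append(_test_statistic(a, c, n_case, n_ctrl, "fisher_p"))
        obs_stat.append(_test_statistic(a, c, n_case, n_ctrl, cfg.statistic))

    k = len(cfg.tests)

    def stats_for(table: CarrierTable) -> tuple[list[float], list[float]]:
        naive, stat = [], []
        for test, (n_case, n_ctrl) in zip(cfg.tests, margins):
            a, c = _test_counts(table, test)
            naive.append(_test_statistic(a, c, n_case, n_ctrl, "fisher_p"))
            stat.append(
                naive[-1]
                if cfg.statistic == "fisher_p"
                else _test_statistic(a, c, n_case, n_ctrl, cfg.statistic)
            )
        return naive, stat

    if cfg.exhaustive:
        naive_rows, stat_rows = [], []
        for allocation in _enumerate_allocations(roster.size, carrier_totals):
            table = CarrierTable()
            for variant_id, positions in allocation.items():
                for group in roster.groups:
                    count = roster.group_count(group.name, positions)
                    if count:
                        table.set_count(group.name, variant_id, count)
            naive, stat = stats_for(table)
            naive_rows.append(naive)
            stat_rows.append(stat)
        b_eff = len(naive_rows)
        perm_p = [
            sum(_more_extreme(row[j], obs_stat[j], cfg.statistic) for row in stat_rows) / b_eff
            for j in range(k)
        ]
    else:
        b_eff = cfg.n_permutations
        streams = np.random.SeedSequence(cfg.seed).spawn(b_eff)
        naive_rows, stat_rows = [], []
        for child in streams:
            rng = np.random.Generator(np.random.PCG64(child))
            table = permute_once(roster, carrier_totals, rng, cfg.allocation_unit)
            naive, stat = stats_for(table)
            naive_rows.append(naive)
            stat_rows.append(stat)
        perm_p = [
            (sum(_more_extreme(row[j], obs_stat[j], cfg.statistic) for row in stat_rows) + 1)
            / (b_eff + 1)
            for j in range(k)
        ]

    naive_matrix = np.asarray(naive_rows, dtype=float)
    rejection = (naive_matrix < cfg.alpha).mean(axis=0)
    fwer = float((naive_matrix.min(axis=1) < cfg.alpha).mean())
    joint = float((naive_matrix < cfg.alpha).all(axis=1).mean())

    def mc_se(p_hat: float) -> float:
        return math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / b_eff)

    return PermutationResult(
        test_names=[t.name for t in cfg.tests],
        observed_naive_p=obs_naive_p,
        observed_statistic=obs_stat,
        perm_p=[float(p) for p in perm_p],
        perm_p_se=[mc_se(float(p)) for p in perm_p],
        rejection_rate_at_alpha=[float(r) for r in rejection],
        fwer_estimate=fwer,
        fwer_se=mc_se(fwer),
        joint_significance=joint,
        joint_se=mc_se(joint),
        n_permutations=b_eff,
        alpha=cfg.alpha,
        seed=cfg.seed,
        exhaustive=cfg.exhaustive,
    )


def estimate_fwer(p_matrix: np.ndarray, alpha: float) -> float:
    """Fraction of permutations in which at least one of k naive tests
    is significant at ``alpha`` (p-value matrix is B x k)."""
    p_matrix = np.asarray(p_matrix, dtype=float)
    if p_matrix.size == 0:
        raise ValueError("empty p-value matrix")
    if p_matrix.ndim == 1:
        p_matrix = p_matrix[:, None]
    return float((p_matrix.min(axis=1) < alpha).mean())
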