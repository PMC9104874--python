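"""Pooling, random re-allocation, permutation p-values and FWER."""

import itertools
from dataclasses import replace
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierscan.permutation import (
    PermutationConfig,
    PermutationTest,
    estimate_fwer,
    permute_once,
    pool_participants,
    run_permutation_study,
)
from carrierscan.stats import fisher_exact_two_sided
from carrierscan.types import (
    CarrierTable,
    Cohort,
    CountingUnit,
    Participant,
    Role,
    StudyGroup,
    validate_cohort,
)


def _flat_cohort(sizes: dict[str, int], n_dup_pairs: int = 0,
                 roles: dict[str, Role] | None = None,
                 carriers: dict[tuple[str, str], int] | None = None) -> Cohort:
    """Participant-counted groups; the first n_dup_pairs persons of the
    first two groups are merged into dual-membership persons."""
    roles = roles or {}
    names = list(sizes)
    participants = []
    counter = 0
    merged = []
    if n_dup_pairs:
        g1, g2 = names[0], names[1]
        for i in range(n_dup_pairs):
            merged.append(
                Participant(f"dup{i}", frozenset({g1, g2}),
                            roles.get(g1, Role.CASE))
            )
    remaining = dict(sizes)
    if n_dup_pairs:
        remaining[names[0]] -= n_dup_pairs
        remaining[names[1]] -= n_dup_pairs
    for name in names:
        for _ in range(remaining[name]):
            participants.append(
                Participant(f"p{counter}", frozenset({name}), roles.get(name, Role.CASE))
            )
            counter += 1
    groups = [
        StudyGroup(name, roles.get(name, Role.CASE), CountingUnit.PARTICIPANT,
                   sizes[name], sizes[name])
        for name in names
    ]
    return validate_cohort(groups, merged + participants, CarrierTable(carriers or {}))


def test_pool_deduplicates_published_arithmetic():
    """9 dual memberships over 10070 memberships pool to 10061 persons."""
    cohort = _flat_cohort({"a": 5000, "b": 5070}, n_dup_pairs=9)
    roster = pool_participants(cohort)
    assert sum(g.n_participants for g in cohort.groups) == 10070
    assert roster.size == 10061


def test_pool_without_duplicates_equals_membership_count():
    cohort = _flat_cohort({"a": 7, "b": 5})
    assert pool_participants(cohort).size == 12


@settings(deadline=None, derandomize=True, max_examples=40)
@given(n_a=st.integers(2, 30), n_b=st.integers(2, 30), dups=st.integers(0, 2))
def test_pool_matches_set_union_oracle(n_a, n_b, dups):
    dups = min(dups, n_a - 1, n_b - 1)
    cohort = _flat_cohort({"a": n_a, "b": n_b}, n_dup_pairs=dups)
    roster = pool_participants(cohort)
    union = {p.participant_id for p in cohort.participants}
    assert roster.size == len(union) == n_a + n_b - dups


def test_permute_zero_carriers_gives_empty_table(rng):
    cohort = _flat_cohort({"a": 4, "b": 4})
    roster = pool_participants(cohort)
    table = permute_once(roster, {"v": 0}, rng)
    assert list(table.items()) == []


def test_permute_conserves_carrier_total(rng):
    cohort = _flat_cohort({"a": 10, "b": 15, "c": 20})
    roster = pool_participants(cohort)
    for _ in range(25):
        table = permute_once(roster, {"v1": 7, "v2": 3}, rng)
        assert sum(table.count(g, "v1") for g in ["a", "b", "c"]) == 7
        assert sum(table.count(g, "v2") for g in ["a", "b", "c"]) == 3


def test_permute_family_dedup(rng):
    """Two carriers landing in one family count that family once."""
    groups = [StudyGroup("fam", Role.CASE, CountingUnit.FAMILY, 1, 2)]
    participants = [
        Participant("p0", frozenset({"fam"}), Role.CASE, family_id="F1"),
        Participant("p1", frozenset({"fam"}), Role.CASE, family_id="F1"),
    ]
    cohort = validate_cohort(groups, participants, CarrierTable())
    roster = pool_participants(cohort)
    table = permute_once(roster, {"v": 2}, rng)
    assert table.count("fam", "v") == 1


def test_permute_deterministic_under_seed():
    cohort = _flat_cohort({"a": 12, "b": 8})
    roster = pool_participants(cohort)
    t1 = permute_once(roster, {"v": 5}, np.random.default_rng(99))
    t2 = permute_once(roster, {"v": 5}, np.random.default_rng(99))
    assert t1 == t2


def test_allocation_is_uniform_over_pairs():
    """Pool of 6 singleton groups, 2 carriers: all C(6,2)=15 pairs
    equally likely (each pair is identified by its group-count pattern)."""
    cohort = _flat_cohort({f"g{i}": 1 for i in range(6)})
    roster = pool_participants(cohort)
    rng = np.random.default_rng(7)
    counts: dict[tuple, int] = {}
    n_draws = 30_000
    for _ in range(n_draws):
        table = permute_once(roster, {"v": 2}, rng)
        key = tuple(sorted(g for (g, _), c in table.items() if c))
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == comb(6, 2)
    expected = n_draws / 15
    se = (n_draws * (1 / 15) * (14 / 15)) ** 0.5
    for observed in counts.values():
        assert abs(observed - expected) <= 3 * se


def test_exhaustive_permutation_matches_full_enumeration():
    """Tiny pool: the exhaustive permutation p equals the directly
    enumerated tail probability over all C(6,2) allocations."""
    cohort = _flat_cohort(
        {"case": 2, "ctrl": 4},
        roles={"case": Role.CASE, "ctrl": Role.CONTROL},
        carriers={("case", "v"): 2},
    )
    test = PermutationTest("t", ("v",), ("case",), ("ctrl",))
    cfg = PermutationConfig(seed=1, tests=(test,), exhaustive=True)
    result = run_permutation_study(cohort, None, cfg)

    # direct enumeration, independent of the module machinery
    obs_p = fisher_exact_two_sided(((2, 0), (0, 4)))
    hits = total = 0
    for pair in itertools.combinations(range(6), 2):
        a = sum(1 for i in pair if i < 2)  # positions 0,1 are the case group
        c = 2 - a
        p = fisher_exact_two_sided(((a, 2 - a), (c, 4 - c)))
        hits += p <= obs_p * (1 + 1e-9)
        total += 1
    assert result.perm_p[0] == pytest.approx(hits / total)
    assert result.n_permutations == total


def test_study_is_deterministic_and_floored(small_cohort):
    tests = (
        PermutationTest("t", ("GENE:c.1A>G",), ("cases", "fams"), ("controls",)),
    )
    cfg = PermutationConfig(seed=5, tests=tests, n_permutations=200)
    r1 = run_permutation_study(small_cohort, None, cfg)
    r2 = run_permutation_study(small_cohort, None, cfg)
    assert r1 == r2
    assert all(p >= 1 / (cfg.n_permutations + 1) for p in r1.perm_p)
    assert r1.fwer_estimate >= max(r1.rejection_rate_at_alpha) - 1e-12
    assert r1.joint_significance <= min(r1.rejection_rate_at_alpha) + 1e-12


def test_all_zero_carriers_gives_p_one(small_cohort):
    empty = CarrierTable()
    tests = (PermutationTest("t", ("GENE:c.1A>G",), ("cases",), ("controls",)),)
    cfg = PermutationConfig(seed=3, tests=tests, n_permutations=50)
    cohort = replace(small_cohort, carrier_table=empty)
    result = run_permutation_study(cohort, empty, cfg)
    assert result.perm_p == [1.0]
    assert result.fwer_estimate == 0.0


def test_estimate_fwer_edges():
    assert estimate_fwer(np.ones((10, 5)), 0.05) == 0.0
    matrix = np.ones((10, 5))
    matrix[:, 2] = 0.001
    assert estimate_fwer(matrix, 0.05) == 1.0
    with pytest.raises(ValueError):
        estimate_fwer(np.empty((0, 5)), 0.05)


def test_fwer_of_independent_uniform_tests(rng):
    """k=5 independent uniform p columns: FWER -> 1 - 0.95^5."""
    b = 20_000
    matrix = rng.random((b, 5))
    fwer = estimate_fwer(matrix, 0.05)
    expected = 1 - 0.95**5
    se = (expected * (1 - expected) / b) ** 0.5
    assert abs(fwer - expected) <= 3 * se
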