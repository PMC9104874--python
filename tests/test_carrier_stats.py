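"""Fisher exact test, carrier frequencies and pairwise comparisons."""

from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from carrierscan import study
from carrierscan.stats import (
    carrier_frequency,
    contingency_test,
    fisher_exact_one_sided_greater,
    fisher_exact_two_sided,
    pairwise_case_control_tests,
)


def enumeration_fisher_p(a, b, c, d):
    """Independent oracle: enumerate every table with the observed
    margins and sum the probabilities <= that of the observed table,
    using exact integer binomial coefficients."""
    n = a + b + c + d
    k = a + c          # carrier column total
    r = a + b          # first-row total
    if k == 0:
        return 1.0
    denom = comb(n, k)
    probs = {}
    for x in range(max(0, r + k - n), min(r, k) + 1):
        probs[x] = comb(r, x) * comb(n - r, k - x) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


@pytest.mark.parametrize(
    "table,expected",
    [
        (((1, 43), (1, 1024)), 0.081),   # familial vs sequencing controls
        (((1, 437), (0, 1025)), 0.299),  # single sporadic carrier
        (((0, 44), (0, 1025)), 1.0),     # empty carrier margin
    ],
)
def test_published_fisher_values(table, expected):
    assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=5e-4)


def test_strong_enrichment_below_bound():
    assert fisher_exact_two_sided(((15, 423), (1, 1024))) < 1e-4


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(((-1, 2), (3, 4)))


def test_fisher_matches_enumeration_and_scipy(rng):
    """Random small tables agree with the enumeration oracle and scipy."""
    for _ in range(300):
        n = int(rng.integers(1, 41))
        cells = rng.multinomial(n, [0.25] * 4)
        a, b, c, d = (int(x) for x in cells)
        p = fisher_exact_two_sided(((a, b), (c, d)))
        assert p == pytest.approx(enumeration_fisher_p(a, b, c, d), rel=1e-9)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-6)


def test_two_sided_at_least_one_sided_and_symmetry(rng):
    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        two = fisher_exact_two_sided(((a, b), (c, d)))
        # the one-sided p in the observed direction (the smaller tail)
        one = min(
            fisher_exact_one_sided_greater(((a, b), (c, d))),
            fisher_exact_one_sided_greater(((c, d), (a, b))),
        )
        assert two >= one - 1e-12
        # swapping both rows and columns preserves the two-sided p
        assert two == pytest.approx(fisher_exact_two_sided(((d, c), (b, a))), rel=1e-12)


def test_one_sided_monotone_in_case_carriers():
    """Moving a carrier into the case row (margins fixed) never raises
    the enrichment-direction one-sided p."""
    n_case, n_ctrl, k = 12, 20, 6
    prev = None
    for a in range(0, k + 1):
        c = k - a
        if a > n_case or c > n_ctrl:
            continue
        p = fisher_exact_one_sided_greater(((a, n_case - a), (c, n_ctrl - c)))
        if prev is not None:
            assert p <= prev + 1e-12
        prev = p


@pytest.mark.parametrize(
    "carriers,denominator,percent",
    [(1, 44, "2.3"), (15, 438, "3.4"), (0, 56, "0.0"), (3, 17, "17.6"), (6, 53, "11.3")],
)
def test_carrier_frequency_formatting(carriers, denominator, percent):
    result = carrier_frequency(carriers, denominator)
    assert result.percent == percent
    assert result.fraction == pytest.approx(carriers / denominator)


def test_carrier_frequency_domain_errors():
    with pytest.raises(ValueError):
        carrier_frequency(1, 0)
    with pytest.raises(ValueError):
        carrier_frequency(5, 4)


def test_pairwise_reproduces_published_cells(study_cohort):
    results = pairwise_case_control_tests(study_cohort, pairs=study.replication_pairs())
    by_key = {(r.variant_id, r.case_group): r for r in results}

    r = by_key[(study.RAD51C_414, study.OC_FAMILIES)]
    assert r.table == ((1, 43), (1, 1024))
    assert r.p_two_sided == pytest.approx(0.081, abs=5e-4)
    assert str(r.carrier_freq_case) == "1/44 (2.3)"

    r = by_key[(study.RAD51D_620, study.SPORADIC)]
    assert r.table == ((15, 423), (1, 1024))
    assert r.p_two_sided < 1e-4
    assert str(r.carrier_freq_case) == "15/438 (3.4)"

    r = by_key[(study.RAD51C_705, study.SPORADIC)]
    assert r.p_two_sided == pytest.approx(0.299, abs=5e-4)


def test_pairwise_matches_per_cell_fisher(study_cohort):
    """Compositional oracle: every pairwise result equals a manual call."""
    results = pairwise_case_control_tests(study_cohort, pairs=study.replication_pairs())
    for r in results:
        (a, b), (c, d) = r.table
        assert r.p_two_sided == fisher_exact_two_sided(((a, b), (c, d)))
        assert a + b == study_cohort.group(r.case_group).n_units
        assert c + d == study_cohort.group(r.control_group).n_units


def test_zero_carrier_variant_all_p_one(small_cohort):
    results = pairwise_case_control_tests(
        small_cohort, variants=["GENE:c.none"], pairs=[("cases", "controls")]
    )
    assert results[0].p_two_sided == 1.0
    assert results[0].carrier_freq_case.fraction == 0.0


def test_unknown_group_raises(small_cohort):
    with pytest.raises(KeyError):
        pairwise_case_control_tests(small_cohort, pairs=[("nope", "controls")])


def test_odds_ratio_only_with_full_cells():
    with_zero = contingency_test("v", "case", "ctrl", 0, 10, 1, 20)
    assert with_zero.odds_ratio is None and with_zero.or_ci95 is None
    full = contingency_test("v", "case", "ctrl", 3, 10, 2, 20)
    assert full.odds_ratio == pytest.approx((3 * 18) / (7 * 2))
    lo, hi = full.or_ci95
    assert lo < full.odds_ratio < hi
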