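"""Estimator closed forms, invariants and resampling contracts.

The expected numbers here were frozen from independent evaluations of the
published closed forms (hand/naive-script oracles kept in this file), not
from the implementation under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lastsight as ls
from lastsight.errors import (
    InsufficientDataError,
    NoValidPairError,
    RateSaturationError,
    RecordValidationError,
)

# ---------------------------------------------------------------- oracles


def oracle_weighted_mcinerny(ts, alpha=0.05):
    """Naive pairwise loop, no vectorization, no tie handling."""
    ts = sorted(ts)
    t1 = ts[0]
    num = den = 0.0
    for i in range(1, len(ts)):
        gap = ts[i] - t1
        if gap <= 0:
            continue  # duplicated youngest date carries no interval
        lam = (i + 1) / gap
        if lam >= 1:
            continue
        ext = math.log(alpha) / math.log(1.0 - lam)
        num += (t1 - ext) / gap
        den += 1.0 / gap
    if den == 0:
        raise ZeroDivisionError
    return num / den


def oracle_ole_bound(ts, alpha=0.05, k=10):
    """Independently coded OLE bound (nested loops, lgamma, matrix inverse)."""
    ts = sorted(ts)[:k]
    x = [-v for v in ts]
    v = sum(math.log((x[0] - x[k - 1]) / (x[0] - x[i])) for i in range(1, k - 1)) / (k - 1)
    lam = np.empty((k, k))
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            a, b = max(i, j), min(i, j)
            lam[i - 1, j - 1] = math.exp(
                math.lgamma(2 * v + a) + math.lgamma(v + b)
                - math.lgamma(v + a) - math.lgamma(b)
            )
    e = np.ones(k)
    inv = np.linalg.inv(lam)
    a_w = inv @ e / (e @ inv @ e)
    c = (-math.log(alpha) / k) ** (-v)
    return ts[0] - (ts[k - 1] - ts[0]) / (c - 1.0), float(a_w.sum())


# ------------------------------------------------------------ closed forms


def test_two_point_strauss_sadler_equals_minus_900():
    s = ls.SightingSeries(np.array([1000.0, 1100.0]))
    res = ls.strauss_sadler(s, 0.05)
    assert res.bound95 == pytest.approx(-900.0, abs=1e-9)
    assert res.no_extinction_signal


@pytest.mark.parametrize(
    "func, expected",
    [
        (ls.strauss_sadler, 676.827),
        (ls.solow93, 693.339),
        (ls.mcinerny, 716.193),
    ],
)
def test_even_series_closed_forms(even_series, func, expected):
    assert func(even_series, 0.05).bound95 == pytest.approx(expected, abs=0.05)


def test_solow_strictly_older_than_strauss_sadler(even_series):
    assert ls.solow93(even_series).bound95 > ls.strauss_sadler(even_series).bound95


def test_extension_monotone_in_alpha(even_series):
    for func in (ls.strauss_sadler, ls.solow93, ls.mcinerny, ls.solow_roberts):
        b_strict = func(even_series, 0.01).bound95
        b_loose = func(even_series, 0.05).bound95
        assert b_strict < b_loose  # smaller alpha -> longer extension


def test_mcinerny_approaches_solow_at_large_n():
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(1_000, 50_000, 400))
    s = ls.SightingSeries(t)
    e_mc = s.t[0] - ls.mcinerny(s).bound95
    e_sol = s.t[0] - ls.solow93(s).bound95
    assert abs(e_mc - e_sol) / e_sol < 0.01


def test_mcinerny_rate_saturation():
    s = ls.SightingSeries(np.array([0.0, 5.0, 10.0]))  # n=3, r=10 ok; force n=r
    sat = ls.SightingSeries(np.array([0.0, 1.5, 3.0]))  # n/r = 1
    ls.mcinerny(s)
    with pytest.raises(RateSaturationError):
        ls.mcinerny(sat)


def test_solow_roberts_two_youngest_only():
    base = ls.SightingSeries(np.array([1000.0, 1200.0, 5000.0, 9000.0]))
    mutated = ls.SightingSeries(np.array([1000.0, 1200.0, 4000.0, 20_000.0]))
    assert ls.solow_roberts(base).bound95 == ls.solow_roberts(mutated).bound95
    # zero-gap limit: bound -> t1
    eps = ls.SightingSeries(np.array([1000.0, 1000.6, 3000.0]))
    assert ls.solow_roberts(eps).bound95 == pytest.approx(1000.0, abs=12.0)


def test_insufficient_data_errors():
    single = ls.SightingSeries(np.array([1000.0]))
    for func in (ls.strauss_sadler, ls.mcinerny, ls.solow_roberts, ls.briwm):
        with pytest.raises(InsufficientDataError):
            func(single)


# ------------------------------------------------------------------- OLE


def test_ole_shape_hand_value():
    s = ls.SightingSeries(np.linspace(10_000.0, 10_400.0, 5))
    res = ls.roberts_solow_ole(s, k=5)
    assert res.settings["vhat"] == pytest.approx(0.5918, abs=1e-4)
    assert res.settings["weights_sum"] == pytest.approx(1.0, abs=1e-9)


def test_ole_matches_independent_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        t = np.sort(rng.uniform(500, 10_000, 25))
        res = ls.roberts_solow_ole(ls.SightingSeries(t), k=10)
        bound, wsum = oracle_ole_bound(t, k=10)
        assert res.bound95 == pytest.approx(bound, rel=1e-9)
        assert wsum == pytest.approx(1.0, abs=1e-8)


def test_ole_window_errors():
    s = ls.SightingSeries(np.linspace(1000, 2000, 5))
    with pytest.raises(InsufficientDataError):
        ls.roberts_solow_ole(s, k=2)
    with pytest.raises(InsufficientDataError):
        ls.roberts_solow_ole(s, k=6)


# ------------------------------------------------- weighted McInerny core


def test_weighted_mcinerny_three_point_oracle():
    s = ls.SightingSeries(np.array([1000.0, 1100.0, 1300.0]))
    est = ls.weighted_mcinerny(s, 0.05)
    assert est == pytest.approx(814.269, abs=0.05)
    assert est == pytest.approx(oracle_weighted_mcinerny([1000.0, 1100.0, 1300.0]), abs=1e-9)


def test_weighted_mcinerny_n2_reduces_to_single_pair():
    s = ls.SightingSeries(np.array([1000.0, 1100.0]))
    lam = 2 / 100.0
    expected = 1000.0 - math.log(0.05) / math.log(1 - lam)
    assert ls.weighted_mcinerny(s) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.integers(0, 10_000), min_size=3, max_size=25, unique=True))
def test_weighted_mcinerny_permutation_invariant_and_matches_oracle(ts):
    ts = [10.0 * t for t in ts]  # spacing >= 10 yr, safely above the tie tolerance
    rng = np.random.default_rng(0)
    shuffled = list(ts)
    rng.shuffle(shuffled)
    try:
        expected = oracle_weighted_mcinerny(ts)
    except (ZeroDivisionError, ValueError):
        return  # saturated cases are covered by the error-path tests
    a = ls.weighted_mcinerny(ls.SightingSeries(np.array(ts)))
    b = ls.weighted_mcinerny(ls.SightingSeries(np.array(shuffled)))
    assert a == b == pytest.approx(expected, rel=1e-12)


def test_weighted_mcinerny_no_valid_pair():
    s = ls.SightingSeries(np.array([0.0, 1.0, 2.0, 3.0]))  # every rate >= 1
    with pytest.raises(NoValidPairError):
        ls.weighted_mcinerny(s)


# --------------------------------------------------------- GRIWM / BRIWM


def test_griwm_requires_sds(even_series):
    with pytest.raises(RecordValidationError):
        ls.griwm(even_series, seed=0)


def test_griwm_degenerates_to_deterministic_core_with_zero_sd():
    t = np.array([25_000.0, 25_600.0, 26_400.0, 27_500.0, 29_000.0])
    s = ls.SightingSeries(t, sd=np.zeros(5))
    res = ls.griwm(s, iters=200, seed=3)
    wm = ls.weighted_mcinerny(s)
    assert res.median == res.ci_lo == res.ci_hi == pytest.approx(wm, abs=1e-12)


def test_resamplers_are_seed_deterministic(variants):
    s = ls.SightingSeries.from_records(variants["include_poz"])
    for func in (ls.griwm, ls.briwm):
        a = func(s, iters=500, seed=42)
        b = func(s, iters=500, seed=42)
        assert (a.median, a.ci_lo, a.ci_hi) == (b.median, b.ci_lo, b.ci_hi)


def test_briwm_median_within_candidate_range():
    t = np.array([1000.0, 1150.0, 1400.0, 1800.0, 2500.0, 3500.0])
    s = ls.SightingSeries(t)
    cands = []
    for i in range(1, len(t)):
        lam = (i + 1) / (t[i] - t[0])
        if lam < 1:
            cands.append(t[0] - math.log(0.05) / math.log(1 - lam))
    res = ls.briwm(s, iters=2_000, seed=5)
    assert min(cands) <= res.median <= max(cands)


def test_resampling_interval_ordering(variants):
    s = ls.SightingSeries.from_records(variants["include_gda"])
    for func in (ls.griwm, ls.briwm):
        res = func(s, iters=1_000, seed=9)
        assert res.ci_hi <= res.median <= res.ci_lo


# -------------------------------------------------------------- properties


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(5, 40))
def test_bounds_strictly_younger_than_t1(seed, n):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(1_000, 50_000, n))
    s = ls.SightingSeries(t)
    for func in (ls.strauss_sadler, ls.solow93, ls.mcinerny, ls.solow_roberts):
        try:
            assert func(s, 0.05).bound95 < s.t[0]
        except (RateSaturationError, NoValidPairError):
            pass
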