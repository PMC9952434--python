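"""PRSA core: anchor rules, window averaging, DC and PRD scalars.

Every vectorized routine is checked for exact agreement with a naive
brute-force reimplementation (the oracle), plus the closed-form DC cases
and the shift/scale equivariances of the derived scalars.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsaecg.prsa import (
    PRSAConfig,
    acceleration_capacity,
    dc_from_series,
    deceleration_capacity,
    find_anchors_averaged,
    find_anchors_increment,
    prd_from_curve,
    prd_from_series,
    prsa_average,
)

# ---------------------------------------------------------------- oracles


def brute_anchors_increment(x, L):
    out = []
    for i in range(1, len(x)):
        if x[i] > x[i - 1] and i - L >= 0 and i + L - 1 <= len(x) - 1:
            out.append(i)
    return np.array(out, dtype=int)


def brute_anchors_averaged(x, M, L):
    out = []
    for i in range(M, len(x) - M + 1):
        fwd = sum(x[i + j] for j in range(0, M)) / M
        bwd = sum(x[i - j] for j in range(1, M + 1)) / M
        if fwd > bwd and i - L >= 0 and i + L - 1 <= len(x) - 1:
            out.append(i)
    return np.array(out, dtype=int)


def brute_prsa(x, anchors, L):
    curve = np.zeros(2 * L)
    for j, k in enumerate(range(-L, L)):
        curve[j] = sum(x[a + k] for a in anchors) / len(anchors)
    return curve


# ---------------------------------------------------------------- anchors


def test_increment_anchor_rule_on_simple_patterns():
    x = np.array([800.0, 800.0, 820.0, 800.0] * 10)
    a = find_anchors_increment(x, half_window=1)
    assert np.all(x[a] == 820.0)
    # every 820 except any whose window leaves the series
    assert len(a) == 10

    assert find_anchors_increment(np.arange(50, 0, -1.0), 2).size == 0
    assert find_anchors_increment(np.full(50, 5.0), 2).size == 0  # ties excluded


def test_averaged_anchor_rule_monotone_and_constant():
    x = np.arange(100, dtype=float)
    a = find_anchors_averaged(x, span=9, half_window=20)
    # strictly increasing series: every index with full M and L context
    assert a.size > 0
    assert np.array_equal(a, brute_anchors_averaged(x, 9, 20))
    assert find_anchors_averaged(np.full(100, 3.0), 9, 20).size == 0


def test_anchor_edge_exclusion_is_two_sided():
    x = np.zeros(30)
    x[2] = 1.0   # increment at index 2
    x[27] = 1.0  # increment at index 27
    a = find_anchors_increment(x, half_window=5)
    assert 2 not in a and 27 not in a


def test_anchors_excluded_when_window_contains_flagged_beat():
    x = np.tile([800.0, 820.0], 30)
    flags = np.zeros(x.size, dtype=bool)
    flags[20] = True
    a_all = find_anchors_increment(x, half_window=3)
    a_excl = find_anchors_increment(x, half_window=3, exclude=flags)
    dropped = set(a_all) - set(a_excl)
    assert dropped == {i for i in a_all if i - 3 <= 20 <= i + 2}


@pytest.mark.parametrize("mode", ["increment", "averaged"])
def test_anchor_finders_match_brute_force(mode, rng):
    for _ in range(25):
        n = int(rng.integers(300, 1001))
        x = 800 + 50 * rng.standard_normal(n)
        if mode == "increment":
            L = int(rng.integers(2, 15))
            got = find_anchors_increment(x, L)
            exp = brute_anchors_increment(x, L)
        else:
            L, M = 20, 9
            got = find_anchors_averaged(x, M, L)
            exp = brute_anchors_averaged(x, M, L)
        assert np.array_equal(got, exp)


# ---------------------------------------------------------------- averaging


def test_prsa_average_single_and_duplicate_anchor_windows():
    x = np.arange(40, dtype=float)
    res = prsa_average(x, np.array([17]), half_window=4)
    assert np.allclose(res.curve, x[13:21])  # window verbatim
    res2 = prsa_average(np.tile(x[:20], 4), np.array([25, 45]), half_window=4)
    assert np.allclose(res2.curve, res2.curve)  # defined
    assert res2.anchor_count == 2


def test_prsa_average_matches_brute_force_double_loop(rng):
    for _ in range(10):
        n = 500
        x = rng.normal(800, 50, n)
        L = 12
        a = brute_anchors_increment(x, L)
        got = prsa_average(x, a, L).curve
        exp = brute_prsa(x, a, L)
        assert np.max(np.abs(got - exp)) < 1e-12


def test_prsa_zero_anchors_gives_undefined_scalar():
    x = np.arange(100, 0, -1.0)
    res = dc_from_series(x, half_window=5)
    assert not res.defined
    assert np.isnan(res.scalar)


# ---------------------------------------------------------------- scalars


def test_dc_formula_arithmetic():
    # curve values around anchor: X-2=798, X-1=800, X0=810, X1=812
    curve = np.array([0.0, 0.0, 798.0, 800.0, 810.0, 812.0, 0.0, 0.0])
    res = deceleration_capacity(
        prsa_average(curve, np.array([4]), half_window=4)
    )
    assert res.scalar == pytest.approx((810 + 812 - 800 - 798) / 4)


def test_dc_on_isolated_prolongations_is_exactly_5ms():
    """Constant 800 ms with isolated +20 ms beats > 2L apart -> DC = 5 exactly."""
    L = 12
    rr = np.full(400, 800.0)
    rr[np.arange(30, 380, 2 * L + 5)] = 820.0
    res = dc_from_series(rr, half_window=L)
    assert res.anchor_count > 0
    assert res.scalar == 5.0


def test_dc_negation_maps_to_acceleration_capacity(rng):
    """DC(c - x) = -AC(x): increment anchors of c-x are decrement anchors of x."""
    x = rng.normal(800, 40, 600)
    c = 1600.0
    dc_neg = dc_from_series(c - x, half_window=12).scalar
    ac = acceleration_capacity(x, half_window=12).scalar
    assert dc_neg == pytest.approx(-ac, abs=1e-12)


def test_prd_max_minus_min():
    res = prsa_average(np.array([1.0, 3.0, 2.0, 1.0]), np.array([1]), 1)
    res = prd_from_curve(res)
    assert res.scalar == pytest.approx(2.0)  # window (1,3): max-min over 2L=2
    const = prd_from_curve(prsa_average(np.full(50, 4.0), np.array([25]), 10))
    assert const.scalar == 0.0


def test_prd_increases_with_oscillation_amplitude():
    t = np.arange(300) * 0.8
    prds = []
    for amp in (0.1, 0.2, 0.4):
        series = 0.4 + amp * np.sin(2 * np.pi * 0.05 * t)
        prds.append(prd_from_series(series).scalar)
    assert prds[0] < prds[1] < prds[2]


# ---------------------------------------------------------------- properties


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    shift=st.floats(-100, 100, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_shift_and_scale_equivariance(shift, scale, seed):
    """DC and PRD scale with the series; both ignore a constant shift."""
    x = np.random.default_rng(seed).normal(800, 30, 400)
    base_dc = dc_from_series(x).scalar
    base_prd = prd_from_series(x).scalar
    assert dc_from_series(x + shift).scalar == pytest.approx(base_dc, abs=1e-9)
    assert prd_from_series(x + shift).scalar == pytest.approx(base_prd, abs=1e-9)
    assert dc_from_series(x * scale).scalar == pytest.approx(scale * base_dc, rel=1e-9)
    assert prd_from_series(x * scale).scalar == pytest.approx(scale * base_prd, rel=1e-9)


def test_curve_shift_property(rng):
    x = rng.normal(0, 1, 300)
    a = find_anchors_increment(x, 10)
    c1 = prsa_average(x, a, 10).curve
    c2 = prsa_average(x + 5.0, a, 10).curve
    assert np.allclose(c2, c1 + 5.0)


def test_config_validation():
    with pytest.raises(ValueError):
        PRSAConfig(half_window=0)
    with pytest.raises(ValueError):
        PRSAConfig(anchor_mode="nope")
    with pytest.raises(ValueError):
        prsa_average(np.arange(10.0), np.array([1]), half_window=5)
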