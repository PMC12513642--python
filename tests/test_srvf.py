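"""SRVF transform, warp actions, and elastic alignment.

The dynamic-programming aligner is checked against two independent oracles:
a top-down memoized recursion over the same slope-constrained lattice, and a
full enumeration of every lattice path at tiny grid sizes.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gyroshape import (
    SrvfCurve,
    Trajectory,
    WarpingFunction,
    amplitude_distance,
    from_srvf,
    l2_norm,
    make_template,
    make_warp,
    pairwise_align,
    to_srvf,
    uniform_grid,
    warp_srvf,
    warp_trajectory,
)
from gyroshape.srvf import DP_STEPS

from conftest import random_smooth_curve


# ---------------------------------------------------------------------------
# independent lattice oracles (plain-Python, written separately from srvf.py)
# ---------------------------------------------------------------------------

def _oracle_segment_cost(q1, q2, dt, i, j, di, dj):
    """Trapezoid cost of the segment (i, j) -> (i+di, j+dj), plain loops."""
    s = dj / di
    total = 0.0
    for k in range(di + 1):
        w = 0.5 if k in (0, di) else 1.0
        pos = j + k * s
        lo = int(math.floor(pos))
        hi = min(lo + 1, len(q2) - 1)
        frac = pos - lo
        q2v = (1 - frac) * q2[lo] + frac * q2[hi]
        d = q1[i + k] - math.sqrt(s) * q2v
        total += w * d * d
    return total * dt


def oracle_min_cost_memo(q1, q2, dt):
    """Minimum path cost by top-down memoized recursion over the lattice."""
    M = len(q1)
    memo = {}

    def best(i, j):
        if (i, j) == (0, 0):
            return 0.0
        if (i, j) in memo:
            return memo[(i, j)]
        out = math.inf
        for di, dj in DP_STEPS:
            if i - di >= 0 and j - dj >= 0:
                prev = best(i - di, j - dj)
                if prev < math.inf:
                    c = prev + _oracle_segment_cost(q1, q2, dt, i - di, j - dj, di, dj)
                    out = min(out, c)
        memo[(i, j)] = out
        return out

    return best(M - 1, M - 1)


def oracle_min_cost_enumerate(q1, q2, dt):
    """Minimum path cost by explicit enumeration of every lattice path."""
    M = len(q1)
    best = [math.inf]

    def walk(i, j, cost):
        if cost >= best[0]:
            pass  # keep exploring: pruning would couple to the answer
        if i == M - 1 and j == M - 1:
            best[0] = min(best[0], cost)
            return
        for di, dj in DP_STEPS:
            if i + di <= M - 1 and j + dj <= M - 1:
                walk(i + di, j + dj,
                     cost + _oracle_segment_cost(q1, q2, dt, i, j, di, dj))

    walk(0, 0, 0.0)
    return best[0]


def _random_smooth_srvf(rng, grid, amplitude=10.0, n_modes=5):
    """Directly-constructed smooth SRVF, vanishing at the boundaries.

    Movement repetitions start and end at rest, so their SRVFs vanish at the
    endpoints; this also keeps the discrete change-of-variables quadrature
    free of boundary terms.
    """
    vals = np.zeros_like(grid)
    for m in range(1, n_modes + 1):
        vals += rng.normal(0, 1.0 / m) * np.sin(np.pi * m * grid)
    return SrvfCurve(grid, amplitude * vals)


def _random_pair(rng, n):
    g = uniform_grid(n)
    a = random_smooth_curve(rng, g, amplitude=10)
    b = random_smooth_curve(rng, g, amplitude=10)
    return to_srvf(a), to_srvf(b)


# ---------------------------------------------------------------------------
# SRVF transform
# ---------------------------------------------------------------------------

class TestSrvfTransform:
    def test_unit_slope_line_has_unit_srvf(self, grid200):
        q = to_srvf(Trajectory(grid200, grid200.copy()))
        assert np.allclose(q.values[2:-2], 1.0, atol=1e-9)

    def test_constant_curve_has_zero_srvf(self, grid200):
        q = to_srvf(Trajectory(grid200, np.full_like(grid200, 3.0)))
        assert np.allclose(q.values, 0.0)

    def test_quadratic_matches_closed_form(self, grid200):
        # beta = t^2 -> q = sqrt(2 t) at interior points
        q = to_srvf(Trajectory(grid200, grid200**2))
        expected = np.sqrt(2 * grid200[5:-5])
        assert np.max(np.abs(q.values[5:-5] - expected)) < 1e-10

    def test_round_trip_on_smooth_library(self, smooth_curve_library):
        for beta in smooth_curve_library:
            rec = from_srvf(to_srvf(beta))
            err = np.max(np.abs(rec.values - beta.values)) / np.ptp(beta.values)
            assert err < 1e-3

    def test_inversion_of_constant_and_unit_srvf(self, grid200):
        const = from_srvf(SrvfCurve(grid200, np.zeros_like(grid200), origin_value=5.0))
        assert np.allclose(const.values, 5.0)
        line = from_srvf(SrvfCurve(grid200, np.ones_like(grid200), origin_value=0.0))
        assert np.allclose(line.values, grid200, atol=1e-9)


# ---------------------------------------------------------------------------
# warp actions
# ---------------------------------------------------------------------------

class TestWarpActions:
    def test_identity_warp_is_noop(self, curl_template):
        ident = WarpingFunction.identity(curl_template.grid)
        assert np.array_equal(warp_trajectory(curl_template, ident).values,
                              curl_template.values)
        q = to_srvf(curl_template)
        assert np.allclose(warp_srvf(q, ident).values, q.values, atol=1e-9)

    def test_warp_then_inverse_restores(self, curl_template, rng):
        gamma = make_warp(0.6, rng)
        back = warp_trajectory(warp_trajectory(curl_template, gamma), gamma.inverse())
        err = np.max(np.abs(back.values - curl_template.values)) / np.ptp(curl_template.values)
        assert err < 5e-3

    def test_endpoints_invariant(self, curl_template, rng):
        for _ in range(5):
            gamma = make_warp(0.8, rng)
            warped = warp_trajectory(curl_template, gamma)
            assert warped.values[0] == curl_template.values[0]
            assert warped.values[-1] == curl_template.values[-1]

    def test_isometry_on_random_curves(self, grid200, rng):
        # the warp action preserves the L2 norm of a smooth q
        for _ in range(100):
            q = _random_smooth_srvf(rng, grid200)
            gamma = make_warp(0.7, rng)
            n0 = l2_norm(q.values, grid200)
            n1 = l2_norm(warp_srvf(q, gamma).values, grid200)
            assert abs(n1 - n0) / n0 < 1e-3

    def test_group_action_composition(self, curl_template, rng):
        q = to_srvf(curl_template)
        g1, g2 = make_warp(0.4, rng), make_warp(0.4, rng)
        comp = g1.compose(g2)  # g1(g2(t))
        lhs = warp_srvf(q, comp)
        rhs = warp_srvf(warp_srvf(q, g1), g2)
        scale = np.max(np.abs(q.values))
        assert np.max(np.abs(lhs.values - rhs.values)) / scale < 0.05


# ---------------------------------------------------------------------------
# discrete L2 norm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "f,expected,atol",
    [
        (lambda t: np.ones_like(t), 1.0, 1e-12),
        (lambda t: np.zeros_like(t), 0.0, 1e-12),
        (lambda t: t, 1 / np.sqrt(3), 1e-2),
    ],
)
def test_l2_norm_matches_integrals(f, expected, atol):
    g = np.linspace(0, 1, 1000)
    assert abs(l2_norm(f(g), g) - expected) <= atol


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

class TestPairwiseAlign:
    def test_self_alignment_is_identity(self, curl_template):
        q = to_srvf(curl_template)
        res = pairwise_align(q, q)
        assert res.distance < 1e-6
        step = curl_template.dt
        assert np.max(np.abs(res.warp.values - curl_template.grid)) < step

    def test_constructed_warp_recovery(self, curl_template, rng):
        q1 = to_srvf(curl_template)
        norm = l2_norm(q1.values, curl_template.grid)
        step = curl_template.dt
        for seed in range(3):
            gamma = make_warp(0.5, np.random.default_rng(seed))
            warped = warp_trajectory(curl_template, gamma)
            res = pairwise_align(q1, to_srvf(warped))
            assert res.distance < 0.02 * norm
            # recovered warp undoes gamma: warp ~ gamma^{-1}
            inv = gamma.inverse()
            assert np.max(np.abs(res.warp.values - inv.values)) < 2 * step

    def test_dp_matches_memoized_recursion_at_n16(self, rng):
        for _ in range(10):
            q1, q2 = _random_pair(rng, 16)
            res = pairwise_align(q1, q2, polish=False)
            oracle = math.sqrt(oracle_min_cost_memo(q1.values, q2.values, q1.dt))
            assert res.dp_cost == pytest.approx(oracle, rel=1e-10)

    def test_dp_matches_full_enumeration_at_n9(self, rng):
        for _ in range(3):
            q1, q2 = _random_pair(rng, 9)
            res = pairwise_align(q1, q2, polish=False)
            oracle = math.sqrt(oracle_min_cost_enumerate(q1.values, q2.values, q1.dt))
            assert res.dp_cost == pytest.approx(oracle, rel=1e-10)

    def test_dp_beats_random_admissible_warps(self, curl_template, rng):
        b2 = make_template("curl", 0.7, 0.3)
        q1, q2 = to_srvf(curl_template), to_srvf(b2)
        best = pairwise_align(q1, q2).distance
        g = curl_template.grid
        for _ in range(1000):
            gamma = make_warp(0.9, rng)
            cost = l2_norm(q1.values - warp_srvf(q2, gamma).values, g)
            assert best <= cost + 1e-9


class TestAmplitudeDistance:
    def test_zero_on_identical_curves(self, curl_template):
        assert amplitude_distance(curl_template, curl_template) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_warping_one_curve(self, curl_template, rng):
        q = to_srvf(curl_template)
        norm = l2_norm(q.values, curl_template.grid)
        for _ in range(3):
            gamma = make_warp(0.6, rng)
            d = amplitude_distance(curl_template, warp_trajectory(curl_template, gamma))
            assert d < 0.02 * norm

    def test_invariant_to_warping_both_curves(self, rng):
        b1 = make_template("curl", 1.0, 0.1)
        b2 = make_template("curl", 0.8, 0.35)
        base = amplitude_distance(b1, b2)
        for _ in range(5):
            ga, gb = make_warp(0.6, rng), make_warp(0.6, rng)
            d = amplitude_distance(warp_trajectory(b1, ga), warp_trajectory(b2, gb))
            assert abs(d - base) / base < 0.05


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_warp_action_isometry_property(seed):
    """Property: ||(q o gamma) sqrt(gamma')|| == ||q|| for any admissible warp."""
    rng = np.random.default_rng(seed)
    g = uniform_grid(200)
    q = _random_smooth_srvf(rng, g)
    gamma = make_warp(rng.uniform(0, 0.7), rng)
    n0 = l2_norm(q.values, g)
    n1 = l2_norm(warp_srvf(q, gamma).values, g)
    assert abs(n1 - n0) <= 1e-3 * max(n0, 1e-9)
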