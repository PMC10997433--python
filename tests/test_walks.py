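"""Random-walk kernels: chord oracle, step laws, feasibility, determinism."""

import numpy as np
import pytest
from scipy.stats import kstest

import polyflux as pf
from polyflux.errors import BoundednessError
from polyflux.walks import (
    WalkState,
    _billiard_trajectory,
    ball_walk_step,
    billiard_step,
    cdhr_step,
    dikin_step,
    sample,
)

ALL_WALKS = ["cdhr", "rdhr", "ball", "billiard", "dikin"]


def square01():
    A = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
    return pf.HPolytope(A, np.array([1.0, 1.0, 1.0, 1.0]))  # [-1,1]^2


class TestBoundaryIntersection:
    def test_center_of_square(self):
        P = square01()
        tm, tp, facet = pf.boundary_intersection(P, np.zeros(2), np.array([1.0, 0]))
        assert (tm, tp) == (-1.0, 1.0)
        np.testing.assert_allclose(P.A[facet], [1.0, 0.0])

    def test_off_center_chord(self):
        P = square01()
        tm, tp, _ = pf.boundary_intersection(P, np.array([0.5, 0.0]),
                                             np.array([1.0, 0]))
        assert abs(tm + 1.5) < 1e-12
        assert abs(tp - 0.5) < 1e-12

    def test_endpoint_lies_on_exactly_one_facet(self):
        rng = np.random.default_rng(42)
        P, _ = pf.make_reference_polytope("random_skew", 4, seed=9)
        x, _ = pf.chebyshev_center(P)
        for _ in range(50):
            u = rng.standard_normal(4)
            u /= np.linalg.norm(u)
            tm, tp, facet = pf.boundary_intersection(P, x, u)
            slack = P.b - P.A @ (x + tp * u)
            on_boundary = np.abs(slack) < 1e-9
            assert on_boundary[facet]
            assert on_boundary.sum() == 1

    def test_unbounded_direction_raises(self):
        P = pf.HPolytope(np.array([[1.0, 0.0]]), np.array([1.0]))
        with pytest.raises(BoundednessError):
            pf.boundary_intersection(P, np.zeros(2), np.array([-1.0, 0.0]))


class TestHitAndRun:
    def test_cdhr_changes_exactly_one_coordinate(self):
        P = square01()
        state = WalkState(x=np.zeros(2), rng=np.random.default_rng(0))
        for _ in range(20):
            new = cdhr_step(P, state)
            assert np.sum(new.x != state.x) <= 1
            state = new

    @pytest.mark.parametrize("stepper", [cdhr_step,
                                         pytest.param(None, id="rdhr")])
    def test_symmetric_chord_mean_is_midpoint(self, stepper):
        """Uniform-on-chord law: from the cube center the expected new
        coordinate is 0 (chord midpoint)."""
        from polyflux.walks import rdhr_step

        step = stepper or rdhr_step
        P = square01()
        rng = np.random.default_rng(1)
        total = np.zeros(2)
        n = 10_000
        for _ in range(n):
            state = WalkState(x=np.zeros(2), rng=rng)
            total += step(P, state).x
        assert np.max(np.abs(total / n)) < 0.02

    def test_one_cdhr_step_on_segment_is_exact_uniform(self):
        P = pf.HPolytope(np.array([[1.0], [-1.0]]), np.array([10.0, 0.0]))
        rng = np.random.default_rng(2)
        draws = np.empty(10_000)
        for i in range(draws.size):
            state = WalkState(x=np.array([3.0]), rng=rng)
            draws[i] = cdhr_step(P, state).x[0]
        ks = kstest(draws, "uniform", args=(0, 10)).statistic
        assert ks < 0.02


class TestBallWalk:
    def test_interior_proposals_always_accepted(self):
        P = square01()
        rng = np.random.default_rng(3)
        state = WalkState(x=np.zeros(2), rng=rng, params={"delta": 0.1})
        for _ in range(1000):
            new = ball_walk_step(P, state)
            assert not np.array_equal(new.x, state.x)  # ball inside polytope
            state = WalkState(x=np.zeros(2), rng=rng, params={"delta": 0.1})

    def test_near_corner_proposals_sometimes_rejected(self):
        P = square01()
        rng = np.random.default_rng(4)
        x0 = np.array([0.95, 0.95])
        rejected = 0
        for _ in range(500):
            state = WalkState(x=x0.copy(), rng=rng, params={"delta": 0.5})
            new = ball_walk_step(P, state)
            rejected += np.array_equal(new.x, x0)
        assert 0 < rejected < 500


class TestBilliard:
    def test_straight_segment_no_reflection(self):
        P = pf.HPolytope(np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]),
                         np.array([1.0, 0, 1, 0]))  # [0,1]^2
        end, nref = _billiard_trajectory(P, np.array([0.5, 0.5]),
                                         np.array([1.0, 0.0]), 0.3, 10)
        np.testing.assert_allclose(end, [0.8, 0.5], atol=1e-12)
        assert nref == 0

    def test_single_mirror_reflection(self):
        P = pf.HPolytope(np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]]),
                         np.array([1.0, 0, 1, 0]))
        end, nref = _billiard_trajectory(P, np.array([0.5, 0.5]),
                                         np.array([1.0, 0.0]), 0.7, 10)
        # hits x=1 after 0.5, reflects, travels 0.2 back
        np.testing.assert_allclose(end, [0.8, 0.5], atol=1e-12)
        assert nref == 1

    def test_reflection_budget_zero_rejects_on_any_facet_hit(self):
        """With R=0 the step degenerates to a straight-segment proposal."""
        P = square01()
        rng = np.random.default_rng(5)
        state = WalkState(x=np.zeros(2), rng=rng,
                          params={"tau": 1.0, "R": 0})
        moved = stayed = 0
        for _ in range(300):
            new = billiard_step(P, state)
            if np.array_equal(new.x, state.x):
                stayed += 1
            else:
                # accepted steps are straight segments fully inside
                assert np.all(P.A @ new.x <= P.b + 1e-9)
                moved += 1
            state = WalkState(x=np.zeros(2), rng=rng,
                              params={"tau": 1.0, "R": 0})
        assert moved > 0 and stayed > 0


class TestDikin:
    def test_acceptance_rate_from_center(self):
        P, _ = pf.make_reference_polytope("cube", 3)
        rng = np.random.default_rng(6)
        accepted = 0
        for _ in range(1000):
            state = WalkState(x=np.zeros(3), rng=rng,
                              params={"dikin_radius": 0.5})
            new = dikin_step(P, state)
            accepted += not np.array_equal(new.x, np.zeros(3))
        assert accepted / 1000 > 0.3

    def test_detailed_balance_ratio_consistency(self):
        """The implemented acceptance ratio equals det-ratio computed directly."""
        from polyflux.walks import _dikin_hessian

        P, _ = pf.make_reference_polytope("random_skew", 3, seed=11)
        x, _ = pf.chebyshev_center(P)
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = x + 0.05 * rng.standard_normal(3)
            if np.any(P.b - P.A @ y <= 0):
                continue
            Hx, Hy = _dikin_hessian(P, x), _dikin_hessian(P, y)
            ratio = np.sqrt(np.linalg.det(Hy) / np.linalg.det(Hx))
            log_ratio = 0.5 * (np.linalg.slogdet(Hy)[1]
                               - np.linalg.slogdet(Hx)[1])
            assert abs(np.log(ratio) - log_ratio) < 1e-12


class TestSampleDriver:
    @pytest.mark.parametrize("walk", ALL_WALKS)
    def test_all_recorded_points_feasible(self, walk):
        P, _ = pf.make_reference_polytope("random_skew", 3, seed=13)
        chain = sample(P, walk, 100, seed=8)
        assert chain.n_samples == 100
        assert np.all(P.A @ chain.X <= P.b[:, None] + 1e-9)

    @pytest.mark.parametrize("walk", ALL_WALKS)
    def test_seed_determinism(self, walk):
        P, _ = pf.make_reference_polytope("cube", 4)
        a = sample(P, walk, 200, seed=123)
        b = sample(P, walk, 200, seed=123)
        np.testing.assert_array_equal(a.X, b.X)
        c = sample(P, walk, 200, seed=124)
        frac_diff = np.mean(a.X != c.X)
        assert frac_diff >= 0.99

    def test_segment_cdhr_mean(self):
        P = pf.HPolytope(np.array([[1.0], [-1.0]]), np.array([10.0, 0.0]))
        chain = sample(P, "cdhr", 10_000, seed=9)
        assert abs(chain.X.mean() - 5.0) < 0.15

    @pytest.mark.parametrize("walk", ["john", "vaidya", "bogus"])
    def test_unknown_and_reserved_walks_raise(self, walk):
        P, _ = pf.make_reference_polytope("cube", 2)
        with pytest.raises(NotImplementedError):
            sample(P, walk, 10, seed=0)
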