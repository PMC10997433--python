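"""Polytope construction: null-space geometry, preprocessing, facet removal."""

import numpy as np
import pytest

import polyflux as pf
from polyflux.errors import InfeasibleModelError, NotFullDimensionalError
from polyflux.lp import solve_lp
from polyflux.polytope import bounding_box


def fva_oracle(model):
    """Direct per-reaction LPs in flux space (independent of build_polytope)."""
    n = model.n_reactions
    lo, hi = np.empty(n), np.empty(n)
    A_eq = model.S if model.n_metabolites else None
    b_eq = np.zeros(model.n_metabolites) if model.n_metabolites else None
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        lo[j] = solve_lp(e, A_eq=A_eq, b_eq=b_eq,
                         bounds=list(zip(model.lb, model.ub))).objective
        hi[j] = solve_lp(e, A_eq=A_eq, b_eq=b_eq,
                         bounds=list(zip(model.lb, model.ub)),
                         maximize=True).objective
    return lo, hi


class TestBuildPolytope:
    def test_two_reaction_chain_is_a_segment(self):
        model = pf.MetabolicModel(
            S=[[1.0, -1.0]], lb=[0, 0], ub=[10, 10], c=[0, 1],
            reaction_ids=["R1", "R2"], metabolite_ids=["A"])
        P, T = pf.build_polytope(model)
        assert P.dim == 1  # rank-nullity: 2 - 1
        lo, hi = bounding_box(P)
        V = pf.map_to_fluxes(np.array([[lo[0], hi[0]]]), T)
        assert sorted(np.round(V[0], 6)) == [0.0, 10.0]

    def test_no_metabolites_gives_the_box(self):
        model = pf.MetabolicModel(
            S=np.zeros((0, 3)), lb=[0, 0, 0], ub=[1, 2, 3], c=[1, 0, 0],
            reaction_ids=["R1", "R2", "R3"], metabolite_ids=[])
        P, T = pf.build_polytope(model)
        assert P.dim == 3
        lo, hi = bounding_box(P)
        widths = sorted(hi - lo)
        np.testing.assert_allclose(widths, [1, 2, 3], atol=1e-7)

    def test_chain_fixture_projects_to_tightest_cap(self, chain_model):
        P, T = pf.build_polytope(chain_model)
        assert P.dim == 1
        lo, hi = bounding_box(P)
        V = pf.map_to_fluxes(np.array([[lo[0], hi[0]]]), T)
        v3 = sorted(V[2])
        np.testing.assert_allclose(v3, [0.0, 5.0], atol=1e-6)

    def test_dimension_matches_rank_nullity(self, branch_model):
        P, T = pf.build_polytope(branch_model)
        assert P.dim == branch_model.n_reactions - np.linalg.matrix_rank(
            branch_model.S)

    def test_affine_map_invariants(self, branch_model):
        P, T = pf.build_polytope(branch_model)
        S = branch_model.S
        assert np.max(np.abs(S @ T.N)) <= 1e-9
        assert np.max(np.abs(S @ T.shift)) <= 1e-9
        np.testing.assert_allclose(T.N.T @ T.N, np.eye(T.dim), atol=1e-10)

    def test_infeasible_model_raises_with_certificate(self):
        model = pf.MetabolicModel(
            S=[[1.0, -1.0]], lb=[2, 0], ub=[10, 1], c=[0, 1],
            reaction_ids=["R1", "R2"], metabolite_ids=["A"])
        with pytest.raises(InfeasibleModelError):
            pf.build_polytope(model)

    def test_all_fixed_model_is_degenerate(self):
        model = pf.MetabolicModel(
            S=[[1.0, -1.0]], lb=[3, 0], ub=[3, 10], c=[0, 1],
            reaction_ids=["R1", "R2"], metabolite_ids=["A"])
        with pytest.raises(NotFullDimensionalError):
            pf.build_polytope(model)

    def test_mapped_samples_respect_original_constraints(self, branch_model):
        P, T = pf.build_polytope(branch_model)
        chain = pf.sample(P, "rdhr", 100, seed=3)
        V = pf.map_to_fluxes(chain.X, T)
        assert np.max(np.abs(branch_model.S @ V)) <= 1e-6
        assert np.all(V >= branch_model.lb[:, None] - 1e-6)
        assert np.all(V <= branch_model.ub[:, None] + 1e-6)


class TestTightenBounds:
    def test_chain_bounds_shrink_to_common_range(self, chain_model):
        tight, fixed = pf.tighten_bounds(chain_model)
        lo, hi = fva_oracle(chain_model)
        np.testing.assert_allclose(tight.lb, lo, atol=1e-9)
        np.testing.assert_allclose(tight.ub, hi, atol=1e-9)
        np.testing.assert_allclose(tight.ub, [5, 5, 5], atol=1e-9)
        assert fixed == []

    def test_explicitly_fixed_reaction_detected(self):
        model = pf.make_chain_model(3, [5, 10, 10])
        model.lb[1] = model.ub[1] = 2.5
        tight, fixed = pf.tighten_bounds(model)
        assert set(fixed) == {0, 1, 2}  # chain propagates the fixed flux
        np.testing.assert_allclose(tight.lb, [2.5, 2.5, 2.5], atol=1e-9)

    def test_pure_box_unchanged(self):
        model = pf.MetabolicModel(
            S=np.zeros((0, 2)), lb=[0, 0], ub=[1, 2], c=[1, 0],
            reaction_ids=["R1", "R2"], metabolite_ids=[])
        tight, fixed = pf.tighten_bounds(model)
        np.testing.assert_allclose(tight.lb, model.lb)
        np.testing.assert_allclose(tight.ub, model.ub)
        assert fixed == []


class TestRemoveRedundantFacets:
    def test_duplicate_facet_removed(self, unit_square):
        A = np.vstack([unit_square.A, [[1.0, 0.0]]])
        b = np.concatenate([unit_square.b, [1.0]])
        P = pf.HPolytope(A, b)
        out = pf.remove_redundant_facets(P)
        assert out.n_facets == 4

    def test_slack_facet_removed(self, unit_square):
        A = np.vstack([unit_square.A, [[1.0, 0.0]]])
        b = np.concatenate([unit_square.b, [5.0]])
        out = pf.remove_redundant_facets(pf.HPolytope(A, b))
        assert out.n_facets == 4

    def test_tight_cube_unchanged(self):
        P, _ = pf.make_reference_polytope("cube", 3)
        out = pf.remove_redundant_facets(P)
        assert out.n_facets == 6
        # per-facet LP oracle: every facet of the cube is attained
        for i in range(P.n_facets):
            res = solve_lp(P.A[i], A_ub=P.A, b_ub=P.b, maximize=True)
            assert abs(res.objective - P.b[i]) < 1e-9

    def test_idempotent(self, unit_square):
        A = np.vstack([unit_square.A, [[1.0, 0.0]], [[0.5, 0.5]]])
        b = np.concatenate([unit_square.b, [3.0], [7.0]])
        once = pf.remove_redundant_facets(pf.HPolytope(A, b))
        twice = pf.remove_redundant_facets(once)
        np.testing.assert_allclose(once.A, twice.A)
        np.testing.assert_allclose(once.b, twice.b)

    def test_point_set_preserved(self, unit_square):
        A = np.vstack([unit_square.A, [[1.0, 1.0]]])
        b = np.concatenate([unit_square.b, [3.0]])
        out = pf.remove_redundant_facets(pf.HPolytope(A, b))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.5, 1.5, size=(2, 500))
        before = pf.HPolytope(A, b).contains(pts)
        after = out.contains(pts)
        np.testing.assert_array_equal(before, after)


class TestChebyshevCenter:
    @pytest.mark.parametrize("d", [2, 5, 8])
    def test_cube_center_and_radius(self, d):
        P, _ = pf.make_reference_polytope("cube", d)
        c, r = pf.chebyshev_center(P)
        np.testing.assert_allclose(c, np.zeros(d), atol=1e-9)
        assert abs(r - 1.0) < 1e-9

    def test_simplex_radius_closed_form(self):
        # {x >= 0, y >= 0, x + y <= 1}: inscribed circle radius 1/(2 + sqrt(2))
        P, _ = pf.make_reference_polytope("simplex", 2)
        c, r = pf.chebyshev_center(P)
        expected = 1.0 / (2.0 + np.sqrt(2.0))
        assert abs(r - expected) < 1e-9
        np.testing.assert_allclose(c, [expected, expected], atol=1e-9)

    def test_translation_equivariance(self):
        A = np.vstack([np.eye(2), -np.eye(2)])
        b = np.array([6.0, 6.0, -4.0, -4.0])  # [4, 6]^2
        c, r = pf.chebyshev_center(pf.HPolytope(A, b))
        np.testing.assert_allclose(c, [5.0, 5.0], atol=1e-9)
        assert abs(r - 1.0) < 1e-9


class TestMapToFluxes:
    def test_zero_column_maps_to_shift(self, chain_model):
        P, T = pf.build_polytope(chain_model)
        V = pf.map_to_fluxes(np.zeros((T.dim, 1)), T)
        np.testing.assert_allclose(V[:, 0], T.shift)

    def test_chain_null_space_forces_equal_fluxes(self, chain_model):
        P, T = pf.build_polytope(chain_model)
        chain = pf.sample(P, "cdhr", 50, seed=1)
        V = pf.map_to_fluxes(chain.X, T)
        assert np.max(np.abs(V[0] - V[1])) < 1e-9
        assert np.max(np.abs(V[1] - V[2])) < 1e-9

    def test_dimension_mismatch_raises(self, chain_model):
        from polyflux.errors import ValidationError

        P, T = pf.build_polytope(chain_model)
        with pytest.raises(ValidationError):
            pf.map_to_fluxes(np.zeros((T.dim + 1, 4)), T)
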