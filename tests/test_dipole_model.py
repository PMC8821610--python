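"""Thole tensor, system assembly, solvers, polarizability invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy.spatial.transform import Rotation

from polscat import (Atom, AtomicStructure, PolarizableSystem,
                     ValidationError, assemble_system,
                     assign_polarizabilities, carbon_cube, carbon_dimer,
                     carbon_line, compute_polarizability, damping_length,
                     random_cluster, solve_dipoles, thole_tensor,
                     threshold_convergence_scan)

ALPHA_C = 1.405


def dimer_closed_forms(alpha, r):
    """Two identical undamped atoms: parallel / perpendicular polarizability."""
    par = 2 * alpha / (1 - 2 * alpha / r ** 3)
    perp = 2 * alpha / (1 + alpha / r ** 3)
    return par, perp


class TestTholeTensor:
    def test_undamped_axial_pair(self):
        t = thole_tensor((0, 0, 0), (0, 0, 2.0), ALPHA_C, ALPHA_C)
        assert not t.damped
        assert t.matrix[2, 2] == pytest.approx(-0.25)
        assert t.matrix[0, 0] == pytest.approx(0.125)
        assert t.matrix[1, 1] == pytest.approx(0.125)
        off = t.matrix - np.diag(np.diag(t.matrix))
        assert np.abs(off).max() == 0

    def test_branches_agree_at_damping_length(self):
        s = damping_length(ALPHA_C, ALPHA_C)
        t = thole_tensor((0, 0, 0), (0, 0, s), ALPHA_C, ALPHA_C)
        undamped = np.diag([1 / s ** 3, 1 / s ** 3, 1 / s ** 3 - 3 / s ** 3])
        np.testing.assert_allclose(t.matrix, undamped, rtol=1e-12)

    def test_damped_pair_at_one_angstrom(self):
        # frozen values from a scalar hand evaluation of the smeared branch
        t = thole_tensor((0, 0, 0), (0, 0, 1.0), ALPHA_C, ALPHA_C)
        assert t.damped
        assert t.matrix[2, 2] == pytest.approx(0.120423, abs=1e-5)
        assert t.matrix[0, 0] == pytest.approx(0.370282, abs=1e-5)

    def test_symmetry_under_swap(self):
        a = thole_tensor((0.3, -1.0, 0.5), (1.1, 0.4, -0.2), 1.405, 0.862)
        b = thole_tensor((1.1, 0.4, -0.2), (0.3, -1.0, 0.5), 0.862, 1.405)
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-14)
        np.testing.assert_allclose(a.matrix, a.matrix.T, rtol=1e-14)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValidationError, match="catastrophe"):
            thole_tensor((0, 0, 0), (0, 0, 0.05), ALPHA_C, ALPHA_C)


class TestAssembly:
    def test_single_atom_diagonal(self):
        s = AtomicStructure([Atom("C", (0, 0, 0))])
        inter = assemble_system(assign_polarizabilities(s))
        np.testing.assert_allclose(inter.matrix.toarray(),
                                   np.eye(3) / ALPHA_C, rtol=1e-12)

    def test_threshold_excludes_all_pairs(self):
        sys_ = assign_polarizabilities(carbon_cube(2.0), threshold_radius=1.0)
        inter = assemble_system(sys_)
        assert inter.n_pairs == 0
        assert inter.nnz == 8 * 9  # diagonal blocks only

    def test_matches_naive_dense_assembly(self):
        cl = random_cluster(n=12, box=8.0, min_dist=1.2, seed=2)
        sys_ = assign_polarizabilities(cl)
        inter = assemble_system(sys_)
        n = cl.n_atoms
        dense = np.zeros((3 * n, 3 * n))
        for i in range(n):
            dense[3 * i:3 * i + 3, 3 * i:3 * i + 3] = np.eye(3) / sys_.alpha[i]
            for j in range(n):
                if i != j:
                    t = thole_tensor(cl.positions[i], cl.positions[j],
                                     sys_.alpha[i], sys_.alpha[j])
                    dense[3 * i:3 * i + 3, 3 * j:3 * j + 3] = t.matrix
        np.testing.assert_allclose(inter.matrix.toarray(), dense, atol=1e-12)
        np.testing.assert_allclose(dense, dense.T, atol=1e-12)

    def test_colliding_atoms_rejected(self):
        s = AtomicStructure([Atom("C", (0, 0, 0)), Atom("C", (0, 0, 0.05))])
        with pytest.raises(ValidationError):
            assemble_system(assign_polarizabilities(s))


class TestSolvers:
    def test_isolated_atom_follows_field(self):
        s = AtomicStructure([Atom("C", (0, 0, 0))])
        sol = solve_dipoles(assemble_system(assign_polarizabilities(s)),
                            np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(sol.mu, [[0, 0, ALPHA_C]], rtol=1e-12)

    def test_dimer_closed_forms(self):
        r = 2.0
        sys_ = assign_polarizabilities(carbon_dimer(r))
        inter = assemble_system(sys_)
        par, perp = dimer_closed_forms(ALPHA_C, r)
        axial = solve_dipoles(inter, np.array([0.0, 0.0, 1.0]))
        assert axial.total_dipole[2] == pytest.approx(par, rel=1e-9)
        trans = solve_dipoles(inter, np.array([1.0, 0.0, 0.0]))
        assert trans.total_dipole[0] == pytest.approx(perp, rel=1e-9)

    @given(r=st_hyp.floats(min_value=1.9, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_dimer_closed_form_over_separations(self, r):
        # r > damping length (1.8615 A for two carbons): undamped branch
        sys_ = assign_polarizabilities(carbon_dimer(r))
        res = compute_polarizability(sys_)
        par, perp = dimer_closed_forms(ALPHA_C, r)
        assert res.alpha_tensor[2, 2] == pytest.approx(par, rel=1e-9)
        assert res.alpha_tensor[0, 0] == pytest.approx(perp, rel=1e-9)

    @pytest.mark.parametrize("builder", [
        lambda: carbon_cube(2.0),
        lambda: random_cluster(n=150, box=15.0, min_dist=1.4, seed=9),
    ])
    def test_dense_and_iterative_agree(self, builder):
        sys_ = assign_polarizabilities(builder())
        inter = assemble_system(sys_)
        field = np.array([0.0, 0.0, 1.0])
        dense = solve_dipoles(inter, field, solver="dense")
        iterative = solve_dipoles(inter, field, solver="minres", tol=1e-8)
        np.testing.assert_allclose(iterative.mu, dense.mu, rtol=0, atol=1e-6)
        assert iterative.residual <= 1e-8

    def test_per_atom_field(self):
        # far-separated dimer, field only on atom 0: atom 0 responds alone
        s = AtomicStructure([Atom("C", (0, 0, 0)), Atom("C", (0, 0, 200.0))])
        inter = assemble_system(assign_polarizabilities(s))
        field = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        sol = solve_dipoles(inter, field)
        assert sol.mu[0, 2] == pytest.approx(ALPHA_C, rel=1e-4)
        assert abs(sol.mu[1, 2]) < 1e-3

    def test_bad_field_rejected(self):
        inter = assemble_system(assign_polarizabilities(carbon_dimer(2.0)))
        with pytest.raises(ValidationError):
            solve_dipoles(inter, np.array([np.nan, 0.0, 0.0]))
        with pytest.raises(ValidationError):
            solve_dipoles(inter, np.zeros((5, 3)))


class TestPolarizability:
    def test_isolated_atom(self):
        s = AtomicStructure([Atom("C", (0, 0, 0))])
        res = compute_polarizability(assign_polarizabilities(s))
        assert res.alpha_avg == pytest.approx(ALPHA_C, rel=1e-12)
        np.testing.assert_allclose(res.alpha_tensor, ALPHA_C * np.eye(3),
                                   atol=1e-12)

    def test_average_is_trace_third(self, cube_result):
        assert cube_result.alpha_avg == pytest.approx(
            np.trace(cube_result.alpha_tensor) / 3, rel=1e-9)

    def test_cube_is_isotropic(self, cube_result):
        assert np.ptp(cube_result.eigenvalues) < 1e-6 * cube_result.alpha_avg

    def test_anisotropy_ordering(self, cube_result, line_result):
        # elongation boosts the axial response beyond any cube direction
        assert line_result.vector_magnitudes.max() > \
            cube_result.vector_magnitudes.max()

    def test_rotation_invariance_and_covariance(self, rng):
        cl = random_cluster(n=30, box=10.0, min_dist=1.4, seed=4)
        base = compute_polarizability(assign_polarizabilities(cl))
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = compute_polarizability(assign_polarizabilities(
            cl.with_positions(cl.positions @ rot.T)))
        assert rotated.alpha_avg == pytest.approx(base.alpha_avg, rel=1e-6)
        np.testing.assert_allclose(rotated.alpha_tensor,
                                   rot @ base.alpha_tensor @ rot.T,
                                   rtol=1e-6, atol=1e-9)

    def test_translation_invariance(self):
        cl = random_cluster(n=20, box=10.0, min_dist=1.4, seed=6)
        base = compute_polarizability(assign_polarizabilities(cl))
        moved = compute_polarizability(assign_polarizabilities(
            cl.with_positions(cl.positions + np.array([50.0, -30.0, 7.0]))))
        np.testing.assert_allclose(moved.alpha_tensor, base.alpha_tensor,
                                   rtol=1e-12, atol=1e-12)

    def test_far_field_additivity(self):
        single = compute_polarizability(assign_polarizabilities(
            carbon_cube(2.0)))
        cube = carbon_cube(2.0)
        far = AtomicStructure(
            list(cube.atoms)
            + [Atom("C", tuple(p + np.array([500.0, 0, 0])))
               for p in cube.positions])
        both = compute_polarizability(assign_polarizabilities(far))
        assert both.alpha_avg == pytest.approx(2 * single.alpha_avg, rel=1e-6)


class TestThresholdScan:
    def test_inactive_threshold_ratio_is_one(self):
        sys_ = assign_polarizabilities(carbon_cube(2.0))
        scan = threshold_convergence_scan(sys_, [10.0])
        assert scan.points[0].ratio == pytest.approx(1.0, rel=1e-12)

    def test_subminimal_threshold_gives_alpha_sum(self):
        sys_ = assign_polarizabilities(carbon_cube(2.0))
        scan = threshold_convergence_scan(sys_, [1.0, 10.0])
        assert scan.points[0].alpha_avg == pytest.approx(8 * ALPHA_C,
                                                         rel=1e-12)

    def test_tail_converges_to_unthresholded(self):
        cl = random_cluster(n=300, box=18.0, min_dist=1.4, seed=8)
        sys_ = assign_polarizabilities(cl)
        scan = threshold_convergence_scan(sys_, [6.0, 12.0, 18.0, 24.0, 31.2])
        errors = [abs(p.ratio - 1.0) for p in scan.points]
        assert errors[-1] < 0.01
        assert errors[-1] <= errors[-2] <= errors[-3]

    def test_bad_radii_rejected(self):
        sys_ = assign_polarizabilities(carbon_cube(2.0))
        with pytest.raises(ValidationError):
            threshold_convergence_scan(sys_, [10.0, 5.0])
        with pytest.raises(ValidationError):
            threshold_convergence_scan(sys_, [])
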