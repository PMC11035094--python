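"""Potential solves, orthogonal decomposition and its invariants."""

import numpy as np
import pytest

import hodgeflow as hf
from hodgeflow.decompose import solve_coexact_potential, solve_exact_potential
from hodgeflow.fields import flat
from hodgeflow.synthetic import SyntheticScenario, analytic_field
from _complexes import (
    annulus_complex,
    random_cochain,
    square_complex,
    staircase_complex,
    two_blocks_complex,
)

SMALL = [
    lambda: square_complex(6),
    lambda: annulus_complex(10),
    lambda: staircase_complex(8, seed=4),
]


def interior_bump(cx, seed=0):
    """Random 0-cochain vanishing on the boundary."""
    rng = np.random.default_rng(seed)
    g = rng.normal(size=cx.n_vertices)
    g[cx.vertex_boundary] = 0.0
    return g


class TestExactPotential:
    @pytest.mark.parametrize("make", SMALL)
    def test_recovers_dirichlet_potential(self, make):
        """omega = d g with g zero on the boundary gives back alpha = g."""
        cx = make()
        g = interior_bump(cx, seed=1)
        om = hf.Cochain(1, cx.exterior_derivative(0) @ g, cx)
        alpha, res, _ = solve_exact_potential(om, cx)
        assert np.abs(alpha.values - g).max() <= 1e-9
        assert res <= 1e-10

    def test_divergence_free_input_gives_zero(self):
        cx = square_complex(6)
        # coexact cochains are divergence-free by delta delta = 0
        r = np.zeros(cx.n_faces)
        r[~cx.face_boundary] = np.random.default_rng(2).normal(
            size=(~cx.face_boundary).sum()
        )
        beta = r / cx.hodge_star(2).diagonal()
        om = hf.Cochain(1, cx.codifferential(2) @ beta, cx)
        alpha, _, _ = solve_exact_potential(om, cx)
        assert np.abs(alpha.values).max() <= 1e-10

    def test_zero_input(self):
        cx = square_complex(4)
        alpha, res, _ = solve_exact_potential(
            hf.Cochain(1, np.zeros(cx.n_edges), cx), cx
        )
        assert np.all(alpha.values == 0) and res == 0.0

    def test_boundary_condition_enforced(self):
        cx = staircase_complex(8, seed=0)
        om = random_cochain(cx, seed=3)
        alpha, _, _ = solve_exact_potential(om, cx)
        assert np.all(alpha.values[cx.vertex_boundary] == 0)


class TestCoexactPotential:
    @pytest.mark.parametrize("make", SMALL)
    def test_recovers_tangential_potential(self, make):
        """omega = delta beta0 with star beta0 zero on boundary faces gives beta0."""
        cx = make()
        rng = np.random.default_rng(7)
        r0 = np.zeros(cx.n_faces)
        r0[~cx.face_boundary] = rng.normal(size=(~cx.face_boundary).sum())
        beta0 = r0 / cx.hodge_star(2).diagonal()
        om = hf.Cochain(1, cx.codifferential(2) @ beta0, cx)
        beta, res, _ = solve_coexact_potential(om, cx)
        assert np.abs(beta.values - beta0).max() <= 1e-9 * max(np.abs(beta0).max(), 1)
        assert res <= 1e-10

    def test_curl_free_input_gives_zero(self):
        cx = square_complex(6)
        om = hf.Cochain(
            1, cx.exterior_derivative(0) @ np.random.default_rng(1).normal(size=cx.n_vertices), cx
        )
        beta, _, _ = solve_coexact_potential(om, cx)
        assert np.abs(beta.values).max() <= 1e-10

    def test_zero_input(self):
        cx = square_complex(4)
        beta, res, _ = solve_coexact_potential(
            hf.Cochain(1, np.zeros(cx.n_edges), cx), cx
        )
        assert np.all(beta.values == 0) and res == 0.0


class TestDenseOracle:
    """Both potential solves match dense least-squares on tiny masks."""

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_lstsq(self, seed):
        cx = staircase_complex(7, seed=seed)  # < 100 vertices
        assert cx.n_vertices <= 100
        om = random_cochain(cx, seed=seed + 10)
        alpha, _, _ = solve_exact_potential(om, cx)
        d0 = cx.exterior_derivative(0).toarray()
        s1 = np.sqrt(cx.hodge_star(1).diagonal())
        interior = ~cx.vertex_boundary
        sol, *_ = np.linalg.lstsq(
            (s1[:, None] * d0)[:, interior], s1 * om.values, rcond=None
        )
        ref = np.zeros(cx.n_vertices)
        ref[interior] = sol
        assert np.abs(alpha.values - ref).max() <= 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_coexact_matches_lstsq(self, seed):
        cx = staircase_complex(7, seed=seed)
        om = random_cochain(cx, seed=seed + 20)
        beta, _, _ = solve_coexact_potential(om, cx)
        delta2 = cx.codifferential(2).toarray()
        s1 = np.sqrt(cx.hodge_star(1).diagonal())
        star2 = cx.hodge_star(2).diagonal()
        interior = ~cx.face_boundary
        design = (s1[:, None] * delta2 / star2[None, :])[:, interior]
        sol, *_ = np.linalg.lstsq(design, s1 * om.values, rcond=None)
        r = np.zeros(cx.n_faces)
        r[interior] = sol
        assert np.abs(beta.values - r / star2).max() <= 1e-8


class TestDecompose:
    def test_zero_input_all_zero(self):
        cx = square_complex(5)
        dec = hf.decompose(hf.Cochain(1, np.zeros(cx.n_edges), cx))
        for comp in (dec.exact, dec.coexact, dec.harmonic):
            assert np.all(comp.values == 0)
        assert dec.energy_fractions() == {"exact": 0.0, "coexact": 0.0, "harmonic": 0.0}

    def test_gradient_input_is_pure_exact(self):
        cx = square_complex(16)
        g = interior_bump(cx, seed=5)
        dec = hf.decompose(hf.Cochain(1, cx.exterior_derivative(0) @ g, cx))
        fr = dec.energy_fractions()
        assert fr["exact"] >= 0.999
        assert fr["coexact"] + fr["harmonic"] <= 1e-3

    def test_circulation_on_annulus_is_harmonic(self):
        cx = annulus_complex(64)
        fld, _ = analytic_field(SyntheticScenario("annulus_harmonic"), cx)
        dec = hf.decompose(flat(fld))
        assert dec.energy_fractions()["harmonic"] >= 0.9

    @pytest.mark.parametrize("make", SMALL)
    @pytest.mark.parametrize("seed", range(3))
    def test_reconstruction_orthogonality_pythagoras(self, make, seed):
        cx = make()
        om = random_cochain(cx, seed=seed)
        dec = hf.decompose(om)
        # identity by construction (up to one rounding of the re-summation)
        resid = om.values - dec.exact.values - dec.coexact.values - dec.harmonic.values
        assert np.abs(resid).max() <= 1e-15 * max(np.abs(om.values).max(), 1.0)
        d = dec.diagnostics
        for o in (d.orth_exact_coexact, d.orth_exact_harmonic, d.orth_coexact_harmonic):
            assert o <= 1e-6
        total = (
            d.energy_fraction_exact + d.energy_fraction_coexact + d.energy_fraction_harmonic
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("make", SMALL)
    def test_components_closed_and_coclosed_exactly(self, make):
        cx = make()
        dec = hf.decompose(random_cochain(cx, seed=8))
        d1 = cx.exterior_derivative(1)
        delta1 = cx.codifferential(1)
        assert np.abs(d1 @ dec.exact.values).max() <= 1e-12  # dd = 0
        assert np.abs(delta1 @ dec.coexact.values).max() <= 1e-10  # delta delta = 0

    @pytest.mark.parametrize("make", SMALL)
    def test_idempotence(self, make):
        """Re-decomposing each component leaves it unchanged (leakage <= 1e-8)."""
        cx = make()
        dec = hf.decompose(random_cochain(cx, seed=12))
        for name in ("exact", "coexact", "harmonic"):
            comp = getattr(dec, name)
            if comp.norm() == 0:
                continue
            redo = hf.decompose(comp)
            fr = redo.energy_fractions()
            leakage = sum(v for k, v in fr.items() if k != name)
            assert leakage <= 1e-8, f"{name} leaked {leakage}"

    def test_disconnected_domain_blockwise(self):
        cx = two_blocks_complex(9)
        om = random_cochain(cx, seed=2)
        dec = hf.decompose(om)
        d = dec.diagnostics
        assert max(d.orth_exact_coexact, d.orth_exact_harmonic, d.orth_coexact_harmonic) <= 1e-6

    def test_cg_matches_direct(self):
        cx = square_complex(24)
        om = random_cochain(cx, seed=1)
        a = hf.decompose(om, solver="direct")
        b = hf.decompose(om, solver="cg", tol=1e-12)
        assert np.abs(a.exact.values - b.exact.values).max() <= 1e-8
        assert b.diagnostics.iterations_exact > 0

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_cg_nonconvergence_raises(self):
        from hodgeflow.decompose import _solve_spd

        cx = square_complex(24)
        d0 = cx.exterior_derivative(0)
        s1 = cx.hodge_star(1)
        interior = ~cx.vertex_boundary
        A = (d0.T @ s1 @ d0).tocsr()[interior][:, interior]
        b = np.random.default_rng(0).normal(size=int(interior.sum()))
        with pytest.raises(hf.SolverError, match="residual"):
            _solve_spd(A, b, "cg", 1e-300)  # unreachable tolerance

    def test_harmonic_residuals_bounded_by_solver_residuals(self):
        cx = annulus_complex(32)
        fld, _ = analytic_field(SyntheticScenario("annulus_harmonic"), cx)
        dec = hf.decompose(flat(fld))
        d = dec.diagnostics
        assert d.harmonic_curl_residual <= 10 * max(d.residual_coexact_solve, 1e-12)
        assert d.harmonic_div_residual <= 10 * max(d.residual_exact_solve, 1e-12)


class TestComponentFields:
    def test_zero_field(self):
        cx = square_complex(4)
        dec = hf.decompose(hf.Cochain(1, np.zeros(cx.n_edges), cx))
        for f in hf.component_fields(dec):
            assert np.all(f.vectors == 0)

    def test_fields_sum_to_sharp_of_input(self):
        cx = staircase_complex(10, seed=6)
        om = random_cochain(cx, seed=3)
        dec = hf.decompose(om)
        e, c, h = hf.component_fields(dec)
        total = e.vectors + c.vectors + h.vectors
        ref = hf.sharp(om).vectors
        assert np.abs(total - ref).max() <= 1e-10 * max(np.abs(ref).max(), 1.0)

    def test_exact_component_passthrough(self):
        cx = square_complex(8)
        g = interior_bump(cx, seed=9)
        om = hf.Cochain(1, cx.exterior_derivative(0) @ g, cx)
        dec = hf.decompose(om)
        e, _, _ = hf.component_fields(dec)
        assert np.allclose(e.vectors, hf.sharp(om).vectors, atol=1e-8)

    def test_constant_field_is_harmonic_on_square(self):
        cx = square_complex(32)
        field = hf.VectorFieldGrid(cx, np.tile([1.0, 0.0], (cx.n_vertices, 1)))
        dec = hf.decompose(flat(field))
        _, _, h = hf.component_fields(dec)
        interior = ~cx.vertex_boundary
        # constant fields are closed and coclosed; harmonic keeps most of it
        assert dec.energy_fractions()["harmonic"] >= 0.8
        assert np.allclose(h.vectors[interior, 0].mean(), 1.0, atol=0.1)


class TestHarmonicConsistency:
    def test_disk_flags_consistent(self):
        cx = square_complex(12)
        g = interior_bump(cx, seed=4)
        dec = hf.decompose(hf.Cochain(1, cx.exterior_derivative(0) @ g, cx))
        rep = hf.harmonic_consistency(dec, hf.compute_topology(cx))
        assert rep.consistent and rep.b1 == 0
        assert "consistent with b1 = 0" in rep.message

    def test_annulus_notes_nontrivial_space(self):
        cx = annulus_complex(32)
        fld, _ = analytic_field(SyntheticScenario("annulus_harmonic"), cx)
        dec = hf.decompose(flat(fld))
        rep = hf.harmonic_consistency(dec, hf.compute_topology(cx))
        assert rep.b1 == 1 and rep.consistent
        assert "nontrivial harmonic space" in rep.message

    def test_two_disks_each_simply_connected(self):
        cx = two_blocks_complex(9)
        dec = hf.decompose(random_cochain(cx, seed=0))
        topo = hf.compute_topology(cx)
        assert (topo.b0, topo.b1) == (2, 0)
        rep = hf.harmonic_consistency(dec, topo)
        assert rep.b1 == 0
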