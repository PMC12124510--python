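"""Deformation-gradient kinematics, polar decomposition, embedded fibers."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fiberalign import fem, kinematics as kin
from fiberalign.fem import DisplacementField, Geometry, Material, build_mesh
from fiberalign.fiber_stats import alignment_index
from fiberalign.kinematics import KinematicsError


def _rand_F(rng, scale=1.0):
    while True:
        F = np.eye(2) + scale * rng.uniform(-0.8, 0.8, (2, 2))
        if np.linalg.det(F) > 0.05:
            return F


def _affine_field(mesh, A):
    u = mesh.nodes @ (A - np.eye(2)).T
    return DisplacementField(u=u, eps_s=0.0, converged=True,
                             residual_norm=0.0)


class TestDeformationGradientAt:
    def test_affine_displacement_reproduced_exactly(self):
        mesh = build_mesh(Geometry(element_size_um=500.0))
        A = np.diag([0.5, 0.9])
        pts = np.array([[0.3, 0.4], [2.0, 5.0], [3.9, 9.9]])
        for F in kin.deformation_gradient_at(mesh, _affine_field(mesh, A), pts):
            assert np.max(np.abs(F - A)) < 1e-12

    def test_zero_displacement_gives_identity(self):
        mesh = build_mesh(Geometry(element_size_um=1000.0))
        field = DisplacementField(u=np.zeros_like(mesh.nodes), eps_s=0.0,
                                  converged=True, residual_norm=0.0)
        (F,) = kin.deformation_gradient_at(mesh, field, [[1.0, 5.0]])
        assert np.allclose(F, np.eye(2), atol=1e-14)

    def test_random_affine_recovered(self):
        rng = np.random.default_rng(0)
        mesh = build_mesh(Geometry(element_size_um=500.0))
        for _ in range(5):
            A = _rand_F(rng)
            (F,) = kin.deformation_gradient_at(
                mesh, _affine_field(mesh, A), [[1.7, 3.3]])
            assert np.max(np.abs(F - A)) < 1e-12

    def test_outside_domain_rejected(self):
        mesh = build_mesh(Geometry(element_size_um=1000.0))
        field = _affine_field(mesh, np.eye(2))
        with pytest.raises(KinematicsError, match="outside"):
            kin.deformation_gradient_at(mesh, field, [[99.0, 0.5]])


class TestPolarDecomposition:
    def test_identity_and_pure_rotation(self):
        U, R = kin.polar_decompose(np.eye(2))
        assert np.allclose(U, np.eye(2)) and np.allclose(R, np.eye(2))
        th = np.radians(30.0)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        U, R = kin.polar_decompose(Q)
        assert np.allclose(U, np.eye(2), atol=1e-12)
        assert np.allclose(R, Q, atol=1e-12)

    @given(seed=st.integers(0, 500))
    def test_matches_svd_oracle(self, seed):
        """U and R agree with an independent SVD-based construction."""
        rng = np.random.default_rng(seed)
        F = _rand_F(rng)
        U, R = kin.polar_decompose(F)
        W, s, Vt = np.linalg.svd(F)
        # enforce proper rotations in the oracle
        d = np.sign(np.linalg.det(W @ Vt))
        D = np.diag([1.0, d])
        U_svd = Vt.T @ D @ np.diag(s) @ D @ Vt
        R_svd = W @ D @ Vt
        assert np.max(np.abs(U - U_svd)) < 1e-10
        assert np.max(np.abs(R - R_svd)) < 1e-10
        # defining invariants
        assert np.max(np.abs(F - R @ U)) < 1e-8 * max(1.0, np.abs(F).max())
        assert np.max(np.abs(R @ R.T - np.eye(2))) < 1e-10
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert np.min(np.linalg.eigvalsh(U)) > 0

    def test_degenerate_F_rejected(self):
        with pytest.raises(KinematicsError):
            kin.polar_decompose(np.diag([1.0, -1.0]))


class TestEllipse:
    def test_pure_stretch_cases(self):
        a, b, alpha, beta = kin.ellipse_from_F(np.diag([2.0, 0.5]), r=1.0)
        assert (a, b, alpha) == pytest.approx((0.5, 2.0, 4.0))
        assert beta == pytest.approx(0.0)
        th = np.radians(30.0)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        _, _, alpha, beta = kin.ellipse_from_F(Q @ np.diag([2.0, 1.0]))
        assert alpha == pytest.approx(2.0)
        assert beta == pytest.approx(30.0)

    def test_isotropic_flagged(self):
        _, _, alpha, beta = kin.ellipse_from_F(0.7 * np.eye(2))
        assert alpha == 1.0 and np.isnan(beta)
        pk = kin.point_kinematics(0.7 * np.eye(2))
        assert pk.isotropic

    def test_alpha_consistent_with_polar_stretches(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            F = _rand_F(rng)
            U, _ = kin.polar_decompose(F)
            lam = np.linalg.eigvalsh(U)
            _, _, alpha, _ = kin.ellipse_from_F(F)
            assert abs(alpha - lam[1] / lam[0]) < 1e-10

    def test_beta_invariant_to_radius_and_scaling(self):
        rng = np.random.default_rng(2)
        F = _rand_F(rng)
        _, _, _, b1 = kin.ellipse_from_F(F, r=0.05)
        _, _, _, b2 = kin.ellipse_from_F(F, r=7.0)
        _, _, _, b3 = kin.ellipse_from_F(3.1 * F, r=0.05)
        assert b1 == pytest.approx(b2) == pytest.approx(b3)


class TestEmbeddedFibers:
    def test_tangent_transformation_example(self):
        f = kin.embed_and_deform_fibers(np.diag([2.0, 1.0]), n=4)
        # fiber seeded at 45 deg maps to atan(1/2)
        assert f.angles_deg[1] == pytest.approx(np.degrees(np.arctan2(1, 2)))

    def test_identity_preserves_angles(self):
        f = kin.embed_and_deform_fibers(np.eye(2), n=150)
        assert np.allclose(f.angles_deg, np.arange(150) * 180.0 / 150)

    @pytest.mark.parametrize("alpha", [1.5, 3.5, 7.8])
    def test_closed_form_bridge_for_pure_stretch(self, alpha):
        """Uniform fibers under pure stretch with axis ratio alpha give
        S -> (alpha - 1)/(alpha + 1); at n = 150 the deviation is < 0.02."""
        F = np.diag([1.0, alpha])
        S_150 = kin.equivalent_alignment_index(F, n=150)
        S_inf = kin.closed_form_S(alpha)
        assert abs(S_150 - S_inf) < 0.02
        S_mc = alignment_index(
            kin.embed_and_deform_fibers(F, n=200001)).S  # brute-force oracle
        assert abs(S_mc - S_inf) < 1e-3

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        F = _rand_F(rng)
        th = np.radians(40.0)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        _, _, a1, b1 = kin.ellipse_from_F(F)
        _, _, a2, b2 = kin.ellipse_from_F(Q @ F)
        assert a1 == pytest.approx(a2)
        d = abs((b1 + 40.0) % 180.0 - b2) % 180.0
        assert min(d, 180.0 - d) < 1e-8
        S1 = kin.equivalent_alignment_index(F)
        S2 = kin.equivalent_alignment_index(Q @ F)
        assert S1 == pytest.approx(S2, abs=1e-12)


class TestAlignmentMap:
    def test_uniform_affine_field_gives_uniform_map(self):
        mesh = build_mesh(Geometry(element_size_um=500.0))
        A = np.diag([0.5, 1.0])   # alpha = 2 everywhere
        amap = kin.alignment_map(mesh, _affine_field(mesh, A))
        assert np.allclose(amap.alpha, 2.0, atol=1e-9)
        assert np.allclose(amap.gamma_model, 1.0, atol=1e-9)
        assert amap.max_elements().size == amap.element_ids.size
        for r in amap.regions.values():
            assert r.alpha == pytest.approx(2.0)
            assert abs(r.S - kin.closed_form_S(2.0)) < 0.02

    def test_nonconverged_field_rejected(self):
        mesh = build_mesh(Geometry(element_size_um=1000.0))
        bad = DisplacementField(u=np.zeros_like(mesh.nodes), eps_s=0.1,
                                converged=False, residual_norm=1.0)
        with pytest.raises(fem.FEMError):
            kin.alignment_map(mesh, bad)

    def test_bestfit_regions_match_reported_pattern(self, mesh_200um,
                                                    bestfit_200um):
        amap = kin.alignment_map(mesh_200um, bestfit_200um.field_best)
        ce, me, mc = (amap.regions[k] for k in ("CE", "ME", "MC"))
        # corner leads, middle locations agree with each other
        assert ce.alpha > me.alpha
        assert me.alpha == pytest.approx(mc.alpha, rel=0.02)
        assert 90.0 < ce.beta_model_deg < 180.0
        assert abs(me.beta_model_deg - 90.0) < 2.0
        assert abs(mc.beta_model_deg - 90.0) < 2.0
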