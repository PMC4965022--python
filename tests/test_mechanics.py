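"""Hyperelastic solver: constitutive laws, assembly, Newton solve, locking."""

from pathlib import Path

import numpy as np
import pytest

from mammosim.config import load_config
from mammosim.mechanics import (
    ActiveParams, Material, MaterialSet, MechModel, NewtonOptions, SkinMaterial,
    pk2_stress, standard_bcs, strain_energy_tissue,
    _membrane_energy, _membrane_forces, _membrane_setup,
)
from mammosim.mesh import Patch, bar_mesh, box_mesh

CONFIG_DIR = Path(__file__).resolve().parents[1] / "configs"

MAT = Material(c1=100.0, c2=25.0, kappa=1e4, rho0=1000.0)


def simple_materials(c1=100.0, c2=25.0, kappa=1e4, skin_alpha=200.0):
    return MaterialSet(
        adipose=Material(c1, c2, kappa, 1000.0),
        fibroglandular=Material(c1, c2, kappa, 1000.0),
        wound=Material(c1, c2, kappa, 1000.0),
        skin=SkinMaterial(alpha=skin_alpha, beta=4.0, c2=-skin_alpha * 2.0),
        active=ActiveParams(tau_f=0.0, alpha_f=1.0, eta0_f=1.0),
    )


def rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestStrainEnergy:
    def test_reference_state_zero_for_any_damage(self):
        for zeta in (0.0, 0.5, 0.999):
            assert strain_energy_tissue(np.eye(3), MAT, zeta) == pytest.approx(0.0)

    def test_pure_rotation_zero(self):
        R = rotation([1, 2, 3], 0.7)
        assert abs(strain_energy_tissue(R, MAT)) < 1e-10 * MAT.c1

    def test_damage_halves_isochoric_part_only(self):
        F = np.eye(3)
        F[0, 1] = 0.1  # simple shear, J = 1 (volumetric term vanishes)
        w0 = strain_energy_tissue(F, MAT, zeta=0.0)
        w_half = strain_energy_tissue(F, MAT, zeta=0.5)
        assert w_half == pytest.approx(0.5 * w0, rel=1e-12)
        # with a volume change the kappa term must be untouched by damage
        Fv = 1.01 * np.eye(3)
        wv0 = strain_energy_tissue(Fv, MAT, 0.0)
        wv5 = strain_energy_tissue(Fv, MAT, 0.5)
        iso0 = wv0 - 0.5 * MAT.kappa * (1.01**3 - 1) ** 2
        assert wv5 == pytest.approx(0.5 * iso0 + (wv0 - iso0), rel=1e-10)

    def test_damage_limit_scales_stiffness(self):
        F = np.eye(3)
        F[0, 1] = 0.05
        w0 = strain_energy_tissue(F, MAT, 0.0)
        w = strain_energy_tissue(F, MAT, 1.0)  # clamped to 1 - 1e-3
        assert w == pytest.approx(1e-3 * w0, rel=1e-9)

    def test_objectivity_of_energy_and_stress(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        R = rotation([1, -1, 2], 1.1)
        w1, w2 = strain_energy_tissue(F, MAT), strain_energy_tissue(R @ F, MAT)
        assert w2 == pytest.approx(w1, rel=1e-10)
        S1, S2 = pk2_stress(F, MAT), pk2_stress(R @ F, MAT)
        assert np.linalg.norm(S1 - S2) < 1e-10 * max(np.linalg.norm(S1), 1.0)


class TestPk2Stress:
    def test_reference_state_stress_free(self):
        S = pk2_stress(np.eye(3), MAT)
        assert np.abs(S).max() < 1e-10 * MAT.c1

    def test_active_stress_is_isotropic_addition(self):
        act = ActiveParams(tau_f=2.0, alpha_f=0.5, eta0_f=3.0)
        S = pk2_stress(np.eye(3), MAT, eta_norm=0.5, in_wound=True, active=act)
        assert np.allclose(S, 2.0 * 0.5 * 0.5 * 3.0 * np.eye(3))
        S_out = pk2_stress(np.eye(3), MAT, eta_norm=0.5, in_wound=False, active=act)
        assert np.abs(S_out).max() < 1e-12

    def test_matches_finite_difference_of_energy(self, rng):
        # S = dW/dE via symmetric central differences on the Green strain
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        zeta = 0.3
        S = pk2_stress(F, MAT, zeta=zeta)
        C = F.T @ F
        h = 1e-6

        def energy_of_C(Cmat):
            lam, vecs = np.linalg.eigh(Cmat)
            Fs = vecs @ np.diag(np.sqrt(lam)) @ vecs.T  # symmetric sqrt
            return strain_energy_tissue(Fs, MAT, zeta)

        S_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dC = np.zeros((3, 3))
                dC[i, j] += h
                dC[j, i] += h
                wp = energy_of_C(C + dC / 2)
                wm = energy_of_C(C - dC / 2)
                S_fd[i, j] = 2.0 * (wp - wm) / (2 * h) * (1.0 if i == j else 1.0)
        scale = np.abs(S).max()
        assert np.abs(S - S_fd).max() / scale < 1e-6


class TestMembrane:
    def triangle(self):
        nodes = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        tris = np.array([[0, 1, 2]])
        return nodes, tris

    def test_undeformed_zero_force(self):
        nodes, tris = self.triangle()
        A0, ainv = _membrane_setup(nodes, tris)
        f = _membrane_forces(nodes[tris], A0, ainv,
                             SkinMaterial(100.0, 4.0, -200.0), 1e-3)
        assert np.abs(f).max() < 1e-12

    def test_rigid_rotation_zero_force(self):
        nodes, tris = self.triangle()
        A0, ainv = _membrane_setup(nodes, tris)
        R = rotation([1, 1, 0], 0.9)
        f = _membrane_forces((nodes @ R.T)[tris], A0, ainv,
                             SkinMaterial(100.0, 4.0, -200.0), 1e-3)
        assert np.abs(f).max() < 1e-10

    def test_equibiaxial_virtual_work_matches_analytic(self):
        # E(lam) = A0 t W with I1 = 2 lam^2 + lam^-4, I2 = lam^4 + 2 lam^-2
        skin = SkinMaterial(100.0, 4.0, -200.0)
        t = 1e-3
        nodes, tris = self.triangle()
        A0, ainv = _membrane_setup(nodes, tris)
        lam = 1.2
        x = lam * nodes

        def W(l):
            I1 = 2 * l**2 + l**-4
            I2 = l**4 + 2 * l**-2
            return skin.alpha * (np.exp(skin.beta * (I1 - 3)) - 1) \
                + skin.c2 * (I2 - 3)

        h = 1e-6
        dE_dlam = float(A0[0]) * t * (W(lam + h) - W(lam - h)) / (2 * h)
        f = _membrane_forces(x[tris], A0, ainv, skin, t)[0]
        virtual_work = float(np.sum(f * nodes[tris[0]]))  # dx/dlam = X
        assert virtual_work == pytest.approx(dE_dlam, rel=1e-6)


class TestAssembly:
    def model(self, formulation="penalty", skin=True, kappa=1e4):
        mesh = box_mesh((0.02, 0.02, 0.02), 0.005,
                        patch_map={"y-": Patch.CHEST})
        return MechModel(mesh, simple_materials(kappa=kappa),
                         formulation=formulation, include_skin=skin)

    def test_zero_state_zero_residual(self):
        model = self.model()
        r, K = model.assemble(np.zeros(model.ndof))
        assert np.abs(r).max() < 1e-10

    @pytest.mark.parametrize("formulation", ["penalty", "anp"])
    def test_tangent_matches_fd_of_residual(self, formulation, rng):
        model = self.model(formulation)
        u = 5e-4 * rng.standard_normal(model.ndof)
        r, K = model.assemble(u)
        h = 1e-7
        for dof in rng.choice(model.ndof, 8, replace=False):
            up, um = u.copy(), u.copy()
            up[dof] += h
            um[dof] -= h
            col = (model.assemble(up, tangent=False)[0]
                   - model.assemble(um, tangent=False)[0]) / (2 * h)
            K_col = K[:, dof].toarray().ravel()
            assert np.abs(col - K_col).max() <= 1e-5 * max(np.abs(col).max(), 1e-8)

    def test_unconstrained_tangent_has_six_rigid_modes(self):
        mesh = box_mesh((0.01, 0.01, 0.01), 0.01)  # one cube, 8 nodes
        model = MechModel(mesh, simple_materials(), include_skin=False,
                          bcs=np.zeros((mesh.num_nodes, 3), dtype=bool))
        _, K = model.assemble(np.zeros(model.ndof))
        w = np.linalg.eigvalsh(K.toarray())
        scale = np.abs(w).max()
        assert (np.abs(w) < 1e-9 * scale).sum() == 6


class TestStaticSolve:
    def test_zero_load_zero_displacement(self):
        mesh = box_mesh((0.02, 0.02, 0.02), 0.01, patch_map={"y-": Patch.CHEST})
        model = MechModel(mesh, simple_materials(), include_skin=False)
        state = model.solve_static()
        assert np.abs(state.u).max() == 0.0

    def test_gravity_reactions_balance_weight(self):
        mesh = box_mesh((0.02, 0.02, 0.02), 0.005, patch_map={"y-": Patch.CHEST})
        mats = simple_materials(kappa=1e6)
        model = MechModel(mesh, mats, include_skin=True)
        g = np.array([0.0, -9.81, 0.0])
        state = model.solve_static(gravity=g)
        weight = (model.mat["rho0"] * model.vol).sum() * 9.81
        weight += (mats.skin.rho0 * model.skin_A0 * mesh.skin_thickness).sum() * 9.81
        total = state.reactions.sum(axis=0)
        assert total[1] == pytest.approx(weight, rel=1e-8)

    def test_volume_change_small_in_penalty_limit(self):
        # kappa/c1 = 1e4: a gravity-loaded supported block stays quasi-isochoric
        mesh = box_mesh((0.02, 0.02, 0.02), 0.005, patch_map={"y-": Patch.CHEST})
        model = MechModel(mesh, simple_materials(kappa=1e6), include_skin=False)
        state = model.solve_static(gravity=np.array([0.0, -9.81, 0.0]))
        v0 = mesh.volumes().sum()
        v1 = mesh.volumes(state.u).sum()
        assert abs(v1 / v0 - 1.0) < 5e-3

    def test_volume_change_decreases_with_kappa(self):
        mesh = box_mesh((0.02, 0.02, 0.02), 0.005, patch_map={"y-": Patch.CHEST})
        changes = []
        for kappa in (1e4, 1e5, 1e6):  # kappa/c1 = 1e2, 1e3, 1e4
            model = MechModel(mesh, simple_materials(kappa=kappa),
                              include_skin=False)
            state = model.solve_static(gravity=np.array([0.0, -9.81, 0.0]))
            changes.append(abs(mesh.volumes(state.u).sum()
                               / mesh.volumes().sum() - 1.0))
        assert changes[0] > changes[1] > changes[2]


class TestUniaxialStretch:
    def test_cauchy_stress_matches_incompressible_closed_form(self):
        """Uniaxial stretch of a Mooney-Rivlin block in the penalty limit.

        Closed form (incompressible): sigma = 2 (c1 + c2/lam)(lam^2 - 1/lam).
        """
        cfg = load_config(CONFIG_DIR / "uniaxial.yaml")
        mat = cfg.materials.adipose
        L, h = 0.01, 0.005
        mesh = box_mesh((L, L, L), h)
        lam = 1.3
        tol = 1e-9
        fixed = np.zeros((mesh.num_nodes, 3), dtype=bool)
        values = np.zeros((mesh.num_nodes, 3))
        z0, z1 = mesh.nodes[:, 2] < tol, mesh.nodes[:, 2] > L - tol
        fixed[z0, 2] = True
        fixed[z1, 2] = True
        values[z1, 2] = (lam - 1.0) * L
        fixed[mesh.nodes[:, 0] < tol, 0] = True
        fixed[mesh.nodes[:, 1] < tol, 1] = True
        model = MechModel(mesh, cfg.materials, include_skin=False, bcs=fixed)
        state = model.solve_static(fixed_values=values,
                                   opts=NewtonOptions(n_increments=6))
        force = state.reactions[z1, 2].sum()
        x = mesh.nodes + state.u
        area = (x[z1, 0].max() - x[z1, 0].min()) * (x[z1, 1].max() - x[z1, 1].min())
        sigma = force / area
        closed = 2.0 * (mat.c1 + mat.c2 / lam) * (lam**2 - 1.0 / lam)
        assert sigma == pytest.approx(closed, rel=0.01)


class TestLockingAndFormulations:
    def cantilever(self, formulation, kappa):
        mesh = bar_mesh(0.1, 0.005, cross=2)
        fixed = np.zeros((mesh.num_nodes, 3), dtype=bool)
        fixed[mesh.nodes[:, 0] < 1e-9, :] = True
        model = MechModel(mesh, simple_materials(c1=1000.0, c2=250.0,
                                                 kappa=kappa),
                          formulation=formulation, include_skin=False, bcs=fixed)
        state = model.solve_static(gravity=np.array([0.0, 0.0, -2.0]))
        return float(np.abs(state.u[:, 2]).max())

    def test_anp_is_locking_free_at_high_kappa(self):
        w_anp_low = self.cantilever("anp", 1e5)    # kappa/c1 = 1e2
        w_anp_high = self.cantilever("anp", 1e7)   # kappa/c1 = 1e4
        w_pen_high = self.cantilever("penalty", 1e7)
        # the u/p-projected deflection must not collapse as kappa grows,
        # while the element-penalty form locks visibly
        assert w_anp_high > 0.6 * w_anp_low
        assert w_anp_high > 1.5 * w_pen_high

    def test_formulations_agree_on_homogeneous_deformation(self):
        # uniform uniaxial stretch: J is element-wise constant, so the nodal
        # projection changes nothing and both forms must coincide
        cfg = load_config(CONFIG_DIR / "uniaxial.yaml")
        L, h, lam = 0.01, 0.005, 1.15
        results = []
        for formulation in ("penalty", "anp"):
            mesh = box_mesh((L, L, L), h)
            tol = 1e-9
            fixed = np.zeros((mesh.num_nodes, 3), dtype=bool)
            values = np.zeros((mesh.num_nodes, 3))
            z1 = mesh.nodes[:, 2] > L - tol
            fixed[mesh.nodes[:, 2] < tol, 2] = True
            fixed[z1, 2] = True
            values[z1, 2] = (lam - 1.0) * L
            fixed[mesh.nodes[:, 0] < tol, 0] = True
            fixed[mesh.nodes[:, 1] < tol, 1] = True
            model = MechModel(mesh, cfg.materials, include_skin=False,
                              formulation=formulation, bcs=fixed)
            state = model.solve_static(fixed_values=values)
            results.append(state.u.copy())
        assert np.allclose(results[0], results[1], atol=1e-8)


def test_standard_bcs_follow_patch_labels():
    from mammosim.mesh import generate_phantom

    mesh = generate_phantom(seed=2, target_edge_length=0.012)
    fixed = standard_bcs(mesh)
    chest = mesh.patch_nodes(Patch.CHEST)
    assert np.all(fixed[chest, :])
    for p in (Patch.CLIP_INFERIOR, Patch.CLIP_SUPERIOR):
        nodes = mesh.patch_nodes(p)
        assert np.all(fixed[nodes, 2])
    skin_only = np.setdiff1d(mesh.patch_nodes(Patch.SKIN),
                             np.concatenate([chest,
                                             mesh.patch_nodes(Patch.CLIP_INFERIOR),
                                             mesh.patch_nodes(Patch.CLIP_SUPERIOR),
                                             mesh.patch_nodes(Patch.LATERAL)]))
    assert not np.any(fixed[skin_only, :])
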