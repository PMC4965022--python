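"""Quasi-static Total-Lagrangian hyperelastic FE solver for breast tissue.

Bulk tissue (adipose / fibroglandular / wound) is a quasi-incompressible
Mooney-Rivlin solid; the dermis is a Veronda-Westmann membrane shell on the
skin patch.  The wound carries two extra ingredients: an isotropic active
(fibroblast traction) 2nd Piola-Kirchhoff stress ``tau_f * eta_f * I`` and a
damage variable ``zeta`` in [0, 1) that scales the isochoric strain energy
by the integrity factor ``(1 - zeta)``.  The volumetric penalty is left
intact by default so the fluid-filled wound stays quasi-incompressible.

Discretisation: linear tetrahedra.  Near-incompressibility is handled either
by the element-wise penalty — which for constant-strain tetrahedra is the
statically condensed form of the mixed u/p element with element-constant
pressure — or by an average-nodal-pressure projection ("anp") that relieves
the volumetric locking of linear tetrahedra in bending-dominated problems.

Stress and tangent come from complex-step differentiation of the stored
energy / stress functions, so the consistent tangent matches the residual to
machine precision without hand-derived elasticity tensors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LabeledMesh, Patch, Region

__all__ = [
    "Material", "SkinMaterial", "ActiveParams", "MaterialSet", "MechState",
    "NewtonOptions", "SolverError", "InvertedElementError", "MechModel",
    "strain_energy_tissue", "pk2_stress", "standard_bcs", "GRAVITY_POSES",
]

log = logging.getLogger(__name__)

_EPS_ZETA = 1e-3       # zeta is clamped to 1 - _EPS_ZETA; never zero stiffness
_CS_H = 1e-30          # complex-step size


class SolverError(RuntimeError):
    """Newton iteration failed to converge after all cutbacks."""


class InvertedElementError(FloatingPointError):
    """An element reached non-positive Jacobian during assembly."""


# gravity unit vectors per pose; X lateral, Y anterior, Z cranial
GRAVITY_POSES = {
    "prone": np.array([0.0, 1.0, 0.0]),     # breast pulled anteriorly
    "supine": np.array([0.0, -1.0, 0.0]),
    "upright": np.array([0.0, 0.0, -1.0]),
}


@dataclass
class Material:
    """Mooney-Rivlin bulk material: W = c1(I1b-3) + c2(I2b-3) + kappa/2 (J-1)^2."""

    c1: float       # Pa
    c2: float       # Pa
    kappa: float    # Pa, incompressibility penalty (~bulk modulus)
    rho0: float     # kg/m^3

    def validate(self):
        if min(self.c1, self.kappa, self.rho0) <= 0 or self.c2 < 0:
            raise ValueError("Mooney-Rivlin parameters must be positive (c2 >= 0)")


@dataclass
class SkinMaterial:
    """Veronda-Westmann membrane: W = a[e^{b(I1-3)} - 1] + c2(I2-3), incompressible."""

    alpha: float    # Pa
    beta: float     # dimensionless
    c2: float       # Pa (classically negative, -alpha*beta/2)
    rho0: float = 1100.0

    def validate(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("skin alpha and beta must be positive")


@dataclass
class ActiveParams:
    """Fibroblast traction: S_active = tau_f * (alpha_f * eta/eta0) * eta0_f * I."""

    tau_f: float        # Pa per unit fibroblast density (Pa m^3/cell)
    alpha_f: float      # dimensionless proportionality
    eta0_f: float       # reference fibroblast density, cell/m^3
    wound_only: bool = True   # apply only in wound-labelled elements

    @property
    def peak_stress(self) -> float:
        """Active stress at full recovery (eta = eta0), Pa."""
        return self.tau_f * self.alpha_f * self.eta0_f


@dataclass
class MaterialSet:
    adipose: Material
    fibroglandular: Material
    wound: Material
    skin: SkinMaterial
    active: ActiveParams
    damage_volumetric: bool = False   # if True, (1-zeta) also scales the kappa term

    def validate(self):
        for m in (self.adipose, self.fibroglandular, self.wound):
            m.validate()
        self.skin.validate()

    def arrays(self, mesh: LabeledMesh) -> dict[str, np.ndarray]:
        """Per-element c1, c2, kappa, rho0 resolved from region labels."""
        by_region = {
            int(Region.ADIPOSE): self.adipose,
            int(Region.FIBROGLANDULAR): self.fibroglandular,
            int(Region.WOUND): self.wound,
        }
        out = {}
        for name in ("c1", "c2", "kappa", "rho0"):
            out[name] = np.array(
                [getattr(by_region[int(r)], name) for r in mesh.tet_region]
            )
        return out


@dataclass
class MechState:
    """Converged mechanical state."""

    u: np.ndarray                  # (N, 3) nodal displacement, m
    pressure: np.ndarray           # (M,) element hydrostatic pressure, Pa
    zeta: np.ndarray               # (M,) element damage used for the solve
    body_force: np.ndarray         # gravity vector actually applied, m/s^2
    reactions: np.ndarray          # (N, 3) reaction forces at constrained dofs
    log: list = field(default_factory=list)


@dataclass
class NewtonOptions:
    tol_rel: float = 1e-8
    tol_abs: float = 1e-10
    max_iter: int = 25
    n_increments: int = 5
    max_cutbacks: int = 4
    line_search: int = 8


# ---------------------------------------------------------------------------
# constitutive point functions (work on (..., 3, 3) arrays, real or complex)
# ---------------------------------------------------------------------------


def _invariants(F):
    C = np.einsum("...ki,...kj->...ij", F, F)
    J = np.linalg.det(F)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    C2 = np.einsum("...ik,...kj->...ij", C, C)
    I2 = 0.5 * (I1**2 - np.trace(C2, axis1=-2, axis2=-1))
    return C, J, I1, I2


def strain_energy_tissue(F, material: Material, zeta=0.0,
                         damage_volumetric: bool = False):
    """Damage-scaled Mooney-Rivlin energy density (J/m^3).

    The isochoric part is multiplied by the integrity factor (1 - zeta); the
    volumetric penalty stays intact unless ``damage_volumetric`` is set.
    """
    F = np.asarray(F)
    _, J, I1, I2 = _invariants(F)
    if np.any(np.real(J) <= 0):
        raise InvertedElementError("non-positive Jacobian in energy evaluation")
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    w_iso = material.c1 * (I1b - 3.0) + material.c2 * (I2b - 3.0)
    w_vol = 0.5 * material.kappa * (J - 1.0) ** 2
    g = 1.0 - np.minimum(np.asarray(zeta), 1.0 - _EPS_ZETA)
    if damage_volumetric:
        return g * (w_iso + w_vol)
    return g * w_iso + w_vol


def _pk2_elements(F, c1, c2, kappa, zeta, tau_act, damage_volumetric=False):
    """Vectorised total 2nd PK stress per element; complex-safe."""
    C, J, I1, I2 = _invariants(F)
    if np.any(np.real(J) <= 0):
        raise InvertedElementError("non-positive Jacobian")
    Cinv = np.linalg.inv(C)
    eye = np.broadcast_to(np.eye(3, dtype=F.dtype), F.shape)
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = J ** (-4.0 / 3.0)
    b = np.broadcast_to
    sh = F.shape[:-2] + (1, 1)
    S_iso = 2.0 * (
        b(c1.reshape(-1, 1, 1), F.shape) * Jm23.reshape(sh)
        * (eye - (I1 / 3.0).reshape(sh) * Cinv)
        + b(c2.reshape(-1, 1, 1), F.shape) * Jm43.reshape(sh)
        * (I1.reshape(sh) * eye - C - (2.0 / 3.0) * I2.reshape(sh) * Cinv)
    )
    S_vol = (kappa.reshape(-1, 1, 1) * (J - 1.0).reshape(sh)) * J.reshape(sh) * Cinv
    g = (1.0 - np.minimum(zeta, 1.0 - _EPS_ZETA)).reshape(-1, 1, 1)
    if damage_volumetric:
        S = g * (S_iso + S_vol)
    else:
        S = g * S_iso + S_vol
    return S + tau_act.reshape(-1, 1, 1) * eye


def pk2_stress(F, material: Material, zeta: float = 0.0,
               eta_norm: float = 0.0, in_wound: bool = False,
               active: ActiveParams | None = None,
               damage_volumetric: bool = False) -> np.ndarray:
    """Total 2nd Piola-Kirchhoff stress at a single deformation gradient.

    Passive stress is the exact derivative of :func:`strain_energy_tissue`
    with respect to the Green-Lagrange strain; the active fibroblast
    traction ``tau_f * alpha_f * eta_norm * eta0_f * I`` is added where the
    point lies in the wound (or everywhere if the active model is global).
    """
    F = np.asarray(F, dtype=float).reshape(1, 3, 3)
    tau = 0.0
    if active is not None and (in_wound or not active.wound_only):
        tau = active.tau_f * active.alpha_f * max(eta_norm, 0.0) * active.eta0_f
    S = _pk2_elements(
        F, np.array([material.c1]), np.array([material.c2]),
        np.array([material.kappa]), np.array([float(zeta)]),
        np.array([tau]), damage_volumetric,
    )
    return S[0]


# ---------------------------------------------------------------------------
# membrane (skin) element routines
# ---------------------------------------------------------------------------


def _membrane_setup(nodes, tris):
    x = nodes[tris]
    e1 = x[:, 1] - x[:, 0]
    e2 = x[:, 2] - x[:, 0]
    n = np.cross(e1, e2)
    A0 = 0.5 * np.linalg.norm(n, axis=1)
    if np.any(A0 <= 0):
        raise InvertedElementError("degenerate skin triangle")
    t1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
    nn = n / (2.0 * A0)[:, None]
    t2 = np.cross(nn, t1)
    a = np.empty((tris.shape[0], 2, 2))
    a[:, 0, 0] = np.einsum("ij,ij->i", e1, t1)
    a[:, 0, 1] = np.einsum("ij,ij->i", e2, t1)
    a[:, 1, 0] = np.einsum("ij,ij->i", e1, t2)
    a[:, 1, 1] = np.einsum("ij,ij->i", e2, t2)
    return A0, np.linalg.inv(a)


def _membrane_energy(xtri, A0, a_inv, skin: SkinMaterial, thickness):
    """Membrane strain energy per element (complex-safe).

    Plane stress with exact through-thickness incompressibility: for surface
    right Cauchy-Green C2 (2x2), the 3D invariants are
    I1 = tr C2 + 1/det C2 and I2 = det C2 + tr C2 / det C2.
    """
    e1 = xtri[:, 1] - xtri[:, 0]
    e2 = xtri[:, 2] - xtri[:, 0]
    m11 = np.einsum("ij,ij->i", e1, e1)
    m12 = np.einsum("ij,ij->i", e1, e2)
    m22 = np.einsum("ij,ij->i", e2, e2)
    m = np.empty(xtri.shape[:1] + (2, 2), dtype=xtri.dtype)
    m[:, 0, 0], m[:, 0, 1], m[:, 1, 0], m[:, 1, 1] = m11, m12, m12, m22
    C2 = np.einsum("eki,ekl,elj->eij", a_inv, m, a_inv)
    tr = C2[:, 0, 0] + C2[:, 1, 1]
    det = C2[:, 0, 0] * C2[:, 1, 1] - C2[:, 0, 1] * C2[:, 1, 0]
    I1 = tr + 1.0 / det
    I2 = det + tr / det
    W = skin.alpha * (np.exp(skin.beta * (I1 - 3.0)) - 1.0) + skin.c2 * (I2 - 3.0)
    return A0 * thickness * W


def _membrane_forces(xtri, A0, a_inv, skin, thickness):
    """Nodal forces dE/dx via complex step over the 9 coordinates."""
    f = np.zeros_like(xtri)
    for a in range(3):
        for i in range(3):
            xc = xtri.astype(complex)
            xc[:, a, i] += 1j * _CS_H
            f[:, a, i] = np.imag(
                _membrane_energy(xc, A0, a_inv, skin, thickness)
            ) / _CS_H
    return f


# ---------------------------------------------------------------------------
# model: assembly and Newton solve
# ---------------------------------------------------------------------------


def standard_bcs(mesh: LabeledMesh) -> np.ndarray:
    """Constrained-dof mask: chest fixed, clip planes u_Z = 0, rest free."""
    fixed = np.zeros((mesh.num_nodes, 3), dtype=bool)
    fixed[mesh.patch_nodes(Patch.CHEST), :] = True
    for p in (Patch.CLIP_INFERIOR, Patch.CLIP_SUPERIOR):
        fixed[mesh.patch_nodes(p), 2] = True
    return fixed


class MechModel:
    """Assembled mechanical model bound to one mesh and material set."""

    def __init__(self, mesh: LabeledMesh, materials: MaterialSet,
                 bcs: np.ndarray | None = None,
                 formulation: str = "penalty",
                 include_skin: bool = True):
        if formulation not in ("penalty", "anp"):
            raise ValueError("formulation must be 'penalty' or 'anp'")
        materials.validate()
        self.mesh = mesh
        self.materials = materials
        self.formulation = formulation
        self.fixed = standard_bcs(mesh) if bcs is None else bcs
        self.free = ~self.fixed.reshape(-1)

        x = mesh.nodes[mesh.tets]
        D = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=2)
        self.vol = np.linalg.det(D) / 6.0
        Dinv = np.linalg.inv(D)
        g = np.empty((mesh.num_tets, 4, 3))
        g[:, 1:, :] = Dinv      # rows of D^-1: grad phi_a . edge_b = delta_ab
        g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
        self.grads = g
        self.mat = materials.arrays(mesh)
        self.wound = mesh.tet_region == int(Region.WOUND)

        self.skin_tris = mesh.skin_shell if include_skin else np.empty((0, 3), int)
        if len(self.skin_tris):
            self.skin_A0, self.skin_ainv = _membrane_setup(mesh.nodes, self.skin_tris)
        self.ndof = mesh.num_nodes * 3

        # sparsity pattern indices for fast COO assembly of the bulk tangent
        t = mesh.tets
        self._rows = (
            (3 * t[:, :, None, None, None] + np.arange(3)[None, None, :, None, None])
            * np.ones((1, 1, 1, 4, 3), dtype=np.int64)
        ).reshape(-1)
        self._cols = (
            (3 * t[:, None, None, :, None] + np.arange(3)[None, None, None, None, :])
            * np.ones((1, 4, 3, 1, 1), dtype=np.int64)
        ).reshape(-1)

    # -- kinematics ----------------------------------------------------------

    def deformation_gradients(self, u):
        ue = u.reshape(-1, 3)[self.mesh.tets]
        F = np.eye(3, dtype=ue.dtype)[None] + np.einsum(
            "eai,eaj->eij", ue, self.grads.astype(ue.dtype)
        )
        return F

    def element_tau(self, eta_norm_el: np.ndarray | None) -> np.ndarray:
        """Active-stress magnitude per element from normalised cell density."""
        act = self.materials.active
        tau = np.zeros(self.mesh.num_tets)
        if eta_norm_el is None or act.peak_stress == 0.0:
            return tau
        mask = self.wound if act.wound_only else np.ones_like(self.wound)
        tau[mask] = act.tau_f * act.alpha_f * np.maximum(eta_norm_el[mask], 0.0) \
            * act.eta0_f
        return tau

    # -- external load -------------------------------------------------------

    def gravity_forces(self, b: np.ndarray) -> np.ndarray:
        """Consistent (lumped) nodal gravity load, bulk plus skin shell."""
        f = np.zeros((self.mesh.num_nodes, 3))
        w = (self.mat["rho0"] * self.vol / 4.0)[:, None] * b[None, :]
        for a in range(4):
            np.add.at(f, self.mesh.tets[:, a], w)
        if len(self.skin_tris):
            ws = (self.materials.skin.rho0 * self.skin_A0
                  * self.mesh.skin_thickness / 3.0)[:, None] * b[None, :]
            for a in range(3):
                np.add.at(f, self.skin_tris[:, a], ws)
        return f

    # -- assembly ------------------------------------------------------------

    def _bulk_stress(self, F, zeta, tau, kappa):
        return _pk2_elements(
            F, self.mat["c1"], self.mat["c2"], kappa, zeta, tau,
            self.materials.damage_volumetric,
        )

    def assemble(self, u, zeta=None, tau=None, f_ext=None, tangent=True):
        """Residual r = f_int - f_ext and (optionally) consistent tangent K."""
        mesh = self.mesh
        zeta = np.zeros(mesh.num_tets) if zeta is None else zeta
        tau = np.zeros(mesh.num_tets) if tau is None else tau
        kappa = self.mat["kappa"] if self.formulation == "penalty" \
            else np.zeros(mesh.num_tets)

        F = self.deformation_gradients(u)
        S = self._bulk_stress(F, zeta, tau, kappa)
        P = np.einsum("eij,ejk->eik", F, S)
        fe = self.vol[:, None, None] * np.einsum("eik,eak->eai", P, self.grads)
        r = np.zeros((mesh.num_nodes, 3))
        for a in range(4):
            np.add.at(r, mesh.tets[:, a], fe[:, a, :])

        K = None
        if tangent:
            A = np.empty((mesh.num_tets, 3, 3, 3, 3))   # A[e,i,k,j,l]=dP_ik/dF_jl
            for j in range(3):
                for l in range(3):
                    Fc = F.astype(complex)
                    Fc[:, j, l] += 1j * _CS_H
                    Sc = self._bulk_stress(Fc, zeta, tau, kappa)
                    Pc = np.einsum("eij,ejk->eik", Fc, Sc)
                    A[:, :, :, j, l] = np.imag(Pc) / _CS_H
            ke = np.einsum(
                "e,eikjl,eak,ebl->eaibj", self.vol, A, self.grads, self.grads
            )
            K = sp.coo_matrix(
                (ke.reshape(-1), (self._rows, self._cols)),
                shape=(self.ndof, self.ndof),
            ).tocsr()

        if self.formulation == "anp":
            r_anp, K_anp = self._anp_volumetric(u, zeta, tangent)
            r += r_anp
            if tangent:
                K = K + K_anp

        if len(self.skin_tris):
            xs = (mesh.nodes + u.reshape(-1, 3))[self.skin_tris]
            fs = _membrane_forces(
                xs, self.skin_A0, self.skin_ainv, self.materials.skin,
                mesh.skin_thickness,
            )
            for a in range(3):
                np.add.at(r, self.skin_tris[:, a], fs[:, a, :])
            if tangent:
                K = K + self._membrane_tangent(xs)

        if f_ext is not None:
            r = r - f_ext
        return r.reshape(-1), K

    def _anp_volumetric(self, u, zeta, tangent):
        """Average-nodal-pressure volumetric term (locking relief for P1 tets).

        E_vol = sum_nodes kappa_a/2 (Jbar_a - 1)^2 V_a with Jbar_a the
        volume-weighted average Jacobian of the elements around node a.
        The consistent tangent is G^T D G plus the curvature term built
        from d2J/dF2 = J (F^-T x F^-T - F^-1 . F^-1).
        """
        mesh = self.mesh
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvertedElementError("non-positive Jacobian")
        Finv_T = np.transpose(np.linalg.inv(F), (0, 2, 1))
        # dJ/du_{a i} = J * Finv_T[i, j] * g[a, j]
        dJ = J[:, None, None] * np.einsum("eij,eaj->eai", Finv_T, self.grads)
        w = self.vol / 4.0
        Va = np.zeros(mesh.num_nodes)
        num = np.zeros(mesh.num_nodes)
        ka_num = np.zeros(mesh.num_nodes)
        kappa_el = self.mat["kappa"]
        if self.materials.damage_volumetric:
            kappa_el = kappa_el * (1.0 - np.minimum(zeta, 1.0 - _EPS_ZETA))
        for a in range(4):
            np.add.at(Va, mesh.tets[:, a], w)
            np.add.at(num, mesh.tets[:, a], w * J)
            np.add.at(ka_num, mesh.tets[:, a], w * kappa_el)
        Jbar = num / Va
        kappa_a = ka_num / Va
        # G[a, dof] = d(Va*Jbar_a)/du = sum_e w_e dJ_e/du
        rows = np.repeat(mesh.tets.reshape(-1), 12)
        cols = np.broadcast_to(
            (3 * mesh.tets[:, None, :, None] + np.arange(3)[None, None, None, :]),
            (mesh.num_tets, 4, 4, 3),
        ).reshape(-1)
        vals = np.broadcast_to(
            (w[:, None, None, None] * dJ[:, None, :, :]),
            (mesh.num_tets, 4, 4, 3),
        ).reshape(-1)
        G = sp.coo_matrix(
            (vals, (rows, cols)), shape=(mesh.num_nodes, self.ndof)
        ).tocsr()
        coef = kappa_a * (Jbar - 1.0)
        r = (G.T @ coef).reshape(-1, 3)
        K = None
        if tangent:
            D = sp.diags(kappa_a / Va)
            K = (G.T @ D @ G).tocsr()
            # curvature: sum_e (V_e/4)(sum_{a in e} coef_a) d2J_e/du2
            ce = coef[mesh.tets].sum(axis=1) * w
            Finv = np.linalg.inv(F)
            FiT = np.transpose(Finv, (0, 2, 1))
            A2 = J[:, None, None, None, None] * (
                np.einsum("eik,ejl->eikjl", FiT, FiT)
                - np.einsum("ekj,eli->eikjl", Finv, Finv)
            )
            ke2 = np.einsum("e,eikjl,eak,ebl->eaibj", ce, A2, self.grads, self.grads)
            K = K + sp.coo_matrix(
                (ke2.reshape(-1), (self._rows, self._cols)),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        return r, K

    def _membrane_tangent(self, xs):
        """Central finite difference of the membrane forces (symmetrised)."""
        ntri = xs.shape[0]
        scale = np.sqrt(self.skin_A0).mean()
        h = 1e-7 * max(scale, 1e-6)
        ke = np.empty((ntri, 3, 3, 3, 3))
        for b in range(3):
            for j in range(3):
                xp = xs.copy()
                xp[:, b, j] += h
                xm = xs.copy()
                xm[:, b, j] -= h
                fp = _membrane_forces(xp, self.skin_A0, self.skin_ainv,
                                      self.materials.skin, self.mesh.skin_thickness)
                fm = _membrane_forces(xm, self.skin_A0, self.skin_ainv,
                                      self.materials.skin, self.mesh.skin_thickness)
                ke[:, :, :, b, j] = (fp - fm) / (2.0 * h)
        ke = 0.5 * (ke + np.transpose(ke, (0, 3, 4, 1, 2)))
        t = self.skin_tris
        rows = (
            (3 * t[:, :, None, None, None] + np.arange(3)[None, None, :, None, None])
            * np.ones((1, 1, 1, 3, 3), dtype=np.int64)
        ).reshape(-1)
        cols = (
            (3 * t[:, None, None, :, None] + np.arange(3)[None, None, None, None, :])
            * np.ones((1, 3, 3, 1, 1), dtype=np.int64)
        ).reshape(-1)
        return sp.coo_matrix(
            (ke.reshape(-1), (rows, cols)), shape=(self.ndof, self.ndof)
        ).tocsr()

    # -- nonlinear solve -----------------------------------------------------

    def _newton(self, u, zeta, tau, f_ext, opts, history):
        # converge relative to the applied load, or to the initial imbalance
        # when the load is internally generated (active wound traction)
        scale = float(np.linalg.norm(f_ext.reshape(-1)[self.free]))
        nonmono, anchor = 0, np.inf
        for it in range(opts.max_iter):
            r, K = self.assemble(u, zeta, tau, f_ext)
            rn = float(np.linalg.norm(r[self.free]))
            history.append(rn)
            if it == 0:
                scale = max(scale, rn, opts.tol_abs)
            if rn <= opts.tol_rel * scale + opts.tol_abs:
                return u, True
            if rn < anchor:
                nonmono, anchor = 0, np.inf
            Kff = K[self.free][:, self.free].tocsc()
            du = spla.spsolve(Kff, -r[self.free])
            if not np.all(np.isfinite(du)):
                return u, False
            # correction at the round-off floor of the residual: converged to
            # the accuracy representable at this stiffness scale
            if np.abs(du).max() < 1e-13 * (1.0 + np.abs(u).max()):
                return u, True
            alpha = 1.0
            full_step = None
            for _ in range(opts.line_search):
                u_try = u.copy()
                u_try.reshape(-1)[self.free] += alpha * du
                try:
                    r_try, _ = self.assemble(u_try, zeta, tau, f_ext, tangent=False)
                    rn_try = float(np.linalg.norm(r_try[self.free]))
                except InvertedElementError:
                    rn_try = np.inf
                if alpha == 1.0 and np.isfinite(rn_try):
                    full_step = u_try
                if np.isfinite(rn_try) and rn_try < rn:
                    u = u_try
                    break
                alpha *= 0.5
            else:
                # non-monotone watchdog: near sharp nonlinearities the full
                # Newton step can transiently raise the residual norm while
                # still being on the convergent path; allow a short burst of
                # full steps, anchored so sustained growth aborts
                if full_step is not None and nonmono < 4:
                    if nonmono == 0:
                        anchor = rn
                    nonmono += 1
                    u = full_step
                else:
                    return u, False
        return u, False

    def solve_static(
        self,
        gravity: np.ndarray | None = None,
        zeta: np.ndarray | None = None,
        eta_norm_el: np.ndarray | None = None,
        init: MechState | None = None,
        opts: NewtonOptions | None = None,
        fixed_values: np.ndarray | None = None,
    ) -> MechState:
        """Solve quasi-static equilibrium under gravity, damage and traction.

        The total load (gravity body force plus active wound traction) is
        ramped in increments with automatic halving on divergence; each
        increment is solved by Newton iteration with backtracking line
        search.  The converged state carries element pressures
        kappa (J - 1) and the reaction forces on the constrained dofs.
        """
        opts = opts or NewtonOptions()
        b = np.zeros(3) if gravity is None else np.asarray(gravity, dtype=float)
        zeta = np.zeros(self.mesh.num_tets) if zeta is None else np.asarray(zeta)
        tau_full = self.element_tau(eta_norm_el)
        u = np.zeros(self.ndof) if init is None else init.u.reshape(-1).copy()
        fv = None if fixed_values is None else np.asarray(fixed_values).reshape(-1)
        f_grav = self.gravity_forces(b)

        def set_prescribed(vec, lam):
            if fv is not None:
                vec[~self.free] = lam * fv[~self.free]
            return vec

        history: list[float] = []
        lam_done, dlam, cutbacks = 0.0, 1.0 / opts.n_increments, 0
        # warm-started states often converge in a single full-load solve
        if init is not None:
            u_try, ok = self._newton(
                set_prescribed(u.copy(), 1.0), zeta, tau_full, f_grav, opts, history
            )
            if ok:
                return self._finish(u_try, zeta, tau_full, b, f_grav, history)
            u = np.zeros(self.ndof)
        while lam_done < 1.0 - 1e-12:
            lam = min(1.0, lam_done + dlam)
            u_try, ok = self._newton(
                set_prescribed(u.copy(), lam), zeta, lam * tau_full,
                lam * f_grav, opts, history,
            )
            if ok:
                u, lam_done = u_try, lam
            else:
                cutbacks += 1
                dlam *= 0.5
                if cutbacks > opts.max_cutbacks:
                    raise SolverError(
                        f"Newton failed at load factor {lam:.3g} after "
                        f"{cutbacks} cutbacks; residual history {history[-5:]}"
                    )
        return self._finish(u, zeta, tau_full, b, f_grav, history)

    def _finish(self, u, zeta, tau, b, f_grav, history):
        F = self.deformation_gradients(u)
        J = np.linalg.det(F)
        pressure = self.mat["kappa"] * (J - 1.0)
        r, _ = self.assemble(u, zeta, tau, f_grav, tangent=False)
        # constraint force on the body at dof c is (f_int - f_ext)_c, so the
        # reactions sum to the negative of the total applied load
        reactions = np.where(self.fixed, r.reshape(-1, 3), 0.0)
        return MechState(
            u.reshape(-1, 3), pressure, zeta.copy(), b.copy(), reactions,
            log=history,
        )
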