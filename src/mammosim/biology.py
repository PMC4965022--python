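"""Five-species wound-healing and angiogenesis model on a fixed tet mesh.

State variables (nodal fields):

* ``eta``      cell density (cells / m^3) — fibroblasts and other tissue cells
* ``sigma_c``  mitosis-regulating growth-factor concentration (arbitrary units)
* ``upsilon``  microvascular (capillary) density (1/m)
* ``xi``       normalised oxygen / nutrient level (dimensionless, ~1 healthy)
* ``mu``       macrophage-derived growth factor, MDGF (arbitrary units)

Cells obey a Fisher–KPP-type reaction–diffusion law whose mitotic source is
modulated chemically (activator or inhibitor kinetics) and gated by the local
oxygen level.  Capillaries grow logistically — no spatial transport term —
at a rate controlled by the MDGF level; oxygen is supplied by capillaries and
consumed by the tissue; MDGF is released by hypoxic macrophages inside the
wound and decays elsewhere.

Space is discretised with linear tetrahedra (Galerkin stiffness, row-sum
lumped mass, zero-flux natural boundaries) and time with forward Euler under
a CFL restriction; sources are evaluated nodally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mesh import LabeledMesh, GeometryError, Region, region_volume

__all__ = [
    "BioParams", "SpeciesState", "Operators", "StepOptions", "DivergenceError",
    "source_S", "source_H", "source_Q", "source_K",
    "assemble_operators", "initialize_state", "classify_nodes",
    "cfl_max_dt", "explicit_step", "run_healing",
]

log = logging.getLogger(__name__)

SPECIES = ("eta", "sigma_c", "upsilon", "xi", "mu")


class DivergenceError(FloatingPointError):
    """Raised when the explicit update produces non-finite values."""


@dataclass
class BioParams:
    """Biochemical coefficients of the healing / angiogenesis system (SI).

    Two constraints make the healthy state ``(eta0, sigma0, upsilon0, 1, 0)``
    an exact fixed point of the kinetics, so undamaged tissue does not drift:

    * the cell loss rate ``k = k_sigma * S(sigma0) * eta0`` with
      ``sigma0 = ell_eta * eta0 / ell``;
    * the oxygen supply rate ``lambda_upsilon = lam / upsilon0``.

    Both are derived at construction; explicitly supplied inconsistent values
    are overridden (and logged).  All defaults live in the versioned
    parameter file ``data/defaults.yaml``; use :meth:`default`.
    """

    D_eta: float            # cell random-motility coefficient, m^2/s
    D_sigma: float          # growth-factor diffusivity, m^2/s
    D_xi: float             # oxygen diffusivity, m^2/s
    D_mu: float             # MDGF diffusivity, m^2/s
    k_sigma: float          # cell production rate, m^3 cell^-1 s^-1
    eta0: float             # reference cell density, cell/m^3
    h0: float               # inhibitor-mode mitosis parameter
    h1: float               # activator-mode mitosis amplitude
    h2: float               # activator-mode mitosis offset
    ell_eta: float          # growth-factor production by cells, units m^3 cell^-1 s^-1
    ell: float              # growth-factor decay rate, 1/s
    beta: float             # capillary growth rate, m/s
    upsilon0: float         # reference capillary density, 1/m
    mu0: float              # MDGF reference concentration, units
    lam: float              # oxygen consumption rate, 1/s
    phi_xi: float           # MDGF release rate under hypoxia, units/s
    phi: float              # MDGF decay rate, 1/s
    xi_hat: float           # oxygen threshold for MDGF release, in (0,1)
    xi_tilde: float         # oxygen threshold for full mitosis rate, in (0,1)
    mitosis_mode: str = "activator"
    sigma_bar: float | None = None     # activator half-max concentration; sigma0 if None
    k: float | None = None             # cell loss rate, 1/s (derived)
    lambda_upsilon: float | None = None  # oxygen production per capillary, m/s (derived)
    # initial conditions inside the wound, as fractions of the references;
    # exactly zero initial density makes the logistic kinetics unable to
    # regrow in the wound interior, so the study default is a small seed
    eta_init_wound: float = 0.0
    upsilon_init_wound: float = 0.0
    xi_init_wound: float = 0.0

    def __post_init__(self) -> None:
        self.validate()
        self.sigma0 = self.ell_eta * self.eta0 / self.ell
        if self.sigma_bar is None:
            self.sigma_bar = self.sigma0
        k_derived = self.k_sigma * float(source_S(self.sigma0, self)) * self.eta0
        if self.k is not None and not np.isclose(self.k, k_derived, rtol=1e-10):
            log.warning(
                "cell loss rate k=%.6g violates healthy homeostasis; "
                "overriding with k = k_sigma*S(sigma0)*eta0 = %.6g",
                self.k, k_derived,
            )
        self.k = k_derived
        lu_derived = self.lam / self.upsilon0
        if self.lambda_upsilon is not None and not np.isclose(
            self.lambda_upsilon, lu_derived, rtol=1e-10
        ):
            log.warning(
                "oxygen supply rate lambda_upsilon=%.6g violates homeostasis; "
                "overriding with lam/upsilon0 = %.6g",
                self.lambda_upsilon, lu_derived,
            )
        self.lambda_upsilon = lu_derived

    def validate(self) -> None:
        errors = []
        for name in ("D_eta", "D_sigma", "D_xi", "D_mu", "k_sigma", "ell_eta",
                     "ell", "beta", "lam", "phi_xi", "phi"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("eta0", "upsilon0", "mu0"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        for name in ("xi_hat", "xi_tilde"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                errors.append(f"{name} must lie in (0, 1)")
        if self.mitosis_mode not in ("activator", "inhibitor"):
            errors.append("mitosis_mode must be 'activator' or 'inhibitor'")
        for name in ("eta_init_wound", "upsilon_init_wound", "xi_init_wound"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if errors:
            raise ValueError("invalid BioParams: " + "; ".join(errors))

    @classmethod
    def default(cls) -> "BioParams":
        from .config import default_bio_params

        return default_bio_params()

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.D_eta, self.D_sigma, 0.0, self.D_xi, self.D_mu])


@dataclass
class SpeciesState:
    """Nodal fields of the five-species model."""

    eta: np.ndarray
    sigma_c: np.ndarray
    upsilon: np.ndarray
    xi: np.ndarray
    mu: np.ndarray
    t: float = 0.0

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            self.eta.copy(), self.sigma_c.copy(), self.upsilon.copy(),
            self.xi.copy(), self.mu.copy(), self.t,
        )

    def as_array(self) -> np.ndarray:
        return np.stack([self.eta, self.sigma_c, self.upsilon, self.xi, self.mu])

    def check_finite(self) -> None:
        for name in SPECIES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise DivergenceError(f"non-finite values in species '{name}'")


# ---------------------------------------------------------------------------
# kinetic source functions
# ---------------------------------------------------------------------------


def source_S(sigma_c, params: BioParams):
    """Chemical modulation of cell mitosis (activator or inhibitor kinetics).

    Activator: S = 2 h1 sigma_bar sigma / (sigma_bar^2 + sigma^2) + h2.
    Inhibitor: S = ((h0-1) sigma + h0 sigma0) / (2 (h0-1) sigma + sigma0).
    The inhibitor expression is typeset ambiguously in the source literature;
    the form above is the classical epidermal-healing inhibitor law, which
    satisfies S(sigma0) = 1, S(0) = h0 and S(inf) = 1/2.
    """
    s = np.asarray(sigma_c, dtype=float)
    if params.mitosis_mode == "activator":
        sb = params.sigma_bar
        return 2.0 * params.h1 * sb * s / (sb * sb + s * s) + params.h2
    h0, s0 = params.h0, params.sigma0
    return ((h0 - 1.0) * s + h0 * s0) / (2.0 * (h0 - 1.0) * s + s0)


def source_H(mu, params: BioParams):
    """Capillary-production response to the MDGF level: H = 3 mu/(2 mu0 + mu)."""
    m = np.asarray(mu, dtype=float)
    return 3.0 * m / (2.0 * params.mu0 + m)


def source_Q(xi, in_wound, params: BioParams):
    """Hypoxia-triggered MDGF release: 1 - xi/xi_hat in hypoxic wound, else 0."""
    x = np.asarray(xi, dtype=float)
    w = np.asarray(in_wound, dtype=bool)
    return np.where(w & (x < params.xi_hat), 1.0 - x / params.xi_hat, 0.0)


def source_K(xi, params: BioParams):
    """Oxygen-gated cell production rate: linear below xi_tilde, k_sigma above."""
    x = np.asarray(xi, dtype=float)
    return np.where(
        x < params.xi_tilde, params.k_sigma * x / params.xi_tilde, params.k_sigma
    )


# ---------------------------------------------------------------------------
# discrete operators and state setup
# ---------------------------------------------------------------------------


@dataclass
class Operators:
    """P1 discrete operators and the node/element wound classification."""

    stiffness: sp.csr_matrix     # Galerkin Laplacian (zero-flux natural BCs)
    lumped_mass: np.ndarray      # row-sum lumped mass (per node)
    grads: np.ndarray            # (M, 4, 3) shape-function gradients
    volumes: np.ndarray          # (M,) element volumes
    wound_elements: np.ndarray   # bool per element
    wound_nodes_strict: np.ndarray   # all incident elements are wound
    wound_nodes_any: np.ndarray      # at least one incident element is wound


def _p1_grads(mesh: LabeledMesh) -> tuple[np.ndarray, np.ndarray]:
    x = mesh.nodes[mesh.tets]
    D = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=2)
    vol = np.linalg.det(D) / 6.0
    if np.any(vol <= 0):
        raise GeometryError("degenerate element in operator assembly")
    Dinv = np.linalg.inv(D)
    g = np.empty((mesh.num_tets, 4, 3))
    g[:, 1:, :] = Dinv          # rows of D^-1: grad phi_a . edge_b = delta_ab
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def classify_nodes(mesh: LabeledMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-node wound flags: (all incident tets wound, any incident tet wound)."""
    wound_el = mesh.tet_region == int(Region.WOUND)
    incident_any = np.zeros(mesh.num_nodes, dtype=bool)
    incident_healthy = np.zeros(mesh.num_nodes, dtype=bool)
    incident_any[np.unique(mesh.tets[wound_el])] = True
    incident_healthy[np.unique(mesh.tets[~wound_el])] = True
    strict = incident_any & ~incident_healthy
    return strict, incident_any


def assemble_operators(mesh: LabeledMesh) -> Operators:
    """Assemble the P1 stiffness and lumped mass with zero-flux boundaries."""
    grads, vol = _p1_grads(mesh)
    # K_e[a,b] = V * g_a . g_b
    ke = np.einsum("e,eai,ebi->eab", vol, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (ke.reshape(-1), (rows, cols)), shape=(mesh.num_nodes, mesh.num_nodes)
    ).tocsr()
    m = np.zeros(mesh.num_nodes)
    np.add.at(m, mesh.tets.reshape(-1), np.repeat(vol / 4.0, 4))
    if np.any(m <= 0):
        raise GeometryError("singular lumped mass (degenerate element)")
    strict, any_ = classify_nodes(mesh)
    return Operators(
        K, m, grads, vol, mesh.tet_region == int(Region.WOUND), strict, any_
    )


def initialize_state(mesh: LabeledMesh, params: BioParams,
                     ops: Operators | None = None) -> SpeciesState:
    """Initial conditions: healthy tissue at homeostasis, wound depleted.

    Nodes whose incident elements are all wound-labelled start at the wound
    values (small seed fractions of the references, zero by default); nodes
    touching any healthy element — including the wound/healthy interface —
    take the healthy values eta0, upsilon0, xi = 1.  The two growth factors
    start at zero everywhere.
    """
    strict, _ = classify_nodes(mesh) if ops is None else (
        ops.wound_nodes_strict, ops.wound_nodes_any)
    n = mesh.num_nodes
    eta = np.full(n, params.eta0)
    ups = np.full(n, params.upsilon0)
    xi = np.ones(n)
    eta[strict] = params.eta_init_wound * params.eta0
    ups[strict] = params.upsilon_init_wound * params.upsilon0
    xi[strict] = params.xi_init_wound
    return SpeciesState(eta, np.zeros(n), ups, xi, np.zeros(n))


def cfl_max_dt(mesh: LabeledMesh, params: BioParams, safety: float = 1.0) -> float:
    """Forward-Euler diffusion stability bound dt = safety*min_e h_min^2/(2 d Dmax)."""
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety factor must lie in (0, 1]")
    d_max = float(np.max(params.diffusivities))
    if d_max == 0.0:
        return np.inf
    x = mesh.nodes[mesh.tets]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge2 = np.stack(
        [np.einsum("ij,ij->i", x[:, a] - x[:, b], x[:, a] - x[:, b]) for a, b in pairs],
        axis=1,
    )
    h2_min = edge2.min()
    return safety * h2_min / (2.0 * 3.0 * d_max)


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


@dataclass
class StepOptions:
    """Switches for verification runs (all off for production)."""

    sources_off: bool = False      # pure diffusion (conservation checks)
    freeze_sigma: bool = False     # hold sigma_c fixed
    freeze_mu: bool = False        # hold mu fixed
    oxygen_gating: bool = True     # if False, K(xi) == k_sigma everywhere
    clamp_H: float | None = None   # override H(mu) with a constant


def explicit_step(
    state: SpeciesState, dt: float, ops: Operators, mesh: LabeledMesh,
    params: BioParams, options: StepOptions | None = None,
) -> SpeciesState:
    """One forward-Euler step of the coupled five-species system."""
    opt = options or StepOptions()
    p = params
    eta, sig, ups, xi, mu = state.eta, state.sigma_c, state.upsilon, state.xi, state.mu

    minv = 1.0 / ops.lumped_mass
    K = ops.stiffness

    def lap(q, D):
        return -D * (minv * (K @ q)) if D != 0.0 else 0.0

    if opt.sources_off:
        r_eta = lap(eta, p.D_eta)
        r_sig = lap(sig, p.D_sigma)
        r_ups = np.zeros_like(ups)
        r_xi = lap(xi, p.D_xi)
        r_mu = lap(mu, p.D_mu)
    else:
        Kxi = source_K(xi, p) if opt.oxygen_gating else p.k_sigma
        S = source_S(sig, p)
        H = opt.clamp_H if opt.clamp_H is not None else source_H(mu, p)
        Q = source_Q(xi, ops.wound_nodes_any, p)
        r_eta = lap(eta, p.D_eta) + Kxi * S * (2.0 * p.eta0 * eta - eta * eta) - p.k * eta
        r_sig = lap(sig, p.D_sigma) + p.ell_eta * eta - p.ell * sig
        r_ups = p.beta * H * (p.upsilon0 * ups - ups * ups)
        r_xi = lap(xi, p.D_xi) + p.lambda_upsilon * ups - p.lam * xi
        r_mu = lap(mu, p.D_mu) + p.phi_xi * Q - p.phi * mu

    new = SpeciesState(
        eta + dt * r_eta,
        sig if opt.freeze_sigma else sig + dt * r_sig,
        ups + dt * r_ups,
        xi + dt * r_xi,
        mu if opt.freeze_mu else mu + dt * r_mu,
        state.t + dt,
    )
    new.check_finite()
    return new


def _wound_means(mesh, ops, state, params):
    """Volume-weighted wound-element means of the normalised species."""
    w = ops.wound_elements
    vol = ops.volumes[w]
    conn = mesh.tets[w]
    tot = vol.sum()

    def vmean(q, ref):
        return float((q[conn].mean(axis=1) * vol).sum() / tot / ref)

    return {
        "wound_mean_eta": vmean(state.eta, params.eta0),
        "wound_mean_upsilon": vmean(state.upsilon, params.upsilon0),
        "wound_mean_xi": vmean(state.xi, 1.0),
        "wound_mean_mu": vmean(state.mu, params.mu0),
    }


def run_healing(
    state: SpeciesState, mesh: LabeledMesh, params: BioParams,
    t_end: float, dt: float,
    ops: Operators | None = None,
    options: StepOptions | None = None,
    sample_every: int = 0,
    observers: list | None = None,
) -> tuple[SpeciesState, pd.DataFrame]:
    """Advance the healing system to ``t_end`` with fixed steps of ``dt``.

    ``sample_every`` > 0 records wound-averaged normalised species every that
    many steps (plus the first and last).  ``observers`` are callables
    ``f(t, state)`` invoked at the same sampling instants.
    """
    ops = ops or assemble_operators(mesh)
    if t_end < state.t:
        raise ValueError("t_end precedes the state time")
    n_steps = int(round((t_end - state.t) / dt)) if t_end > state.t else 0
    records = []
    has_wound = bool(np.any(ops.wound_elements))

    def sample(s):
        row = {"time_s": s.t}
        if has_wound:
            row.update(_wound_means(mesh, ops, s, params))
            row["wound_volume_m3"] = region_volume(mesh, Region.WOUND)
        records.append(row)
        for obs in observers or []:
            obs(s.t, s)

    if sample_every > 0:
        sample(state)
    for i in range(n_steps):
        state = explicit_step(state, dt, ops, mesh, params, options)
        if sample_every > 0 and ((i + 1) % sample_every == 0 or i + 1 == n_steps):
            sample(state)
    return state, pd.DataFrame.from_records(records)
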