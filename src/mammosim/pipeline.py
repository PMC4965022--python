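"""Gravity pipeline: unloaded-configuration recovery and posed forward solves.

Imaged breast geometry is acquired under gravity (prone in an MRI coil), so
the mesh read from an image is already a loaded equilibrium.  The reference
(gravity-free) configuration is recovered by a Sellier-style fixed-point
inverse analysis: guess the reference coordinates, forward-solve gravity,
and correct the guess by the mismatch with the acquired shape.  Forward
solves from the unloaded mesh then predict prone, supine and upright shapes.
"""

from __future__ import annotations

import logging

import numpy as np

from .mechanics import (
    GRAVITY_POSES, MaterialSet, MechModel, MechState, NewtonOptions, SolverError,
)
from .mesh import LabeledMesh

__all__ = ["forward_pose", "inverse_unloaded", "InverseError"]

log = logging.getLogger(__name__)


class InverseError(RuntimeError):
    """Unloaded-state fixed-point iteration failed to converge."""

    def __init__(self, msg, residuals):
        super().__init__(msg)
        self.residuals = residuals


def pose_vector(pose: str | np.ndarray, magnitude: float = 9.81) -> np.ndarray:
    if isinstance(pose, str):
        if pose in ("none", "zero"):
            return np.zeros(3)
        if pose not in GRAVITY_POSES:
            raise ValueError(f"unknown pose {pose!r}; use {sorted(GRAVITY_POSES)}")
        return magnitude * GRAVITY_POSES[pose]
    return np.asarray(pose, dtype=float)


def forward_pose(
    unloaded_mesh: LabeledMesh,
    materials: MaterialSet,
    pose: str | np.ndarray = "upright",
    magnitude: float = 9.81,
    formulation: str = "penalty",
    include_skin: bool = True,
    opts: NewtonOptions | None = None,
) -> MechState:
    """Gravity-load the unloaded mesh in the given pose (prone/supine/upright)."""
    b = pose_vector(pose, magnitude)
    model = MechModel(unloaded_mesh, materials, formulation=formulation,
                      include_skin=include_skin)
    return model.solve_static(gravity=b, opts=opts)


def inverse_unloaded(
    loaded_mesh: LabeledMesh,
    materials: MaterialSet,
    gravity_of_acquisition: str | np.ndarray = "prone",
    magnitude: float = 9.81,
    tol: float = 1e-4,
    max_iter: int = 20,
    formulation: str = "penalty",
    include_skin: bool = True,
    opts: NewtonOptions | None = None,
) -> tuple[LabeledMesh, dict]:
    """Recover the gravity-free reference mesh from a loaded acquisition.

    Fixed-point iteration: with target coordinates x* (the acquired loaded
    shape) and current reference guess X, forward-solve gravity to get
    x(X) = X + u(X) and update X <- X - (x(X) - x*).  Converged when
    max |x(X) - x*| < tol (metres).  Returns the unloaded mesh and an info
    dict with the residual history.
    """
    b = pose_vector(gravity_of_acquisition, magnitude)
    x_target = loaded_mesh.nodes.copy()
    ref = loaded_mesh.copy()
    residuals = []
    if not np.any(b):
        return ref, {"residuals": [0.0], "iterations": 0}
    for it in range(max_iter):
        model = MechModel(ref, materials, formulation=formulation,
                          include_skin=include_skin)
        try:
            state = model.solve_static(gravity=b, opts=opts)
        except SolverError as exc:
            raise InverseError(
                f"forward solve failed at inverse iteration {it}: {exc}", residuals
            ) from exc
        mismatch = ref.nodes + state.u - x_target
        res = float(np.abs(mismatch).max())
        residuals.append(res)
        log.info("inverse iteration %d: residual %.3e m", it, res)
        if res < tol:
            return ref, {"residuals": residuals, "iterations": it + 1,
                         "final_state": state}
        new_nodes = ref.nodes - mismatch
        candidate = ref.with_nodes(new_nodes)
        if np.any(candidate.volumes() <= 0):
            # damp the update if the full correction would invert elements
            candidate = ref.with_nodes(ref.nodes - 0.5 * mismatch)
        ref = candidate
    raise InverseError(
        f"unloaded-state iteration did not reach tol={tol:g} m in "
        f"{max_iter} iterations (last residual {residuals[-1]:.3e} m)",
        residuals,
    )
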