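"""Cosmetic-outcome evaluation: rigid surface alignment and distance statistics.

The predicted post-operative skin surface is compared against a follow-up
surface acquisition: a point-to-point iterative-closest-point (ICP) rigid
alignment, followed by exact per-vertex point-to-triangle distances and
their summary statistics (mean, standard deviation and the 50th/90th/95th
percentiles, in millimetres in the standard workflow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform", "AlignmentError", "icp_rigid",
    "point_triangle_distances", "surface_distance", "distance_histogram",
]


class AlignmentError(RuntimeError):
    """ICP could not establish correspondence between the surfaces."""


@dataclass
class RigidTransform:
    rotation: np.ndarray       # (3, 3)
    translation: np.ndarray    # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def icp_rigid(
    source_vertices: np.ndarray,
    target_vertices: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[RigidTransform, list[float]]:
    """Point-to-point ICP aligning source onto target.

    Alternates nearest-neighbour correspondence with the optimal rigid
    (Kabsch/SVD) transform; the mean squared closest-point distance is
    non-increasing over iterations for fixed correspondences.  Returns the
    accumulated transform and the per-iteration RMS error.
    """
    src = np.asarray(source_vertices, dtype=float)
    dst = np.asarray(target_vertices, dtype=float)
    if len(src) < 3 or len(dst) < 3:
        raise AlignmentError("surfaces must have at least 3 vertices each")
    tree = cKDTree(dst)
    current = src.copy()
    total = RigidTransform(np.eye(3), np.zeros(3))
    errors: list[float] = []
    for _ in range(max_iter):
        d, idx = tree.query(current)
        errors.append(float(np.sqrt(np.mean(d**2))))
        step = _kabsch(current, dst[idx])
        current = step.apply(current)
        total = RigidTransform(
            step.rotation @ total.rotation,
            step.rotation @ total.translation + step.translation,
        )
        if len(errors) > 1 and abs(errors[-2] - errors[-1]) < tol:
            break
    return total, errors


def point_triangle_distances(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Exact distance from each point to the closest triangle of a mesh.

    Vectorised closest-point-on-triangle (Voronoi-region) computation over
    all point/triangle pairs, chunked over points to bound memory.
    """
    points = np.asarray(points, dtype=float)
    a = vertices[faces[:, 0]]
    ab = vertices[faces[:, 1]] - a
    ac = vertices[faces[:, 2]] - a
    if len(faces) == 0 or len(points) == 0:
        raise AlignmentError("empty mesh or point set")
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk][:, None, :]       # (P,1,3)
        ap = p - a[None, :, :]
        d1 = np.einsum("tj,ptj->pt", ab, ap)
        d2 = np.einsum("tj,ptj->pt", ac, ap)
        d11 = np.einsum("tj,tj->t", ab, ab)[None, :]
        d12 = np.einsum("tj,tj->t", ab, ac)[None, :]
        d22 = np.einsum("tj,tj->t", ac, ac)[None, :]
        denom = d11 * d22 - d12 * d12
        v = np.clip((d22 * d1 - d12 * d2) / denom, 0.0, 1.0)
        w = np.clip((d11 * d2 - d12 * d1) / denom, 0.0, 1.0)
        # interior candidate
        inside = (v + w) <= 1.0
        # edge candidates: clamp barycentric coordinates onto each edge
        t_ab = np.clip(d1 / d11, 0.0, 1.0)
        t_ac = np.clip(d2 / d22, 0.0, 1.0)
        bp = ap - ab[None, :, :]
        t_bc = np.clip(
            np.einsum("tj,ptj->pt", ac - ab, bp)
            / np.einsum("tj,tj->t", ac - ab, ac - ab)[None, :],
            0.0, 1.0,
        )

        def dist2_to(vv, ww):
            q = vv[..., None] * ab[None, :, :] + ww[..., None] * ac[None, :, :]
            diff = ap - q
            return np.einsum("ptj,ptj->pt", diff, diff)

        d2_face = np.where(inside, dist2_to(v, w), np.inf)
        d2_ab = dist2_to(t_ab, np.zeros_like(t_ab))
        d2_ac = dist2_to(np.zeros_like(t_ac), t_ac)
        d2_bc = dist2_to(1.0 - t_bc, t_bc)
        best = np.min(
            np.stack([d2_face, d2_ab, d2_ac, d2_bc]), axis=0
        ).min(axis=1)
        out[lo : lo + chunk] = np.sqrt(np.maximum(best, 0.0))
    return out


def surface_distance(
    a_vertices: np.ndarray,
    b_vertices: np.ndarray,
    b_faces: np.ndarray,
    symmetric: bool = False,
    a_faces: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Per-vertex distances from surface a to surface b, with statistics.

    The measure is asymmetric by default (simulation vertices against the
    follow-up surface); ``symmetric=True`` appends the reverse direction
    (requires ``a_faces``).  Percentiles interpolate linearly between order
    statistics.
    """
    d = point_triangle_distances(a_vertices, b_vertices, b_faces)
    if symmetric:
        if a_faces is None:
            raise ValueError("symmetric distance requires a_faces")
        d = np.concatenate(
            [d, point_triangle_distances(b_vertices, a_vertices, a_faces)]
        )
    stats = {
        "mean": float(np.mean(d)),
        "std": float(np.std(d)),
        "p50": float(np.percentile(d, 50)),
        "p90": float(np.percentile(d, 90)),
        "p95": float(np.percentile(d, 95)),
        "n": int(d.size),
    }
    return d, stats


def distance_histogram(d: np.ndarray, bins: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Normalised frequency-of-occurrence histogram of the distances."""
    counts, edges = np.histogram(d, bins=bins)
    freq = counts / counts.sum()
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, freq
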