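"""Labelled tetrahedral meshes, synthetic breast phantoms and virtual resection.

The mesh data model is deliberately small: nodes, tetrahedra with a tissue
region label (adipose, fibroglandular or wound), and the boundary triangles
grouped into named patches (skin, chest wall, the superior/inferior clipping
planes and the lateral clipping planes).  The skin patch doubles as the
membrane shell of the mechanical model and carries a uniform thickness.

All coordinates are SI metres.  Tetrahedra are stored with positive signed
volume; meshes that violate the convention are repaired on construction by
swapping the last two vertices of the offending elements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "Patch",
    "LabeledMesh",
    "ResectionPlan",
    "GeometryError",
    "LabellingError",
    "ResectionError",
    "tet_volumes",
    "generate_phantom",
    "box_mesh",
    "bar_mesh",
    "mark_resection",
    "region_volume",
    "extract_patch_surface",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent mesh geometry."""


class LabellingError(ValueError):
    """Raised when element or face labels are missing or unmappable."""


class ResectionError(ValueError):
    """Raised when a resection plan does not intersect the mesh."""


class Region(enum.IntEnum):
    ADIPOSE = 0
    FIBROGLANDULAR = 1
    WOUND = 2


class Patch(enum.IntEnum):
    SKIN = 0
    CHEST = 1
    CLIP_INFERIOR = 2
    CLIP_SUPERIOR = 3
    LATERAL = 4


#: default dermis+epidermis thickness of the membrane shell, metres
DEFAULT_SKIN_THICKNESS = 1.5e-3


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive under the package convention)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap the last two vertices of negatively oriented tets."""
    vol = tet_volumes(nodes, tets)
    if np.any(vol == 0.0):
        raise GeometryError(f"{int(np.sum(vol == 0.0))} zero-volume tetrahedra")
    flipped = tets.copy()
    neg = vol < 0
    flipped[neg, 2], flipped[neg, 3] = tets[neg, 3], tets[neg, 2]
    return flipped


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces of the tet mesh that appear exactly once (outward oriented)."""
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


@dataclass
class LabeledMesh:
    """Tetrahedral volume mesh with tissue-region and boundary-patch labels."""

    nodes: np.ndarray                  # (N, 3) float, metres
    tets: np.ndarray                   # (M, 4) int
    tet_region: np.ndarray             # (M,) Region values
    boundary_tris: np.ndarray          # (B, 3) int
    tri_patch: np.ndarray              # (B,) Patch values
    skin_thickness: float = DEFAULT_SKIN_THICKNESS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.tet_region = np.ascontiguousarray(self.tet_region, dtype=np.int64)
        self.boundary_tris = np.ascontiguousarray(self.boundary_tris, dtype=np.int64)
        self.tri_patch = np.ascontiguousarray(self.tri_patch, dtype=np.int64)
        self.tets = _fix_orientation(self.nodes, self.tets)

    # -- basic queries -------------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_tets(self) -> int:
        return self.tets.shape[0]

    def volumes(self, displacement: np.ndarray | None = None) -> np.ndarray:
        """Per-element volumes, deformed if a nodal displacement is given."""
        x = self.nodes if displacement is None else self.nodes + displacement
        return tet_volumes(x, self.tets)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @property
    def skin_shell(self) -> np.ndarray:
        """Triangles of the skin patch (the membrane shell)."""
        return self.boundary_tris[self.tri_patch == Patch.SKIN]

    def patch_tris(self, patch: Patch) -> np.ndarray:
        return self.boundary_tris[self.tri_patch == int(patch)]

    def patch_nodes(self, patch: Patch) -> np.ndarray:
        return np.unique(self.patch_tris(patch))

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.nodes.copy(), self.tets.copy(), self.tet_region.copy(),
            self.boundary_tris.copy(), self.tri_patch.copy(),
            self.skin_thickness, dict(self.meta),
        )

    def with_nodes(self, nodes: np.ndarray) -> "LabeledMesh":
        out = self.copy()
        out.nodes = np.ascontiguousarray(nodes, dtype=float)
        return out

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        vol = self.volumes()
        if np.any(vol <= 0):
            raise GeometryError("non-positive tetrahedron volume")
        bf = boundary_faces(self.tets)
        have = {tuple(sorted(f)) for f in self.boundary_tris}
        want = {tuple(sorted(f)) for f in bf}
        if have != want:
            raise GeometryError(
                "boundary triangles do not tile the tet-mesh boundary "
                f"({len(have - want)} extra, {len(want - have)} missing)"
            )
        if len(have) != len(self.boundary_tris):
            raise GeometryError("duplicate boundary triangles")


@dataclass(frozen=True)
class ResectionPlan:
    """Cylindrical excision: axis through ``axis_point`` along ``axis_direction``.

    The cylinder runs perpendicular to the chest wall, from skin to fascia,
    enclosing the tumour plus margin.
    """

    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ResectionError("resection radius must be positive")
        d = np.asarray(self.axis_direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ResectionError("resection axis direction must be non-zero")
        object.__setattr__(self, "axis_direction", tuple(d / n))
        object.__setattr__(
            self, "axis_point", tuple(np.asarray(self.axis_point, dtype=float))
        )


# ---------------------------------------------------------------------------
# structured meshing helpers (Kuhn 6-tet cube split; conforming across faces)
# ---------------------------------------------------------------------------

# Six tetrahedra per cube, each an edge path from vertex 000 to vertex 111
# of the unit cube; shared faces triangulate identically in adjacent cubes.
_KUHN = np.array([
    [0b000, 0b100, 0b110, 0b111],
    [0b000, 0b100, 0b101, 0b111],
    [0b000, 0b010, 0b110, 0b111],
    [0b000, 0b010, 0b011, 0b111],
    [0b000, 0b001, 0b101, 0b111],
    [0b000, 0b001, 0b011, 0b111],
])


def _structured_tets(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Node grid-index array and tets of a structured box of nx*ny*nz cells."""
    nx, ny, nz = shape
    idx = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    corners = np.empty((nx, ny, nz, 8), dtype=np.int64)
    for c in range(8):
        dx, dy, dz = (c >> 2) & 1, (c >> 1) & 1, c & 1
        corners[..., c] = idx[ii + dx, jj + dy, kk + dz]
    corners = corners.reshape(-1, 8)
    tets = corners[:, _KUHN].reshape(-1, 4)
    return idx, tets


def _grid_nodes(origin, h, shape):
    nx, ny, nz = shape
    x = origin[0] + h * np.arange(nx + 1)
    y = origin[1] + h * np.arange(ny + 1)
    z = origin[2] + h * np.arange(nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def _compress(nodes, tets):
    """Drop unreferenced nodes, renumber tets."""
    used, inv = np.unique(tets, return_inverse=True)
    return nodes[used], inv.reshape(tets.shape).astype(np.int64)


def box_mesh(lengths, h, origin=(0.0, 0.0, 0.0), region=Region.ADIPOSE,
             patch_map=None) -> LabeledMesh:
    """Structured box mesh; all boundary faces labelled skin unless mapped.

    ``patch_map`` maps face names ('x-','x+','y-','y+','z-','z+') to Patch.
    """
    shape = tuple(max(1, int(round(L / h))) for L in lengths)
    nodes = _grid_nodes(origin, h, shape)
    _, tets = _structured_tets(shape)
    region_arr = np.full(tets.shape[0], int(region), dtype=np.int64)
    bf = boundary_faces(tets)
    cent = nodes[bf].mean(axis=1)
    lo = np.asarray(origin, float)
    hi = lo + h * np.asarray(shape, float)
    tol = 1e-9 * max(hi - lo)
    names = np.full(bf.shape[0], "", dtype=object)
    for ax, (lo_name, hi_name) in enumerate([("x-", "x+"), ("y-", "y+"), ("z-", "z+")]):
        names[np.abs(cent[:, ax] - lo[ax]) < tol] = lo_name
        names[np.abs(cent[:, ax] - hi[ax]) < tol] = hi_name
    patch_map = patch_map or {}
    patches = np.array(
        [int(patch_map.get(n, Patch.SKIN)) for n in names], dtype=np.int64
    )
    return LabeledMesh(nodes, tets, region_arr, bf, patches)


def bar_mesh(length, h, cross=1) -> LabeledMesh:
    """Quasi-1D bar along x (cross*cross cells in section) for front studies."""
    n = int(round(length / h))
    shape = (n, cross, cross)
    nodes = _grid_nodes((0.0, 0.0, 0.0), h, shape)
    _, tets = _structured_tets(shape)
    bf = boundary_faces(tets)
    return LabeledMesh(
        nodes, tets, np.full(tets.shape[0], int(Region.ADIPOSE)),
        bf, np.full(bf.shape[0], int(Patch.SKIN)),
    )


def generate_phantom(
    breast_radius: float = 0.06,
    slab_depth: float = 0.02,
    target_edge_length: float = 0.009,
    fibro_fraction: float = 0.25,
    seed: int = 0,
    margin: float | None = None,
    jitter: float = 0.01,
    skin_thickness: float = DEFAULT_SKIN_THICKNESS,
) -> LabeledMesh:
    """Synthetic breast phantom: hemisphere of breast tissue on a chest slab.

    The geometry stands in for an MRI-derived model: a hemispherical breast
    (radius ``breast_radius``) protruding anteriorly (+Y) from a rectangular
    slab of chest-wall tissue of thickness ``slab_depth``.  An inner
    half-ellipsoidal core is labelled fibroglandular so that it occupies
    approximately ``fibro_fraction`` of the breast volume; the remainder is
    adipose.  The posterior slab face is the chest patch (fixed in the
    mechanical model), the slab faces at +/-Z are the superior/inferior
    clipping planes, the +/-X faces are lateral (traction-free), and
    everything else — the hemisphere plus the anterior slab face — is skin.

    Coordinate convention: X lateral, Y anterior, Z cranial.

    Elements are kept when their centroid lies inside the solid, so the
    curved surface is resolved to the grid spacing.  Interior nodes receive
    a small seeded jitter (``jitter`` as a fraction of the edge length) to
    break the structured-lattice symmetry; boundary nodes are untouched.
    """
    R, d, h = float(breast_radius), float(slab_depth), float(target_edge_length)
    if min(R, d, h) <= 0:
        raise GeometryError("radius, slab depth and edge length must be positive")
    if not 0.0 <= fibro_fraction <= 1.0:
        raise GeometryError("fibro_fraction must lie in [0, 1]")
    if h > R / 2:
        raise GeometryError("target edge length too large relative to breast radius")
    margin = 0.5 * R if margin is None else float(margin)

    half_w = h * int(np.ceil((R + margin) / h))
    n_lat = int(round(2 * half_w / h))
    n_back = max(1, int(round(d / h)))
    n_front = int(np.ceil(R / h))
    origin = (-half_w, -n_back * h, -half_w)
    shape = (n_lat, n_back + n_front, n_lat)
    nodes = _grid_nodes(origin, h, shape)
    _, tets = _structured_tets(shape)

    cent = nodes[tets].mean(axis=1)
    in_slab = cent[:, 1] < 0.0
    r2 = np.einsum("ij,ij->i", cent, cent)
    in_dome = (cent[:, 1] >= 0.0) & (r2 <= R * R)
    keep = in_slab | in_dome
    tets = tets[keep]
    nodes, tets = _compress(nodes, tets)

    cent = nodes[tets].mean(axis=1)
    region = np.full(tets.shape[0], int(Region.ADIPOSE), dtype=np.int64)
    if fibro_fraction > 0:
        s = fibro_fraction ** (1.0 / 3.0)
        core = (cent[:, 1] >= 0.0) & (
            np.einsum("ij,ij->i", cent, cent) <= (s * R) ** 2
        )
        region[core] = int(Region.FIBROGLANDULAR)

    bf = boundary_faces(tets)
    fc = nodes[bf].mean(axis=1)
    tol = 1e-9
    patches = np.full(bf.shape[0], int(Patch.SKIN), dtype=np.int64)
    patches[np.abs(fc[:, 1] + n_back * h) < tol] = int(Patch.CHEST)
    patches[np.abs(fc[:, 2] + half_w) < tol] = int(Patch.CLIP_INFERIOR)
    patches[np.abs(fc[:, 2] - half_w) < tol] = int(Patch.CLIP_SUPERIOR)
    patches[np.abs(np.abs(fc[:, 0]) - half_w) < tol] = int(Patch.LATERAL)

    if jitter > 0:
        rng = np.random.default_rng(seed)
        interior = np.ones(nodes.shape[0], dtype=bool)
        interior[np.unique(bf)] = False
        delta = rng.uniform(-jitter * h, jitter * h, size=(int(interior.sum()), 3))
        nodes = nodes.copy()
        nodes[interior] += delta

    mesh = LabeledMesh(
        nodes, tets, region, bf, patches, skin_thickness=skin_thickness,
        meta={
            "kind": "phantom", "breast_radius": R, "slab_depth": d,
            "edge_length": h, "fibro_fraction": float(fibro_fraction),
            "seed": int(seed), "half_width": half_w,
        },
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# virtual resection and volume bookkeeping
# ---------------------------------------------------------------------------


def mark_resection(mesh: LabeledMesh, plan: ResectionPlan) -> LabeledMesh:
    """Relabel as wound every tet whose centroid lies inside the plan cylinder.

    Resected elements are retained and relabelled, not deleted: the damaged
    volume stays embedded in the healthy one, with its mechanical integrity
    handled by the damage variable.  The skin shell is left untouched (no
    skin is resected).  Returns a new mesh; the input is not modified.
    """
    cent = mesh.centroids()
    p0 = np.asarray(plan.axis_point)
    d = np.asarray(plan.axis_direction)
    rel = cent - p0
    axial = rel @ d
    radial2 = np.einsum("ij,ij->i", rel, rel) - axial**2
    inside = radial2 <= plan.radius**2
    if not np.any(inside):
        raise ResectionError("resection cylinder does not contain any element")
    out = mesh.copy()
    out.tet_region[inside] = int(Region.WOUND)
    out.meta["resection"] = {
        "axis_point": plan.axis_point, "axis_direction": plan.axis_direction,
        "radius": plan.radius, "n_wound": int(inside.sum()),
    }
    return out


def region_volume(
    mesh: LabeledMesh, region: Region | int,
    displacement: np.ndarray | None = None,
) -> float:
    """Total (deformed) volume of all elements of one tissue region."""
    if displacement is not None and displacement.shape != mesh.nodes.shape:
        raise GeometryError("displacement must be defined on all nodes")
    vol = mesh.volumes(displacement)
    return float(vol[mesh.tet_region == int(region)].sum())


def extract_patch_surface(
    mesh: LabeledMesh,
    patches: tuple[Patch, ...] = (Patch.SKIN,),
    displacement: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices and faces of the union of boundary patches (renumbered)."""
    sel = np.isin(mesh.tri_patch, [int(p) for p in patches])
    tris = mesh.boundary_tris[sel]
    if tris.size == 0:
        raise LabellingError("no boundary triangles in requested patches")
    x = mesh.nodes if displacement is None else mesh.nodes + displacement
    verts, faces = _compress(x, tris)
    return verts, faces
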