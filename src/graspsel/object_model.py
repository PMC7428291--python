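"""Rigid objects, mesh I/O, mass properties and candidate contact points.

Participant frame convention: x rightward, y away from the participant,
z up, table plane at z = 0, lengths in mm, masses in g.  This convention
is used everywhere downstream (gravity acts along -z, the visibility
penalty projects onto the horizontal x-y plane).

Mesh input is deliberately minimal and text based: Wavefront OBJ, ASCII
STL and ASCII PLY.  Mass properties of closed meshes are integrated
exactly via the divergence theorem over signed tetrahedra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: Default cube edge length (mm) for the polycube stimulus family.
DEFAULT_CUBE_EDGE = 25.0

#: Per-cube masses in g, calibrated so that 10 wood cubes total 97 g and
#: 5 wood + 5 brass cubes total 716 g.
CUBE_MASSES = {"wood": 9.7, "brass": 133.5}

#: Triangles per exposed cube face: 128 (8x8 grid) in "fine" mode,
#: 2 (single quad) in "coarse" mode.
FACE_RESOLUTIONS = {"fine": 8, "coarse": 1}


class DegenerateGeometryError(ValueError):
    """Raised when an input point/mesh configuration is too degenerate."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rotation_about_axis(axis: str | np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about 'x'/'y'/'z' or an arbitrary axis, degrees.

    Positive angles are counterclockwise when looking down the axis
    (right-hand rule).
    """
    if isinstance(axis, str):
        axis = {"x": [1, 0, 0], "y": [0, 1, 0], "z": [0, 0, 1]}[axis.lower()]
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


# ---------------------------------------------------------------------------
# Rigid objects
# ---------------------------------------------------------------------------


@dataclass
class RigidObject:
    """Triangulated rigid object with mass distribution and pose.

    Vertices and derived object-frame quantities are stored in the object
    frame; ``com``, ``centroid`` and ``posed_vertices`` are expressed in
    the participant frame through ``pose``.
    """

    vertices: np.ndarray  # (nv, 3) mm, object frame
    faces: np.ndarray  # (nf, 3) int
    mass: float  # g
    com_object: np.ndarray  # (3,) mm, object frame
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    face_density: np.ndarray | None = None  # (nf,) g/mm^3
    centroid_object: np.ndarray | None = None  # uniform-density volume centroid
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.com_object = np.asarray(self.com_object, dtype=float).reshape(3)
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.centroid_object is None:
            self.centroid_object = self.com_object.copy()

    # -- derived geometry ---------------------------------------------------

    @property
    def posed_vertices(self) -> np.ndarray:
        return self.pose.apply(self.vertices)

    @property
    def com(self) -> np.ndarray:
        """Center of mass in the participant frame (mm)."""
        return self.pose.apply(self.com_object)

    @property
    def centroid(self) -> np.ndarray:
        """Uniform-density volume centroid in the participant frame (mm)."""
        return self.pose.apply(self.centroid_object)

    @property
    def d_max(self) -> float:
        """Largest pairwise vertex distance (mm); pose invariant."""
        return max_pairwise_distance(self.vertices)

    @property
    def signed_volume(self) -> float:
        """Signed volume (mm^3); positive for outward-wound closed meshes."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0)

    def with_pose(self, pose: RigidTransform) -> "RigidObject":
        return replace(self, pose=pose)

    def face_centers(self, posed: bool = True) -> np.ndarray:
        v = self.posed_vertices if posed else self.vertices
        return v[self.faces].mean(axis=1)

    def face_normals(self, posed: bool = True) -> np.ndarray:
        v = self.posed_vertices if posed else self.vertices
        t = v[self.faces]
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        lengths = np.linalg.norm(n, axis=1)
        lengths[lengths == 0] = 1.0
        return n / lengths[:, None]

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )


def max_pairwise_distance(points: np.ndarray) -> float:
    """Exact diameter of a point set, via convex-hull reduction."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat) sets: fall through to brute force
    return float(pdist(pts).max())


# ---------------------------------------------------------------------------
# Polycube builder
# ---------------------------------------------------------------------------

# (in-plane axis pair) chosen so that e_u x e_v = outward normal
_FACE_AXES = {
    (0, +1): (1, 2),
    (0, -1): (2, 1),
    (1, +1): (2, 0),
    (1, -1): (0, 2),
    (2, +1): (0, 1),
    (2, -1): (1, 0),
}


def build_polycube(
    cube_coords,
    materials=None,
    cube_edge: float = DEFAULT_CUBE_EDGE,
    resolution: str | int = "fine",
    cube_masses: dict | None = None,
    pose: RigidTransform | None = None,
    name: str = "",
) -> RigidObject:
    """Build a watertight polycube object from integer grid positions.

    Parameters
    ----------
    cube_coords
        Iterable of distinct integer (ix, iy, iz) grid positions.
    materials
        Per-cube material labels (keys of ``cube_masses``); defaults to
        all ``"wood"``.
    cube_edge
        Edge length of each cube, mm.
    resolution
        ``"fine"`` (128 triangles per exposed cube face), ``"coarse"``
        (2 triangles per face), or an integer n for an n-by-n quad grid.
    cube_masses
        Mapping material label -> mass of one cube in g.  The defaults
        make 10 wood cubes total 97 g and 5 wood + 5 brass total 716 g.
    """
    coords = [tuple(int(x) for x in c) for c in cube_coords]
    if len(coords) == 0:
        raise ValueError("at least one cube required")
    if len(set(coords)) != len(coords):
        raise ValueError("overlapping cube coordinates")
    if cube_edge <= 0:
        raise ValueError("cube_edge must be positive")
    if materials is None:
        materials = ["wood"] * len(coords)
    materials = list(materials)
    if len(materials) != len(coords):
        raise ValueError("materials length must equal cube count")
    masses_by_mat = dict(CUBE_MASSES if cube_masses is None else cube_masses)
    for m in materials:
        if m not in masses_by_mat:
            raise ValueError(f"unknown material {m!r}")
    if isinstance(resolution, str):
        res = FACE_RESOLUTIONS[resolution]
    else:
        res = int(resolution)
        if res < 1:
            raise ValueError("resolution must be >= 1")

    if not _is_face_connected(coords):
        warnings.warn("polycube layout is not face-connected", stacklevel=2)

    occupied = set(coords)
    e = float(cube_edge)
    units = np.eye(3)

    tri_pts: list[np.ndarray] = []
    tri_cube: list[int] = []
    for ci, c in enumerate(coords):
        c = np.asarray(c, dtype=float)
        for axis in range(3):
            for sign in (+1, -1):
                nb = tuple((c + sign * units[axis]).astype(int))
                if nb in occupied:
                    continue  # interior shared face
                origin = c * e
                if sign > 0:
                    origin = origin + units[axis] * e
                bu, bv = _FACE_AXES[(axis, sign)]
                u = units[bu] * (e / res)
                v = units[bv] * (e / res)
                for i in range(res):
                    for j in range(res):
                        p00 = origin + i * u + j * v
                        p10, p01, p11 = p00 + u, p00 + v, p00 + u + v
                        tri_pts.append(np.array([p00, p10, p11]))
                        tri_pts.append(np.array([p00, p11, p01]))
                        tri_cube.extend([ci, ci])

    all_pts = np.concatenate(tri_pts, axis=0)
    vertices, inverse = np.unique(
        np.round(all_pts, 9), axis=0, return_inverse=True
    )
    faces = inverse.reshape(-1, 3)

    cube_mass = np.array([masses_by_mat[m] for m in materials], dtype=float)
    mass = float(cube_mass.sum())
    centers = (np.asarray(coords, dtype=float) + 0.5) * e
    com = (cube_mass[:, None] * centers).sum(axis=0) / mass
    centroid = centers.mean(axis=0)
    face_density = cube_mass[np.asarray(tri_cube)] / e**3

    return RigidObject(
        vertices=vertices,
        faces=faces,
        mass=mass,
        com_object=com,
        centroid_object=centroid,
        face_density=face_density,
        pose=pose or RigidTransform.identity(),
        name=name,
    )


def _is_face_connected(coords) -> bool:
    occupied = set(coords)
    seen = {coords[0]}
    stack = [coords[0]]
    while stack:
        c = stack.pop()
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if nb in occupied and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(occupied)


def load_layout(path) -> tuple[list[tuple[int, int, int]], list[str]]:
    """Read a polycube layout file: one cube per line ``ix iy iz material``."""
    coords, mats = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"bad layout line: {raw!r}")
        coords.append(tuple(int(p) for p in parts[:3]))
        mats.append(parts[3] if len(parts) == 4 else "wood")
    if not coords:
        raise ValueError("empty layout file")
    return coords, mats


def default_layout_path(shape: str) -> Path:
    """Path to one of the bundled approximate stimulus layouts (L/U/S/V)."""
    p = Path(__file__).parent / "layouts" / f"{shape.upper()}.txt"
    if not p.exists():
        raise ValueError(f"no bundled layout named {shape!r}")
    return p


# ---------------------------------------------------------------------------
# Mesh loading
# ---------------------------------------------------------------------------


def load_mesh(
    path,
    density: float | np.ndarray = 1e-3,
    pose: RigidTransform | None = None,
    name: str = "",
) -> RigidObject:
    """Load an OBJ / ASCII-STL / ASCII-PLY mesh as a RigidObject.

    ``density`` is g/mm^3; a scalar means uniform material.  Mass and CoM
    are integrated from the signed-tetrahedron decomposition of a closed
    mesh; for open meshes the CoM falls back to the area-weighted surface
    centroid (with a logged warning).
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".obj":
        vertices, faces = _read_obj(path)
    elif ext == ".stl":
        vertices, faces = _read_stl_ascii(path)
    elif ext == ".ply":
        vertices, faces = _read_ply_ascii(path)
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (OBJ/STL/PLY)")
    return mesh_to_object(vertices, faces, density=density, pose=pose,
                          name=name or path.stem)


def mesh_to_object(
    vertices: np.ndarray,
    faces: np.ndarray,
    density: float | np.ndarray = 1e-3,
    pose: RigidTransform | None = None,
    name: str = "",
) -> RigidObject:
    """Build a RigidObject from raw triangles, integrating mass properties."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    dens = np.asarray(density, dtype=float)
    if np.any(dens <= 0):
        raise ValueError("density must be positive")

    vol = _signed_volume(vertices, faces)
    if vol < 0:
        logger.warning("mesh %s wound inward; flipping faces", name)
        faces = faces[:, ::-1]
        vol = -vol

    closed = _is_closed(faces)
    if closed and vol > 0:
        com = _volume_centroid(vertices, faces)
    else:
        logger.warning("mesh %s is not closed; using surface centroid as CoM", name)
        com = _surface_centroid(vertices, faces)

    if dens.ndim == 0:
        mass = abs(vol) * float(dens)
        face_density = np.full(len(faces), float(dens))
    else:
        if dens.shape != (len(faces),):
            raise ValueError("per-face density must have one value per face")
        face_density = dens
        mass = abs(vol) * float(dens.mean())  # approximate for mixed materials
    if mass <= 0:
        raise ValueError("mesh has zero volume; cannot assign mass")

    return RigidObject(
        vertices=vertices,
        faces=faces,
        mass=mass,
        com_object=com,
        centroid_object=com if closed else None,
        face_density=face_density,
        pose=pose or RigidTransform.identity(),
        name=name,
    )


def _signed_volume(vertices, faces) -> float:
    t = vertices[faces]
    return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0)


def _volume_centroid(vertices, faces) -> np.ndarray:
    t = vertices[faces]
    tet_vol = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
    tet_cent = t.sum(axis=1) / 4.0  # centroid of tet (origin, v0, v1, v2)
    return (tet_vol[:, None] * tet_cent).sum(axis=0) / tet_vol.sum()


def _surface_centroid(vertices, faces) -> np.ndarray:
    t = vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    centers = t.mean(axis=1)
    return (areas[:, None] * centers).sum(axis=0) / areas.sum()


def _is_closed(faces) -> bool:
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _read_obj(path):
    verts, faces = [], []
    for raw in Path(path).read_text().splitlines():
        parts = raw.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = []
            for p in parts[1:]:
                i = int(p.split("/")[0])
                idx.append(i - 1 if i > 0 else len(verts) + i)
            for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                faces.append([idx[0], idx[k], idx[k + 1]])
    if not verts or not faces:
        raise ValueError(f"no triangles found in {path}")
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def _read_stl_ascii(path):
    data = Path(path).read_bytes()
    if not data.lstrip()[:5].lower().startswith(b"solid") or b"facet" not in data:
        raise ValueError(f"{path}: only ASCII STL is supported")
    pts = []
    for raw in data.decode("utf-8", errors="replace").splitlines():
        parts = raw.split()
        if parts and parts[0] == "vertex":
            pts.append([float(x) for x in parts[1:4]])
    pts = np.asarray(pts, dtype=float)
    if len(pts) == 0 or len(pts) % 3:
        raise ValueError(f"{path}: malformed STL vertex list")
    vertices, inverse = np.unique(np.round(pts, 9), axis=0, return_inverse=True)
    return vertices, inverse.reshape(-1, 3).astype(np.int64)


def _read_ply_ascii(path):
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    vprops: list[str] = []
    element = None
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise ValueError(f"{path}: only ASCII PLY is supported")
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vert = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "vertex" and parts[1] != "list":
            vprops.append(parts[-1])
        elif parts[0] == "end_header":
            break
    ix, iy, iz = (vprops.index(a) for a in ("x", "y", "z"))
    verts = np.array(
        [[float(v) for v in lines[i + k].split()] for k in range(n_vert)]
    )[:, [ix, iy, iz]]
    i += n_vert
    faces = []
    for k in range(n_face):
        parts = [int(v) for v in lines[i + k].split()]
        idx = parts[1 : 1 + parts[0]]
        for j in range(1, len(idx) - 1):
            faces.append([idx[0], idx[j], idx[j + 1]])
    return verts.astype(float), np.asarray(faces, dtype=np.int64)


def write_obj(path, obj: RigidObject, posed: bool = False) -> None:
    """Write the mesh (object frame by default) as a Wavefront OBJ file."""
    v = obj.posed_vertices if posed else obj.vertices
    with open(path, "w") as fh:
        fh.write(f"# graspsel mesh: {obj.name}\n")
        for p in v:
            fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in obj.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Pose estimation
# ---------------------------------------------------------------------------


def align_procrustes(model_points, measured_points) -> RigidTransform:
    """Rigid transform (rotation + translation, no scaling/reflection)
    mapping model points onto measured points by least squares.

    Requires at least 4 non-coplanar correspondences.
    """
    A = np.asarray(model_points, dtype=float)
    B = np.asarray(measured_points, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("model and measured points must be matched (n, 3) arrays")
    if len(A) < 4:
        raise DegenerateGeometryError("need at least 4 point correspondences")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    s = np.linalg.svd(Ac, compute_uv=False)
    if s[2] < 1e-8 * max(s[0], 1e-12):
        raise DegenerateGeometryError("model points are (nearly) coplanar")
    U, _, Vt = np.linalg.svd(Ac.T @ Bc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cb - R @ ca)


# ---------------------------------------------------------------------------
# Candidate contact points
# ---------------------------------------------------------------------------

#: Faces whose vertices all lie within this distance of the table plane
#: are considered in contact with the table and inaccessible (mm).
TABLE_CONTACT_TOL = 1.0


@dataclass
class CandidateSet:
    """Accessible candidate contact points: posed triangle centers."""

    positions: np.ndarray  # (n, 3) mm, participant frame
    normals: np.ndarray  # (n, 3) outward unit vectors
    areas: np.ndarray  # (n,) mm^2
    parent_face: np.ndarray  # (n,) index into the source mesh's faces

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.parent_face = np.asarray(self.parent_face, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n(self) -> int:
        return len(self.positions)

    def subset(self, indices) -> "CandidateSet":
        idx = np.asarray(indices, dtype=np.int64)
        return CandidateSet(
            self.positions[idx], self.normals[idx], self.areas[idx],
            self.parent_face[idx],
        )


def candidate_contacts(
    obj: RigidObject,
    table_z: float = 0.0,
    subsample_pct: float = 100.0,
    seed: int | None = None,
) -> CandidateSet:
    """Enumerate accessible candidate contact points on the posed mesh.

    A face is accessible unless all three of its vertices lie within
    ``TABLE_CONTACT_TOL`` of the table plane z = ``table_z``.  When
    ``subsample_pct`` < 100, a seeded uniform subset of that proportion
    of candidates is retained (candidate order preserved).
    """
    if not 0 < subsample_pct <= 100:
        raise ValueError("subsample_pct must be in (0, 100]")
    v = obj.posed_vertices
    near_table = np.abs(v[:, 2] - table_z) <= TABLE_CONTACT_TOL
    face_on_table = near_table[obj.faces].all(axis=1)
    accessible = np.flatnonzero(~face_on_table)
    if len(accessible) == 0:
        raise ValueError("no accessible faces above the table plane")

    centers = obj.face_centers(posed=True)[accessible]
    normals = obj.face_normals(posed=True)[accessible]
    areas = obj.face_areas()[accessible]
    cands = CandidateSet(centers, normals, areas, accessible)

    if subsample_pct < 100:
        n_keep = int(round(subsample_pct / 100.0 * cands.n))
        if n_keep < 1:
            raise ValueError(
                f"subsampling to {subsample_pct}% leaves no candidates"
            )
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(cands.n, size=n_keep, replace=False))
        cands = cands.subset(keep)
    return cands


def mean_nearest_candidate_spacing(cands: CandidateSet) -> float:
    """Average distance from each candidate to its nearest neighbour (mm)."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(cands.positions).query(cands.positions, k=2)
    return float(d[:, 1].mean())
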