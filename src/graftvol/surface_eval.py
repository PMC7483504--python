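"""Surface rendering, point-based rigid registration and deviation maps.

Segmented masks are iso-surfaced (marching cubes at level 0.5) into
triangle meshes in physical millimetres.  A test mesh is rigidly aligned
to a reference mesh from >= 3 corresponding landmark points (least-squares
rotation + translation, no scaling), then every test vertex is mapped to
its nearest point on the reference triangle set; the signed distance (sign
given by the nearest triangle's outward normal: positive outside the
reference) forms the deviation color map and its summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .errors import DegenerateLandmarksError, EmptyMaskError
from .grid import VoxelGrid


@dataclass
class SurfaceMesh:
    """Triangle mesh with vertices in mm."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int
    provenance: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle references an out-of-range vertex")

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset), self.triangles.copy(),
                           self.provenance)


def extract_surface(mask: VoxelGrid, level: float = 0.5) -> SurfaceMesh:
    """Iso-surface of a binary mask at the given level, in physical mm.

    The mask is zero-padded by one voxel first, so meshes of masks that
    touch the grid boundary still close.
    """
    data = np.asarray(mask.data, dtype=bool)
    if not data.any():
        raise EmptyMaskError("cannot extract a surface from an empty mask")
    padded = np.pad(data, 1).astype(np.float32)
    sp = float(mask.spacing)
    verts, faces, _, _ = measure.marching_cubes(padded, level=level, spacing=(sp, sp, sp))
    verts = verts - sp + mask.origin  # undo the pad offset
    mesh = SurfaceMesh(verts, faces, provenance=f"marching_cubes level={level}")
    if mesh_volume(mesh) < 0:  # orient outward
        mesh.triangles = mesh.triangles[:, ::-1]
    return mesh


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem."""
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def face_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Unit outward normals per triangle (mesh assumed oriented outward)."""
    v = mesh.vertices
    t = mesh.triangles
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def is_closed(mesh: SurfaceMesh) -> bool:
    """True iff every edge is shared by exactly two triangles."""
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


# ---------------------------------------------------------------------------
# Rigid registration (Kabsch, no scaling)


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def point_based_register(
    test: SurfaceMesh | None,
    reference: SurfaceMesh | None,
    landmark_pairs,
) -> RigidTransform:
    """Least-squares rigid transform mapping test landmarks onto reference.

    ``landmark_pairs`` is a sequence of ``(test_point, reference_point)``
    pairs (>= 3, non-collinear), or a tuple of two (n, 3) arrays.  The mesh
    arguments are carried for provenance only; the fit uses the landmarks.
    Raises :class:`DegenerateLandmarksError` on collinear configurations.
    """
    if isinstance(landmark_pairs, tuple) and len(landmark_pairs) == 2:
        p, q = (np.asarray(a, dtype=float) for a in landmark_pairs)
    else:
        pairs = [(np.asarray(a, float), np.asarray(b, float)) for a, b in landmark_pairs]
        p = np.stack([a for a, _ in pairs])
        q = np.stack([b for _, b in pairs])
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise DegenerateLandmarksError("need >= 3 corresponding 3-D landmark pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    P, Q = p - pc, q - qc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear landmarks leave the rotation about their axis undetermined
    if S[1] < 1e-9 * max(S[0], 1e-300):
        raise DegenerateLandmarksError("landmarks are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    residuals = (p @ R.T + t) - q
    rms = float(np.sqrt((residuals**2).sum(axis=1).mean()))
    return RigidTransform(R, t, rms)


# ---------------------------------------------------------------------------
# Deviation maps


@dataclass
class DeviationMap:
    """Signed per-vertex distance from a test mesh to a reference surface."""

    distances: np.ndarray  # mm, one per test vertex; positive outside
    mean: float = field(init=False)
    rms: float = field(init=False)
    max_abs: float = field(init=False)
    mean_abs: float = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        self.distances = d
        self.mean = float(d.mean())
        self.rms = float(np.sqrt((d**2).mean()))
        self.max_abs = float(np.abs(d).max())
        self.mean_abs = float(np.abs(d).mean())


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> tuple:
    """Closest point on each candidate triangle for each query point.

    ``points``: (n, 3); ``tri``: (n, k, 3, 3) candidate triangles per
    point.  Vectorized region-wise point-triangle projection.  Returns
    (closest (n, k, 3), squared distance (n, k)).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where(
            (d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0
        )

    closest = a + v[..., None] * ab + w[..., None] * ac  # interior default

    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, closest)
    # edge AB
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(
        on_ab[..., None], a + np.clip(v_ab, 0, 1)[..., None] * ab, closest
    )
    # edge AC
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(
        on_ac[..., None], a + np.clip(w_ac, 0, 1)[..., None] * ac, closest
    )
    # edge BC
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(
        on_bc[..., None], b + np.clip(w_bc, 0, 1)[..., None] * (c - b), closest
    )

    diff = closest - p
    return closest, np.einsum("...i,...i->...", diff, diff)


def deviation_map(
    test: SurfaceMesh,
    reference: SurfaceMesh,
    transform: RigidTransform | None = None,
    k_candidates: int = 24,
) -> DeviationMap:
    """Signed distance of every (transformed) test vertex to the reference.

    Candidate triangles are found with a KD-tree over reference-triangle
    centroids (``k_candidates`` nearest), then the exact closest point on
    each candidate is computed; the sign comes from the winning triangle's
    outward normal.
    """
    if len(test.vertices) == 0 or len(reference.vertices) == 0:
        raise EmptyMaskError("deviation map needs two non-empty meshes")
    if transform is None:
        transform = RigidTransform.identity()
    pts = transform.apply(test.vertices)

    rv = reference.vertices
    rt = reference.triangles
    tri_pts = rv[rt]  # (m, 3, 3)
    centroids = tri_pts.mean(axis=1)
    k = min(k_candidates, len(rt))
    tree = cKDTree(centroids)
    _, idx = tree.query(pts, k=k, workers=-1)
    if k == 1:
        idx = idx[:, None]
    normals = face_normals(reference)

    n = len(pts)
    distances = np.empty(n)
    chunk = max(1, int(4_000_000 / max(k, 1)))
    for s in range(0, n, chunk):
        sl = slice(s, min(n, s + chunk))
        cand = tri_pts[idx[sl]]  # (c, k, 3, 3)
        closest, d2 = _closest_on_triangles(pts[sl], cand)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(best))
        cp = closest[rows, best]
        tid = idx[sl][rows, best]
        vec = pts[sl] - cp
        dist = np.sqrt(d2[rows, best])
        sign = np.sign(np.einsum("ij,ij->i", vec, normals[tid]))
        sign[sign == 0] = 1.0
        distances[sl] = sign * dist
    return DeviationMap(distances)


# ---------------------------------------------------------------------------
# STL and color-map export


def save_stl(mesh: SurfaceMesh, path) -> None:
    """Write a binary STL (millimetre units)."""
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    tm.export(str(path), file_type="stl")


def load_stl(path) -> SurfaceMesh:
    """Read a binary or ASCII STL file."""
    import trimesh

    tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       provenance=str(path))


def export_deviation_colormap(
    mesh: SurfaceMesh, deviations: DeviationMap, path, elev: float = 25,
    azim: float = -60,
) -> None:
    """Static 3-D scatter of vertices colored by signed deviation (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    v = mesh.vertices
    lim = max(np.abs(deviations.distances).max(), 1e-6)
    sc = ax.scatter(
        v[:, 0], v[:, 1], v[:, 2], c=deviations.distances, cmap="coolwarm",
        vmin=-lim, vmax=lim, s=1,
    )
    fig.colorbar(sc, label="signed deviation (mm)")
    ax.view_init(elev=elev, azim=azim)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
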