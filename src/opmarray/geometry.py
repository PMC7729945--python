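"""Synthetic head geometry: scalp and folded-cortex surfaces, parcellations
and deep/superficial source selections.

Real MEG array-design studies start from a subject or template (MNI) cortical
mesh with ~3 mm vertex spacing and an atlas parcellation. This module builds
stand-ins with the same structural properties — a closed scalp surface of
adult-head scale, a folded cortical surface strictly inside it whose outward
vertex normals define dipole orientations, contiguous labelled parcels, and
depth-ranked source sets — so every downstream stage (forward modelling,
array packing, inversion, aliasing) runs on controlled, reproducible inputs.

Units are mm throughout; the coordinate frame is right-handed with the origin
at the scalp centre and +Z superior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, cKDTree

from ._meshmath import closest_point_on_mesh

__all__ = [
    "SurfaceMesh",
    "SourceSpace",
    "SourceSet",
    "make_scalp",
    "make_cortex",
    "assign_parcels",
    "select_sources",
    "read_mesh",
    "write_mesh",
    "fit_sphere",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed triangulated surface (scalp or cortex) in mm.

    ``vertex_normals`` are unit vectors pointing away from ``center``; for a
    cortical surface they define the dipole orientations.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (f, 3) int
    vertex_normals: np.ndarray  # (n, 3) unit
    center: np.ndarray  # (3,) mm

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if not np.all(np.isfinite(v)):
            raise ValueError("mesh vertices must be finite")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "vertex_normals", np.asarray(self.vertex_normals, float))
        object.__setattr__(self, "center", np.asarray(self.center, float))

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def volume(self) -> float:
        return float(self.as_trimesh().volume)

    def mean_vertex_spacing(self) -> float:
        """Mean nearest-neighbour distance between vertices (mm)."""
        d, _ = cKDTree(self.vertices).query(self.vertices, k=2)
        return float(d[:, 1].mean())

    def vertex_adjacency(self) -> list[np.ndarray]:
        """1-ring neighbours per vertex."""
        tm = self.as_trimesh()
        return [np.asarray(nb, dtype=np.int64) for nb in tm.vertex_neighbors]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transform the mesh (rotation applied about the origin)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return SurfaceMesh(
            vertices=self.vertices @ R.T + t,
            faces=self.faces,
            vertex_normals=self.vertex_normals @ R.T,
            center=R @ self.center + t,
        )


@dataclass(frozen=True)
class SourceSpace:
    """Cortical source space: mesh plus per-vertex parcel labels and depths.

    ``depth`` is the Euclidean distance from each cortex vertex to the
    nearest point on the scalp surface. ``parcel_label`` is -1 until
    :func:`assign_parcels` has been run.
    """

    mesh: SurfaceMesh
    depth: np.ndarray  # (n,) mm, > 0
    parcel_label: np.ndarray = field(default=None)  # (n,) int

    def __post_init__(self):
        d = np.asarray(self.depth, float)
        if np.any(d <= 0):
            raise ValueError("cortex must lie strictly inside the scalp (depth > 0)")
        object.__setattr__(self, "depth", d)
        if self.parcel_label is None:
            object.__setattr__(
                self, "parcel_label", np.full(self.mesh.n_vertices, -1, dtype=np.int64)
            )

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices

    @property
    def n_parcels(self) -> int:
        labels = self.parcel_label
        return int(len(np.unique(labels[labels >= 0])))


@dataclass(frozen=True)
class SourceSet:
    """Depth-stratified dipole locations: at most one per parcel."""

    vertex_indices: np.ndarray  # (m,) int
    depth_class: np.ndarray  # (m,) str: "deep" | "superficial"

    @property
    def deep(self) -> np.ndarray:
        return self.vertex_indices[self.depth_class == "deep"]

    @property
    def superficial(self) -> np.ndarray:
        return self.vertex_indices[self.depth_class == "superficial"]

    def __len__(self) -> int:
        return len(self.vertex_indices)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _hull_faces_outward(dirs: np.ndarray) -> np.ndarray:
    """Triangulate unit directions via their convex hull, oriented outward."""
    hull = ConvexHull(dirs)
    faces = hull.simplices.copy()
    tri = dirs[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cen = tri.mean(axis=1)
    flip = np.einsum("ij,ij->i", n, cen) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def _radial_normals(vertices: np.ndarray, faces: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals, flipped (if needed) to point outward."""
    tm = trimesh.Trimesh(vertices, faces, process=False)
    vn = np.array(tm.vertex_normals, dtype=float)
    radial = vertices - center
    flip = np.einsum("ij,ij->i", vn, radial) < 0
    vn[flip] *= -1
    return vn / np.linalg.norm(vn, axis=1, keepdims=True)


def make_scalp(radius_mm: float = 90.0, n_vertices: int = 2562, seed: int = 0) -> SurfaceMesh:
    """Build a spherical scalp surface of adult-head scale.

    Vertices sit exactly at ``radius_mm`` from the origin on a golden-spiral
    lattice (approximately uniform density for any vertex count); the
    triangulation is the convex hull. The seed applies a random rigid
    rotation of the lattice so that repeated calls with different seeds
    decorrelate vertex placement.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be positive, got {radius_mm}")
    if n_vertices < 12:
        raise ValueError(f"need at least 12 vertices for a closed surface, got {n_vertices}")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(n_vertices)
    # random rotation: QR of a Gaussian matrix, det +1
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    dirs = dirs @ q.T
    faces = _hull_faces_outward(dirs)
    vertices = dirs * radius_mm
    # the surface is an exact sphere: analytic (radial) normals
    return SurfaceMesh(vertices, faces, dirs.copy(), np.zeros(3))


def _band_limited_field(
    dirs: np.ndarray, order: int, rng: np.random.Generator, n_waves: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Random band-limited function on the sphere with its tangential gradient.

    Superposition of ``n_waves`` oriented cosine waves cos(order * u.x + phase)
    with random axes u — a Gaussian-like random field whose angular spectrum
    concentrates near the requested ``order`` (gyrus/sulcus-like oscillation
    of angular wavelength ~2*pi/order). Returned field has zero mean and
    unit RMS over ``dirs``; the gradient (per unit arc length on the unit
    sphere, same normalisation) is analytic, projected tangent to the sphere.
    """
    axes = rng.standard_normal((n_waves, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    amps = rng.standard_normal(n_waves)
    phases = rng.uniform(0, 2 * np.pi, n_waves)
    proj = dirs @ axes.T  # (n, m)
    arg = order * proj + phases
    f = np.cos(arg) @ amps
    # d/d(x) of cos(order u.x + phi) = -order sin(...) u, then project tangent
    g = -(order * np.sin(arg) * amps) @ axes  # (n, 3)
    g -= np.einsum("ij,ij->i", g, dirs)[:, None] * dirs
    mean, rms = f.mean(), f.std()
    if rms == 0:
        return np.zeros(len(dirs)), np.zeros_like(dirs)
    return (f - mean) / rms, g / rms


def make_cortex(
    scalp: SurfaceMesh,
    min_depth_mm: float = 8.0,
    max_depth_mm: float = 45.0,
    fold_amplitude_mm: float = 12.0,
    fold_order: int = 10,
    target_spacing_mm: float = 3.0,
    fine_fold_amplitude_mm: float = 3.0,
    fine_fold_order: int = 40,
    truncate_inferior: bool = True,
    seed: int = 0,
) -> SourceSpace:
    """Build a folded cortical surface strictly inside the scalp.

    The surface is a star-shaped perturbation of a sphere. Two fold scales
    emulate distinct features of a real cortex:

    * a *depth* field — band-limited oscillation of order ``fold_order`` and
      RMS ``fold_amplitude_mm``, softly saturated (tanh) into the
      [min_depth, max_depth] band — creates the cm-scale depth spread that
      separates deep from superficial sources;
    * a *fine* fold field — order ``fine_fold_order`` (~10 mm wavelength),
      RMS ``fine_fold_amplitude_mm`` — represents gyral/sulcal walls at and
      below the sampling resolution. Dipole orientations are the analytic
      normals of the fully folded surface evaluated at the mesh vertices,
      so they tilt away from the conductor-radial direction the way real
      cortical normals do. (Purely radial dipoles are silent in a spherical
      conductor; without the fine scale, depth-extreme vertices would be
      exactly radial and the selected sources magnetically degenerate.)

    With ``truncate_inferior`` the surface is cut flat at
    z = -(scalp_radius - max_depth_mm), emulating the skull base: the brain
    occupies the upper head and its inferior edge sets a head-like Z floor
    for sensor packing. Vertex count is chosen so the mean nearest-neighbour
    spacing is ~``target_spacing_mm``. Depth is the exact Euclidean distance
    to the scalp triangulation.
    """
    center, scalp_radius = fit_sphere(scalp.vertices)
    if not (0 < min_depth_mm < max_depth_mm < scalp_radius):
        raise ValueError(
            f"need 0 < min_depth ({min_depth_mm}) < max_depth ({max_depth_mm}) "
            f"< scalp radius ({scalp_radius:.1f})"
        )
    rng = np.random.default_rng(seed)
    r_mid = scalp_radius - 0.5 * (min_depth_mm + max_depth_mm)
    # hexagonal-packing estimate of the vertex count needed for the spacing
    area = 4 * np.pi * r_mid**2
    n = max(100, int(round(area / (np.sqrt(3) / 2 * target_spacing_mm**2))))
    dirs = _fibonacci_directions(n)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    dirs = dirs @ q.T

    half_band = 0.5 * (max_depth_mm - min_depth_mm)
    if fold_amplitude_mm > 0:
        pert, _ = _band_limited_field(dirs, fold_order, rng)
        radius = r_mid + half_band * np.tanh(fold_amplitude_mm * pert / half_band)
    else:
        radius = np.full(n, r_mid)

    z_cut = -(scalp_radius - max_depth_mm)
    if truncate_inferior:
        below = dirs[:, 2] < 0
        r_plane = np.where(below, z_cut / np.where(below, dirs[:, 2], -1.0), np.inf)
        radius = np.minimum(radius, r_plane)

    vertices = center + dirs * radius[:, None]
    faces = _hull_faces_outward(dirs)

    # dipole orientations: mesh normal tilted by the fine fold field's slope
    mesh_normals = _radial_normals(vertices, faces, center)
    if fine_fold_amplitude_mm > 0:
        _, grad = _band_limited_field(dirs, fine_fold_order, rng)
        tilt = -fine_fold_amplitude_mm * grad / radius[:, None]
        tilt -= np.einsum("ij,ij->i", tilt, mesh_normals)[:, None] * mesh_normals
        normals = mesh_normals + tilt
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        # keep orientations on the outward side of the surface
        radial = vertices - center
        flip = np.einsum("ij,ij->i", normals, radial) < 0
        normals[flip] = mesh_normals[flip]
    else:
        normals = mesh_normals
    mesh = SurfaceMesh(vertices, faces, normals, center)
    _, depth = closest_point_on_mesh(vertices, scalp.vertices, scalp.faces)
    return SourceSpace(mesh=mesh, depth=depth)


def assign_parcels(space: SourceSpace, n_parcels: int = 90, seed: int = 0) -> SourceSpace:
    """Partition the cortex into contiguous labelled parcels (atlas stand-in).

    Seed vertices are chosen by farthest-point sampling (well spread, hence
    roughly balanced regions); every vertex is then assigned to its nearest
    seed. Labels are 0..n_parcels-1.
    """
    if n_parcels < 40:
        raise ValueError("need at least 40 parcels to host 40 mutually-exclusive sources")
    nv = space.n_vertices
    if n_parcels > nv:
        raise ValueError(f"n_parcels ({n_parcels}) exceeds vertex count ({nv})")
    rng = np.random.default_rng(seed)
    v = space.mesh.vertices
    seeds = np.empty(n_parcels, dtype=np.int64)
    seeds[0] = rng.integers(nv)
    d = np.linalg.norm(v - v[seeds[0]], axis=1)
    for i in range(1, n_parcels):
        seeds[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(v - v[seeds[i]], axis=1))
    _, labels = cKDTree(v[seeds]).query(v)
    return replace(space, parcel_label=labels.astype(np.int64))


def select_sources(space: SourceSpace, n_deep: int = 20, n_superficial: int = 20) -> SourceSet:
    """Pick the deepest and the most superficial sources, one per parcel.

    Greedy selection by depth rank: deep sources from the largest depths
    down, superficial from the smallest depths up, skipping any vertex whose
    parcel already hosts a source. This spreads sources across brain regions
    while stratifying them by depth.
    """
    labels = space.parcel_label
    if np.any(labels < 0):
        raise ValueError("assign_parcels must be run before selecting sources")
    n_parc = space.n_parcels
    if n_deep + n_superficial > n_parc:
        raise ValueError(
            f"{n_deep}+{n_superficial} sources do not fit in {n_parc} exclusive parcels"
        )
    depth = space.depth
    used: set[int] = set()
    idx: list[int] = []
    cls: list[str] = []
    for order, want, name in (
        (np.argsort(-depth), n_deep, "deep"),
        (np.argsort(depth), n_superficial, "superficial"),
    ):
        got = 0
        for vi in order:
            if got == want:
                break
            lab = int(labels[vi])
            if lab in used:
                continue
            used.add(lab)
            idx.append(int(vi))
            cls.append(name)
            got += 1
        if got < want:
            raise ValueError(f"could not place {want} {name} sources in distinct parcels")
    out = SourceSet(np.array(idx, dtype=np.int64), np.array(cls, dtype=object))
    if len(out.deep) and len(out.superficial):
        if depth[out.deep].min() <= depth[out.superficial].max():
            warnings.warn("deep and superficial depth ranges overlap after parcel exclusion")
    return out


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns (center, radius).

    Linearized fit: ||p||^2 = 2 c·p + (R^2 - ||c||^2).
    """
    p = np.asarray(points, float)
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = x[:3]
    radius = np.sqrt(x[3] + center @ center)
    return center, float(radius)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write to STL or Wavefront OBJ (extension decides; mm units)."""
    mesh.as_trimesh().export(str(path))


def read_mesh(path: str | Path, center: np.ndarray | None = None) -> SurfaceMesh:
    """Read an STL/OBJ surface (mm units assumed).

    STL stores a triangle soup, so coincident vertices are welded on load;
    OBJ vertex indexing is preserved as-is. ``center`` defaults to a
    least-squares sphere fit of the vertices.
    """
    suffix = Path(path).suffix.lower()
    tm = trimesh.load_mesh(str(path), process=suffix in (".stl",))
    vertices = np.asarray(tm.vertices, float)
    faces = np.asarray(tm.faces, np.int64)
    if center is None:
        center, _ = fit_sphere(vertices)
    return SurfaceMesh(vertices, faces, _radial_normals(vertices, faces, center), center)
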