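"""Sensor array design: point packing on the scalp at a target spacing.

Arrays are designed by a five-step packing algorithm:

1. the bounding box of the scalp is subdivided into squares with edge equal
   to the target inter-sensor spacing;
2. the square corners on each box face are projected along the face normal
   onto the surface and snapped to scalp vertices, initialising the layout
   at roughly the right density;
3. at each optimisation iteration a random sensor is moved to a 1-ring
   neighbouring vertex if that brings the observed sampling density
   (nearest-sensor Euclidean distances) closer to the target;
4. any scalp vertex farther than the target spacing from every sensor gets
   a sensor added, guaranteeing coverage;
5. steps 3-4 repeat for a large (default 10,000) number of iterations.

Sensors are restricted to vertices at or above a Z floor (normally the most
inferior point of the brain) and are single-axis radial magnetometers:
orientation = outward scalp normal. Standoff from the scalp (6.5 mm for
wearable on-scalp arrays, ~20 mm for a cryogenic helmet) is applied by
:func:`offset_array` along the vertex normal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._meshmath import ray_mesh_intersect
from .geometry import SurfaceMesh

__all__ = ["SensorArray", "pack_sensors", "offset_array"]


@dataclass(frozen=True)
class SensorArray:
    """Point-magnetometer array tied to scalp vertices.

    ``positions = scalp vertex + scalp_offset * vertex normal``;
    orientations are the outward scalp normals (radial sensors).
    """

    positions: np.ndarray  # (n, 3) mm
    orientations: np.ndarray  # (n, 3) unit
    vertex_indices: np.ndarray  # (n,) scalp vertex ids
    target_spacing: float  # mm
    scalp_offset: float  # mm
    scalp_center: np.ndarray  # (3,) mm

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    def nearest_sensor_distances(self) -> np.ndarray:
        """Distance from each sensor to its nearest other sensor (mm)."""
        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return d[:, 1]

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.hstack([self.positions, self.orientations]),
            columns=["x", "y", "z", "ox", "oy", "oz"],
        )
        df.insert(0, "name", [f"MAG{i:03d}" for i in range(self.n_channels)])
        df["offset"] = self.scalp_offset
        return df

    def save_json(self, path: str | Path) -> None:
        payload = {
            "target_spacing": self.target_spacing,
            "scalp_offset": self.scalp_offset,
            "scalp_center": self.scalp_center.tolist(),
            "vertex_indices": self.vertex_indices.tolist(),
            "positions": self.positions.tolist(),
            "orientations": self.orientations.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load_json(cls, path: str | Path) -> "SensorArray":
        d = json.loads(Path(path).read_text())
        return cls(
            positions=np.array(d["positions"], float),
            orientations=np.array(d["orientations"], float),
            vertex_indices=np.array(d["vertex_indices"], np.int64),
            target_spacing=float(d["target_spacing"]),
            scalp_offset=float(d["scalp_offset"]),
            scalp_center=np.array(d["scalp_center"], float),
        )


def _init_box_projection(scalp: SurfaceMesh, spacing: float) -> np.ndarray:
    """Steps 1-2: project bounding-box square corners onto the surface.

    Returns scalp vertex indices (deduplicated). Corners whose rays miss
    the surface contribute nothing.
    """
    lo = scalp.vertices.min(axis=0)
    hi = scalp.vertices.max(axis=0)
    tree = cKDTree(scalp.vertices)
    hits: list[np.ndarray] = []
    for axis in range(3):
        u, v = [a for a in range(3) if a != axis]
        gu = np.arange(lo[u], hi[u] + 1e-9, spacing)
        gv = np.arange(lo[v], hi[v] + 1e-9, spacing)
        if gu[-1] < hi[u]:
            gu = np.append(gu, hi[u])
        if gv[-1] < hi[v]:
            gv = np.append(gv, hi[v])
        uu, vv = np.meshgrid(gu, gv, indexing="ij")
        for side, sign in ((lo[axis], 1.0), (hi[axis], -1.0)):
            origins = np.zeros((uu.size, 3))
            origins[:, axis] = side
            origins[:, u] = uu.ravel()
            origins[:, v] = vv.ravel()
            direction = np.zeros(3)
            direction[axis] = sign  # inward face normal
            mask, pts = ray_mesh_intersect(origins, direction, scalp.vertices, scalp.faces)
            if mask.any():
                hits.append(pts[mask])
    if not hits:
        return np.empty(0, dtype=np.int64)
    pts = np.vstack(hits)
    _, idx = tree.query(pts)
    return np.unique(idx)


def _coverage_fill(
    sensors: set[int], candidate_pos: np.ndarray, candidate_ids: np.ndarray, spacing: float
) -> None:
    """Step 4: add sensors until no candidate vertex is farther than
    ``spacing`` from its nearest sensor. Mutates ``sensors`` in place."""
    while True:
        if not sensors:
            # seed with the topmost vertex
            sensors.add(int(candidate_ids[np.argmax(candidate_pos[:, 2])]))
            continue
        occupied = sorted(sensors)
        pos = candidate_pos[np.searchsorted(candidate_ids, occupied)]
        d, _ = cKDTree(pos).query(candidate_pos)
        worst = int(np.argmax(d))
        if d[worst] <= spacing:
            return
        sensors.add(int(candidate_ids[worst]))


def pack_sensors(
    scalp: SurfaceMesh,
    spacing_mm: float,
    n_iterations: int = 10_000,
    z_floor_mm: float | None = None,
    seed: int = 0,
) -> SensorArray:
    """Place sensors on scalp vertices at a target inter-sensor spacing.

    See the module docstring for the algorithm. The move-acceptance
    objective is the summed absolute deviation of every sensor's
    nearest-sensor distance from the target spacing; a proposed 1-ring move
    is accepted only if it lowers this objective. Optimisation stops early
    after 1,000 consecutive rejected moves. On return, no scalp vertex at
    or above ``z_floor_mm`` is farther than ``spacing_mm`` from its nearest
    sensor (the coverage guarantee).

    ``z_floor_mm`` defaults to the scalp's minimum Z (whole surface); pass
    the cortex minimum Z to restrict the array to a helmet-like cap.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    tm = scalp.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("scalp mesh must be a closed manifold surface")
    if z_floor_mm is None:
        z_floor_mm = float(scalp.vertices[:, 2].min())
    zmin, zmax = scalp.vertices[:, 2].min(), scalp.vertices[:, 2].max()
    if not (zmin <= z_floor_mm <= zmax):
        raise ValueError(f"z_floor {z_floor_mm} outside mesh Z range [{zmin:.1f}, {zmax:.1f}]")
    extent = float((scalp.vertices.max(0) - scalp.vertices.min(0)).max())
    if spacing_mm > extent:
        warnings.warn(
            f"spacing {spacing_mm} mm exceeds surface extent {extent:.0f} mm; "
            "returning a minimal covering array"
        )

    rng = np.random.default_rng(seed)
    candidate_mask = scalp.vertices[:, 2] >= z_floor_mm
    candidate_ids = np.nonzero(candidate_mask)[0]
    candidate_pos = scalp.vertices[candidate_ids]
    adjacency = scalp.vertex_adjacency()

    sensors: set[int] = {
        int(i) for i in _init_box_projection(scalp, spacing_mm) if candidate_mask[i]
    }
    _coverage_fill(sensors, candidate_pos, candidate_ids, spacing_mm)

    def objective(ids: np.ndarray) -> float:
        if len(ids) < 2:
            return 0.0
        pos = scalp.vertices[ids]
        d, _ = cKDTree(pos).query(pos, k=2)
        return float(np.abs(d[:, 1] - spacing_mm).sum())

    ids = np.array(sorted(sensors), dtype=np.int64)
    current = objective(ids)
    rejected = 0
    for it in range(n_iterations):
        if rejected >= 1000:
            break
        k = rng.integers(len(ids))
        nbrs = adjacency[ids[k]]
        nbrs = [n for n in nbrs if candidate_mask[n] and n not in sensors]
        if not nbrs:
            rejected += 1
            continue
        proposal = int(nbrs[rng.integers(len(nbrs))])
        trial = ids.copy()
        trial[k] = proposal
        val = objective(trial)
        if val < current:
            sensors.remove(int(ids[k]))
            sensors.add(proposal)
            ids = trial
            current = val
            rejected = 0
        else:
            rejected += 1
        if (it + 1) % 1000 == 0:
            before = len(sensors)
            _coverage_fill(sensors, candidate_pos, candidate_ids, spacing_mm)
            if len(sensors) != before:
                ids = np.array(sorted(sensors), dtype=np.int64)
                current = objective(ids)

    _coverage_fill(sensors, candidate_pos, candidate_ids, spacing_mm)
    ids = np.array(sorted(sensors), dtype=np.int64)
    return SensorArray(
        positions=scalp.vertices[ids].copy(),
        orientations=scalp.vertex_normals[ids].copy(),
        vertex_indices=ids,
        target_spacing=float(spacing_mm),
        scalp_offset=0.0,
        scalp_center=scalp.center.copy(),
    )


def offset_array(array: SensorArray, offset_mm: float) -> SensorArray:
    """Displace every sensor by ``offset_mm`` along its outward scalp normal.

    The offset is absolute (from the scalp surface), not cumulative:
    offsetting a 6.5 mm array to 20 mm lands at 20 mm. Channel count,
    ordering and orientations are unchanged.
    """
    if offset_mm < 0:
        raise ValueError("offset_mm must be non-negative")
    base = array.positions - array.scalp_offset * array.orientations
    return replace(
        array,
        positions=base + offset_mm * array.orientations,
        scalp_offset=float(offset_mm),
    )
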