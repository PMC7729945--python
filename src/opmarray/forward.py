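"""Dipole forward model in a spherical volume conductor and lead fields.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has an exact closed form (Sarvas 1987): with the dipole at r0 and the
field point at r (both relative to the sphere centre), a = r - r0,

    B(r) = mu0 / (4 pi F^2) * (F Q x r0 - (Q x r0 . r) grad F),
    F = a (r a + r^2 - r0 . r),
    grad F = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0,

where a = |a|, r = |r|. Volume currents are accounted for exactly; the
field outside depends only on the sphere centre, not its radius or
conductivity. Radial dipoles are magnetically silent, and the radial field
component equals that of the primary current alone — both properties are
used as test oracles.

Sensors are point magnetometers: the measurement is the projection of B
onto the sensor orientation. Units: positions mm, moments nAm, fields fT.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import SourceSpace, fit_sphere

__all__ = ["Dipole", "LeadField", "RankSpectrum", "dipole_field", "build_leadfield", "rank_spectrum"]

_MU0_4PI = 1e-7  # T m / A

# combined unit factor: positions mm -> m contributes 1/m^2 overall (B ~ Q/len^2),
# moment nAm -> Am is 1e-9, field T -> fT is 1e15; handled by explicit conversion.
_MM = 1e-3
_NAM = 1e-9
_T_TO_FT = 1e15


class GeometryError(ValueError):
    """Source/sensor placement violates the conductor geometry."""


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (mm), unit orientation, moment (nAm)."""

    position: np.ndarray
    orientation: np.ndarray
    moment: float = 1.0

    def __post_init__(self):
        o = np.asarray(self.orientation, float)
        n = np.linalg.norm(o)
        if abs(n - 1) > 1e-9:
            raise ValueError(f"orientation must be unit length (got norm {n:.3g})")
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "orientation", o)


@dataclass(frozen=True)
class RankSpectrum:
    """Cumulative variance explained of the lead-field covariance by rank."""

    cumulative_ve: np.ndarray  # fraction in [0, 1], non-decreasing
    singular_values: np.ndarray
    rank_95: int
    rank_99: int


@dataclass(frozen=True)
class LeadField:
    """Gain matrix L (channels x sources, fT per nAm) with metadata.

    Column i is the sensor response to a unit (1 nAm) dipole at source i
    oriented along its cortical vertex normal.
    """

    matrix: np.ndarray
    channel_positions: np.ndarray  # (c, 3) mm
    channel_orientations: np.ndarray  # (c, 3) unit
    source_vertex_indices: np.ndarray  # (s,) int
    source_positions: np.ndarray  # (s, 3) mm
    source_orientations: np.ndarray  # (s, 3) unit

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]

    def subset_sources(self, indices: np.ndarray) -> "LeadField":
        """Lead field restricted to the given source columns (by position in
        the matrix, not vertex id)."""
        idx = np.asarray(indices, dtype=np.int64)
        return LeadField(
            matrix=self.matrix[:, idx],
            channel_positions=self.channel_positions,
            channel_orientations=self.channel_orientations,
            source_vertex_indices=self.source_vertex_indices[idx],
            source_positions=self.source_positions[idx],
            source_orientations=self.source_orientations[idx],
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in (
                "matrix",
                "channel_positions",
                "channel_orientations",
                "source_vertex_indices",
                "source_positions",
                "source_orientations",
            ):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load(cls, path) -> "LeadField":
        with h5py.File(path, "r") as f:
            return cls(**{k: f[k][()] for k in f.keys()})


def _sarvas(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Sarvas field (T) for dipoles (r0, q) [m, A m] at points r [m].

    Broadcasts: r0, q are (s, 3); r is (c, 3); returns (c, s, 3).
    """
    r0 = np.atleast_2d(r0)[None, :, :]  # (1, s, 3)
    q = np.atleast_2d(q)[None, :, :]
    r = np.atleast_2d(r)[:, None, :]  # (c, 1, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)  # (c, s)
    if np.any(a < 1e-12):
        raise GeometryError("sensor coincides with dipole position")
    rn = np.linalg.norm(r, axis=-1)  # (c, 1)
    r0_dot_r = np.einsum("...i,...i->...", r0, r)  # (c, s)
    a_dot_r = np.einsum("...i,...i->...", a_vec, r)
    F = a * (rn * a + rn**2 - r0_dot_r)
    gF = (a**2 / rn + a_dot_r / a + 2 * a + 2 * rn)[..., None] * r - (
        a + 2 * rn + a_dot_r / a
    )[..., None] * r0
    qxr0 = np.cross(q, r0)  # (1, s, 3)
    qxr0_dot_r = np.einsum("...i,...i->...", qxr0, r)
    B = _MU0_4PI / F[..., None] ** 2 * (F[..., None] * qxr0 - qxr0_dot_r[..., None] * gF)
    return B


def dipole_field(
    dipole: Dipole,
    sensor_position: np.ndarray,
    sensor_orientation: np.ndarray,
    conductor_center: np.ndarray = (0.0, 0.0, 0.0),
    conductor_radius_mm: float | None = None,
) -> float:
    """Field (fT) of one dipole at one point magnetometer.

    The measurement is the projection of the Sarvas field onto
    ``sensor_orientation``; linear in the dipole moment. If
    ``conductor_radius_mm`` is given, placement is validated: the dipole
    must be strictly inside and the sensor strictly outside the sphere.
    """
    c = np.asarray(conductor_center, float)
    r0 = (dipole.position - c) * _MM
    r = (np.asarray(sensor_position, float) - c) * _MM
    if conductor_radius_mm is not None:
        rad = conductor_radius_mm * _MM
        if np.linalg.norm(r0) >= rad:
            raise GeometryError("dipole lies outside the conductor sphere")
        if np.linalg.norm(r) <= rad:
            raise GeometryError("sensor lies inside the conductor sphere")
    elif np.linalg.norm(r) <= np.linalg.norm(r0):
        raise GeometryError("sensor must be farther from the centre than the dipole")
    q = dipole.orientation * dipole.moment * _NAM
    B = _sarvas(r0[None, :], q[None, :], r[None, :])[0, 0]
    return float(B @ np.asarray(sensor_orientation, float)) * _T_TO_FT


def build_leadfield(space: SourceSpace, array, source_indices: np.ndarray | None = None) -> LeadField:
    """Assemble the lead field for a sensor array over (a subset of) the
    cortical source space.

    One column per source vertex: unit 1 nAm dipole along the vertex
    normal. Computation is vectorized and chunked over sources. Raises
    :class:`GeometryError` naming the offending element if any sensor lies
    inside the sphere enclosing the cortex or any source outside it.
    """
    center = np.asarray(space.mesh.center, float)
    if source_indices is None:
        source_indices = np.arange(space.n_vertices)
    source_indices = np.asarray(source_indices, dtype=np.int64)
    src_pos = space.mesh.vertices[source_indices]
    src_ori = space.mesh.vertex_normals[source_indices]

    sens_pos = np.asarray(array.positions, float)
    sens_ori = np.asarray(array.orientations, float)

    src_r = np.linalg.norm(src_pos - center, axis=1)
    sens_r = np.linalg.norm(sens_pos - center, axis=1)
    bad = np.nonzero(sens_r <= src_r.max())[0]
    if len(bad):
        raise GeometryError(
            f"sensor {bad[0]} (radius {sens_r[bad[0]]:.1f} mm) is not outside the "
            f"sphere enclosing the cortex ({src_r.max():.1f} mm)"
        )

    r = (sens_pos - center) * _MM
    out = np.empty((len(sens_pos), len(src_pos)))
    chunk = max(1, int(2e7 // max(1, len(sens_pos))))
    for lo in range(0, len(src_pos), chunk):
        hi = min(lo + chunk, len(src_pos))
        r0 = (src_pos[lo:hi] - center) * _MM
        q = src_ori[lo:hi] * _NAM  # 1 nAm
        B = _sarvas(r0, q, r)  # (c, s, 3) in T
        out[:, lo:hi] = np.einsum("csi,ci->cs", B, sens_ori) * _T_TO_FT
    return LeadField(
        matrix=out,
        channel_positions=sens_pos,
        channel_orientations=sens_ori,
        source_vertex_indices=source_indices,
        source_positions=src_pos,
        source_orientations=src_ori,
    )


def rank_spectrum(lf: LeadField | np.ndarray) -> RankSpectrum:
    """Eigen-spectrum of the lead-field covariance L L^T.

    Returns the cumulative fraction of variance explained by the top-k
    spatial components and the ranks reaching 95% and 99% — a measure of
    how many independent spatial degrees of freedom the array sees.
    """
    L = lf.matrix if isinstance(lf, LeadField) else np.asarray(lf, float)
    if L.size == 0:
        raise ValueError("empty lead field")
    s = np.linalg.svd(L, compute_uv=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        raise ValueError("all-zero lead field has no rank spectrum")
    cum = np.cumsum(ev) / total
    rank_95 = int(np.searchsorted(cum, 0.95) + 1)
    rank_99 = int(np.searchsorted(cum, 0.99) + 1)
    return RankSpectrum(cumulative_ve=cum, singular_values=s, rank_95=rank_95, rank_99=rank_99)
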