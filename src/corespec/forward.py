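"""Spherical-head MEG forward model.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has the closed form derived by Sarvas: with sensor position ``r``
and dipole position ``r0`` (both relative to the sphere center), moment
``q``, and

    a = r - r0,  a = |a|,  r = |r|,
    F = a (r a + r^2 - r0 . r),
    grad F = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0,

the field outside the conductor is

    B(r) = mu0 / (4 pi F^2) * ( F (q x r0) - ((q x r0) . r) grad F ).

Volume currents are fully accounted for; radial dipoles are magnetically
silent, and the sphere's conductivity profile drops out.  The lead field
projects B onto each sensor's orientation, with every dipole fixed normal
to the cortical surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SensorArray, SourceSpace
from .exceptions import ConfigurationError, DegenerateGeometryError

MU0_OVER_4PI = 1e-7  # mu0 / (4 pi), T*m/A


@dataclass(frozen=True)
class HeadSphere:
    """Conductor sphere: center (m) and radius (m)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )
        if not self.radius > 0:
            raise ConfigurationError("sphere radius must be positive")


@dataclass
class LeadField:
    """Sensors x sources gain matrix, tesla per A*m, fixed orientation."""

    matrix: np.ndarray  # (n_sensors, n_sources)
    sphere: HeadSphere

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ConfigurationError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def fit_sphere_lstsq(positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through a point cloud.

    Solves ``|v|^2 = 2 c.v + (r^2 - |c|^2)`` in the least-squares sense.
    Raises for degenerate (e.g. coplanar) geometry.
    """
    v = np.asarray(positions, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 4:
        raise DegenerateGeometryError("need at least 4 points in 3D")
    design = np.column_stack([2.0 * v, np.ones(len(v))])
    target = np.einsum("ij,ij->i", v, v)
    sol, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "vertex cloud is degenerate (coplanar or collinear); "
            "cannot fit a sphere"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    return center, float(np.sqrt(r2))


def fit_sphere(source_space: SourceSpace, inflate: float = 0.1) -> HeadSphere:
    """Best-fit sphere for a source space, inflated to contain all vertices.

    The fitted radius is expanded by ``inflate`` (default 10%) and never
    smaller than the farthest vertex, so every source lies strictly inside.
    """
    center, radius = fit_sphere_lstsq(source_space.positions)
    max_dist = float(
        np.linalg.norm(source_space.positions - center, axis=1).max()
    )
    return HeadSphere(center=center, radius=(1.0 + inflate) * max(radius, max_dist))


def sarvas_field(
    sensor_pos: np.ndarray,
    source_pos: np.ndarray,
    moments: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (T) of current dipoles in a conducting sphere.

    Parameters are broadcast over sources: ``source_pos`` and ``moments``
    are (m, 3); ``sensor_pos`` is a single (3,) point.  Returns (m, 3)
    field vectors.  Degeneracies (dipole at the center, or exactly radial
    moments) resolve to the analytic limit of a vanishing field, never to
    non-finite output.
    """
    sensor = np.asarray(sensor_pos, dtype=float).reshape(3)
    r0 = np.atleast_2d(np.asarray(source_pos, dtype=float))
    q = np.atleast_2d(np.asarray(moments, dtype=float))
    if center is not None:
        c = np.asarray(center, dtype=float).reshape(3)
        sensor = sensor - c
        r0 = r0 - c

    a_vec = sensor[None, :] - r0
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(sensor)
    if np.any(a < 1e-15) or r < 1e-15:
        raise ConfigurationError("sensor coincides with a source or the center")
    ar = a_vec @ sensor
    f = a * (r * a + r**2 - (r0 @ sensor))
    grad_f = (
        (a**2 / r + ar / a + 2.0 * a + 2.0 * r)[:, None] * sensor[None, :]
        - (a + 2.0 * r + ar / a)[:, None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0 - (q_x_r0 @ sensor)[:, None] * grad_f
    )
    return b


def compute_lead_field(
    source_space: SourceSpace,
    array: SensorArray,
    sphere: HeadSphere,
) -> LeadField:
    """Fixed-orientation lead field: field of a unit dipole (1 A*m) along
    each vertex normal, projected on each sensor's orientation.

    Sensors must lie outside the conductor sphere and sources strictly
    inside.
    """
    rel_sources = source_space.positions - sphere.center
    rel_sensors = array.positions - sphere.center
    src_r = np.linalg.norm(rel_sources, axis=1)
    sen_r = np.linalg.norm(rel_sensors, axis=1)
    if np.any(src_r >= sphere.radius):
        raise ConfigurationError(
            "source vertices must lie strictly inside the conductor sphere"
        )
    if np.any(sen_r <= sphere.radius):
        raise ConfigurationError(
            "sensors must lie outside the conductor sphere"
        )
    gain = np.empty((array.n, source_space.n))
    for i in range(array.n):
        b = sarvas_field(
            array.positions[i], source_space.positions, source_space.normals,
            center=sphere.center,
        )
        gain[i] = b @ array.orientations[i]
    return LeadField(matrix=gain, sphere=sphere)
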