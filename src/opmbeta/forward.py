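"""Analytic forward model: current dipole in a homogeneous conducting sphere.

Uses the closed-form (Sarvas) expression for the magnetic field outside a
spherically symmetric volume conductor.  Radial dipoles, and any dipole at
the sphere centre, are magnetically silent; the lead field is therefore
restricted to the two tangential source orientations where needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ChannelGeometry, GeometryError, HeadModel

MU0_4PI = 1e-7  # mu_0 / 4 pi, T m / (A m)


def sphere_dipole_field(
    dipole_pos: np.ndarray,
    moment: np.ndarray,
    sensor_pos: np.ndarray,
    orientation: np.ndarray,
    head: HeadModel | None = None,
) -> np.ndarray:
    """Field component (T) seen by point magnetometers.

    Parameters
    ----------
    dipole_pos : (3,) dipole location, m (head frame).
    moment : (3,) dipole moment, A m.
    sensor_pos : (n, 3) or (3,) sensor positions outside the sphere.
    orientation : (n, 3) or (3,) unit sensing orientation per sensor.
    head : conducting sphere; default origin 0, radius 0.09 m.
    """
    head = head or HeadModel()
    sensor_pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    orientation = np.atleast_2d(np.asarray(orientation, dtype=float))
    B = _sarvas(
        np.asarray(dipole_pos, float)[None, :] - head.origin,
        np.asarray(moment, float)[None, :],
        sensor_pos - head.origin,
        head.radius,
    )[0]
    out = np.einsum("nj,nj->n", B, orientation)
    return out if out.size > 1 else float(out[0])


def _sarvas(r0: np.ndarray, Q: np.ndarray, r: np.ndarray, radius: float) -> np.ndarray:
    """Vectorised Sarvas formula.

    r0 : (V, 3) dipole positions (sphere-centred), Q : (V, 3) moments,
    r : (C, 3) sensor positions (sphere-centred).  Returns (V, C, 3).
    """
    if np.any(np.linalg.norm(r0, axis=-1) >= radius):
        raise GeometryError("dipole must lie strictly inside the sphere")
    if np.any(np.linalg.norm(r, axis=-1) <= radius):
        raise GeometryError("sensors must lie strictly outside the sphere")
    a_vec = r[None, :, :] - r0[:, None, :]            # (V, C, 3)
    a = np.linalg.norm(a_vec, axis=-1)                # (V, C)
    rn = np.linalg.norm(r, axis=-1)[None, :]          # (1, C)
    ar = np.einsum("vcj,cj->vc", a_vec, r)            # a . r
    r0r = np.einsum("vj,cj->vc", r0, r)               # r0 . r
    F = a * (rn * a + rn**2 - r0r)
    gradF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[..., None] * r[None, :, :]
        - (a + 2.0 * rn + ar / a)[..., None] * r0[:, None, :]
    )
    Qxr0 = np.cross(Q, r0)                            # (V, 3)
    Qxr0_r = np.einsum("vj,cj->vc", Qxr0, r)
    B = (F[..., None] * Qxr0[:, None, :] - Qxr0_r[..., None] * gradF) / F[..., None] ** 2
    return MU0_4PI * B


def tangential_basis(points: np.ndarray, origin: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal tangential basis (V, 3, 2) at each point.

    The radial direction at a source is magnetically silent in the sphere,
    so the usable source space at each voxel is this 2-D subspace.  Points
    too close to the origin get a zero basis (flagged unlocalizable later).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if origin is not None:
        pts = pts - origin
    rad = np.linalg.norm(pts, axis=-1)
    ok = rad > 1e-9
    e_r = np.zeros_like(pts)
    e_r[ok] = pts[ok] / rad[ok, None]
    # pick the global axis least aligned with e_r, then Gram-Schmidt
    ref = np.zeros_like(pts)
    ref[:, 2] = 1.0
    swap = np.abs(e_r[:, 2]) > 0.9
    ref[swap] = [1.0, 0.0, 0.0]
    t1 = np.cross(e_r, ref)
    n1 = np.linalg.norm(t1, axis=-1)
    t1[ok] /= n1[ok, None]
    t2 = np.cross(e_r, t1)
    basis = np.stack([t1, t2], axis=-1)
    basis[~ok] = 0.0
    return basis


@dataclass
class SourceGrid:
    """Voxel coordinates for source scanning."""

    points: np.ndarray   # (V, 3)
    spacing: float       # m

    @property
    def n_voxels(self) -> int:
        return self.points.shape[0]


def make_grid(
    head: HeadModel,
    spacing: float,
    center: np.ndarray | None = None,
    half_extent: float | None = None,
) -> SourceGrid:
    """Isotropic grid of voxels strictly inside the sphere.

    With ``center``/``half_extent`` the grid is a refined cube around a
    region of interest (still clipped to the sphere interior).
    """
    if spacing <= 0:
        raise GeometryError("grid spacing must be positive")
    if center is None:
        lo, hi = -head.radius, head.radius
        ax = np.arange(lo, hi + spacing / 2, spacing)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = pts + head.origin
    else:
        center = np.asarray(center, float)
        ax = np.arange(-half_extent, half_extent + spacing / 2, spacing)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        pts = pts + center
    # keep voxels safely interior so the forward model is well conditioned
    inside = np.linalg.norm(pts - head.origin, axis=-1) < head.radius - spacing / 4
    return SourceGrid(points=pts[inside], spacing=spacing)


@dataclass
class LeadField:
    """Per-voxel forward fields.

    ``L[v]`` is (n_channels, 3): the field of unit dipoles along x, y, z at
    voxel ``v``, projected on every channel orientation.
    """

    L: np.ndarray        # (V, n_channels, 3)
    points: np.ndarray   # (V, 3)
    head: HeadModel

    @property
    def n_voxels(self) -> int:
        return self.L.shape[0]

    def tangential(self) -> tuple[np.ndarray, np.ndarray]:
        """(V, n_channels, 2) tangential-subspace lead fields + bases."""
        basis = tangential_basis(self.points, self.head.origin)
        return np.einsum("vcj,vjk->vck", self.L, basis), basis


def compute_leadfield(
    points: np.ndarray,
    geometry: ChannelGeometry,
    head: HeadModel | None = None,
) -> LeadField:
    """Forward fields for unit dipoles along the 3 cardinal axes."""
    head = head or HeadModel()
    pts = np.atleast_2d(np.asarray(points, float))
    r0 = pts - head.origin
    r = geometry.positions - head.origin
    V, C = r0.shape[0], r.shape[0]
    L = np.empty((V, C, 3))
    eye = np.eye(3)
    for j in range(3):
        Bj = _sarvas(r0, np.tile(eye[j], (V, 1)), r, head.radius)
        L[:, :, j] = np.einsum("vck,ck->vc", Bj, geometry.orientations)
    return LeadField(L=L, points=pts, head=head)
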