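"""Minimal surface-surface distance between two finite cylinders.

Nucleosomes are modelled as solid cylinders (radius ~5.5 nm, height
~6 nm, axis = disc normal).  Contact classification needs the minimal
distance between the two cylinder surfaces and, for each cylinder, the
facet (flat cap = "face", curved wall = "side") on which the closest
point lies.  The minimum is found by sampling one cylinder's surface on
a structured parameter grid, evaluating the exact signed distance to the
other (solid) cylinder, and polishing the best sample with a local
bounded optimisation; the sweep is done in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = ["CylinderSpec", "cylinder_surface_distance", "signed_distance_to_cylinder"]


@dataclass(frozen=True)
class CylinderSpec:
    center: np.ndarray
    axis: np.ndarray  # unit
    radius: float
    half_height: float

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        """World points -> (rho, z) cylindrical coordinates of this cylinder."""
        d = np.atleast_2d(pts) - self.center
        z = d @ self.axis
        radial = d - np.outer(z, self.axis)
        rho = np.linalg.norm(radial, axis=1)
        return rho, z


def signed_distance_to_cylinder(pts: np.ndarray, cyl: CylinderSpec) -> np.ndarray:
    """Exact signed Euclidean distance from points to a solid cylinder.

    Negative inside, positive outside.
    """
    rho, z = cyl.to_local(pts)
    drho = rho - cyl.radius
    dz = np.abs(z) - cyl.half_height
    outside = np.sqrt(np.maximum(drho, 0.0) ** 2 + np.maximum(dz, 0.0) ** 2)
    inside = np.minimum(np.maximum(drho, dz), 0.0)
    return np.where((drho > 0) | (dz > 0), outside, inside)


def _closest_surface_region(pt: np.ndarray, cyl: CylinderSpec, face_frac: float) -> str:
    """Facet of ``cyl`` on which the surface point closest to ``pt`` lies."""
    rho, z = cyl.to_local(pt.reshape(1, 3))
    rho, z = float(rho[0]), float(z[0])
    drho = rho - cyl.radius
    dz = abs(z) - cyl.half_height
    if drho > 0 and dz > 0:
        # closest point is the rim circle: radial coordinate = radius
        return "side"
    if drho > 0:
        return "side"
    if dz > 0:
        region_rho = rho
    else:
        # inside the solid: nearer surface wins
        if drho >= dz:
            return "side"
        region_rho = rho
    return "face" if region_rho <= face_frac * cyl.radius else "side"


def _surface_grid(radius: float, half_height: float, n_phi: int = 40, n_z: int = 9,
                  n_r: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Structured sample of the full cylinder surface in local coordinates.

    Returns (points (n,3) in local frame, is_cap flags with signed z for caps).
    """
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    pts = []
    # lateral wall
    z = np.linspace(-half_height, half_height, n_z)
    zz, pp = np.meshgrid(z, phi, indexing="ij")
    pts.append(
        np.column_stack(
            [radius * np.cos(pp.ravel()), radius * np.sin(pp.ravel()), zz.ravel()]
        )
    )
    # caps (include centre and rim)
    r = np.linspace(0.0, radius, n_r)
    rr, pp = np.meshgrid(r[1:], phi, indexing="ij")
    for sign in (-1.0, 1.0):
        cap = np.column_stack(
            [rr.ravel() * np.cos(pp.ravel()), rr.ravel() * np.sin(pp.ravel()),
             np.full(rr.size, sign * half_height)]
        )
        pts.append(cap)
        pts.append(np.array([[0.0, 0.0, sign * half_height]]))
    return np.vstack(pts)


_GRID_CACHE: dict[tuple[float, float], np.ndarray] = {}


def _local_frame(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.column_stack([e1, e2, axis])


def _sweep(src: CylinderSpec, dst: CylinderSpec):
    """Min over sampled src-surface points of signed distance to dst.

    Returns the polished minimum plus every sample point exactly tied
    (within 1e-9) with the unpolished grid minimum; ties arise for
    degenerate flat-on-flat or wall-on-wall geometries and are resolved
    by the caller's facet preference.
    """
    key = (src.radius, src.half_height)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = _surface_grid(src.radius, src.half_height)
    local = _GRID_CACHE[key]
    R = _local_frame(src.axis)
    world = local @ R.T + src.center
    d = signed_distance_to_cylinder(world, dst)
    i = int(np.argmin(d))
    grid_min = float(d[i])
    tied = world[d <= grid_min + 1e-9]
    best_pt, best_d = _polish(local[i], R, src, dst, world[i], grid_min)
    return best_d, best_pt, tied, grid_min


def _polish(local_pt, R, src, dst, best_pt, best_d):
    """Refine the grid argmin by shrinking local grids on its chart."""
    rho = float(np.hypot(local_pt[0], local_pt[1]))
    phi = float(np.arctan2(local_pt[1], local_pt[0]))
    on_cap = abs(abs(local_pt[2]) - src.half_height) < 1e-9 and rho < src.radius - 1e-9
    n_loc = 7
    if on_cap:
        zs = np.sign(local_pt[2]) * src.half_height
        u, v = rho, phi
        du, dv = src.radius / 6.0, 2 * np.pi / 40.0
        for _ in range(3):
            uu = np.clip(np.linspace(u - du, u + du, n_loc), 0.0, src.radius)
            vv = np.linspace(v - dv, v + dv, n_loc)
            U, V = np.meshgrid(uu, vv, indexing="ij")
            pts = np.column_stack(
                [U.ravel() * np.cos(V.ravel()), U.ravel() * np.sin(V.ravel()),
                 np.full(U.size, zs)]
            )
            d = signed_distance_to_cylinder(pts @ R.T + src.center, dst)
            i = int(np.argmin(d))
            u, v = float(U.ravel()[i]), float(V.ravel()[i])
            cand_d, cand = float(d[i]), pts[i]
            du /= 3.0
            dv /= 3.0
    else:
        u, v = float(local_pt[2]), phi
        du, dv = src.half_height / 4.0, 2 * np.pi / 40.0
        for _ in range(3):
            uu = np.clip(np.linspace(u - du, u + du, n_loc), -src.half_height, src.half_height)
            vv = np.linspace(v - dv, v + dv, n_loc)
            U, V = np.meshgrid(uu, vv, indexing="ij")
            pts = np.column_stack(
                [src.radius * np.cos(V.ravel()), src.radius * np.sin(V.ravel()), U.ravel()]
            )
            d = signed_distance_to_cylinder(pts @ R.T + src.center, dst)
            i = int(np.argmin(d))
            u, v = float(U.ravel()[i]), float(V.ravel()[i])
            cand_d, cand = float(d[i]), pts[i]
            du /= 3.0
            dv /= 3.0
    if cand_d < best_d:
        return cand @ R.T + src.center, cand_d
    return best_pt, best_d


def cylinder_surface_distance(
    a: CylinderSpec, b: CylinderSpec, face_frac: float = 0.9
) -> tuple[float, str, str]:
    """Minimal surface-surface distance and per-cylinder facets.

    Returns ``(distance, facet_a, facet_b)``; negative distance is the
    deepest penetration of one surface into the other solid, and the
    facets are then those of the deepest-overlap point.
    """
    d_ab, pt_a, tied_a, grid_ab = _sweep(a, b)  # pt_a on surface of a
    d_ba, pt_b, tied_b, grid_ba = _sweep(b, a)
    dist = min(d_ab, d_ba)

    candidates: list[tuple[str, str]] = []
    if d_ab <= d_ba:
        candidates.append(
            (_point_facet(pt_a, a, face_frac), _closest_surface_region(pt_a, b, face_frac))
        )
    if d_ba <= d_ab:
        fb = _point_facet(pt_b, b, face_frac)
        fa = _closest_surface_region(pt_b, a, face_frac)
        candidates.append((fa, fb))
    # exact grid ties mark degenerate (flat-on-flat) contact geometry:
    # consider every tied sample and prefer the face interpretation
    if grid_ab <= dist + 1e-9:
        for pt in tied_a:
            candidates.append(
                (_point_facet(pt, a, face_frac), _closest_surface_region(pt, b, face_frac))
            )
    if grid_ba <= dist + 1e-9:
        for pt in tied_b:
            candidates.append(
                (_closest_surface_region(pt, a, face_frac), _point_facet(pt, b, face_frac))
            )

    def rank(pair):  # face-to-face > face-to-side > side-to-side
        return ("face", "face") == pair and 2 or ("face" in pair and 1 or 0)

    facet_a, facet_b = max(candidates, key=rank)
    return dist, facet_a, facet_b


def _point_facet(pt: np.ndarray, cyl: CylinderSpec, face_frac: float) -> str:
    rho, z = cyl.to_local(pt.reshape(1, 3))
    rho, z = float(rho[0]), float(z[0])
    if abs(abs(z) - cyl.half_height) < 1e-6 and rho <= face_frac * cyl.radius:
        return "face"
    return "side"
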