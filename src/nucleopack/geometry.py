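"""Nucleosome poses, fibers and per-fiber geometric descriptors.

A nucleosome is modelled as an oriented disc: a centre point plus an
orthonormal frame in which the local +z axis is the disc (superhelical)
normal and the local +x axis is the dyad.  Fibers are ordered lists of
poses in DNA-connectivity order; the descriptors computed here are the
centre distance ``D`` and plane dihedral ``para`` of semi-adjacent
(N, N+2) nucleosomes, and the signed plane dihedral ``alpha`` and centre
distance ``d_adj`` of adjacent (N, N+1) nucleosomes.

Conventions
-----------
* ``para`` is the folded plane angle in [0, 90] degrees (flip-invariant).
* ``alpha`` follows the right-hand rule about the N -> N+1 centre axis and
  lives in [0, 360); reversing the traversal maps alpha -> (360 - alpha).
* All lengths are nanometres, all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "NucleosomePose",
    "Fiber",
    "StepParameters",
    "DISC_RADIUS_NM",
    "DISC_HEIGHT_NM",
    "plane_angle",
    "signed_dihedral",
    "fiber_step_table",
    "radius_of_gyration",
    "build_ideal_fiber",
    "build_two_start_fiber",
    "build_zigzag_fiber",
]

#: Canonical nucleosome disc dimensions (nm); used wherever a physical
#: extent is needed (sterics, contact classification, rasterisation).
DISC_RADIUS_NM = 5.5
DISC_HEIGHT_NM = 6.0

_UNIT_TOL = 1e-6


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalised")
    return v / n


def _rodrigues(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues formula)."""
    axis = _unit(axis)
    t = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


@dataclass(frozen=True)
class NucleosomePose:
    """Rigid-body pose of one nucleosome disc.

    Parameters
    ----------
    center : (3,) array_like
        Disc centre, nm.
    normal : (3,) array_like
        Unit disc normal (superhelical axis).
    dyad : (3,) array_like
        Unit dyad axis, perpendicular to ``normal``.
    id : int
        Particle identifier; unique within a model.
    """

    center: np.ndarray
    normal: np.ndarray
    dyad: np.ndarray
    id: int = 0

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        dyad = np.asarray(self.dyad, dtype=float).reshape(3)
        if abs(np.linalg.norm(normal) - 1.0) > 1e-3:
            raise ValueError("normal must be a unit vector")
        if abs(np.linalg.norm(dyad) - 1.0) > 1e-3:
            raise ValueError("dyad must be a unit vector")
        normal = _unit(normal)
        # Gram-Schmidt: enforce exact orthogonality within tolerance.
        proj = float(np.dot(dyad, normal))
        if abs(proj) > 1e-3:
            raise ValueError("dyad must be perpendicular to normal")
        dyad = _unit(dyad - proj * normal)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "normal", normal)
        object.__setattr__(self, "dyad", dyad)

    @property
    def binormal(self) -> np.ndarray:
        """Third axis completing the right-handed frame (normal x dyad)."""
        return np.cross(self.normal, self.dyad)

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Columns (dyad, normal x dyad, normal): local +z is the normal."""
        return np.column_stack([self.dyad, self.binormal, self.normal])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NucleosomePose":
        return NucleosomePose(
            center=rotation @ self.center + translation,
            normal=rotation @ self.normal,
            dyad=rotation @ self.dyad,
            id=self.id,
        )


@dataclass
class Fiber:
    """Ordered nucleosome poses in DNA-connectivity order."""

    nucleosomes: list[NucleosomePose]
    linker_bp: int = 25
    fiber_id: int | str = 0
    #: ground-truth construction parameters, filled by the builders
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.nucleosomes) < 2:
            raise ValueError("a fiber needs at least 2 nucleosomes")
        c = self.centers
        if np.any(np.linalg.norm(np.diff(c, axis=0), axis=1) <= 0):
            raise ValueError("adjacent nucleosome centres must be distinct")

    def __len__(self) -> int:
        return len(self.nucleosomes)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.nucleosomes])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Fiber":
        return Fiber(
            nucleosomes=[p.transformed(rotation, translation) for p in self.nucleosomes],
            linker_bp=self.linker_bp,
            fiber_id=self.fiber_id,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class StepParameters:
    """Descriptors at one fiber position N."""

    position: int
    D: float  # nm, N <-> N+2 centre distance (NaN if N+2 absent)
    para: float  # deg, folded N <-> N+2 plane angle
    alpha: float  # deg in [0, 360), signed N <-> N+1 plane dihedral
    d_adj: float  # nm, N <-> N+1 centre distance


def plane_angle(a: NucleosomePose, b: NucleosomePose) -> float:
    """Folded angle in [0, 90] degrees between two disc planes.

    Zero means parallel discs, ninety perpendicular.  Invariant to
    flipping either normal and symmetric in its arguments.
    """
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def signed_dihedral(
    a: NucleosomePose, b: NucleosomePose, direction: np.ndarray | None = None
) -> float:
    """Signed plane dihedral in [0, 360) about the a -> b centre axis.

    Both normals are projected onto the plane perpendicular to
    ``direction`` (default: the unit vector from ``a.center`` to
    ``b.center``); the returned angle rotates the projected normal of
    ``a`` onto that of ``b`` by the right-hand rule about ``direction``.
    """
    if direction is None:
        direction = b.center - a.center
    u = _unit(direction)
    for pose in (a, b):
        if 1.0 - abs(float(np.dot(pose.normal, u))) < 1e-6:
            raise ValueError(
                "degenerate geometry: disc normal parallel to the centre axis"
            )
    pa = a.normal - np.dot(a.normal, u) * u
    pb = b.normal - np.dot(b.normal, u) * u
    ang = np.degrees(np.arctan2(float(np.dot(u, np.cross(pa, pb))), float(np.dot(pa, pb))))
    return float(ang % 360.0)


def fiber_step_table(f: Fiber) -> pd.DataFrame:
    """Per-position descriptor table for a fiber.

    One row per position N in [0, len-2]: ``alpha_deg`` and ``d_adj_nm``
    from the (N, N+1) pair, ``D_nm`` and ``para_deg`` from the (N, N+2)
    pair (NaN on the last row, where N+2 does not exist).  Summary means
    and standard deviations are attached in ``DataFrame.attrs["summary"]``.
    """
    n = len(f)
    if n < 3:
        raise ValueError("fiber_step_table requires a fiber of length >= 3")
    rows = []
    for i in range(n - 1):
        a, b = f.nucleosomes[i], f.nucleosomes[i + 1]
        alpha = signed_dihedral(a, b)
        d_adj = float(np.linalg.norm(b.center - a.center))
        if i + 2 < n:
            c = f.nucleosomes[i + 2]
            D = float(np.linalg.norm(c.center - a.center))
            para = plane_angle(a, c)
        else:
            D, para = np.nan, np.nan
        rows.append(
            {"position": i, "D_nm": D, "para_deg": para, "alpha_deg": alpha, "d_adj_nm": d_adj}
        )
    table = pd.DataFrame(rows)
    summary = {}
    for col in ("D_nm", "para_deg", "d_adj_nm"):
        v = table[col].dropna().to_numpy()
        summary[col] = {"mean": float(np.mean(v)), "sd": float(np.std(v))}
    # alpha is circular: mean via the circular mean, SD via circular spread
    a = np.deg2rad(table["alpha_deg"].to_numpy())
    z = np.mean(np.exp(1j * a))
    circ_mean = float(np.degrees(np.angle(z)) % 360.0)
    r = min(abs(z), 1.0)
    circ_sd = float(np.degrees(np.sqrt(max(-2.0 * np.log(r), 0.0)))) if r > 0 else np.inf
    summary["alpha_deg"] = {"mean": circ_mean, "sd": circ_sd, "circular": True}
    summary["para_convention"] = "folded [0, 90] deg (flip-invariant)"
    table.attrs["summary"] = summary
    return table


def radius_of_gyration(f: Fiber | np.ndarray) -> float:
    """Radius of gyration over nucleosome centres, unweighted (nm).

    Pose tables carry no mass information, so each nucleosome counts as
    one equal point mass at its geometric centre.
    """
    c = f.centers if isinstance(f, Fiber) else np.atleast_2d(np.asarray(f, dtype=float))
    if c.shape[0] == 0:
        raise ValueError("need at least one centre")
    d = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# idealised fiber builders
# ---------------------------------------------------------------------------


def _check_sterics(centers: np.ndarray, min_sep: float, skip_adjacent: bool = False) -> None:
    n = len(centers)
    diff = centers[:, None, :] - centers[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(n, k=2 if skip_adjacent else 1)
    bad = d[iu] < min_sep
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        i, j = int(iu[0][k]), int(iu[1][k])
        raise ValueError(
            f"steric overlap beyond tolerance: nucleosomes {i} and {j} "
            f"are {d[i, j]:.2f} nm apart (< {min_sep} nm)"
        )


def _two_start_poses(n: int, rise: float, theta_deg: float, sign: float, lateral_sep: float):
    """Two face-to-face stacks with axes tilted +/- theta from z in the y-z plane."""
    t = np.deg2rad(theta_deg)
    a_axis = np.array([0.0, sign * np.sin(t), np.cos(t)])
    b_axis = np.array([0.0, -sign * np.sin(t), np.cos(t)])
    p_a = np.array([-lateral_sep / 2.0, 0.0, 0.0])
    p_b = np.array([lateral_sep / 2.0, 0.0, 0.0]) + 0.5 * rise * b_axis
    poses = []
    for i in range(n):
        m, odd = divmod(i, 2)
        axis = b_axis if odd else a_axis
        base = p_b if odd else p_a
        center = base + m * rise * axis
        # dyad: any unit vector perpendicular to the stack axis
        dyad = _unit(np.cross(axis, np.array([1.0, 0.0, 0.0]))
                     if abs(axis[0]) > 0.9 else np.cross(axis, np.array([0.0, 0.0, 1.0]))
                     if abs(axis[2]) < 0.999999 else np.array([1.0, 0.0, 0.0]))
        poses.append(NucleosomePose(center=center, normal=axis, dyad=dyad, id=i))
    return poses


_TWO_START_TILT_CACHE: dict[tuple, tuple[float, float]] = {}


def _mean_alpha(poses: Sequence[NucleosomePose]) -> float:
    a = np.deg2rad([signed_dihedral(poses[i], poses[i + 1]) for i in range(len(poses) - 1)])
    return float(np.degrees(np.angle(np.mean(np.exp(1j * a)))) % 360.0)


def build_two_start_fiber(
    n: int,
    rise: float = 6.0,
    alpha: float = 80.0,
    lateral_sep: float = 10.0,
    tilt_sd: float = 0.0,
    seed: int | None = None,
    linker_bp: int = 30,
    fiber_id: int | str = 0,
    min_sep: float = 3.0,
) -> Fiber:
    """Two-start helical fiber: N and N+2 stacked face-to-face at ``rise``.

    Nucleosomes alternate between two coaxial stacks whose axes are tilted
    symmetrically away from the fiber axis; the tilt is solved so that the
    mean adjacent-plane dihedral of the built fiber equals ``alpha``.
    Within each stack the discs share a normal, so D = ``rise`` and
    para = 0 exactly for every (N, N+2) pair.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= alpha < 360.0:
        raise ValueError("alpha must lie in [0, 360)")
    if tilt_sd > 0 and seed is None:
        raise ValueError("seed is mandatory for noisy builds")

    folded_target = alpha if alpha <= 180.0 else 360.0 - alpha

    def built(theta: float, sign: float):
        return _two_start_poses(n, rise, theta, sign, lateral_sep)

    def measure(theta: float, sign: float) -> float:
        m = _mean_alpha(built(theta, sign))
        return m if m <= 180.0 else 360.0 - m

    cache_key = (n, rise, alpha, lateral_sep)
    if cache_key in _TWO_START_TILT_CACHE:
        theta, sign = _TWO_START_TILT_CACHE[cache_key]
        poses = built(theta, sign)
    else:
        # the sign of the tilt selects the [0,180] vs (180,360) branch
        for sign in (1.0, -1.0):
            lo, hi = 1e-9, 89.999
            f_lo = measure(lo, sign) - folded_target
            f_hi = measure(hi, sign) - folded_target
            branch_hits = False
            if abs(folded_target) < 1e-9:
                theta = 0.0
                branch_hits = True
            elif f_lo * f_hi <= 0:
                theta = brentq(lambda t: measure(t, sign) - folded_target, lo, hi,
                               xtol=1e-12)
                branch_hits = True
            if branch_hits:
                poses = built(theta, sign)
                m = _mean_alpha(poses)
                if abs(((m - alpha) + 180.0) % 360.0 - 180.0) < 1e-6:
                    _TWO_START_TILT_CACHE[cache_key] = (theta, sign)
                    break
        else:
            raise ValueError(
                f"could not realise mean alpha = {alpha} deg in two_start mode"
            )

    if tilt_sd > 0:
        rng = np.random.default_rng(seed)
        poses = _apply_tilt_noise(poses, tilt_sd, rng)
    centers = np.array([p.center for p in poses])
    _check_sterics(centers, min_sep, skip_adjacent=False)
    meta = {
        "mode": "two_start",
        "rise_nm": rise,
        "alpha_deg": alpha,
        "lateral_sep_nm": lateral_sep,
        "tilt_sd_deg": tilt_sd,
        "seed": seed,
        "para_convention": "folded",
    }
    return Fiber(nucleosomes=poses, linker_bp=linker_bp, fiber_id=fiber_id, meta=meta)


def _apply_tilt_noise(poses, tilt_sd, rng):
    out = []
    for p in poses:
        angle = rng.normal(0.0, tilt_sd)
        # random axis perpendicular to the normal
        raw = rng.normal(size=3)
        axis = raw - np.dot(raw, p.normal) * p.normal
        if np.linalg.norm(axis) < 1e-12:
            axis = p.dyad
        rot = _rodrigues(axis, angle)
        out.append(
            NucleosomePose(center=p.center, normal=rot @ p.normal, dyad=rot @ p.dyad, id=p.id)
        )
    return out


def _zigzag_step(center, normal, dyad, u, d_adj, alpha, para, psi_hint=None,
                 clamp_para=False):
    """Place the next pose given the current pose and step direction u.

    The normal advances by rotation of ``alpha`` about u (so the signed
    dihedral recovers ``alpha`` exactly); the next step direction is u
    rotated about the *new* normal by an angle psi solved so that the
    N <-> N+2 folded plane angle equals ``para``.
    """
    new_center = center + d_adj * u
    rot = _rodrigues(u, alpha)
    new_normal = rot @ normal
    new_dyad = rot @ dyad

    def para_of(psi: float) -> float:
        u2 = _rodrigues(new_normal, psi) @ u
        n2 = _rodrigues(u2, alpha) @ new_normal
        c = abs(float(np.clip(np.dot(normal, n2), -1.0, 1.0)))
        return float(np.degrees(np.arccos(c)))

    psi = _solve_turn_angle(para_of, para, psi_hint, clamp=clamp_para)
    new_u = _rodrigues(new_normal, psi) @ u
    return new_center, new_normal, new_dyad, new_u, psi


def _solve_turn_angle(para_of, target, psi_hint=None, n_grid=73, clamp=False):
    grid = np.linspace(0.0, 360.0, n_grid)
    vals = np.array([para_of(p) for p in grid])
    err = vals - target
    if np.all(np.abs(err) < 1e-9):
        return 0.0
    # bracket a sign change, preferring one near the previous solution
    brackets = [
        (grid[i], grid[i + 1]) for i in range(n_grid - 1) if err[i] * err[i + 1] <= 0
    ]
    if not brackets:
        if clamp:
            # noisy builds: realise the nearest achievable plane angle
            return float(grid[int(np.argmin(np.abs(err)))])
        lo, hi = float(vals.min()), float(vals.max())
        raise ValueError(
            f"target para = {target} deg unreachable for this alpha "
            f"(achievable range [{lo:.1f}, {hi:.1f}] deg)"
        )
    if psi_hint is not None:
        brackets.sort(key=lambda b: abs(0.5 * (b[0] + b[1]) - psi_hint))
    a, b = brackets[0]
    if para_of(a) == target:
        return a
    return brentq(lambda p: para_of(p) - target, a, b, xtol=1e-12)


def build_zigzag_fiber(
    n: int,
    d_adj: float = 10.0,
    alpha: float = 230.0,
    para: float = 45.0,
    alpha_sd: float = 0.0,
    d_adj_sd: float = 0.0,
    para_sd: float = 0.0,
    seed: int | None = None,
    linker_bp: int = 25,
    fiber_id: int | str = 0,
    min_sep: float = 3.0,
) -> Fiber:
    """Open zig-zag fiber generated from per-step (d_adj, alpha, para).

    Noise, when requested, is wrapped-normal on alpha and truncated normal
    on d_adj and para; the noiseless build recovers the configured
    parameters exactly under :func:`fiber_step_table`.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    noisy = alpha_sd > 0 or d_adj_sd > 0 or para_sd > 0
    if noisy and seed is None:
        raise ValueError("seed is mandatory for noisy builds")
    rng = np.random.default_rng(seed) if noisy else None

    center = np.zeros(3)
    normal = np.array([0.0, 0.0, 1.0])
    dyad = np.array([1.0, 0.0, 0.0])
    u = np.array([1.0, 0.0, 0.0])  # step direction, kept perpendicular to normal
    poses = [NucleosomePose(center=center, normal=normal, dyad=dyad, id=0)]
    psi = None
    for i in range(1, n):
        a_i, d_i, p_i = alpha, d_adj, para
        if noisy:
            a_i = float(rng.normal(alpha, alpha_sd) % 360.0)
            d_i = max(float(rng.normal(d_adj, d_adj_sd)), 0.1 * d_adj)
            p_i = float(np.clip(rng.normal(para, para_sd), 0.0, 90.0))
        center, normal, dyad, u, psi = _zigzag_step(
            center, normal, dyad, u, d_i, a_i, p_i, psi_hint=psi,
            clamp_para=noisy,
        )
        poses.append(NucleosomePose(center=center, normal=normal, dyad=dyad, id=i))
    centers = np.array([p.center for p in poses])
    _check_sterics(centers, min_sep, skip_adjacent=True)
    meta = {
        "mode": "zigzag",
        "d_adj_nm": d_adj,
        "alpha_deg": alpha,
        "para_deg": para,
        "alpha_sd_deg": alpha_sd,
        "seed": seed,
        "para_convention": "folded",
    }
    return Fiber(nucleosomes=poses, linker_bp=linker_bp, fiber_id=fiber_id, meta=meta)


def build_ideal_fiber(
    mode: str, n: int, params: dict | None = None, seed: int | None = None, **kwargs
) -> Fiber:
    """Build an idealised fiber; ``mode`` is ``two_start`` or ``zigzag``.

    ``params``/keyword arguments are forwarded to
    :func:`build_two_start_fiber` or :func:`build_zigzag_fiber`.
    """
    opts = dict(params or {})
    opts.update(kwargs)
    if mode == "two_start":
        return build_two_start_fiber(n, seed=seed, **opts)
    if mode == "zigzag":
        return build_zigzag_fiber(n, seed=seed, **opts)
    raise ValueError(f"unknown fiber mode: {mode!r}")
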