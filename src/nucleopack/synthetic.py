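"""Synthetic data with known ground truth for every pipeline stage.

These generators stand in for tomographic pose tables, coarse-grained
simulation frames and microscopy trajectories.  They are statistical
stand-ins, not molecular-dynamics ensembles: each output carries its
construction parameters (the ground truth) in a ``meta`` dictionary, and
every stochastic mode is reproducible from (config, seed).

Fiber kinds
-----------
``bp25_like``
    Heterogeneous zig-zag fibers: successive nucleosome planes phased by
    a large adjacent dihedral (alpha ~ 230 deg in the open, low-salt
    regime, ~200 deg compacted) with wrapped-normal disorder; N and N+2
    face away from each other, so there is no face-to-face stacking.
``bp30_like``
    Two-start helical fibers: N and N+2 stacked face-to-face at a
    6-nm disc-height rise, alpha ~ 50 deg open / ~80 deg compacted, with
    small tilt disorder.  The two kinds differ in mean alpha by nearly
    180 deg, reflecting the ~10 bp/turn phasing of the linker DNA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import (
    DISC_HEIGHT_NM,
    DISC_RADIUS_NM,
    Fiber,
    NucleosomePose,
    build_two_start_fiber,
    build_zigzag_fiber,
)
from .masks import BoxMask
from .packing import CondensateModel
from .rheology import KB, BeadTrajectory
from .spt import Trajectory
from .tails import CGFrame, count_contacts

__all__ = [
    "FIBER_DEFAULTS",
    "gen_fiber",
    "gen_condensate",
    "gen_cg_frames",
    "gen_trapped_bead",
    "gen_spt",
]

#: regime-dependent construction defaults for the two fiber kinds; the
#: alpha and para targets encode the measured fiber geometry, the noise
#: scales are package choices reproducing the heterogeneous (zig-zag)
#: versus stereotyped (two-start) contrast
FIBER_DEFAULTS: dict[tuple[str, str], dict] = {
    ("bp25_like", "low"): {"alpha": 230.0, "para": 45.0, "d_adj": 10.0, "alpha_sd": 25.0},
    ("bp25_like", "high"): {"alpha": 200.0, "para": 30.0, "d_adj": 9.0, "alpha_sd": 25.0},
    ("bp30_like", "low"): {"alpha": 50.0, "rise": 6.0, "lateral_sep": 10.0, "tilt_sd": 8.0},
    ("bp30_like", "high"): {"alpha": 80.0, "rise": 6.0, "lateral_sep": 10.0, "tilt_sd": 8.0},
}


def gen_fiber(
    kind: str,
    n: int = 12,
    salt_regime: str = "low",
    seed: int | None = None,
    **overrides,
) -> Fiber:
    """Generate one synthetic nucleosome fiber of the requested kind."""
    if (kind, salt_regime) not in FIBER_DEFAULTS:
        raise ValueError(
            f"unknown kind/regime: {kind!r}/{salt_regime!r}; valid: "
            f"{sorted(set(k for k, _ in FIBER_DEFAULTS))} x ['low', 'high']"
        )
    if n < 3:
        raise ValueError("fibers need at least 3 nucleosomes")
    params = dict(FIBER_DEFAULTS[(kind, salt_regime)])
    params.update(overrides)
    if kind == "bp25_like":
        fiber = build_zigzag_fiber(n, seed=seed, linker_bp=25, **params)
    else:
        fiber = build_two_start_fiber(n, seed=seed, linker_bp=30, **params)
    fiber.meta.update({"kind": kind, "salt_regime": salt_regime, "n": n})
    return fiber


# ---------------------------------------------------------------------------
# condensates
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def gen_condensate(
    fiber_kind: str = "bp30_like",
    n_fibers: int | None = None,
    target_density: float = 6.0e5,
    box_nm: float | None = None,
    seed: int = 0,
    salt_regime: str = "high",
    n_per_fiber: int = 12,
    max_sweeps: int = 500,
    hard_min_sep: float = 4.5,
    push_cutoff: float = 5.5,
    **fiber_overrides,
) -> CondensateModel:
    """Pack synthetic fibers into a cubic condensate at a target density.

    Fibers are placed with random orientation on a jittered cubic
    lattice, then relaxed by pairwise push-apart sweeps acting on whole
    fibers until no inter-fiber nucleosome pair is closer than
    ``hard_min_sep`` nm (centre-centre).  Exactly one of ``n_fibers`` and
    ``box_nm`` may be left unset; the other is derived from the target
    density.  Array assignments, sequence positions and a box mask are
    attached; fiber construction parameters are recorded as ground truth.
    """
    if target_density <= 0:
        raise ValueError("target density must be positive")
    if n_fibers is None and box_nm is None:
        raise ValueError("give either n_fibers or box_nm")
    if box_nm is None:
        volume_nm3 = n_fibers * n_per_fiber / target_density * 1e9
        box_nm = volume_nm3 ** (1.0 / 3.0)
    if n_fibers is None:
        n_fibers = max(int(round(target_density * box_nm**3 * 1e-9 / n_per_fiber)), 1)
    n_poses = n_fibers * n_per_fiber
    disc_volume = math.pi * DISC_RADIUS_NM**2 * DISC_HEIGHT_NM
    vol_frac = n_poses * disc_volume / box_nm**3
    if vol_frac > 0.45:
        raise ValueError(
            f"implied volume fraction {vol_frac:.2f} exceeds the packable limit (0.45)"
        )

    ss = np.random.SeedSequence(seed)
    fiber_seeds = ss.spawn(n_fibers)
    rng = np.random.default_rng(ss.spawn(1)[0])

    fibers = []
    for k in range(n_fibers):
        child = int(fiber_seeds[k].generate_state(1)[0] % (2**31))
        fibers.append(
            gen_fiber(fiber_kind, n=n_per_fiber, salt_regime=salt_regime,
                      seed=child, fiber_id=k, **fiber_overrides)
        )

    # jittered lattice of fiber centroids
    m_side = int(np.ceil(n_fibers ** (1.0 / 3.0)))
    cell = box_nm / m_side
    sites = np.array(
        [(i, j, k) for i in range(m_side) for j in range(m_side) for k in range(m_side)],
        dtype=float,
    )
    order = rng.permutation(len(sites))[:n_fibers]
    centroids = (sites[order] + 0.5) * cell + rng.uniform(-cell / 4, cell / 4,
                                                          size=(n_fibers, 3))

    centers = np.empty((n_poses, 3))
    fiber_idx = np.empty(n_poses, dtype=int)
    rotations = []
    offsets = np.empty((n_fibers, 3))
    margins = np.empty(n_fibers)
    for k, fiber in enumerate(fibers):
        rot = _random_rotation(rng)
        local = fiber.centers
        local = (local - local.mean(axis=0)) @ rot.T
        # keep nucleosomes inside the box by clamping the centroid with the
        # fiber's own maximal reach; in boxes small relative to the fiber
        # this would over-crowd the centre, so the margin is capped (a few
        # poses may then protrude, which only matters for density work in
        # large boxes where the cap is inactive)
        reach = float(np.linalg.norm(local, axis=1).max()) + 1.0
        margins[k] = min(reach, 0.15 * box_nm)
        centroids[k] = np.clip(centroids[k], margins[k], box_nm - margins[k])
        sl = slice(k * n_per_fiber, (k + 1) * n_per_fiber)
        centers[sl] = local + centroids[k]
        fiber_idx[sl] = k
        rotations.append(rot)
        offsets[k] = centroids[k]

    # push-apart relaxation of whole fibers
    converged = False
    for sweep in range(max_sweeps):
        tree = cKDTree(centers)
        pairs = tree.query_pairs(push_cutoff, output_type="ndarray")
        if len(pairs):
            inter = fiber_idx[pairs[:, 0]] != fiber_idx[pairs[:, 1]]
            pairs = pairs[inter]
        if len(pairs) == 0:
            converged = True
            break
        d = centers[pairs[:, 0]] - centers[pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        deep = dist < hard_min_sep
        if sweep > 0 and not deep.any():
            converged = True
            break
        push = (push_cutoff - dist) / np.maximum(dist, 1e-6)
        vec = 0.5 * d * push[:, None]
        disp = np.zeros((n_fibers, 3))
        np.add.at(disp, fiber_idx[pairs[:, 0]], vec)
        np.add.at(disp, fiber_idx[pairs[:, 1]], -vec)
        disp *= 0.7
        if sweep > max_sweeps // 2 and deep.any():
            # jiggle fibers locked in persistent deep overlaps
            stuck = np.unique(fiber_idx[pairs[deep].ravel()])
            disp[stuck] += rng.normal(0.0, 0.8, size=(len(stuck), 3))
        new_offsets = np.clip(offsets + disp, margins[:, None],
                              box_nm - margins[:, None])
        shift = new_offsets - offsets
        centers += shift[fiber_idx]
        offsets = new_offsets
    if not converged:
        tree = cKDTree(centers)
        pairs = tree.query_pairs(hard_min_sep, output_type="ndarray")
        n_deep = int((fiber_idx[pairs[:, 0]] != fiber_idx[pairs[:, 1]]).sum()) if len(pairs) else 0
        if n_deep:
            inside = np.all((centers >= 0) & (centers <= box_nm), axis=1).sum()
            achieved = inside / (box_nm**3 * 1e-9)
            raise RuntimeError(
                f"overlap relaxation failed: {n_deep} deep inter-fiber overlaps "
                f"remain after {max_sweeps} sweeps (achieved density "
                f"{achieved:.3g}/um^3)"
            )

    poses = []
    array_of: dict[int, int] = {}
    seq_of: dict[int, int] = {}
    pid = 0
    for k, fiber in enumerate(fibers):
        local = fiber.centers
        local = (local - local.mean(axis=0)) @ rotations[k].T
        for j, p in enumerate(fiber.nucleosomes):
            poses.append(
                NucleosomePose(
                    center=local[j] + offsets[k],
                    normal=rotations[k] @ p.normal,
                    dyad=rotations[k] @ p.dyad,
                    id=pid,
                )
            )
            array_of[pid] = k
            seq_of[pid] = j
            pid += 1

    mask = BoxMask(lo=np.zeros(3), hi=np.full(3, box_nm))
    meta = {
        "kind": "condensate",
        "fiber_kind": fiber_kind,
        "salt_regime": salt_regime,
        "n_fibers": n_fibers,
        "n_per_fiber": n_per_fiber,
        "box_nm": box_nm,
        "target_density_per_um3": target_density,
        "volume_fraction": vol_frac,
        "seed": seed,
        "fiber_meta": fibers[0].meta,
    }
    return CondensateModel(
        poses=poses, array_of=array_of, seq_of=seq_of, mask=mask,
        density_target=target_density, meta=meta,
    )


# ---------------------------------------------------------------------------
# coarse-grained frames
# ---------------------------------------------------------------------------

#: residues per histone tail in the one-bead-per-residue template
TAIL_LENGTHS = {"tail-H3": 38, "tail-H4": 25, "tail-H2A(N)": 15, "tail-H2B": 23}
_CG_STEP_A = 3.8  # bead-bead step, Angstrom


def _nucleosome_template(rng: np.random.Generator) -> dict:
    """Rigid bead template in the local disc frame (Angstrom).

    DNA beads follow a 1.65-turn superhelix (radius 41.9 A, pitch
    25.9 A); core beads sit on an inner cylinder.  Tail anchor points:
    H3 near the DNA entry/exit, H4 on the disc faces (where the H4 basic
    patch meets a stacked neighbour), H2A(N)/H2B on the wall.
    """
    n_dna = 147
    t = np.linspace(-0.825, 0.825, n_dna) * 2 * np.pi
    dna = np.column_stack(
        [41.9 * np.cos(t), 41.9 * np.sin(t), 25.9 * t / (2 * np.pi)]
    )
    n_core = 64
    phi = rng.uniform(0, 2 * np.pi, n_core)
    core = np.column_stack(
        [
            25.0 * np.cos(phi),
            25.0 * np.sin(phi),
            rng.uniform(-20.0, 20.0, n_core),
        ]
    )
    anchors = {
        "tail-H3": [dna[0] * 0.8, dna[-1] * 0.8],
        "tail-H4": [np.array([20.0, 0.0, 28.0]), np.array([-20.0, 0.0, -28.0])],
        "tail-H2A(N)": [np.array([0.0, 28.0, 10.0]), np.array([0.0, -28.0, -10.0])],
        "tail-H2B": [np.array([28.0, 10.0, 0.0]), np.array([-28.0, -10.0, 0.0])],
    }
    return {"dna": dna, "core": core, "anchors": anchors}


def _grow_tail(
    anchor: np.ndarray,
    length: int,
    rng: np.random.Generator,
    target: np.ndarray | None,
    bias: float,
    max_retries: int = 20,
) -> np.ndarray:
    """Anchored self-avoiding walk with optional drift toward a target.

    The walk always returns exactly ``length`` beads: a step that stays
    self-trapped after ``max_retries`` attempts is accepted anyway (with
    a warning), so the chain topology is identical across frames.
    """
    beads = [anchor]
    trapped = False
    for _step in range(length - 1):
        cand = None
        for _try in range(max_retries):
            step = rng.normal(size=3)
            if target is not None and bias > 0:
                to_target = target - beads[-1]
                nt = np.linalg.norm(to_target)
                if nt > 1e-9:
                    step = (1 - bias) * step / np.linalg.norm(step) + bias * to_target / nt
            step = step / np.linalg.norm(step) * _CG_STEP_A
            cand = beads[-1] + step
            if all(np.linalg.norm(cand - b) > 2.0 for b in beads[:-1]):
                break
        else:
            trapped = True
        beads.append(cand)
    if trapped:
        warnings.warn("tail walk self-trapped; accepted an overlapping step",
                      stacklevel=2)
    return np.array(beads)


def gen_cg_frames(
    layout: str | list[tuple[NucleosomePose, int]] = "dinucleosome_face",
    n_frames: int = 5,
    seed: int = 0,
    tail_bias: str = "partner_face",
    bias_strength: float = 0.6,
) -> list[CGFrame]:
    """Coarse-grained bead frames with constructed tail contacts.

    ``layout`` is either the preset ``"dinucleosome_face"`` (two
    nucleosomes of different arrays stacked face-to-face) or an explicit
    list of (pose, array_id) pairs.  ``tail_bias`` steers the H4 tails:
    ``"partner_face"`` sends them toward the nearest neighbouring
    nucleosome's face (inter-nucleosome bridging, as in stacked
    chromatin), ``"own_dna"`` folds every tail back onto its own DNA
    gyres (the low-salt, intra-nucleosome regime).  Rigid DNA/core beads
    are identical across frames; tails are resampled per frame.  Each
    frame's realised contacts are recorded in ``meta["truth"]``.
    """
    if tail_bias not in ("partner_face", "own_dna", "none"):
        raise ValueError("tail_bias must be partner_face, own_dna or none")
    if isinstance(layout, str):
        if layout != "dinucleosome_face":
            raise ValueError(f"unknown layout preset: {layout!r}")
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        poses = [
            (NucleosomePose(center=np.zeros(3), normal=z, dyad=x, id=0), 0),
            (NucleosomePose(center=np.array([0.0, 0.0, 7.0]), normal=z, dyad=x, id=1), 1),
        ]
    else:
        poses = list(layout)

    rng = np.random.default_rng(seed)
    template = _nucleosome_template(rng)
    frames: list[CGFrame] = []
    centers_a = np.array([p.center * 10.0 for p, _ in poses])  # nm -> A
    for fi in range(n_frames):
        rows = []
        for (pose, array_id) in poses:
            R = pose.rotation_matrix
            c = pose.center * 10.0
            nid = pose.id

            def world(local):
                return local @ R.T + c

            for name, local, role in (("dna", template["dna"], "DNA"),
                                      ("core", template["core"], "histone-core")):
                w = world(local)
                for ri, xyz in enumerate(w):
                    rows.append((f"n{nid}_{name}", ri, "BEAD", role, nid, array_id, *xyz))
            # neighbour target: closest other nucleosome centre
            others = centers_a[[i for i in range(len(poses)) if poses[i][0].id != nid]]
            if len(others):
                nearest = others[np.argmin(np.linalg.norm(others - c, axis=1))]
            else:
                nearest = None
            for role, anchors in template["anchors"].items():
                for copy_i, anchor_local in enumerate(anchors):
                    anchor = world(anchor_local[None, :])[0]
                    target, bias = None, 0.0
                    if tail_bias == "own_dna":
                        dna_w = world(template["dna"])
                        target = dna_w[np.argmin(np.linalg.norm(dna_w - anchor, axis=1))]
                        bias = bias_strength
                    elif tail_bias == "partner_face" and role == "tail-H4" and nearest is not None:
                        # aim at the partner's nearest face centre
                        target = nearest + (c - nearest) * 0.1
                        bias = bias_strength
                    walk = _grow_tail(anchor, TAIL_LENGTHS[role], rng, target, bias)
                    chain = f"n{nid}_{role}_{copy_i}"
                    for ri, xyz in enumerate(walk):
                        rows.append((chain, ri, "RES", role, nid, array_id, *xyz))
        beads = pd.DataFrame(
            rows,
            columns=["chain_id", "residue_index", "residue_name", "role",
                     "nucleosome_id", "array_id", "x", "y", "z"],
        )
        frame = CGFrame(beads=beads, meta={
            "layout": layout if isinstance(layout, str) else "custom",
            "tail_bias": tail_bias,
            "frame_index": fi,
            "seed": seed,
        })
        truth = count_contacts(frame)
        frame.meta["truth"] = {
            "n_contacts": int(len(truth)),
            "by_scope": truth["scope"].value_counts().to_dict() if len(truth) else {},
        }
        frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# trapped-bead trajectories
# ---------------------------------------------------------------------------


def gen_trapped_bead(
    material: str = "newtonian",
    eta: float = 1.0,
    G0: float | None = None,
    lam: float | None = None,
    kappa: float = 1.0e-5,
    a_um: float = 0.5,
    T: float = 298.0,
    dt: float = 1.0e-3,
    n: int = 200_000,
    seed: int = 0,
    n_axes: int = 2,
    eta_solvent: float | None = None,
) -> BeadTrajectory:
    """Overdamped trapped-bead trajectory in a model viscoelastic medium.

    ``newtonian`` (viscosity ``eta``) and ``kelvin_voigt`` (spring ``G0``
    plus dashpot ``eta``) reduce to an Ornstein-Uhlenbeck process and use
    its exact discretisation; ``maxwell`` (modulus ``G0``, relaxation
    time ``lam``, plus a small solvent viscosity for regularity) is a
    two-variable linear Langevin system integrated with the exact
    matrix-exponential update.  Fluctuation-dissipation holds exactly in
    all cases.
    """
    rng = np.random.default_rng(seed)
    a_m = a_um * 1e-6
    kbt = KB * T
    if material == "newtonian":
        gamma = 6.0 * np.pi * eta * a_m
        k_tot = kappa
        truth: dict = {"material": "newtonian", "eta": eta}
    elif material == "kelvin_voigt":
        if G0 is None:
            raise ValueError("kelvin_voigt requires G0")
        gamma = 6.0 * np.pi * eta * a_m
        k_tot = kappa + 6.0 * np.pi * a_m * G0
        truth = {"material": "kelvin_voigt", "eta": eta, "G0": G0}
    elif material == "maxwell":
        if G0 is None or lam is None:
            raise ValueError("maxwell requires G0 and lam")
        if eta_solvent is None:
            # small regulariser: keeps the bead mobile at high frequency
            # while shifting the G'/G'' crossover by only a few percent
            eta_solvent = G0 * lam / 100.0
        k_m = 6.0 * np.pi * a_m * G0
        gamma_m = k_m * lam
        gamma_s = 6.0 * np.pi * a_m * eta_solvent
        if dt * (kappa + k_m) / gamma_s >= 0.1:
            # exact update is unconditionally stable, but a coarse step
            # under-resolves the fast solvent mode
            warnings.warn("dt is coarse relative to the solvent relaxation",
                          stacklevel=2)
        A = np.array(
            [
                [-(kappa + k_m) / gamma_s, k_m / gamma_s],
                [k_m / gamma_m, -k_m / gamma_m],
            ]
        )
        D = np.diag([2.0 * kbt / gamma_s, 2.0 * kbt / gamma_m])
        Sigma = solve_continuous_lyapunov(A, -D)
        Ad = expm(A * dt)
        Q = Sigma - Ad @ Sigma @ Ad.T
        Lq = np.linalg.cholesky(Q + 1e-30 * np.eye(2))
        Ls = np.linalg.cholesky(Sigma + 1e-30 * np.eye(2))
        pos = np.empty((n, n_axes))
        for ax in range(n_axes):
            state = Ls @ rng.standard_normal(2)
            noise = rng.standard_normal((n, 2))
            xs = np.empty(n)
            for i in range(n):
                xs[i] = state[0]
                state = Ad @ state + Lq @ noise[i]
            pos[:, ax] = xs * 1e9
        times = np.arange(n) * dt
        return BeadTrajectory(
            times=times, positions=pos, bead_radius_um=a_um, temperature_K=T,
            trap_stiffness_N_per_m=kappa,
            meta={"material": "maxwell", "G0": G0, "lam": lam,
                  "eta_solvent": eta_solvent, "kappa": kappa, "seed": seed},
        )
    else:
        raise ValueError(f"unknown material: {material!r}")

    # exact OU discretisation for the one-variable materials
    tau = gamma / k_tot
    if dt * kappa / gamma >= 0.1:
        raise ValueError(
            "unstable parameters: dt * kappa / gamma must stay below 0.1"
        )
    phi = np.exp(-dt / tau)
    sigma_eq = np.sqrt(kbt / k_tot)
    sigma_step = sigma_eq * np.sqrt(1.0 - phi * phi)
    pos = np.empty((n, n_axes))
    for ax in range(n_axes):
        noise = rng.standard_normal(n)
        xs = np.empty(n)
        x = sigma_eq * rng.standard_normal()
        for i in range(n):
            xs[i] = x
            x = phi * x + sigma_step * noise[i]
        pos[:, ax] = xs * 1e9
    truth.update({"kappa": kappa, "tau_c": tau, "seed": seed})
    times = np.arange(n) * dt
    return BeadTrajectory(
        times=times, positions=pos, bead_radius_um=a_um, temperature_K=T,
        trap_stiffness_N_per_m=kappa, meta=truth,
    )


# ---------------------------------------------------------------------------
# single-particle tracking
# ---------------------------------------------------------------------------


def gen_spt(
    D: float,
    model: str = "free",
    R: float | None = None,
    dt: float = 0.02,
    n_tracks: int = 2000,
    steps: int = 20,
    localization_sd: float = 0.0,
    seed: int = 0,
) -> list[Trajectory]:
    """Simulated 2-D single-molecule tracks (positions in um).

    ``free``: Gaussian steps of variance 2 D dt per axis.  ``confined``:
    the same steps reflected at a circular boundary of radius ``R``
    centred at the track origin.  Localisation noise is added i.i.d. to
    every localisation after the dynamics.
    """
    if D < 0 or dt <= 0:
        raise ValueError("D and dt must be positive")
    if model not in ("free", "confined"):
        raise ValueError("model must be 'free' or 'confined'")
    if model == "confined":
        if R is None or R <= 0:
            raise ValueError("confined model requires a positive radius R")
        if R < np.sqrt(2 * D * dt) / 10.0:
            warnings.warn("confinement radius far below the step scale",
                          stacklevel=2)
    rng = np.random.default_rng(seed)
    sd_step = np.sqrt(2.0 * D * dt)
    tracks = []
    for tid in range(n_tracks):
        increments = rng.normal(0.0, sd_step, size=(steps, 2))
        if model == "free":
            pos = np.vstack([np.zeros(2), np.cumsum(increments, axis=0)])
        else:
            pos = np.empty((steps + 1, 2))
            p = np.zeros(2)
            pos[0] = p
            for s in range(steps):
                p = p + increments[s]
                r = np.linalg.norm(p)
                while r > R:  # radial reflection at the boundary
                    p = p * (2.0 * R - r) / r
                    r = abs(2.0 * R - r)
                pos[s + 1] = p
        if localization_sd > 0:
            pos = pos + rng.normal(0.0, localization_sd, size=pos.shape)
        tracks.append(
            Trajectory(
                track_id=tid,
                frames=np.arange(steps + 1),
                dt=dt,
                positions=pos,
                localization_sd=localization_sd or None,
                meta={"model": model, "D_true": D, "R": R, "seed": seed},
            )
        )
    return tracks
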