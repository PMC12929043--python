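"""Single-particle tracking statistics: diffusion coefficients from MSD
fits, jump-angle distributions and the asymmetry coefficient.

The diffusion coefficient comes from a weighted linear fit of the
ensemble-averaged time-averaged MSD over the first few lags,
MSD(n dt) = 4 D n dt + b, where the intercept absorbs localisation
error (b = 4 sigma_loc^2).  The jump angle is the angle between two
consecutive displacements (0 deg = directed, 180 deg = back-and-forth);
the asymmetry coefficient AC = log2(f_fwd / f_bwd) compares the fraction
of forward angles (<= 30 deg) with backward ones (>= 150 deg), negative
values indicating confined, back-stepping motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "diffusion_coefficient",
    "jump_angles",
    "jump_angles_ensemble",
    "asymmetry_coefficient",
    "split_at_gaps",
    "tracks_from_table",
    "link_localizations",
]


@dataclass
class Trajectory:
    """One tracked molecule: frame indices and positions in micrometres."""

    track_id: int | str
    frames: np.ndarray  # strictly increasing integers
    dt: float  # s, frame interval
    positions: np.ndarray  # (n, 2) or (n, 3), um
    localization_sd: float | None = None  # um
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=int)
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[0] != len(frames):
            raise ValueError("positions and frames have different lengths")
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if pos.shape[1] not in (2, 3):
            raise ValueError("positions must be 2-D or 3-D")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.frames = frames
        self.positions = pos

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return bool(len(self.frames) > 1 and np.any(np.diff(self.frames) != 1))


def split_at_gaps(traj: Trajectory) -> list[Trajectory]:
    """Split a trajectory into contiguous segments at frame gaps."""
    if not traj.has_gaps:
        return [traj]
    cut = np.flatnonzero(np.diff(traj.frames) != 1) + 1
    segments = []
    for part, (fr, pos) in enumerate(
        zip(np.split(traj.frames, cut), np.split(traj.positions, cut))
    ):
        if len(fr) < 2:
            continue
        segments.append(
            Trajectory(
                track_id=f"{traj.track_id}.{part}",
                frames=fr,
                dt=traj.dt,
                positions=pos,
                localization_sd=traj.localization_sd,
            )
        )
    return segments


def tracks_from_table(
    df: pd.DataFrame, dt: float | None = None
) -> list[Trajectory]:
    """Build trajectories from a tidy track table.

    Expected columns: track_id, frame, x_um, y_um and optionally z_um and
    t_s (used to infer dt when not given).
    """
    if dt is None:
        if "t_s" not in df.columns:
            raise ValueError("dt not given and no t_s column to infer it from")
        ts = np.sort(df["t_s"].unique())
        dt = float(np.min(np.diff(ts)))
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    out = []
    for tid, sub in df.sort_values("frame").groupby("track_id"):
        out.append(
            Trajectory(
                track_id=tid,
                frames=sub["frame"].to_numpy(int),
                dt=dt,
                positions=sub[cols].to_numpy(float),
            )
        )
    return out


def link_localizations(
    df: pd.DataFrame, dt: float, max_displacement: float
) -> list[Trajectory]:
    """Naive nearest-neighbour frame-to-frame linker (convenience only).

    Greedily links each localisation to the nearest one in the next
    frame within ``max_displacement`` (um).  This plumbing is not a
    validated tracker — it ignores merge/split events, blinking and
    competition between close molecules; use dedicated tracking software
    for real movies.  Expected columns: frame, x_um, y_um.
    """
    frames = sorted(df["frame"].unique())
    active: list[list] = []  # each: [frames, positions]
    prev_frame = None
    prev_pts = None
    prev_tracks: list[int] = []
    for fr in frames:
        pts = df.loc[df["frame"] == fr, ["x_um", "y_um"]].to_numpy(float)
        assigned = np.full(len(pts), -1)
        if prev_pts is not None and fr == prev_frame + 1 and len(prev_pts):
            order = []
            for i, p in enumerate(prev_pts):
                d = np.linalg.norm(pts - p, axis=1) if len(pts) else np.array([])
                if len(d) and d.min() <= max_displacement:
                    order.append((float(d.min()), i, int(np.argmin(d))))
            for _, i, j in sorted(order):
                if assigned[j] == -1:
                    assigned[j] = prev_tracks[i]
        new_tracks = []
        for j, p in enumerate(pts):
            if assigned[j] >= 0:
                t = int(assigned[j])
                active[t][0].append(fr)
                active[t][1].append(p)
            else:
                active.append([[fr], [p]])
                t = len(active) - 1
            new_tracks.append(t if assigned[j] >= 0 else len(active) - 1)
        prev_frame, prev_pts, prev_tracks = fr, pts, new_tracks
    out = []
    for tid, (frs, pos) in enumerate(active):
        if len(frs) >= 2:
            out.append(Trajectory(track_id=tid, frames=np.array(frs), dt=dt,
                                  positions=np.array(pos)))
    return out


def _track_msd(pos: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-track time-averaged MSD and pair counts for lags 1..n_lags."""
    n = len(pos)
    msd = np.full(n_lags, np.nan)
    counts = np.zeros(n_lags, dtype=int)
    for k in range(1, min(n_lags, n - 1) + 1):
        d = pos[k:] - pos[:-k]
        msd[k - 1] = float(np.mean(np.sum(d * d, axis=1)))
        counts[k - 1] = n - k
    return msd, counts


def diffusion_coefficient(
    trajs: Sequence[Trajectory],
    fit_points: int = 3,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
    min_length: int = 5,
) -> dict:
    """Ensemble diffusion coefficient (um^2/s) with bootstrap CI.

    Short lags (default 1..3) minimise confinement and localisation
    bias; the weighted fit MSD(n dt) = 4 D n dt + b uses displacement
    pair counts as weights, and the 95% CI comes from resampling whole
    trajectories.  Tracks with frame gaps are split at the gaps; tracks
    shorter than ``min_length`` points are dropped.
    """
    if not 2 <= fit_points <= 5:
        raise ValueError("fit_points must lie in [2, 5]")
    segments: list[Trajectory] = []
    n_split = 0
    for tr in trajs:
        parts = split_at_gaps(tr)
        n_split += len(parts) - 1
        segments.extend(p for p in parts if len(p) >= min_length)
    if n_split:
        warnings.warn(f"split {n_split} trajectories at frame gaps", stacklevel=2)
    if not segments:
        raise ValueError(f"no trajectories of length >= {min_length}")
    dt = segments[0].dt
    if any(abs(s.dt - dt) > 1e-12 for s in segments):
        raise ValueError("all trajectories must share the same frame interval")

    msds = np.array([_track_msd(s.positions, fit_points)[0] for s in segments])
    counts = np.array([_track_msd(s.positions, fit_points)[1] for s in segments])
    lags = np.arange(1, fit_points + 1) * dt

    def fit(index: np.ndarray) -> tuple[float, float]:
        w = counts[index].sum(axis=0).astype(float)
        m = np.nansum(msds[index] * counts[index], axis=0) / w
        # weighted least squares for m = 4 D tau + b
        W = np.diag(w)
        A = np.column_stack([4.0 * lags, np.ones_like(lags)])
        coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ m)
        return float(coef[0]), float(coef[1])

    all_idx = np.arange(len(segments))
    d_hat, intercept = fit(all_idx)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = fit(rng.choice(all_idx, size=len(all_idx), replace=True))[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "D_um2_per_s": d_hat,
        "ci95": (float(lo), float(hi)),
        "intercept_um2": intercept,
        "n_tracks": len(segments),
        "fit_points": fit_points,
    }


def jump_angles(
    traj: Trajectory, min_step: float = 0.0, return_excluded: bool = False
):
    """Angles (deg, [0, 180]) between consecutive displacement pairs.

    Steps shorter than ``min_step`` (and zero-length steps) are excluded
    from both sides of an angle.
    """
    if len(traj) < 3:
        raise ValueError("jump angles need at least 3 points")
    steps = np.diff(traj.positions, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    angles = []
    excluded = 0
    for i in range(len(steps) - 1):
        if norms[i] <= max(min_step, 0.0) or norms[i + 1] <= max(min_step, 0.0):
            if norms[i] == 0.0 or norms[i + 1] == 0.0 or min_step > 0:
                excluded += 1
                continue
        c = np.dot(steps[i], steps[i + 1]) / (norms[i] * norms[i + 1])
        angles.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    angles = np.array(angles)
    if return_excluded:
        return angles, excluded
    return angles


def jump_angles_ensemble(
    trajs: Sequence[Trajectory], min_step: float = 0.0
) -> np.ndarray:
    """Pooled jump angles over many trajectories (>= 3 points each)."""
    pooled = [jump_angles(t, min_step=min_step) for t in trajs if len(t) >= 3]
    if not pooled:
        raise ValueError("no trajectory long enough for angle analysis")
    return np.concatenate(pooled)


def asymmetry_coefficient(
    angles: np.ndarray, forward_max_deg: float = 30.0, backward_min_deg: float = 150.0
) -> float:
    """AC = log2(fraction of forward / fraction of backward angles).

    Forward angles fall in [0, ``forward_max_deg``], backward in
    [``backward_min_deg``, 180].  Negative values mean backward-biased
    (confined) motion; the result is +/- inf when one window is empty
    (flagged with a warning) and an error when both are.
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) == 0:
        raise ValueError("no angles supplied")
    if len(angles) < 100:
        warnings.warn(
            f"only {len(angles)} angles; AC is noisy below ~100", stacklevel=2
        )
    f_fwd = float(np.mean(angles <= forward_max_deg))
    f_bwd = float(np.mean(angles >= backward_min_deg))
    if f_fwd == 0.0 and f_bwd == 0.0:
        raise ValueError("no angles in either the forward or backward window")
    if f_bwd == 0.0:
        warnings.warn("empty backward window: AC = +inf", stacklevel=2)
        return float("inf")
    if f_fwd == 0.0:
        warnings.warn("empty forward window: AC = -inf", stacklevel=2)
        return float("-inf")
    return float(np.log2(f_fwd / f_bwd))
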