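"""Spatial masks delimiting the condensate region.

A mask answers three questions: which points are inside, what is the
enclosed volume, and how to draw uniform random points from it.  The
radial-distribution reference bath and the number-density estimator both
operate through this interface, so irregular (voxel) masks and simple
boxes are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoxMask", "GridMask"]


@dataclass(frozen=True)
class BoxMask:
    """Axis-aligned box, nm."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lo, dtype=float).reshape(3)
        hi = np.asarray(self.hi, dtype=float).reshape(3)
        if np.any(hi <= lo):
            raise ValueError("box mask must have positive extent on every axis")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.hi - self.lo))

    @property
    def extent_nm(self) -> float:
        """Largest distance between two points of the mask (box diagonal)."""
        return float(np.linalg.norm(self.hi - self.lo))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 3))


@dataclass(frozen=True)
class GridMask:
    """Voxelised mask: boolean occupancy of the condensate region."""

    origin: np.ndarray
    voxel_nm: float
    array: np.ndarray  # 3-D bool

    def __post_init__(self):
        if self.voxel_nm <= 0:
            raise ValueError("voxel size must be positive")
        arr = np.asarray(self.array, dtype=bool)
        if arr.ndim != 3 or not arr.any():
            raise ValueError("grid mask must be a non-empty 3-D boolean array")
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))

    @property
    def volume_nm3(self) -> float:
        return float(self.array.sum()) * self.voxel_nm**3

    @property
    def extent_nm(self) -> float:
        return float(np.linalg.norm(np.array(self.array.shape) * self.voxel_nm))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        idx = np.floor((pts - self.origin) / self.voxel_nm).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(self.array.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.array[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        flat = np.flatnonzero(self.array.ravel())
        pick = rng.choice(flat, size=n, replace=True)
        idx = np.column_stack(np.unravel_index(pick, self.array.shape)).astype(float)
        jitter = rng.uniform(0.0, 1.0, size=(n, 3))
        return self.origin + (idx + jitter) * self.voxel_nm
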