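"""Readers and writers for pose tables, trajectories and grids.

Pose tables travel as CSV (columns ``id, fiber_id, x_nm, y_nm, z_nm,
qw, qx, qy, qz``; scalar-first unit quaternion, disc normal = local +z,
dyad = local +x, right-handed frame, nm units) or as RELION-style STAR
particle files (``rlnCoordinateX/Y/Z`` plus ``rlnAngleRot/Tilt/Psi``,
intrinsic ZYZ Euler angles in degrees).  All coordinates are converted
to nm on read.  Occupancy grids export as CCP4/MRC volumes via gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import NucleosomePose
from .masks import BoxMask
from .packing import CondensateModel

__all__ = [
    "PoseTableDialect",
    "read_poses",
    "write_poses",
    "read_pose_csv",
    "write_pose_csv",
    "read_star_poses",
    "write_star_poses",
    "derive_frame_from_template",
    "read_cg_frame_csv",
    "read_cg_frame_pdb",
    "write_occupancy_mrc",
]


@dataclass(frozen=True)
class PoseTableDialect:
    """How a pose table encodes geometry.

    ``length_unit`` is one of nm / angstrom / pixel (pixel requires
    ``pixel_size_nm``); the angle convention is fixed per format:
    scalar-first quaternions for CSV, ZYZ Euler degrees for STAR.
    """

    format: str = "csv"  # csv | star
    length_unit: str = "nm"  # nm | angstrom | pixel
    pixel_size_nm: float | None = None

    def scale_to_nm(self) -> float:
        if self.length_unit == "nm":
            return 1.0
        if self.length_unit == "angstrom":
            return 0.1
        if self.length_unit == "pixel":
            if self.pixel_size_nm is None:
                raise ValueError("pixel units require pixel_size_nm")
            return float(self.pixel_size_nm)
        raise ValueError(f"unknown length unit: {self.length_unit!r}")


def _poses_to_model(
    centers, rotations, ids, fiber_ids=None, mask_pad: float = 1.0
) -> CondensateModel:
    poses = [
        NucleosomePose(
            center=centers[i], normal=rotations[i][:, 2], dyad=rotations[i][:, 0],
            id=int(ids[i]),
        )
        for i in range(len(ids))
    ]
    array_of = None
    if fiber_ids is not None:
        array_of = {int(ids[i]): fiber_ids[i] for i in range(len(ids))
                    if not pd.isna(fiber_ids[i])}
        if not array_of:
            array_of = None
    lo = centers.min(axis=0) - mask_pad
    hi = centers.max(axis=0) + mask_pad
    return CondensateModel(
        poses=poses, array_of=array_of, mask=BoxMask(lo=lo, hi=hi)
    )


def read_pose_csv(path, dialect: PoseTableDialect | None = None) -> CondensateModel:
    dialect = dialect or PoseTableDialect()
    df = pd.read_csv(path)
    required = ["id", "x_nm", "y_nm", "z_nm", "qw", "qx", "qy", "qz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pose CSV is missing columns: {missing}")
    scale = dialect.scale_to_nm()
    centers = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float) * scale
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy(float)
    norms = np.linalg.norm(quat, axis=1)
    bad = np.abs(norms - 1.0) > 1e-3
    if bad.any():
        raise ValueError(f"non-unit quaternions at rows {np.flatnonzero(bad)[:5]}")
    quat = quat / norms[:, None]
    rots = Rotation.from_quat(quat, scalar_first=True).as_matrix()
    fiber_ids = df["fiber_id"].to_numpy() if "fiber_id" in df.columns else None
    return _poses_to_model(centers, rots, df["id"].to_numpy(), fiber_ids)


def write_pose_csv(m: CondensateModel, path) -> None:
    rows = []
    for p in m.poses:
        q = Rotation.from_matrix(p.rotation_matrix).as_quat(scalar_first=True)
        row = {
            "id": p.id,
            "x_nm": p.center[0], "y_nm": p.center[1], "z_nm": p.center[2],
            "qw": q[0], "qx": q[1], "qy": q[2], "qz": q[3],
        }
        if m.array_of is not None:
            row["fiber_id"] = m.array_of.get(p.id, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_STAR_COORD = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]
_STAR_ANGLE = ["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]
_STAR_ORIGIN = ["rlnOriginX", "rlnOriginY", "rlnOriginZ"]


def read_star_poses(path, dialect: PoseTableDialect | None = None) -> CondensateModel:
    """RELION-style particle STAR file -> pose model.

    Euler angles (rot, tilt, psi) are interpreted as an intrinsic ZYZ
    rotation applied to the reference frame; origin-offset columns, when
    present, are subtracted from the coordinates.
    """
    dialect = dialect or PoseTableDialect(format="star", length_unit="angstrom")
    doc = gemmi.cif.read(str(path))
    block = None
    for b in doc:
        if b.find_loop(f"_{_STAR_COORD[0]}"):
            block = b
            break
    if block is None:
        raise ValueError("no particle loop with rlnCoordinateX found")

    def col(tag):
        vals = block.find_loop(f"_{tag}")
        return np.array([float(v) for v in vals]) if vals else None

    coords = [col(t) for t in _STAR_COORD]
    if any(c is None for c in coords):
        raise ValueError("STAR file lacks one of the coordinate columns")
    centers = np.column_stack(coords)
    origins = [col(t) for t in _STAR_ORIGIN]
    if all(o is not None for o in origins):
        centers = centers - np.column_stack(origins)
    centers = centers * dialect.scale_to_nm()
    angles = [col(t) for t in _STAR_ANGLE]
    if any(a is None for a in angles):
        raise ValueError("STAR file lacks one of the Euler angle columns")
    rot, tilt, psi = angles
    rots = Rotation.from_euler("ZYZ", np.column_stack([rot, tilt, psi]),
                               degrees=True).as_matrix()
    ids = np.arange(len(centers))
    return _poses_to_model(centers, rots, ids)


def write_star_poses(m: CondensateModel, path,
                     dialect: PoseTableDialect | None = None) -> None:
    dialect = dialect or PoseTableDialect(format="star", length_unit="angstrom")
    scale = 1.0 / dialect.scale_to_nm()
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("_", ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ",
                                 "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"])
    for p in m.poses:
        eul = Rotation.from_matrix(p.rotation_matrix).as_euler("ZYZ", degrees=True)
        c = p.center * scale
        loop.add_row([f"{c[0]:.6f}", f"{c[1]:.6f}", f"{c[2]:.6f}",
                      f"{eul[0]:.6f}", f"{eul[1]:.6f}", f"{eul[2]:.6f}"])
    doc.write_file(str(path))


def read_poses(path, dialect: PoseTableDialect | None = None) -> CondensateModel:
    """Dispatch on dialect/extension to the CSV or STAR reader."""
    path = Path(path)
    fmt = dialect.format if dialect else ("star" if path.suffix == ".star" else "csv")
    if fmt == "star":
        return read_star_poses(path, dialect)
    return read_pose_csv(path, dialect)


def write_poses(m: CondensateModel, path,
                dialect: PoseTableDialect | None = None) -> None:
    path = Path(path)
    fmt = dialect.format if dialect else ("star" if path.suffix == ".star" else "csv")
    if fmt == "star":
        write_star_poses(m, path, dialect)
    else:
        write_pose_csv(m, path)


# ---------------------------------------------------------------------------
# template frames from atomic structures
# ---------------------------------------------------------------------------

_DNA_RESIDUES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U"}


def _refine_cylinder_axis(pts: np.ndarray, axis0: np.ndarray) -> np.ndarray:
    """Axis minimising the spread of radial distances of ``pts``."""
    from scipy.optimize import minimize

    def to_axis(angles):
        t, ph = angles
        return np.array([np.sin(t) * np.cos(ph), np.sin(t) * np.sin(ph), np.cos(t)])

    # parameterise around axis0 by rotating the frame so axis0 = +z
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis0)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis0, e1)
    basis = np.column_stack([e1, e2, axis0])
    local = pts @ basis

    def objective(angles):
        ax = to_axis(angles)
        z = local @ ax
        radial = local - np.outer(z, ax)
        rho = np.linalg.norm(radial, axis=1)
        return float(np.var(rho) / np.mean(rho) ** 2)

    res = minimize(objective, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 500})
    return basis @ to_axis(res.x)


def derive_frame_from_template(
    structure, h4_chains: tuple[str, ...] = ("B", "F"), h4_max_residue: int = 25
) -> dict:
    """Disc frame (centre, normal, dyad) from a nucleosome structure.

    The normal is the smallest-variance principal axis of the DNA
    phosphate coordinates, with its sign fixed toward the centroid of
    the N-terminal residues of the H4 chains (the H4-tail-bearing face);
    the dyad is the projection, perpendicular to the normal, of the
    vector from the centre to the central DNA phosphate.  Lengths in nm.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    model = structure[0]
    p_coords = []
    p_chain_pos = []
    h4_coords = []
    for chain in model:
        for res in chain:
            if res.name.strip() in _DNA_RESIDUES:
                for atom in res:
                    if atom.name == "P":
                        p_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        p_chain_pos.append((chain.name, res.seqid.num))
            if chain.name in h4_chains and res.seqid.num <= h4_max_residue:
                for atom in res:
                    if atom.name in ("CA", "CB") or len(res) == 1:
                        h4_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if len(p_coords) < 10:
        raise ValueError("structure lacks DNA phosphates (need at least 10)")
    p = np.asarray(p_coords) * 0.1  # A -> nm
    center = p.mean(axis=0)
    cov = np.cov((p - center).T)
    eigval, eigvec = np.linalg.eigh(cov)
    # PCA gives a first guess of the superhelical axis; refine it by
    # cylinder fitting (the wrapped DNA is equidistant from the true
    # axis, whereas an incomplete helical turn tilts plain PCA)
    normal = _refine_cylinder_axis(p - center, eigvec[:, 0])
    if h4_coords:
        h4c = np.asarray(h4_coords).mean(axis=0) * 0.1
        if np.dot(normal, h4c - center) < 0:
            normal = -normal
    else:
        warnings.warn("no H4 chain found; normal sign is arbitrary", stacklevel=2)
    # dyad: central phosphate of the wrapped DNA, projected into the disc
    order = np.lexsort((
        [n for _, n in p_chain_pos], [c for c, _ in p_chain_pos],
    ))
    mid = p[order[len(order) // 2]]
    dyad_raw = mid - center
    dyad = dyad_raw - np.dot(dyad_raw, normal) * normal
    nrm = np.linalg.norm(dyad)
    if nrm < 1e-9:
        raise ValueError("degenerate dyad: central phosphate on the normal axis")
    dyad = dyad / nrm
    return {
        "center_nm": center,
        "normal": normal,
        "dyad": dyad,
        "n_phosphates": len(p),
        "sign_rule": "normal points toward the H4 N-terminal centroid",
        "h4_chains": h4_chains,
    }


def read_cg_frame_csv(path) -> "CGFrame":
    """Coarse-grained bead table from CSV (columns as in tails.CGFrame)."""
    from .tails import CGFrame

    return CGFrame(beads=pd.read_csv(path))


def read_cg_frame_pdb(path, label_map: dict) -> "CGFrame":
    """Coarse-grained frame from a PDB/mmCIF file plus a chain label map.

    ``label_map`` maps chain name -> {"role": ..., "nucleosome_id": ...,
    "array_id": ...}; one bead per atom, residue indices from the file,
    coordinates in Angstrom.
    """
    from .tails import CGFrame

    st = gemmi.read_structure(str(path))
    rows = []
    for chain in st[0]:
        if chain.name not in label_map:
            raise ValueError(f"chain {chain.name!r} missing from the label map")
        lab = label_map[chain.name]
        for res in chain:
            for atom in res:
                rows.append(
                    {
                        "chain_id": chain.name,
                        "residue_index": res.seqid.num,
                        "residue_name": res.name,
                        "role": lab["role"],
                        "nucleosome_id": lab["nucleosome_id"],
                        "array_id": lab.get("array_id", 0),
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                    }
                )
    return CGFrame(beads=pd.DataFrame(rows))


def write_occupancy_mrc(grid, path, which: str = "occupied") -> None:
    """Export an occupancy/mask grid as a CCP4/MRC volume (float32)."""
    arr = getattr(grid, which).astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(arr))
    ext = np.array(arr.shape) * grid.voxel_nm * 10.0  # nm -> A
    m.grid.unit_cell = gemmi.UnitCell(ext[0], ext[1], ext[2], 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
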