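"""Representative complex selection and RMSD diagnostics.

The selection pipeline mirrors standard practice for picking binding poses
out of large replica ensembles: (1) geometric pre-filters (partner COM
distance, complex RMSD to a reference structure), (2) restriction to frames
whose ligand COM falls inside the high-occupancy density region, and
(3) a seeded uniform draw of n poses from the surviving candidate pool.
Pairwise pose RMSD matrices and the refolding RMSD relative to the
first-contact complex diagnose how much the bound pose rearranges after the
initial encounter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import (
    DegenerateSelectionError,
    apply_transform,
    check_noncollinear,
    kabsch,
    rmsd as _plain_rmsd,
)
from .contacts import DEFAULT_CUTOFF, encounter_time
from .density import DensityGrid, high_density_region
from .trajectory_io import Selection, Trajectory, center_of_mass

__all__ = [
    "PoseSet",
    "kabsch_superpose",
    "select_representatives",
    "pairwise_rmsd",
    "refolding_rmsd",
]


@dataclass
class PoseSet:
    """Selected representative poses with per-filter survivor counts."""

    frames: list[tuple[int, int]]  # (replica_id, frame_index)
    selection_log: dict[str, int]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frames, columns=["replica", "frame"])


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray, subset=None):
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` where the proper rotation
    (det = +1) and translation map B onto A (``b @ R.T + t``) with minimal
    RMSD over ``subset`` (all points when None).
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.shape != coords_b.shape:
        raise ValueError(f"coordinate shape mismatch: {coords_a.shape} vs {coords_b.shape}")
    sub = np.arange(len(coords_a)) if subset is None else np.asarray(subset, dtype=np.intp)
    check_noncollinear(coords_b[sub])
    rot, trans = kabsch(coords_b[sub], coords_a[sub])
    fitted = apply_transform(coords_b[sub], rot, trans)
    return rot, trans, _plain_rmsd(fitted, coords_a[sub])


def _fit_or_translate(mobile: np.ndarray, target: np.ndarray):
    """Kabsch fit, falling back to a pure centroid translation when the
    alignment subset is too small or collinear (e.g. a point-like ligand)."""
    try:
        return kabsch(mobile, target)
    except DegenerateSelectionError:
        return np.eye(3), np.asarray(target).mean(axis=0) - np.asarray(mobile).mean(axis=0)


def _resolve(traj: Trajectory, sel) -> np.ndarray:
    return traj.select(sel) if isinstance(sel, (str, Selection)) else np.asarray(sel, dtype=np.intp)


def select_representatives(
    trajs: list[Trajectory],
    ref_coords: np.ndarray,
    ligand_sel,
    receptor_sel,
    grid: DensityGrid,
    com_cutoff: float = 30.0,
    rmsd_cutoff: float = 50.0,
    density_threshold: float = 0.6,
    n: int = 20,
    seed: int = 0,
) -> PoseSet:
    """Pick n representative bound complexes from replica trajectories.

    Pipeline (frames must share the alignment frame of ``grid``):

    1. keep frames with ligand-receptor COM distance < ``com_cutoff`` and
       complex RMSD to ``ref_coords`` < ``rmsd_cutoff`` (aligned on the
       ligand, measured over all particles);
    2. keep frames whose ligand COM falls inside
       ``high_density_region(grid, density_threshold)``;
    3. draw n uniformly without replacement (seeded).

    ``selection_log`` records survivor counts after each stage.
    """
    if not trajs:
        raise ValueError("select_representatives: no trajectories")
    ref_coords = np.asarray(ref_coords, dtype=float)
    lig = _resolve(trajs[0], ligand_sel)
    rec = _resolve(trajs[0], receptor_sel)
    mask = high_density_region(grid, density_threshold)

    log = {"total": 0, "geometry": 0, "density": 0, "selected": 0}
    candidates: list[tuple[int, int]] = []
    for traj in trajs:
        lig_com = center_of_mass(traj, lig)
        rec_com = center_of_mass(traj, rec)
        com_ok = np.linalg.norm(lig_com - rec_com, axis=1) < com_cutoff
        log["total"] += traj.n_frames
        for f in range(traj.n_frames):
            if not com_ok[f]:
                continue
            rot, trans = _fit_or_translate(traj.coordinates[f][lig], ref_coords[lig])
            fitted = apply_transform(traj.coordinates[f], rot, trans)
            if _plain_rmsd(fitted, ref_coords) >= rmsd_cutoff:
                continue
            log["geometry"] += 1
            voxel = grid.voxel_of(lig_com[f])[0]
            if voxel[0] < 0 or not mask[tuple(voxel)]:
                continue
            log["density"] += 1
            candidates.append((traj.replica_id, f))
    if log["geometry"] == 0:
        raise ValueError("select_representatives: COM/RMSD pre-filters left no candidates")
    if not candidates:
        raise ValueError("select_representatives: density filter left no candidates")
    rng = np.random.default_rng(seed)
    if len(candidates) <= n:
        chosen = list(candidates)
    else:
        pick = rng.choice(len(candidates), size=n, replace=False)
        chosen = [candidates[i] for i in sorted(pick)]
    log["selected"] = len(chosen)
    return PoseSet(frames=chosen, selection_log=log, seed=seed)


def pairwise_rmsd(frames: list[np.ndarray], align_idx, measure_idx) -> np.ndarray:
    """Symmetric pairwise RMSD matrix over ``measure_idx`` after fitting on ``align_idx``."""
    if len(frames) < 2:
        raise ValueError("pairwise_rmsd needs at least 2 frames")
    align_idx = np.asarray(align_idx, dtype=np.intp)
    measure_idx = np.asarray(measure_idx, dtype=np.intp)
    n = len(frames)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, trans = kabsch(frames[j][align_idx], frames[i][align_idx])
            fitted = apply_transform(frames[j][measure_idx], rot, trans)
            out[i, j] = out[j, i] = _plain_rmsd(fitted, frames[i][measure_idx])
    return out


def refolding_rmsd(
    traj: Trajectory, sel_receptor, sel_ligand, cutoff: float = DEFAULT_CUTOFF
) -> pd.Series:
    """Ligand RMSD of each post-encounter frame vs the first-contact complex.

    The reference is the frame where the first inter-protein contact forms;
    each later frame is superposed on the receptor selection and the RMSD is
    measured over the ligand selection, isolating binding-pose rearrangement
    from rigid tumbling of the whole complex.  The series starts at 0.
    """
    rec = _resolve(traj, sel_receptor)
    lig = _resolve(traj, sel_ligand)
    record = encounter_time(traj, sel_receptor, sel_ligand, cutoff=cutoff)
    if record.encounter_time is None:
        raise ValueError("refolding_rmsd: no inter-protein contact in trajectory")
    fc = int(round(record.encounter_time / traj.dt))
    ref = traj.coordinates[fc]
    values = np.empty(traj.n_frames - fc)
    for k, f in enumerate(range(fc, traj.n_frames)):
        rot, trans = kabsch(traj.coordinates[f][rec], ref[rec])
        fitted = apply_transform(traj.coordinates[f][lig], rot, trans)
        values[k] = _plain_rmsd(fitted, ref[lig])
    times = (np.arange(fc, traj.n_frames) - fc) * traj.dt
    return pd.Series(values, index=pd.Index(times, name="time_since_contact_ns"), name="rmsd")
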