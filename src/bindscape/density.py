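"""3D occupancy grids of one binding partner around the other.

Frames are first rigidly superposed on the receptor (or any reference
selection), then observations of the mobile partner are binned on a regular
grid (0.5 Å voxels by default) and normalized to a reference mass density
(bulk water, 1.0 g/cm³).  High-relative-density voxels (> 0.6 of the grid
maximum by default) mark the most probable binding patterns; their
26-connected components count distinct binding modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import apply_transform, check_noncollinear, kabsch
from .constants import A3_TO_CM3, AMU_TO_GRAM
from .trajectory_io import Selection, Trajectory

__all__ = [
    "DensityGrid",
    "align_on",
    "occupancy_grid",
    "high_density_region",
    "region_components",
    "component_weights",
    "planar_projection",
    "write_dx",
]

#: Default per-bead mass equivalent used for the g/cm³ conversion (one water).
DEFAULT_BEAD_MASS = 18.0


@dataclass
class DensityGrid:
    """Voxel occupancy of a selection accumulated over frames.

    ``counts`` are raw particle observations per voxel; ``values`` are
    per-frame mass densities relative to ``reference_density``.  ``origin``
    is the lower corner of voxel (0,0,0); voxel centers sit at
    ``origin + (i + 0.5) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    values: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("voxel counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.spacing for d in range(3)
        )

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Voxel indices of Cartesian points; -1 marks out-of-grid axes."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((points - self.origin) / self.spacing).astype(int)
        bad = (idx < 0) | (idx >= np.array(self.shape))
        idx[bad.any(axis=1)] = -1
        return idx


def align_on(traj: Trajectory, ref_frame, align_sel) -> Trajectory:
    """Rigidly superpose every frame onto a reference over a selection.

    ``ref_frame`` is either a frame index of ``traj`` or a full-particle
    coordinate array.  The least-squares (Kabsch) transform fitted on
    ``align_sel`` is applied to all particles of each frame.
    """
    idx = traj.select(align_sel) if isinstance(align_sel, (str, Selection)) else np.asarray(align_sel, dtype=np.intp)
    if isinstance(ref_frame, (int, np.integer)):
        ref = traj.coordinates[int(ref_frame)]
    else:
        ref = np.asarray(ref_frame, dtype=float)
        if ref.shape != (traj.topology.n_particles, 3):
            raise ValueError(f"reference frame shape {ref.shape} != (n_particles, 3)")
    check_noncollinear(ref[idx])
    out = np.empty_like(traj.coordinates, dtype=float)
    for f in range(traj.n_frames):
        rot, trans = kabsch(traj.coordinates[f][idx], ref[idx])
        out[f] = apply_transform(traj.coordinates[f], rot, trans)
    return Trajectory(topology=traj.topology, coordinates=out, dt=traj.dt, replica_id=traj.replica_id)


def occupancy_grid(
    aligned,
    density_sel,
    spacing: float = 0.5,
    reference_density: float = 1.0,
    bead_mass: float = DEFAULT_BEAD_MASS,
    padding: float = 5.0,
) -> DensityGrid:
    """Bin selected-particle observations of aligned frames into a 3D grid.

    ``aligned`` is a Trajectory or a list of Trajectories (replicas) sharing
    one topology, already superposed into a common frame.  Grid extent is the
    bounding box of all observations padded by ``padding`` Å, with edges
    snapped to multiples of ``spacing``.  Normalized values are
    ``count × bead_mass / (voxel volume × n_frames) / reference_density``
    with ``bead_mass`` in Da and ``reference_density`` in g/cm³.
    """
    trajs = [aligned] if isinstance(aligned, Trajectory) else list(aligned)
    if not trajs:
        raise ValueError("occupancy_grid: no trajectories")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    sel = (
        trajs[0].select(density_sel)
        if isinstance(density_sel, (str, Selection))
        else np.asarray(density_sel, dtype=np.intp)
    )
    if sel.size == 0:
        raise ValueError("occupancy_grid: empty density selection")
    n_frames = sum(t.n_frames for t in trajs)
    if n_frames == 0:
        raise ValueError("occupancy_grid: zero frames")
    points = np.concatenate([t.coordinates[:, sel, :].reshape(-1, 3) for t in trajs]).astype(float)
    lo = np.floor((points.min(axis=0) - padding) / spacing) * spacing
    hi = np.ceil((points.max(axis=0) + padding) / spacing) * spacing
    nbins = np.maximum(np.round((hi - lo) / spacing).astype(int), 1)
    edges = [lo[d] + np.arange(nbins[d] + 1) * spacing for d in range(3)]
    counts, _ = np.histogramdd(points, bins=edges)
    counts = counts.astype(np.int64)
    voxel_cm3 = spacing**3 * A3_TO_CM3
    values = counts * (bead_mass * AMU_TO_GRAM) / (n_frames * voxel_cm3) / reference_density
    return DensityGrid(origin=lo, spacing=spacing, counts=counts, values=values, n_frames=n_frames)


def high_density_region(grid: DensityGrid, relative_threshold: float = 0.6) -> np.ndarray:
    """Boolean voxel mask where value / max(value) > threshold (strict)."""
    vmax = grid.values.max(initial=0.0)
    if vmax <= 0:
        raise ValueError("high_density_region: grid has no positive density")
    return grid.values / vmax > relative_threshold


def region_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 26-connected components of a voxel mask."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return labels, int(n)


def component_weights(grid: DensityGrid, labels: np.ndarray, n_components: int) -> np.ndarray:
    """Integrated normalized density of each labeled component (1..n)."""
    return np.array(
        [grid.values[labels == i].sum() for i in range(1, n_components + 1)]
    )


def component_basin_weights(
    grid: DensityGrid, labels: np.ndarray, n_components: int, floor: float = 0.05
) -> np.ndarray:
    """Integrated density of each component's whole basin.

    Thresholding truncates a weaker mode at the same absolute level as a
    stronger one, biasing peak-voxel integrals toward the strong mode.  Here
    every voxel above ``floor`` (relative to the grid maximum, low enough to
    exclude the diffuse bulk cloud) is assigned to the nearest component
    centroid, so basin integrals recover the underlying mode populations.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    centroids = np.array(
        [np.argwhere(labels == i).mean(axis=0) for i in range(1, n_components + 1)]
    )
    active = np.argwhere(grid.values / grid.values.max() > floor)
    d = np.linalg.norm(active[:, None, :] - centroids[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    vals = grid.values[tuple(active.T)]
    return np.array([vals[nearest == i].sum() for i in range(n_components)])


def planar_projection(aligned: Trajectory, proj_sel) -> pd.DataFrame:
    """Drop z: (x, y) of every selected particle in every aligned frame.

    Returns a DataFrame with frame/particle provenance for plotting.
    """
    sel = (
        aligned.select(proj_sel)
        if isinstance(proj_sel, (str, Selection))
        else np.asarray(proj_sel, dtype=np.intp)
    )
    xy = aligned.coordinates[:, sel, :2]
    n_frames, n_sel = xy.shape[:2]
    return pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n_sel),
            "particle": np.tile(sel, n_frames),
            "x": xy[:, :, 0].ravel(),
            "y": xy[:, :, 1].ravel(),
        }
    )


def write_dx(grid: DensityGrid, path) -> None:
    """Export normalized densities in OpenDX format (readable by VMD etc.)."""
    nx, ny, nz = grid.shape
    ox, oy, oz = grid.origin + grid.spacing / 2.0  # voxel centers
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6g} {oy:.6g} {oz:.6g}\n")
        fh.write(f"delta {s:.6g} 0 0\ndelta 0 {s:.6g} 0\ndelta 0 0 {s:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = grid.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
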