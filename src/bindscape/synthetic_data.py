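"""Synthetic two-body binding trajectories and umbrella-window samples.

This module emulates, at desk scale, the statistical structure of large
replica sets of coarse-grained protein-protein binding simulations: many
independent replicas of a diffusing ligand binding a fixed receptor carrying
one or more planted binding basins of controllable depth and population, an
optional flexible tail on the ligand (an IDR mimic), random initial placement
on a shell >= 40 Å from the receptor, and umbrella-window samples drawn from
an analytic 1D potential.  Every planted quantity (well depth, site
populations, well geometry) is known exactly, so downstream analyses can be
verified against closed-form ground truth.

Model
-----
The receptor is a frozen shell of beads centered at the origin.  The ligand
is a rigid core of beads that translates with its center of mass (COM); the
COM obeys overdamped (Euler-Maruyama) Langevin dynamics in a potential that
is the sum of

* planted binding sites: smoothed flat-bottom spherical wells
  ``U(d) = -depth`` for ``d < width``, switched to zero with a cosine ramp
  over ``width .. width + switch`` (equal-volume wells make equilibrium
  occupancy ratios exactly Boltzmann in the depth difference);
* a soft-core radial repulsion keeping the COM outside the receptor shell;
* a soft spherical wall at ``box_radius`` confining the search volume.

Optional tail beads hang off the core on harmonic springs and diffuse with
their own per-bead mobility, extending the capture radius — the fly-casting
effect.  The drag model is free-draining: a flexible tail's beads carry
their own friction and do not slow the core, so the COM drag is
``friction * n_core``.  ``tail_rigid=True`` instead freezes the tail
compactly against the core: the conformational search and capture-radius
extension vanish while the rigidly attached beads now add their drag to the
COM (``friction * (n_core + tail_length)``), which is how rigidifying the
IDR slows binding in this translation-only model.  ``friction`` is a
per-bead drag coefficient in kcal/mol·ns/Å² (mobility = 1/drag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import kT as _kT
from .trajectory_io import Particle, Selection, Topology, Trajectory, center_of_mass

__all__ = [
    "BindingSiteSpec",
    "SimConfig",
    "UmbrellaDataset",
    "IntegrationError",
    "simulate_binding_replicas",
    "generate_umbrella_samples",
    "generate_reference_profile",
    "write_umbrella_dir",
    "read_umbrella_dir",
    "site_occupancy",
    "ligand_com",
]

LIGAND_CORE_SEL = Selection("chain L and domain core")
LIGAND_SEL = Selection("chain L")
RECEPTOR_SEL = Selection("chain R")


class IntegrationError(RuntimeError):
    """Integration produced non-finite coordinates; reduce dt."""


@dataclass(frozen=True)
class BindingSiteSpec:
    """A planted binding basin: flat-bottom spherical well in ligand-COM space.

    ``depth`` (kcal/mol, > 0) is the well depth, ``width`` (Å) the flat-bottom
    radius, ``switch`` (Å) the cosine switching length over which the well
    rises back to zero.
    """

    center: tuple[float, float, float]
    depth: float
    width: float
    switch: float = 2.0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"site depth must be > 0, got {self.depth}")
        if self.width <= 0:
            raise ValueError(f"site width must be > 0, got {self.width}")
        if self.switch <= 0:
            raise ValueError(f"site switch must be > 0, got {self.switch}")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def energy(self, d: np.ndarray) -> np.ndarray:
        """Well energy at COM-to-center distance d (Å)."""
        d = np.asarray(d, dtype=float)
        s = np.zeros_like(d)
        inside = d < self.width
        ramp = (~inside) & (d < self.width + self.switch)
        s[inside] = 1.0
        t = (d[ramp] - self.width) * (math.pi / (2.0 * self.switch))
        s[ramp] = np.cos(t) ** 2
        return -self.depth * s


def _check_sites(sites: list[BindingSiteSpec]) -> None:
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            sep = np.linalg.norm(sites[i].center_array - sites[j].center_array)
            rec = 2.0 * max(sites[i].width, sites[j].width)
            if sep <= rec:
                warnings.warn(
                    f"binding sites {i} and {j} are {sep:.1f} Å apart "
                    f"(< recommended {rec:.1f} Å); wells overlap",
                    stacklevel=3,
                )


@dataclass
class SimConfig:
    """Parameters of the synthetic binding simulator.

    Defaults are chosen so that a 50-replica run reaches the receptor from a
    40 Å start within a fraction of the trajectory and hops between planted
    sites many times, giving equilibrated site populations at desk scale.
    """

    sites: list[BindingSiteSpec] = field(default_factory=list)
    n_receptor: int = 24
    receptor_radius: float = 9.0
    n_ligand_core: int = 10
    core_radius: float = 2.5
    tail_length: int = 0
    tail_rigid: bool = False
    tail_bond: float = 4.0
    tail_spring_k: float = 0.5
    temperature: float = 300.0
    friction: float = 0.005
    dt: float = 0.0025
    n_steps: int = 640_000
    n_replicas: int = 50
    min_start_separation: float = 40.0
    box_radius: float = 46.0
    repulsion_k: float = 2.0
    wall_k: float = 2.0
    save_every: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.temperature <= 0:
            raise ValueError("dt, friction and temperature must be positive")
        if self.tail_length < 0:
            raise ValueError("tail_length must be >= 0")
        if self.min_start_separation >= self.box_radius:
            raise ValueError(
                f"min_start_separation ({self.min_start_separation}) must be inside "
                f"box_radius ({self.box_radius})"
            )
        _check_sites(self.sites)
        # Euler-Maruyama stability: the stiffest force constant acting on the
        # fastest (single-bead) mobility must relax over more than one step.
        # interior tail beads see two bonds -> effective stiffness 2k
        k_max = max(
            [2.0 * self.tail_spring_k, self.repulsion_k, self.wall_k]
            + [s.depth * (math.pi / (2.0 * s.switch)) ** 2 for s in self.sites]
        )
        if self.dt * k_max / self.friction >= 2.0:
            raise ValueError(
                f"dt = {self.dt} ns is unstable for stiffness {k_max:.2f} kcal/mol/Å² "
                f"at friction {self.friction}; reduce dt"
            )

    @property
    def gamma_com(self) -> float:
        """COM drag: free-draining flexible tail beads carry their own
        friction, so only a rigidified tail adds its drag to the core."""
        n_dragging = self.n_ligand_core + (self.tail_length if self.tail_rigid else 0)
        return self.friction * n_dragging

    @property
    def n_particles(self) -> int:
        return self.n_receptor + self.n_ligand_core + self.tail_length


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_topology(config: SimConfig) -> Topology:
    """Receptor chain R (domain ``receptor``) + ligand chain L (``core``/``tail``)."""
    particles = []
    idx = 0
    for i in range(config.n_receptor):
        particles.append(Particle(idx, "BB", i + 1, "REC", "R", "receptor"))
        idx += 1
    for i in range(config.n_ligand_core):
        particles.append(Particle(idx, "BB", i + 1, "LIG", "L", "core"))
        idx += 1
    for i in range(config.tail_length):
        particles.append(
            Particle(idx, "BB", config.n_ligand_core + i + 1, "TAI", "L", "tail", flexible=not config.tail_rigid)
        )
        idx += 1
    return Topology(particles)


def _com_forces(com: np.ndarray, config: SimConfig) -> np.ndarray:
    """Deterministic force on the ligand COM for each replica; com is (R, 3)."""
    force = np.zeros_like(com)
    r = np.linalg.norm(com, axis=1)
    unit_r = com / np.maximum(r, 1e-12)[:, None]
    # planted wells
    for site in config.sites:
        d_vec = com - site.center_array
        d = np.linalg.norm(d_vec, axis=1)
        ramp = (d >= site.width) & (d < site.width + site.switch)
        if np.any(ramp):
            t = (d[ramp] - site.width) * (math.pi / (2.0 * site.switch))
            # U = -depth*cos²(t) -> dU/dd = depth*(pi/2switch)*sin(2t); F = -dU/dd * unit
            mag = -site.depth * (math.pi / (2.0 * site.switch)) * np.sin(2.0 * t)
            force[ramp] += mag[:, None] * (d_vec[ramp] / d[ramp][:, None])
    # soft-core repulsion around the receptor shell
    r_rep = config.receptor_radius + 2.0
    inside = r < r_rep
    if np.any(inside):
        force[inside] += (config.repulsion_k * (r_rep - r[inside]))[:, None] * unit_r[inside]
    # confining wall
    outside = r > config.box_radius
    if np.any(outside):
        force[outside] -= (config.wall_k * (r[outside] - config.box_radius))[:, None] * unit_r[outside]
    return force


def simulate_binding_replicas(config: SimConfig) -> list[Trajectory]:
    """Run all replicas of the overdamped Langevin binding simulation.

    Each replica consumes its own random stream derived from ``config.seed``,
    so results for a given replica are independent of ``n_replicas`` and the
    same seed reproduces trajectories bitwise.  Frames are recorded every
    ``save_every`` steps starting from the initial placement; the returned
    trajectories have ``dt = config.dt * config.save_every`` ns per frame.
    """
    topology = build_topology(config)
    receptor = _fibonacci_sphere(config.n_receptor, config.receptor_radius)
    core_offsets = _fibonacci_sphere(config.n_ligand_core, config.core_radius)
    anchor_offset = core_offsets[0]
    rigid_tail_offsets = _fibonacci_sphere(max(config.tail_length, 1), config.core_radius + 1.0)[
        : config.tail_length
    ]

    n_rep, n_tail = config.n_replicas, config.tail_length
    kt = _kT(config.temperature)
    gamma_com = config.gamma_com
    sig_com = math.sqrt(2.0 * kt * config.dt / gamma_com)
    sig_bead = math.sqrt(2.0 * kt * config.dt / config.friction)
    mob_com = config.dt / gamma_com
    mob_bead = config.dt / config.friction

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n_rep)]

    # initial placement: uniformly on the shell at min_start_separation
    com = np.empty((n_rep, 3))
    for r, rng in enumerate(streams):
        d = rng.standard_normal(3)
        com[r] = d / np.linalg.norm(d) * config.min_start_separation
    tail = np.zeros((n_rep, n_tail, 3))
    if n_tail:
        for r, rng in enumerate(streams):
            jitter = 0.5 * rng.standard_normal((n_tail, 3))
            anchor = com[r] + anchor_offset
            tail[r] = anchor + np.arange(1, n_tail + 1)[:, None] * 0.5 * _unit(anchor_offset) + jitter

    n_saved = config.n_steps // config.save_every + 1
    frames = np.empty((n_rep, n_saved, config.n_particles, 3), dtype=np.float32)

    def record(slot: int) -> None:
        frames[:, slot, : config.n_receptor, :] = receptor[None, :, :]
        frames[:, slot, config.n_receptor : config.n_receptor + config.n_ligand_core, :] = (
            com[:, None, :] + core_offsets[None, :, :]
        )
        if n_tail:
            if config.tail_rigid:
                frames[:, slot, config.n_receptor + config.n_ligand_core :, :] = (
                    com[:, None, :] + rigid_tail_offsets[None, :, :]
                )
            else:
                frames[:, slot, config.n_receptor + config.n_ligand_core :, :] = tail

    record(0)
    slot = 1
    chunk = 2048
    flexible_tail = n_tail > 0 and not config.tail_rigid
    step = 0
    while step < config.n_steps:
        this_chunk = min(chunk, config.n_steps - step)
        noise_com = np.stack([rng.standard_normal((this_chunk, 3)) for rng in streams])
        noise_tail = (
            np.stack([rng.standard_normal((this_chunk, n_tail, 3)) for rng in streams])
            if flexible_tail
            else None
        )
        for s in range(this_chunk):
            force = _com_forces(com, config)
            com += mob_com * force + sig_com * noise_com[:, s, :]
            if flexible_tail:
                anchor = com + anchor_offset  # (R, 3)
                prev = np.concatenate([anchor[:, None, :], tail[:, :-1, :]], axis=1)
                bond = tail - prev  # (R, T, 3)
                blen = np.linalg.norm(bond, axis=2)
                bunit = bond / np.maximum(blen, 1e-12)[:, :, None]
                stretch = (blen - config.tail_bond)[:, :, None]
                f_tail = -config.tail_spring_k * stretch * bunit
                f_tail[:, :-1, :] += config.tail_spring_k * stretch[:, 1:, :] * bunit[:, 1:, :]
                tail += mob_bead * f_tail + sig_bead * noise_tail[:, s, :, :]
            step += 1
            if step % config.save_every == 0:
                record(slot)
                slot += 1
        if not np.all(np.isfinite(com)) or (flexible_tail and not np.all(np.isfinite(tail))):
            raise IntegrationError("coordinates became non-finite; reduce dt")

    dt_frame = config.dt * config.save_every
    return [
        Trajectory(topology=topology, coordinates=frames[r, :slot], dt=dt_frame, replica_id=r)
        for r in range(n_rep)
    ]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def ligand_com(traj: Trajectory) -> np.ndarray:
    """Ligand rigid-core COM per frame (the coordinate the wells act on)."""
    return center_of_mass(traj, LIGAND_CORE_SEL)


def site_occupancy(
    com: np.ndarray, sites: list[BindingSiteSpec], discard_until_bound: bool = False
) -> np.ndarray:
    """Assign each COM frame to a site (index) or to bulk (-1).

    A frame belongs to a site when the COM is inside the flat bottom
    (distance < width).  With ``discard_until_bound`` frames before the first
    bound frame are marked -2 (burn-in), the standard choice when measuring
    equilibrium populations from association runs that start far away.
    """
    com = np.asarray(com, dtype=float)
    d = np.stack([np.linalg.norm(com - s.center_array, axis=1) for s in sites], axis=1)
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(len(com)), nearest] < np.array([s.width for s in sites])[nearest]
    assign = np.where(within, nearest, -1)
    if discard_until_bound:
        bound_idx = np.flatnonzero(assign >= 0)
        if bound_idx.size:
            assign[: bound_idx[0]] = -2
        else:
            assign[:] = -2
    return assign


# ---------------------------------------------------------------------------
# Umbrella-window samples from an analytic 1D potential
# ---------------------------------------------------------------------------


@dataclass
class UmbrellaDataset:
    """Per-window biased reaction-coordinate samples.

    ``windows`` is a list of (center Å, force constant kcal/mol/Å², samples Å)
    sorted by center; the harmonic bias is ``k/2 (x - center)²``.
    """

    windows: list[tuple[float, float, np.ndarray]]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        centers = [w[0] for w in self.windows]
        if centers != sorted(centers):
            self.windows = sorted(self.windows, key=lambda w: w[0])
        for c, k, samples in self.windows:
            if len(samples) == 0:
                raise ValueError(f"umbrella window at {c} Å has no samples")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w[0] for w in self.windows])


def generate_umbrella_samples(
    potential,
    centers,
    k: float,
    n_per_window: int,
    temperature: float = 300.0,
    seed: int = 0,
    burn_in: int = 1000,
    thin: int = 5,
) -> UmbrellaDataset:
    """Metropolis samples of ``exp(-[U(x) + k/2 (x-c)²]/kBT)`` per window.

    The proposal step is auto-tuned to 30-50% acceptance during burn-in;
    recorded samples are thinned by ``thin`` to reduce autocorrelation.
    """
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    kt = _kT(temperature)
    centers = np.asarray(centers, dtype=float)
    if not np.all(np.isfinite(potential(centers))):
        raise ValueError("potential is non-finite at one or more window centers")
    rngs = np.random.SeedSequence(seed).spawn(len(centers))
    windows = []
    for c, ss in zip(centers, rngs):
        rng = np.random.default_rng(ss)

        def energy(x: float) -> float:
            return float(potential(x)) + 0.5 * k * (x - c) ** 2

        x = float(c)
        e = energy(x)
        step = max(math.sqrt(kt / k), 1e-3)
        accepted = 0
        for i in range(burn_in):
            x, e, acc = _metropolis_step(x, e, step, energy, kt, rng)
            accepted += acc
            if (i + 1) % 50 == 0:
                rate = accepted / 50.0
                if rate < 0.3:
                    step *= 0.8
                elif rate > 0.5:
                    step *= 1.25
                accepted = 0
        samples = np.empty(n_per_window)
        for i in range(n_per_window * thin):
            x, e, _ = _metropolis_step(x, e, step, energy, kt, rng)
            if (i + 1) % thin == 0:
                samples[(i + 1) // thin - 1] = x
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"non-finite samples in window at {c} Å (potential diverges on support?)")
        windows.append((float(c), float(k), samples))
    return UmbrellaDataset(windows=windows, temperature=temperature)


def _metropolis_step(x, e, step, energy, kt, rng):
    x_new = x + step * rng.standard_normal()
    e_new = energy(x_new)
    if e_new <= e or rng.random() < math.exp(-(e_new - e) / kt):
        return x_new, e_new, 1
    return x, e, 0


def write_umbrella_dir(dataset: UmbrellaDataset, directory) -> None:
    """Plain-text umbrella layout: one file per window plus a metadata list.

    Each window file starts with ``# center k`` and has one sample per line;
    ``metadata.txt`` lists ``filename center k`` — the same layout the PMF
    reader expects for real data.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = []
    for i, (c, k, samples) in enumerate(dataset.windows):
        name = f"window_{i:03d}.dat"
        lines = [f"# {c:.6g} {k:.6g}"] + [f"{x:.8g}" for x in samples]
        (directory / name).write_text("\n".join(lines) + "\n")
        meta_lines.append(f"{name} {c:.6g} {k:.6g}")
    (directory / "metadata.txt").write_text("\n".join(meta_lines) + "\n")


def read_umbrella_dir(directory, temperature: float = 300.0) -> UmbrellaDataset:
    """Read the plain-text umbrella layout written by :func:`write_umbrella_dir`."""
    from pathlib import Path

    directory = Path(directory)
    meta = directory / "metadata.txt"
    if not meta.exists():
        raise FileNotFoundError(f"{meta}: umbrella metadata file not found")
    windows = []
    for line in meta.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, c, k = line.split()
        samples = np.loadtxt(directory / name, comments="#", ndmin=1)
        windows.append((float(c), float(k), samples))
    return UmbrellaDataset(windows=windows, temperature=temperature)


# ---------------------------------------------------------------------------
# Reference perturbation profile (NMR CSP-like)
# ---------------------------------------------------------------------------


def generate_reference_profile(
    n_residues: int,
    interface,
    signal: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Per-residue perturbation profile mimicking an NMR CSP experiment.

    Residues in ``interface`` (1-based ids) get ``signal`` plus Gaussian
    noise, others noise only; values are floored at zero.  Returned as a
    Series indexed by residue id 1..n_residues.
    """
    residue_ids = np.arange(1, n_residues + 1)
    interface = set(int(i) for i in interface)
    if not interface <= set(residue_ids.tolist()):
        raise ValueError("interface residues must be a subset of 1..n_residues")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, n_residues) if noise_sd > 0 else np.zeros(n_residues)
    values[[i - 1 for i in interface]] += signal
    return pd.Series(np.maximum(values, 0.0), index=residue_ids, name="perturbation")


def write_reference_profile(profile: pd.Series, path) -> None:
    """Two-column text file ``residue_id value``."""
    with open(path, "w") as fh:
        for rid, v in profile.items():
            fh.write(f"{rid} {v:.8g}\n")


def read_reference_profile(path) -> pd.Series:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return pd.Series(data[:, 1], index=data[:, 0].astype(int), name="perturbation")
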