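"""Run configuration and end-to-end pipeline orchestration.

``RunConfig`` collects every tunable default of the analysis stack in one
flat, validated record (unknown keys are rejected so typos fail loudly).
``run_pipeline`` wires the stages together over the synthetic generator —
simulate → contacts → density → sketchmap → pmf → poses — writing CSV/JSON
artifacts plus a machine-readable summary and a config echo into the output
directory.  Real trajectory/umbrella inputs can be substituted per stage via
the path fields.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import contacts as contacts_mod
from . import density as density_mod
from . import pmf as pmf_mod
from . import poses as poses_mod
from . import sketchmap as sketch_mod
from . import synthetic_data as synth
from .trajectory_io import write_fixture, write_models

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "contacts", "density", "sketchmap", "pmf", "poses")

log = logging.getLogger("bindscape")


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults."""

    # randomness
    seed: int = 0
    # synthetic simulation
    n_replicas: int = 50
    n_steps: int = 640_000
    tail_length: int = 0
    tail_rigid: bool = False
    site_depths: tuple[float, ...] = (3.0, 2.495)  # kcal/mol; 0.7/0.3 split at 300 K
    site_width: float = 4.0
    site_distance: float = 13.0  # Å from receptor center
    min_start_separation: float = 40.0
    # contacts
    cutoff: float = 7.0
    bootstrap_resamples: int = 10_000
    # density
    grid_spacing: float = 0.5
    density_threshold: float = 0.6
    # sketch-map
    sigmoid_sigma: float = 6.0
    sigmoid_a_hd: float = 2.0
    sigmoid_b_hd: float = 6.0
    sigmoid_a_ld: float = 2.0
    sigmoid_b_ld: float = 2.0
    max_embed_points: int = 400
    min_population_fraction: float = 0.05
    # pmf
    bin_width: float = 0.1
    mc_trials: int = 100
    rc_bound: float = 1.5
    rc_unbound: float = 14.5
    temperature: float = 300.0
    # poses
    n_poses: int = 20
    com_cutoff: float = 30.0
    rmsd_cutoff: float = 50.0
    # optional real-data inputs (override the synthetic stage inputs)
    umbrella_metadata: str | None = None
    reference_profile: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "site_depths" in raw:
            raw["site_depths"] = tuple(raw["site_depths"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["site_depths"] = list(d["site_depths"])
        return d

    def echo(self, outdir: Path) -> None:
        (outdir / "config.yaml").write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def sites(self) -> list[synth.BindingSiteSpec]:
        """Planted sites spread on the receptor surface at ``site_distance``."""
        directions = [(1.0, 0.0, 0.0), (-1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, -1.0, 0.0)]
        return [
            synth.BindingSiteSpec(
                center=tuple(self.site_distance * np.array(directions[i % 4])),
                depth=d,
                width=self.site_width,
            )
            for i, d in enumerate(self.site_depths)
        ]


def _demo_potential(x):
    """Analytic double-well dissociation potential for the pmf demo stage."""
    x = np.asarray(x, dtype=float)
    return -6.0 * np.exp(-((x - 3.0) ** 2) / (2 * 1.2**2)) - 2.0 * np.exp(-((x - 12.0) ** 2) / (2 * 1.5**2))


def run_pipeline(config: RunConfig, stages=ALL_STAGES, outdir="bindscape_out") -> Path:
    """Run the requested stages and write artifacts + summary.json.

    Later stages consume products of earlier ones; requesting a stage whose
    inputs are not available (e.g. ``contacts`` without ``simulate``) raises
    before any computation starts.
    """
    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    need_sim = {"contacts", "density", "sketchmap", "poses"} & set(stages)
    if need_sim and "simulate" not in stages:
        raise ValueError(f"stages {sorted(need_sim)} require the 'simulate' stage")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    logging.basicConfig(filename=outdir / "run.log", level=logging.INFO, force=True)
    log.info("bindscape %s, seed %d, stages %s", __version__, config.seed, stages)

    summary: dict = {"version": __version__, "seed": config.seed, "stages": stages}
    trajs = None
    grid = None
    sites = config.sites()
    lig_sel = synth.LIGAND_SEL
    core_sel = synth.LIGAND_CORE_SEL
    rec_sel = synth.RECEPTOR_SEL

    if "simulate" in stages:
        sim = synth.SimConfig(
            sites=sites,
            n_replicas=config.n_replicas,
            n_steps=config.n_steps,
            tail_length=config.tail_length,
            tail_rigid=config.tail_rigid,
            min_start_separation=config.min_start_separation,
            temperature=config.temperature,
            seed=config.seed,
        )
        trajs = synth.simulate_binding_replicas(sim)
        write_fixture(trajs[0], outdir / "replica_000.bsfx")
        summary["simulate"] = {
            "n_replicas": len(trajs),
            "n_frames": trajs[0].n_frames,
            "dt_ns": trajs[0].dt,
        }
        log.info("simulated %d replicas", len(trajs))

    if "contacts" in stages:
        profiles = [contacts_mod.contact_frequency(t, rec_sel, lig_sel, config.cutoff) for t in trajs]
        freq = np.mean([p.frequency for p in profiles], axis=0)
        mean_profile = contacts_mod.ContactProfile(profiles[0].residue_ids, freq)
        norm = contacts_mod.normalize_profile(mean_profile)
        if config.reference_profile:
            ref = synth.read_reference_profile(config.reference_profile)
        else:
            interface = _interface_residues(trajs[0], sites[0], rec_sel)
            ref = synth.generate_reference_profile(
                len(norm.residue_ids), interface, signal=1.0, noise_sd=0.05, seed=config.seed
            )
        rmse = contacts_mod.profile_rmse(norm, ref.to_numpy())
        records = [contacts_mod.encounter_time(t, rec_sel, lig_sel, config.cutoff) for t in trajs]
        stats = contacts_mod.encounter_statistics(
            records, n_resamples=config.bootstrap_resamples, seed=config.seed
        )
        norm.to_frame().to_csv(outdir / "contact_profile.csv", index=False)
        summary["contacts"] = {"rmse_vs_reference": rmse, "encounter": stats}
        log.info("contact RMSE %.3f, encounter mean %.1f ns", rmse, stats["mean_ns"])

    if "density" in stages:
        grid = density_mod.occupancy_grid(trajs, core_sel, spacing=config.grid_spacing)
        mask = density_mod.high_density_region(grid, config.density_threshold)
        labels, n_modes = density_mod.region_components(mask)
        weights = density_mod.component_weights(grid, labels, n_modes)
        density_mod.write_dx(grid, outdir / "occupancy.dx")
        summary["density"] = {
            "n_high_density_components": n_modes,
            "component_weight_fractions": (weights / weights.sum()).tolist() if n_modes else [],
            "max_normalized_density": float(grid.values.max()),
        }

    if "sketchmap" in stages:
        enc, frame_ids = _bound_encodings(trajs, sites, config)
        hd = sketch_mod.SigmoidParams(config.sigmoid_sigma, config.sigmoid_a_hd, config.sigmoid_b_hd)
        ld = sketch_mod.SigmoidParams(config.sigmoid_sigma, config.sigmoid_a_ld, config.sigmoid_b_ld)
        emb = sketch_mod.minimize_stress(enc, params_hd=hd, params_ld=ld, seed=config.seed)
        modes = sketch_mod.identify_modes(emb, min_population_fraction=config.min_population_fraction)
        import pandas as pd

        pd.DataFrame(
            {
                "replica": [r for r, _ in frame_ids],
                "frame": [f for _, f in frame_ids],
                "x": emb.points[:, 0],
                "y": emb.points[:, 1],
                "mode": emb.mode_labels,
            }
        ).to_csv(outdir / "sketchmap.csv", index=False)
        summary["sketchmap"] = {
            "stress": emb.stress,
            "modes": [{"label": m.label, "population": m.population} for m in modes],
        }

    if "pmf" in stages:
        if config.umbrella_metadata:
            dataset = synth.read_umbrella_dir(
                Path(config.umbrella_metadata).parent, temperature=config.temperature
            )
        else:
            centers = np.arange(1.0, 15.01, 0.5)
            dataset = synth.generate_umbrella_samples(
                _demo_potential, centers, k=10.0, n_per_window=2000,
                temperature=config.temperature, seed=config.seed,
            )
        profile = pmf_mod.mc_bootstrap_pmf_error(
            dataset, bin_width=config.bin_width, n_trials=config.mc_trials, seed=config.seed
        )
        dg = pmf_mod.binding_dG(profile, config.rc_bound, config.rc_unbound)
        profile.to_frame().to_csv(outdir / "pmf.csv", index=False)
        summary["pmf"] = {
            "dG_kcal_mol": dg.dG,
            "dG_error_kcal_mol": dg.dG_error,
            "rc_bound": dg.rc_bound,
            "rc_unbound": dg.rc_unbound,
        }

    if "poses" in stages:
        if grid is None:
            raise ValueError("poses stage requires the density stage")
        ref_coords = trajs[0].coordinates[-1].astype(float)
        pose_set = poses_mod.select_representatives(
            trajs, ref_coords, core_sel, rec_sel, grid,
            com_cutoff=config.com_cutoff, rmsd_cutoff=config.rmsd_cutoff,
            density_threshold=config.density_threshold, n=config.n_poses, seed=config.seed,
        )
        pose_set.to_frame().to_csv(outdir / "poses.csv", index=False)
        by_replica = {t.replica_id: t for t in trajs}
        frames = np.array([by_replica[r].coordinates[f] for r, f in pose_set.frames])
        write_models(trajs[0].topology, frames, outdir / "poses.pdb")
        summary["poses"] = {"selection_log": pose_set.selection_log}

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return outdir


def _interface_residues(traj, site: synth.BindingSiteSpec, rec_sel) -> list[int]:
    """Receptor residues whose bead lies within width+switch of a site center."""
    idx = traj.select(rec_sel)
    coords = traj.coordinates[0][idx]
    d = np.linalg.norm(coords - site.center_array, axis=1)
    near = d < (site.width + site.switch + 3.0)
    particles = traj.topology.particles
    return sorted({particles[i].residue_id for i, keep in zip(idx, near) if keep})


def _bound_encodings(trajs, sites, config: RunConfig):
    """Min-distance encodings of bound frames, subsampled deterministically."""
    top = trajs[0].topology
    lig_idx = top.select(synth.LIGAND_CORE_SEL)
    rec_idx = top.select(synth.RECEPTOR_SEL)
    groups_a = [np.array([i]) for i in lig_idx]
    n_b = min(11, len(rec_idx))
    groups_b = [np.array([i]) for i in rec_idx[np.linspace(0, len(rec_idx) - 1, n_b).astype(int)]]
    rows, ids = [], []
    for t in trajs:
        com = synth.ligand_com(t)
        assign = synth.site_occupancy(com, sites, discard_until_bound=True)
        for f in np.flatnonzero(assign >= 0):
            rows.append((t, f))
            ids.append((t.replica_id, int(f)))
    if len(rows) < 3:
        raise ValueError("not enough bound frames to embed; extend the simulation")
    if len(rows) > config.max_embed_points:
        step = len(rows) / config.max_embed_points
        keep = [int(i * step) for i in range(config.max_embed_points)]
        rows = [rows[i] for i in keep]
        ids = [ids[i] for i in keep]
    enc = np.array(
        [sketch_mod.encode_min_distances(t.coordinates[f], groups_a, groups_b).vector for t, f in rows]
    )
    return enc, ids
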