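"""Inter-protein contact statistics.

A residue of protein A "contacts" protein B in a frame iff the minimum
particle-particle distance from that residue to any B particle is below the
cutoff (7 Å by default, the standard native-contact cutoff at coarse-grained
resolution).  Contact frequencies are per-residue fractions of frames;
profiles are compared to per-residue reference perturbation data (e.g. NMR
chemical-shift perturbations) via RMSE after max-normalizing both.  Replica
statistics (encounter-time means etc.) use a bootstrap over replicas
(10000 resamples of sample size n by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .trajectory_io import Selection, SelectionError, Trajectory

__all__ = [
    "ContactProfile",
    "EncounterRecord",
    "contact_frequency",
    "normalize_profile",
    "profile_rmse",
    "encounter_time",
    "domain_contact_timeseries",
    "bootstrap_mean_sem",
    "encounter_statistics",
]

DEFAULT_CUTOFF = 7.0

_CHUNK_ELEMENTS = 4_000_000


@dataclass
class ContactProfile:
    """Per-residue contact frequency for one protein.

    ``residue_ids`` are author-style residue numbers (one chain); frequencies
    live in [0, 1] before normalization.  ``bootstrap_sem`` is optional and
    aligned with ``residue_ids``.
    """

    residue_ids: list[int]
    frequency: np.ndarray
    normalized: bool = False
    bootstrap_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        if len(self.residue_ids) != len(self.frequency):
            raise ValueError("residue_ids and frequency lengths differ")
        if not self.normalized and (self.frequency.min(initial=0.0) < 0 or self.frequency.max(initial=0.0) > 1):
            raise ValueError("raw contact frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue": self.residue_ids, "frequency": self.frequency})
        if self.bootstrap_sem is not None:
            df["sem"] = self.bootstrap_sem
        return df


@dataclass(frozen=True)
class EncounterRecord:
    """First inter-protein contact time of one replica (None if never)."""

    replica_id: int
    encounter_time: float | None
    definition: str = "any-any"

    def __post_init__(self) -> None:
        if self.encounter_time is not None and self.encounter_time < 0:
            raise ValueError("encounter_time must be >= 0 when present")


def _resolve_pair(traj: Trajectory, sel_a, sel_b) -> tuple[np.ndarray, np.ndarray]:
    idx_a = traj.select(sel_a) if isinstance(sel_a, (str, Selection)) else np.asarray(sel_a, dtype=np.intp)
    idx_b = traj.select(sel_b) if isinstance(sel_b, (str, Selection)) else np.asarray(sel_b, dtype=np.intp)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("contact analysis requires nonempty selections on both sides")
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact selections must be disjoint")
    return idx_a, idx_b


def _min_dist_frames(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-frame (n_frames, n_a) minimum distance of each A particle to any B."""
    n_frames = coords.shape[0]
    out = np.empty((n_frames, idx_a.size))
    chunk = max(1, _CHUNK_ELEMENTS // max(1, idx_a.size * idx_b.size))
    for start in range(0, n_frames, chunk):
        sl = slice(start, min(start + chunk, n_frames))
        diff = coords[sl][:, idx_a, None, :] - coords[sl][:, None, idx_b, :]
        out[sl] = np.sqrt(np.sum(diff * diff, axis=-1)).min(axis=2)
    return out


def contact_frequency(
    traj: Trajectory, sel_a, sel_b, cutoff: float = DEFAULT_CUTOFF
) -> ContactProfile:
    """Per-residue contact frequency of the A selection against B.

    Frequency of a residue = fraction of frames in which any of its particles
    is within ``cutoff`` Å of any B particle.
    """
    if traj.n_frames == 0:
        raise ValueError("contact_frequency: trajectory has zero frames")
    idx_a, idx_b = _resolve_pair(traj, sel_a, sel_b)
    min_d = _min_dist_frames(traj.coordinates, idx_a, idx_b)  # (F, nA)
    particles = traj.topology.particles
    keys: list[tuple[str, int]] = []
    cols: dict[tuple[str, int], list[int]] = {}
    for col, pi in enumerate(idx_a):
        key = (particles[pi].chain_id, particles[pi].residue_id)
        if key not in cols:
            keys.append(key)
            cols[key] = []
        cols[key].append(col)
    freq = np.array(
        [np.mean(min_d[:, cols[k]].min(axis=1) < cutoff) for k in keys]
    )
    return ContactProfile(residue_ids=[k[1] for k in keys], frequency=freq)


def normalize_profile(profile: ContactProfile) -> ContactProfile:
    """Divide by the largest value so the profile maximum is 1.

    An all-zero profile is returned unchanged (flagged normalized) with a
    warning.  Calling this on an already-normalized profile is an error.
    """
    if profile.normalized:
        raise ValueError("profile is already normalized")
    peak = profile.frequency.max(initial=0.0)
    if peak == 0.0:
        warnings.warn("normalize_profile: all-zero profile left unchanged", stacklevel=2)
        return replace(profile, normalized=True)
    return replace(profile, frequency=profile.frequency / peak, normalized=True)


def profile_rmse(profile: ContactProfile, reference) -> float:
    """RMSE between a normalized contact profile and a reference profile.

    ``sqrt(sum_i (CG_i - REF_i)² / N)`` with the reference max-normalized by
    its own largest value first, mirroring the contact-profile normalization
    so both vectors live on [0, 1].
    """
    if not profile.normalized:
        raise ValueError("profile_rmse expects a normalized ContactProfile")
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 1 or len(ref) == 0:
        raise ValueError("reference must be a nonempty 1D vector")
    if len(ref) != len(profile.frequency):
        raise ValueError(f"length mismatch: profile {len(profile.frequency)} vs reference {len(ref)}")
    peak = ref.max(initial=0.0)
    if peak > 0:
        ref = ref / peak
    return float(np.sqrt(np.mean((profile.frequency - ref) ** 2)))


def encounter_time(
    traj: Trajectory, sel_a, sel_b, cutoff: float = DEFAULT_CUTOFF, definition: str = "any-any"
) -> EncounterRecord:
    """Time of the first inter-selection contact (None if it never forms).

    The time is ``dt × index`` of the first frame with any cross-selection
    particle pair below ``cutoff``.
    """
    if traj.n_frames == 0:
        raise ValueError("encounter_time: trajectory has zero frames")
    idx_a, idx_b = _resolve_pair(traj, sel_a, sel_b)
    min_d = _min_dist_frames(traj.coordinates, idx_a, idx_b).min(axis=1)
    hits = np.flatnonzero(min_d < cutoff)
    t = float(hits[0] * traj.dt) if hits.size else None
    return EncounterRecord(replica_id=traj.replica_id, encounter_time=t, definition=definition)


def domain_contact_timeseries(
    traj: Trajectory,
    ligand_sel,
    receptor_sel,
    cutoff: float = DEFAULT_CUTOFF,
    window: int = 1,
) -> pd.DataFrame:
    """Per-domain residue-pair contact counts over time.

    For every frame and every domain tag carried by the ligand selection,
    counts the (ligand residue, receptor residue) pairs in contact, then
    block-averages over ``window`` frames.  Every selected ligand particle
    must carry a domain tag.
    """
    idx_l, idx_r = _resolve_pair(traj, ligand_sel, receptor_sel)
    particles = traj.topology.particles
    for pi in idx_l:
        if not particles[pi].domain_tag:
            raise ValueError(f"ligand particle {pi} carries no domain tag")
    if window < 1:
        raise ValueError("window must be >= 1")

    # group ligand particles by residue, tagging each residue with its domain
    res_keys: list[tuple[str, int]] = []
    res_cols: dict[tuple[str, int], list[int]] = {}
    res_domain: dict[tuple[str, int], str] = {}
    for col, pi in enumerate(idx_l):
        key = (particles[pi].chain_id, particles[pi].residue_id)
        if key not in res_cols:
            res_keys.append(key)
            res_cols[key] = []
            res_domain[key] = particles[pi].domain_tag
        res_cols[key].append(col)
    rec_keys: list[tuple[str, int]] = []
    rec_cols: dict[tuple[str, int], list[int]] = {}
    for col, pi in enumerate(idx_r):
        key = (particles[pi].chain_id, particles[pi].residue_id)
        if key not in rec_cols:
            rec_keys.append(key)
            rec_cols[key] = []
        rec_cols[key].append(col)

    coords = traj.coordinates
    diff = coords[:, idx_l, None, :] - coords[:, None, idx_r, :]
    dmat = np.sqrt(np.sum(diff * diff, axis=-1))  # (F, nL, nR)
    # reduce particle-level to residue-level minima
    res_min = np.stack([dmat[:, res_cols[k], :].min(axis=1) for k in res_keys], axis=1)  # (F, RL, nR)
    pair_min = np.stack([res_min[:, :, rec_cols[k]].min(axis=2) for k in rec_keys], axis=2)  # (F, RL, RR)
    in_contact = pair_min < cutoff

    domains = sorted({res_domain[k] for k in res_keys})
    series = {}
    for tag in domains:
        rows = [i for i, k in enumerate(res_keys) if res_domain[k] == tag]
        series[tag] = in_contact[:, rows, :].sum(axis=(1, 2)).astype(float)
    df = pd.DataFrame(series)
    if window > 1:
        n_blocks = len(df) // window
        if n_blocks == 0:
            raise ValueError("window longer than trajectory")
        df = df.iloc[: n_blocks * window].groupby(np.arange(n_blocks * window) // window).mean()
        df.index = (df.index + 0.5) * window * traj.dt
    else:
        df.index = traj.times
    df.index.name = "time_ns"
    return df


def bootstrap_mean_sem(
    values, n_resamples: int = 10_000, sample_size: int | None = None, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap mean and SEM of a replica-level statistic.

    Draws ``n_resamples`` resamples of ``sample_size`` (default: len(values))
    with replacement; returns (mean of resample means, SD of resample means).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_mean_sem: empty input")
    if sample_size is None:
        sample_size = values.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, sample_size))
    means = values[idx].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1))


def encounter_statistics(
    records: list[EncounterRecord],
    n_resamples: int = 10_000,
    sample_size: int | None = None,
    seed: int = 0,
) -> dict:
    """Bootstrap mean ± SEM of encounter times across replicas.

    Replicas that never formed a contact are excluded from the mean and
    reported separately under ``n_no_contact`` (dropping, not censoring).
    """
    times = np.array([r.encounter_time for r in records if r.encounter_time is not None])
    n_absent = sum(1 for r in records if r.encounter_time is None)
    if times.size == 0:
        raise ValueError("no replica formed a contact; encounter statistics undefined")
    mean, sem = bootstrap_mean_sem(times, n_resamples=n_resamples, sample_size=sample_size, seed=seed)
    return {"mean_ns": mean, "sem_ns": sem, "n_replicas": len(records), "n_no_contact": n_absent}
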