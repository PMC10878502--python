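"""Umbrella-sampling free energies: WHAM, bootstrap errors, binding ΔG.

The weighted histogram analysis method (WHAM) combines biased histograms
from harmonic umbrella windows into one unbiased probability profile by
iterating the self-consistent equations

    P(x_b) = Σ_w n_w(x_b) / Σ_w N_w exp[(f_w − U_w(x_b)) / kBT]
    f_w    = −kBT ln Σ_b P(x_b) exp(−U_w(x_b) / kBT)

to convergence of the window shifts f_w.  The PMF is −kBT ln P with its
minimum set to zero.  Per-bin errors come from a Monte-Carlo bootstrap
(resample each window's points with replacement, re-solve WHAM, take the
per-bin SD over trials; 100 trials by default).  Binding ΔG is the PMF
difference between a bound and an unbound reaction-coordinate value
(1.5 and 14.5 Å by default) with errors added in quadrature.

``detect_gliding`` classifies an enforced dissociation series: a clean
dissociation loses inter-protein contacts monotonically as the windows move
out, whereas "gliding" (the ligand sliding over the receptor surface) keeps
forming new residue-pair contacts well into the pull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import ttest_ind

from .constants import kT as _kT
from .contacts import DEFAULT_CUTOFF, _resolve_pair
from .synthetic_data import UmbrellaDataset
from .trajectory_io import Trajectory

__all__ = [
    "PMFProfile",
    "BindingDG",
    "ConvergenceError",
    "wham",
    "mc_bootstrap_pmf_error",
    "binding_dG",
    "detect_gliding",
    "GlidingReport",
    "welch_ttest",
]


class ConvergenceError(RuntimeError):
    """WHAM iteration did not reach tolerance within max_iter."""


@dataclass
class PMFProfile:
    """Free energy (kcal/mol) on reaction-coordinate bins (Å).

    Unsampled bins carry NaN free energy.  ``reference_convention`` records
    how the additive constant was fixed.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    error: np.ndarray | None = None
    reference_convention: str = "minimum-zero"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.error is not None and np.any(np.asarray(self.error) < -1e-12):
            raise ValueError("errors must be nonnegative")

    def nearest_bin(self, rc: float) -> int:
        """Index of the nearest sampled (finite) bin; error outside range."""
        if rc < self.bin_centers[0] - 1e-9 or rc > self.bin_centers[-1] + 1e-9:
            raise ValueError(
                f"RC = {rc} Å outside profile range "
                f"[{self.bin_centers[0]:.3g}, {self.bin_centers[-1]:.3g}] Å"
            )
        finite = np.isfinite(self.free_energy)
        if not finite.any():
            raise ValueError("profile has no sampled bins")
        idx = np.flatnonzero(finite)
        return int(idx[np.argmin(np.abs(self.bin_centers[idx] - rc))])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rc": self.bin_centers, "pmf": self.free_energy})
        if self.error is not None:
            df["error"] = self.error
        return df


@dataclass
class BindingDG:
    """PMF-derived binding free energy between two RC anchor points.

    ``rc_bound``/``rc_unbound`` record the actual bin centers used for the
    nearest-bin lookup.
    """

    dG: float
    dG_error: float
    rc_bound: float
    rc_unbound: float


def _histogram(data: UmbrellaDataset, bin_width: float):
    samples = [np.asarray(w[2], dtype=float) for w in data.windows]
    pooled_min = min(s.min() for s in samples)
    pooled_max = max(s.max() for s in samples)
    lo = np.floor(pooled_min / bin_width) * bin_width
    n_bins = int(np.ceil((pooled_max - lo) / bin_width)) or 1
    edges = lo + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.stack([np.histogram(s, bins=edges)[0] for s in samples])  # (W, B)
    return centers, edges, hist


def _check_overlap(hist: np.ndarray) -> None:
    for w in range(hist.shape[0] - 1):
        if not np.any((hist[w] > 0) & (hist[w + 1] > 0)):
            warnings.warn(
                f"umbrella windows {w} and {w + 1} share no occupied bin; "
                "PMF pieces may be poorly connected",
                stacklevel=3,
            )


def _solve_wham(hist, centers, window_centers, window_k, kt, tol, max_iter, f_init=None):
    n_w = hist.shape[0]
    n_samples = hist.sum(axis=1).astype(float)  # N_w
    bias = 0.5 * window_k[:, None] * (centers[None, :] - window_centers[:, None]) ** 2  # (W, B)
    log_nw = np.log(n_samples)[:, None]
    h_tot = hist.sum(axis=0).astype(float)  # (B,)
    occupied = h_tot > 0
    log_h = np.full_like(h_tot, -np.inf)
    log_h[occupied] = np.log(h_tot[occupied])
    f = np.zeros(n_w) if f_init is None else np.array(f_init, dtype=float)
    for iteration in range(max_iter):
        # log denominator per bin: ln Σ_w N_w exp((f_w − U_wb)/kT)
        log_denom = logsumexp(log_nw + (f[:, None] - bias) / kt, axis=0)
        log_p = log_h - log_denom
        f_new = -kt * logsumexp(log_p[None, :] - bias / kt, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {delta:.3g} kcal/mol)"
        )
    log_p = log_h - logsumexp(log_nw + (f[:, None] - bias) / kt, axis=0)
    pmf = np.full(len(centers), np.nan)
    pmf[occupied] = -kt * log_p[occupied]
    pmf -= np.nanmin(pmf)
    return pmf, f


def wham(
    data: UmbrellaDataset,
    bin_width: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    f_init=None,
) -> PMFProfile:
    """Self-consistent WHAM solution of an umbrella dataset.

    Convergence is max |Δf_w| < ``tol`` kcal/mol on the window free-energy
    shifts.  Adding a constant to every window's bias leaves the result
    unchanged (gauge invariance).
    """
    if not data.windows:
        raise ValueError("wham: dataset has no windows")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    kt = _kT(data.temperature)
    centers, _, hist = _histogram(data, bin_width)
    if len(centers) == 0:
        raise ValueError("wham: empty bin range")
    _check_overlap(hist)
    window_centers = np.array([w[0] for w in data.windows])
    window_k = np.array([w[1] for w in data.windows])
    pmf, _ = _solve_wham(hist, centers, window_centers, window_k, kt, tol, max_iter, f_init)
    return PMFProfile(bin_centers=centers, free_energy=pmf)


def mc_bootstrap_pmf_error(
    data: UmbrellaDataset,
    bin_width: float = 0.1,
    n_trials: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Monte-Carlo bootstrap PMF errors (per-bin SD over resampling trials).

    Each trial resamples every window's points with replacement and re-solves
    WHAM on the same bin grid; the returned profile carries the original PMF
    plus per-bin errors.  Seeded and reproducible.
    """
    if not data.windows:
        raise ValueError("mc_bootstrap_pmf_error: dataset has no windows")
    kt = _kT(data.temperature)
    centers, edges, hist = _histogram(data, bin_width)
    window_centers = np.array([w[0] for w in data.windows])
    window_k = np.array([w[1] for w in data.windows])
    base_pmf, base_f = _solve_wham(hist, centers, window_centers, window_k, kt, tol, max_iter)
    rng = np.random.default_rng(seed)
    trials = np.full((n_trials, len(centers)), np.nan)
    for t in range(n_trials):
        hist_t = np.stack(
            [
                np.histogram(rng.choice(w[2], size=len(w[2]), replace=True), bins=edges)[0]
                for w in data.windows
            ]
        )
        trials[t], _ = _solve_wham(
            hist_t, centers, window_centers, window_k, kt, tol, max_iter, f_init=base_f
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        err = np.nanstd(trials, axis=0, ddof=1)
    err[~np.isfinite(base_pmf)] = np.nan
    return PMFProfile(bin_centers=centers, free_energy=base_pmf, error=np.nan_to_num(err, nan=0.0))


def binding_dG(profile: PMFProfile, rc_bound: float = 1.5, rc_unbound: float = 14.5) -> BindingDG:
    """ΔG = PMF(bound) − PMF(unbound) at the nearest sampled bins.

    Errors (when the profile carries them) combine in independent quadrature.
    """
    if rc_bound == rc_unbound:
        raise ValueError("rc_bound and rc_unbound must differ")
    ib = profile.nearest_bin(rc_bound)
    iu = profile.nearest_bin(rc_unbound)
    dg = float(profile.free_energy[ib] - profile.free_energy[iu])
    if profile.error is not None:
        err = float(np.sqrt(profile.error[ib] ** 2 + profile.error[iu] ** 2))
    else:
        err = float("nan")
    return BindingDG(
        dG=dg,
        dG_error=err,
        rc_bound=float(profile.bin_centers[ib]),
        rc_unbound=float(profile.bin_centers[iu]),
    )


@dataclass
class GlidingReport:
    """Outcome of the new-contact analysis over an umbrella window series."""

    classification: str  # "dissociation" or "gliding"
    new_contact_counts: list[int]
    late_fraction: float


def detect_gliding(
    window_trajectories: list[tuple[float, Trajectory]],
    sel_a,
    sel_b,
    cutoff: float = DEFAULT_CUTOFF,
    late_fraction_threshold: float = 0.10,
) -> GlidingReport:
    """Classify an enforced-dissociation window series.

    ``window_trajectories`` is a list of (window center Å, Trajectory) in
    increasing-center order.  For each window, the residue pairs in contact
    in any frame are collected; pairs never seen in earlier windows count as
    "new".  If more than ``late_fraction_threshold`` of all observed pairs
    first appear in the upper half of the series, the ligand is still forming
    fresh interfaces while being pulled away: gliding.  Otherwise the series
    is a clean dissociation.
    """
    centers = [c for c, _ in window_trajectories]
    if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
        raise ValueError("windows must be ordered by strictly increasing center")
    new_counts: list[int] = []
    seen: set[tuple] = set()
    first_window: dict[tuple, int] = {}
    for w, (_, traj) in enumerate(window_trajectories):
        idx_a, idx_b = _resolve_pair(traj, sel_a, sel_b)
        particles = traj.topology.particles
        pairs: set[tuple] = set()
        # residue-pair resolution: particle-level would over-count
        diff = traj.coordinates[:, idx_a, None, :] - traj.coordinates[:, None, idx_b, :]
        dmat = np.sqrt(np.sum(diff * diff, axis=-1))
        contact_any = (dmat < cutoff).any(axis=0)
        for ia, ib in zip(*np.nonzero(contact_any)):
            ra = (particles[idx_a[ia]].chain_id, particles[idx_a[ia]].residue_id)
            rb = (particles[idx_b[ib]].chain_id, particles[idx_b[ib]].residue_id)
            pairs.add((ra, rb))
        fresh = pairs - seen
        new_counts.append(len(fresh))
        for p in fresh:
            first_window[p] = w
        seen |= pairs
    total = len(seen)
    n_windows = len(window_trajectories)
    late = sum(1 for w in first_window.values() if w >= n_windows / 2.0)
    late_fraction = late / total if total else 0.0
    classification = "gliding" if late_fraction > late_fraction_threshold else "dissociation"
    return GlidingReport(classification=classification, new_contact_counts=new_counts, late_fraction=late_fraction)


def welch_ttest(set_a, set_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided) between two ΔG sets."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_ttest: each set needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("welch_ttest: both sets have zero variance with different means")
    t, p = ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
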