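"""Sketch-map embedding of binding configurations.

Each frame is encoded as a vector of inter-protein minimum distances between
rigid structural elements of the two partners (N = nA + nB entries: for each
ligand element the minimum distance to any receptor element particle, then
the reverse).  The 2D embedding minimizes the sketch-map stress

    chi² = Σ_{i<j} w_i w_j [F(R_ij) − f(r_ij)]² / Σ_{i<j} w_i w_j

where R_ij / r_ij are high- and low-dimensional pairwise distances and F, f
are sigmoid transfer functions s(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a}
that map distances into [0, 1], focusing the embedding on near-neighbor
structure.  Binding modes are kernel-density maxima of the embedded cloud:
the most populated cluster is the "prime" mode, other clusters above a
population floor are "secondary" modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import MeanShift, estimate_bandwidth

from .trajectory_io import Trajectory

__all__ = [
    "SigmoidParams",
    "DistanceEncoding",
    "Embedding",
    "Mode",
    "encode_min_distances",
    "encode_trajectory",
    "sigmoid",
    "stress",
    "minimize_stress",
    "identify_modes",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Sigmoid shape: s(sigma) = 1/2 for any exponents a, b > 0."""

    sigma: float = 6.0
    a_exp: float = 2.0
    b_exp: float = 6.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.a_exp <= 0 or self.b_exp <= 0:
            raise ValueError("sigma, a_exp and b_exp must all be positive")


#: Defaults for the high-dimensional (F) and low-dimensional (f) transfer
#: functions; sigma in Å on the distance-encoding scale.
DEFAULT_HD_PARAMS = SigmoidParams(sigma=6.0, a_exp=2.0, b_exp=6.0)
DEFAULT_LD_PARAMS = SigmoidParams(sigma=6.0, a_exp=2.0, b_exp=2.0)


@dataclass
class DistanceEncoding:
    """Minimum-distance vector of one frame (D_1..D_N, Å)."""

    frame_index: int
    vector: np.ndarray
    n_groups_a: int
    n_groups_b: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if len(self.vector) != self.n_groups_a + self.n_groups_b:
            raise ValueError("encoding length must equal |groupsA| + |groupsB|")
        if np.any(self.vector < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class Embedding:
    """2D sketch-map coordinates of n encoded frames."""

    points: np.ndarray
    weights: np.ndarray
    stress: float
    params_hd: SigmoidParams
    params_ld: SigmoidParams
    seed: int
    mode_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")


def _group_indices(groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        idx = np.asarray(g, dtype=np.intp).ravel()
        if idx.size == 0:
            raise ValueError("encoding groups must be nonempty")
        out.append(idx)
    return out


def encode_min_distances(frame_coords: np.ndarray, groups_a, groups_b, frame_index: int = 0) -> DistanceEncoding:
    """Encode one frame: D_i = min distance from element i to the other protein.

    For each group in ``groups_a`` (ligand rigid elements) the minimum
    distance from any of its particles to any particle of any B group, then
    the reverse for ``groups_b``.
    """
    coords = np.asarray(frame_coords, dtype=float)
    ga = _group_indices(groups_a)
    gb = _group_indices(groups_b)
    all_a = np.concatenate(ga)
    all_b = np.concatenate(gb)
    dmat = cdist(coords[all_a], coords[all_b])
    # row/col offsets of each group inside the concatenated index lists
    vec = np.empty(len(ga) + len(gb))
    row = 0
    for i, g in enumerate(ga):
        vec[i] = dmat[row : row + g.size, :].min()
        row += g.size
    col = 0
    for j, g in enumerate(gb):
        vec[len(ga) + j] = dmat[:, col : col + g.size].min()
        col += g.size
    return DistanceEncoding(frame_index=frame_index, vector=vec, n_groups_a=len(ga), n_groups_b=len(gb))


def encode_trajectory(traj: Trajectory, groups_a, groups_b, frames=None) -> np.ndarray:
    """Stack encodings of many frames into an (n_frames, N) array."""
    if frames is None:
        frames = range(traj.n_frames)
    return np.array(
        [encode_min_distances(traj.coordinates[f], groups_a, groups_b, frame_index=f).vector for f in frames]
    )


def sigmoid(r, params: SigmoidParams) -> np.ndarray:
    """s(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a}; s(0)=0, s(σ)=1/2, s(∞)=1."""
    r = np.asarray(r, dtype=float)
    a, b, sigma = params.a_exp, params.b_exp, params.sigma
    c = 2.0 ** (a / b) - 1.0
    return 1.0 - (1.0 + c * (r / sigma) ** a) ** (-b / a)


def _sigmoid_deriv(r, params: SigmoidParams) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    a, b, sigma = params.a_exp, params.b_exp, params.sigma
    c = 2.0 ** (a / b) - 1.0
    u = c * (r / sigma) ** a
    return b * c * r ** (a - 1.0) / sigma**a * (1.0 + u) ** (-b / a - 1.0)


def _prepare(encodings, weights):
    enc = np.asarray(encodings, dtype=float)
    if enc.ndim != 2:
        raise ValueError("encodings must be a 2D (n_points, N) array")
    n = enc.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError(f"weights shape {weights.shape} does not match {n} points")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return enc, weights


def stress(
    points_2d,
    encodings,
    weights=None,
    params_hd: SigmoidParams = DEFAULT_HD_PARAMS,
    params_ld: SigmoidParams = DEFAULT_LD_PARAMS,
) -> float:
    """Normalized weighted sketch-map stress over unordered pairs.

    Invariant under rigid transforms (rotation/translation/reflection) of the
    2D points, since only pairwise distances enter.
    """
    enc, w = _prepare(encodings, weights)
    pts = np.asarray(points_2d, dtype=float)
    if pts.shape != (enc.shape[0], 2):
        raise ValueError(f"points_2d must be ({enc.shape[0]}, 2); got {pts.shape}")
    f_hd = sigmoid(pdist(enc), params_hd)
    f_ld = sigmoid(pdist(pts), params_ld)
    iu = np.triu_indices(enc.shape[0], k=1)
    wpair = np.outer(w, w)[iu]
    return float(np.sum(wpair * (f_hd - f_ld) ** 2) / np.sum(wpair))


def _stress_and_grad(x, f_hd_mat, wmat, wsum, params_ld, n):
    pts = x.reshape(n, 2)
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    np.fill_diagonal(r, 1.0)  # diagonal excluded by wmat's zero diagonal
    r = np.maximum(r, 1e-9)  # coincident pairs: resid -> 0 faster than 1/r
    f_ld = sigmoid(r, params_ld)
    fp = _sigmoid_deriv(r, params_ld)
    resid = f_hd_mat - f_ld
    np.fill_diagonal(resid, 0.0)
    chi2 = np.sum(wmat * resid * resid) / wsum
    coef = wmat * resid * fp / r  # (n, n)
    grad = -4.0 / wsum * np.sum(coef[:, :, None] * diff, axis=1)
    return chi2, grad.ravel()


def minimize_stress(
    encodings,
    weights=None,
    params_hd: SigmoidParams = DEFAULT_HD_PARAMS,
    params_ld: SigmoidParams = DEFAULT_LD_PARAMS,
    n_starts: int = 4,
    seed: int = 0,
    maxiter: int = 1000,
) -> Embedding:
    """Best-of-``n_starts`` gradient minimization of the sketch-map stress.

    Each start is a seeded random 2D scatter (plus, for the first start, a
    PCA projection of the encodings, usually an excellent initial guess);
    L-BFGS-B refines each and the lowest-stress solution wins.  Deterministic
    under ``seed``.
    """
    enc, w = _prepare(encodings, weights)
    n = enc.shape[0]
    if n < 3:
        raise ValueError("minimize_stress needs at least 3 points")
    f_hd_mat = sigmoid(squareform(pdist(enc)), params_hd)
    wmat = np.outer(w, w)
    np.fill_diagonal(wmat, 0.0)
    wsum = wmat.sum()
    rng = np.random.default_rng(seed)

    # PCA initialization: center, project on top-2 principal axes
    centered = enc - enc.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pca0 = centered @ vt[:2].T

    best = None
    for start in range(n_starts):
        x0 = pca0 if start == 0 else rng.normal(scale=params_ld.sigma, size=(n, 2))
        res = minimize(
            _stress_and_grad,
            x0.ravel(),
            args=(f_hd_mat, wmat, wsum, params_ld, n),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError(f"sketch-map optimizer diverged on start {start}: {res.message}")
        if best is None or res.fun < best.fun:
            best = res
    return Embedding(
        points=best.x.reshape(n, 2),
        weights=w,
        stress=float(best.fun),
        params_hd=params_hd,
        params_ld=params_ld,
        seed=seed,
    )


@dataclass
class Mode:
    """One binding mode: a cluster of embedded configurations."""

    label: str  # "prime" or "secondary"
    members: np.ndarray  # point indices
    population: float  # fraction of all embedded points
    center: np.ndarray  # 2D cluster center


def identify_modes(
    embedding: Embedding,
    bandwidth: float | None = None,
    min_population_fraction: float = 0.05,
) -> list[Mode]:
    """Cluster the 2D embedding into prime/secondary binding modes.

    Mean-shift clustering (kernel-density local maxima with nearest-maximum
    assignment) at the given bandwidth (estimated from the data when None).
    The most populated cluster is labeled ``prime``; every other cluster with
    population fraction >= ``min_population_fraction`` is ``secondary``.
    Smaller clusters are not reported.
    """
    pts = embedding.points
    if len(pts) == 0:
        raise ValueError("identify_modes: empty embedding")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if bandwidth is None:
        bandwidth = estimate_bandwidth(pts, quantile=0.25, random_state=0)
        if bandwidth <= 0:  # degenerate cloud (all points coincident)
            bandwidth = 1.0
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=False, cluster_all=True)
    labels = ms.fit_predict(pts)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)])
    modes: list[Mode] = []
    n = len(pts)
    for rank, c in enumerate(order):
        members = np.flatnonzero(labels == c)
        frac = members.size / n
        if rank == 0:
            modes.append(Mode("prime", members, frac, ms.cluster_centers_[c]))
        elif frac >= min_population_fraction:
            modes.append(Mode("secondary", members, frac, ms.cluster_centers_[c]))
    emb_labels = np.full(n, -1)
    for i, m in enumerate(modes):
        emb_labels[m.members] = i
    embedding.mode_labels = emb_labels
    return modes
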