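"""Rigid-body superposition primitives shared by the density and pose modules."""

from __future__ import annotations

import numpy as np


class DegenerateSelectionError(ValueError):
    """Raised when a fitting selection is too small or (near-)collinear."""


def check_noncollinear(coords: np.ndarray, tol: float = 1e-8) -> None:
    """Require >= 3 points that span a plane (two nonzero principal axes)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise DegenerateSelectionError(
            f"superposition needs >= 3 points, got {coords.shape[0] if coords.ndim == 2 else 'malformed'}"
        )
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= tol * max(s[0], 1.0):
        raise DegenerateSelectionError("superposition points are collinear or coincident")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto ``target``.

    Returns a proper rotation (det = +1) and translation such that
    ``mobile @ R.T + t`` best fits ``target``.  Equal weights.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"coordinate shape mismatch: {mobile.shape} vs {target.shape}")
    check_noncollinear(mobile)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
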