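"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they check: rotation search by
direct numerical optimisation over a hand-written Rodrigues map (instead of
the SVD route), and a plain-loop RMSD recomputation for matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def rodrigues(axis_angle: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle (rotation) vector, written out."""
    v = np.asarray(axis_angle, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def fit_rmsd(P: np.ndarray, Q: np.ndarray, R: np.ndarray) -> float:
    """RMSD of centred P rotated by R against centred Q."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    d = Pc @ R.T - Qc
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 200,
                         seed: int = 0) -> float:
    """Minimum fit RMSD by rotation-space search: a coarse random grid of
    axis-angle vectors refined locally by Nelder-Mead."""
    rng = np.random.default_rng(seed)
    starts = [np.zeros(3)]
    for _ in range(n_starts):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        starts.append(axis * rng.uniform(0, np.pi))
    f = lambda rv: fit_rmsd(P, Q, rodrigues(rv))
    best_rv = min(starts, key=f)
    res = minimize(f, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000})
    return float(res.fun)


def kabsch_svd_reference(P: np.ndarray, Q: np.ndarray) -> float:
    """Closed-form minimum RMSD via a directly-written SVD Kabsch."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    return rodrigues(axis * rng.uniform(0, np.pi))


def apply_rigid(positions: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t along the last axis."""
    return positions @ R.T + t
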