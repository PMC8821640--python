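"""Small rigid-body and segment geometry helpers (internal)."""

from __future__ import annotations

import math

import numpy as np


def rotation_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ mobile.T + t ≈ target.

    Returns (R, t) minimizing RMSD; proper rotation enforced.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of b onto a after optimal rigid superposition."""
    R, t = kabsch(b, a)
    moved = b @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))


def fit_line_segment(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares center line of a point cloud, clipped to the cloud's extent.

    Returns the two segment endpoints.  The direction is the principal axis of
    the centered coordinates, sign-fixed to point along +z (ties: +x, +y).
    """
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    X = pts - c
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    d = Vt[0]
    for comp in (2, 0, 1):
        if abs(d[comp]) > 1e-12:
            if d[comp] < 0:
                d = -d
            break
    proj = X @ d
    return c + proj.min() * d, c + proj.max() * d


def segment_segment_distance(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimal distance between segments [p1, q1] and [p2, q2]."""
    p1, q1, p2, q2 = (np.asarray(v, float) for v in (p1, q1, p2, q2))
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e = d1 @ d1, d2 @ d2
    f = d2 @ r
    eps = 1e-12
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= eps:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = float(np.clip((b * f - c * e) / denom, 0.0, 1.0)) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, float(np.clip(-c / a, 0.0, 1.0))
            elif t > 1.0:
                t, s = 1.0, float(np.clip((b - c) / a, 0.0, 1.0))
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))
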