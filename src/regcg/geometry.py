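"""Rigid-body superposition helpers (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None):
    """Optimal rotation + translation of ``mobile`` onto ``target``.

    Returns (rotated_mobile, rmsd).  Both inputs are (n, 3); ``weights``
    (n,) weights both the centroid and the least-squares fit.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (n, 3)")
    if weights is None:
        w = np.full(mobile.shape[0], 1.0 / mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    mc = mobile - np.sum(w[:, None] * mobile, axis=0)
    tc = target - np.sum(w[:, None] * target, axis=0)
    h = (w[:, None] * mc).T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = mc @ rot.T + np.sum(w[:, None] * target, axis=0)
    dev = aligned - target
    rmsd = float(np.sqrt(np.sum(w * np.sum(dev * dev, axis=1))))
    return aligned, rmsd


def align_frames(frames: np.ndarray, reference: np.ndarray, weights=None) -> np.ndarray:
    """Superpose every frame of (n_frames, n, 3) onto ``reference``."""
    out = np.empty_like(frames)
    for k in range(frames.shape[0]):
        out[k], _ = kabsch(frames[k], reference, weights)
    return out
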