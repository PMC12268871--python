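"""Ordered collections of bead-coordinate frames.

An :class:`Ensemble` is the common currency of the package: the mapped
reference trajectory, the frames produced by the Langevin sampler, and the
dense weighted "grids" used by the quadrature oracles in the test-suite are
all ensembles.  Coordinates are in nm.  Frames may carry statistical
weights (uniform by default), which every ensemble average in the training
machinery respects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Ensemble:
    """Frames of bead coordinates with optional weights and recorded observables.

    Parameters
    ----------
    coords
        Array of shape (n_frames, n_beads, 3), nm.
    box
        Optional periodic box lengths (3,), nm; pass-through metadata only.
    weights
        Optional per-frame statistical weights; need not be normalized.
    v_bind
        Optional per-frame inter-monomer binding energy, kJ/mol.
    du_dtheta
        Optional per-frame gradient of the potential with respect to the
        trainable parameters, shape (n_frames, n_theta), kJ mol^-1 per
        unit of theta.
    """

    coords: np.ndarray
    box: np.ndarray | None = None
    weights: np.ndarray | None = None
    v_bind: np.ndarray | None = None
    du_dtheta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_beads, 3), got {self.coords.shape}"
            )
        if self.n_frames == 0:
            raise ValueError("ensemble must contain at least one frame")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (self.n_frames,):
                raise ValueError("weights must be one scalar per frame")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be non-negative with positive sum")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def normalized_weights(self) -> np.ndarray:
        """Per-frame weights normalized to sum to 1 (uniform if unset)."""
        if self.weights is None:
            return np.full(self.n_frames, 1.0 / self.n_frames)
        return self.weights / self.weights.sum()

    def average(self, per_frame: np.ndarray) -> np.ndarray:
        """Weighted ensemble average of a per-frame quantity."""
        per_frame = np.asarray(per_frame, dtype=np.float64)
        if per_frame.shape[0] != self.n_frames:
            raise ValueError("per-frame array does not match frame count")
        w = self.normalized_weights()
        return np.tensordot(w, per_frame, axes=(0, 0))
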