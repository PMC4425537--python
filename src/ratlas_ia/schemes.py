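"""Diffusion gradient schemes (b-values and unit direction vectors).

A scheme pairs each frame of a 4D diffusion acquisition with a b-value in
s/mm^2 and a gradient direction.  b0 frames carry a zero vector.  The
single-shell acquisition emulated throughout the package is 10 non-collinear
directions at b = 1000 s/mm^2 plus one unweighted (b0) frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientScheme",
    "ten_direction_scheme",
    "load_bvals_bvecs",
    "save_bvals_bvecs",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientScheme:
    """Per-frame b-values (s/mm^2) and unit gradient directions.

    Invariants enforced at construction: equal lengths, unit-norm non-b0
    vectors (within 1e-6), and at least 6 non-collinear diffusion directions
    (full-rank tensor design) plus at least one b0 frame.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) lengths differ"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        dwi = ~self.b0_mask
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-b0 gradient vectors must be unit norm (tol 1e-6)")
        if not np.any(self.b0_mask):
            raise ValueError("scheme needs at least one b0 frame")
        if np.linalg.matrix_rank(self.design_matrix()[dwi, :6]) < 6:
            raise ValueError("scheme needs >=6 non-collinear diffusion directions")

    @property
    def n_frames(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Log-linear tensor design: ln S = X @ [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz, ln S0].

        Diffusivities are expressed in 1e-3 mm^2/s, so the b-value is scaled
        by 1e-3 inside the matrix.
        """
        b = self.bvals[:, None] * 1e-3
        g = self.bvecs
        return np.hstack(
            [
                -b * g[:, [0]] ** 2,
                -b * g[:, [1]] ** 2,
                -b * g[:, [2]] ** 2,
                -2 * b * g[:, [0]] * g[:, [1]],
                -2 * b * g[:, [0]] * g[:, [2]],
                -2 * b * g[:, [1]] * g[:, [2]],
                np.ones((self.n_frames, 1)),
            ]
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors via the golden-angle spiral."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    v = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def ten_direction_scheme(bval: float = 1000.0, n_directions: int = 10) -> GradientScheme:
    """Single-shell scheme: one b0 followed by ``n_directions`` at ``bval``."""
    dirs = _fibonacci_sphere(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(bval))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientScheme(bvals, bvecs)


def save_bvals_bvecs(scheme: GradientScheme, bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> None:
    """Write FSL-style whitespace text: one row of b-values, three rows of components."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def load_bvals_bvecs(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)
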