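"""Rigid-body registration of subject volumes to an atlas template.

A 6-parameter rigid transform (3 rotation angles in degrees, 3 translations
in mm) maps moving-image world coordinates into fixed-image world
coordinates.  Estimation minimizes negative normalized cross-correlation
(NCC) with a derivative-free Nelder-Mead simplex over a 2-level
coarse-to-fine pyramid; same-modality b0-to-b0 alignment makes NCC a smooth,
well-behaved cost.  Everything is deterministic given the initial guess.

Label volumes are resampled with nearest-neighbour interpolation only, which
preserves the label value set exactly; trilinear interpolation is reserved
for intensity maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

__all__ = ["RigidTransform", "estimate_rigid", "resample", "transform_errors"]


def _rot(angles_deg: np.ndarray) -> np.ndarray:
    rx, ry, rz = np.deg2rad(angles_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """Rigid world-space transform: w' = R (w - c) + c + t.

    ``angles_deg`` rotate about x, y, z (applied in that order) around the
    center ``center_mm``; ``translation_mm`` is applied after rotation.
    """

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        R = _rot(np.asarray(self.angles_deg, float))
        c = np.asarray(self.center_mm, float)
        t = np.asarray(self.translation_mm, float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        if not np.isclose(np.linalg.det(R), 1.0):
            raise ValueError("rotation block must have det +1")
        return M

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_dict(self) -> dict:
        return {
            "angles_deg": list(self.angles_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            angles_deg=tuple(d["angles_deg"]),
            translation_mm=tuple(d["translation_mm"]),
            center_mm=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )


def _world_center(shape: tuple[int, ...], affine: np.ndarray) -> np.ndarray:
    idx = (np.asarray(shape, float) - 1) / 2.0
    return (affine @ np.append(idx, 1.0))[:3]


def resample(
    volume: np.ndarray,
    xform: RigidTransform,
    moving_affine: np.ndarray,
    fixed_affine: np.ndarray,
    fixed_shape: tuple[int, int, int],
    mode: str = "trilinear",
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``volume`` onto the fixed grid after mapping it through ``xform``.

    ``mode`` is "nearest" or "trilinear".  Nearest never invents values absent
    from the input; requesting trilinear for an integer (label) volume raises.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError("mode must be 'nearest' or 'trilinear'")
    volume = np.asarray(volume)
    if mode == "trilinear" and np.issubdtype(volume.dtype, np.integer):
        raise ValueError("label (integer) volumes require nearest-neighbour resampling")
    inv = np.linalg.inv(moving_affine) @ xform.inverse_matrix() @ fixed_affine
    ii, jj, kk = np.meshgrid(
        *[np.arange(n, dtype=float) for n in fixed_shape], indexing="ij"
    )
    pts = np.stack([ii, jj, kk, np.ones_like(ii)])
    src = np.einsum("ab,bxyz->axyz", inv, pts)[:3]
    order = 0 if mode == "nearest" else 1
    return ndimage.map_coordinates(
        volume.astype(float), src, order=order, mode="constant", cval=cval
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        return 0.0
    return float((a * b).sum() / den)


def _decimate(vol: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sm = ndimage.gaussian_filter(vol, 1.0)
    out = sm[::2, ::2, ::2]
    scale = np.diag([2.0, 2.0, 2.0, 1.0])
    return out, affine @ scale


def estimate_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    moving_affine: np.ndarray | None = None,
    fixed_affine: np.ndarray | None = None,
    init: RigidTransform | None = None,
    pyramid: bool = True,
) -> tuple[RigidTransform, float]:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Returns (transform, final negative-NCC cost).  Raises on non-finite cost
    (no overlap between the volumes at the initial position).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving_affine is None:
        moving_affine = np.eye(4)
    if fixed_affine is None:
        fixed_affine = np.eye(4)
    center = tuple(_world_center(fixed.shape, fixed_affine))
    if init is None:
        init = RigidTransform(center_mm=center)
    p0 = np.concatenate([init.angles_deg, init.translation_mm])

    levels = []
    if pyramid:
        mv_c, mv_aff_c = _decimate(moving, moving_affine)
        fx_c, fx_aff_c = _decimate(fixed, fixed_affine)
        levels.append((mv_c, mv_aff_c, fx_c, fx_aff_c, 1e-2))
    levels.append((moving, moving_affine, fixed, fixed_affine, 1e-4))

    p = p0
    cost = np.inf
    for mv, mv_aff, fx, fx_aff, xatol in levels:
        # NCC is evaluated on the eroded support of the fixed image with cubic
        # interpolation: both choices remove sub-voxel bias of the optimum
        # (edge voxels and trilinear kinks otherwise displace it)
        support = fx > 0.05 * np.abs(fx).max()
        interior = ndimage.binary_erosion(support, iterations=2)
        if interior.sum() < 100:
            interior = support
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in fx.shape], indexing="ij")
        pts = np.stack(list(grids) + [np.ones_like(grids[0])])
        inv_mv = np.linalg.inv(mv_aff)

        def cost_fn(params: np.ndarray) -> float:
            xf = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
            m = inv_mv @ xf.inverse_matrix() @ fx_aff
            src = np.einsum("ab,bxyz->axyz", m, pts)[:3]
            res = ndimage.map_coordinates(mv, src, order=3, mode="constant", cval=np.nan)
            ok = np.isfinite(res) & interior
            if ok.sum() < 10:
                return 1.0
            return -_ncc(res[ok], fx[ok])

        xf0 = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
        m0 = inv_mv @ xf0.inverse_matrix() @ fx_aff
        src0 = np.einsum("ab,bxyz->axyz", m0, pts)[:3]
        res0 = ndimage.map_coordinates(mv, src0, order=1, mode="constant", cval=np.nan)
        if (np.isfinite(res0) & interior).sum() < 10:
            raise ValueError("non-finite registration cost: volumes do not overlap at init")
        c0 = cost_fn(p)
        if not np.isfinite(c0):
            raise ValueError("non-finite registration cost")
        sol = minimize(
            cost_fn,
            p,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": 1e-10,
                "maxiter": 2000,
                "initial_simplex": _simplex(p, angle_step=2.0, trans_step=1.0)
                if np.isinf(cost)
                else _simplex(p, angle_step=0.3, trans_step=0.15),
            },
        )
        p, cost = sol.x, float(sol.fun)
    xf = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
    return xf, cost


def _simplex(p0: np.ndarray, angle_step: float, trans_step: float) -> np.ndarray:
    steps = np.array([angle_step] * 3 + [trans_step] * 3)
    simplex = np.tile(p0, (7, 1))
    for i in range(6):
        simplex[i + 1, i] += steps[i]
    return simplex


def transform_errors(estimated: RigidTransform, truth: RigidTransform) -> dict[str, float]:
    """Rotation (deg) and translation (mm) error of ``estimated`` composed with truth.

    If ``estimated`` undoes ``truth`` exactly, the composition is the identity;
    the residual rotation angle and translation norm quantify the misfit.
    """
    M = estimated.matrix @ truth.matrix
    R = M[:3, :3]
    angle = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0)))
    # translation error measured at the rotation center
    c = np.asarray(truth.center_mm)
    residual = M @ np.append(c, 1.0)
    trans = float(np.linalg.norm(residual[:3] - c))
    return {"rotation_deg": float(angle), "translation_mm": trans}
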