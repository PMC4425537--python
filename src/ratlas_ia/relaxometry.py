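"""Multi-echo T2 relaxometry and seeded lesion segmentation.

Per-voxel spin-spin relaxation is modelled as a mono-exponential decay with
an absolute bias term,

    y(t) = A + C * exp(-t / T2)

with A the bias, C the amplitude and t the echo time in ms.  The nonlinear
fit is initialized from a log-linear fit of (y - min y) and may optionally be
inverse-variance weighted when per-echo SDs are supplied.

Edema appears as a hyperintensity on T2-weighted images; its volume is
measured by seeding a point inside the lesion and growing over connected
neighbours whose intensity lies inside an absolute threshold interval.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["T2Fit", "LesionMask", "fit_t2", "grow_lesion", "lesion_volume"]


@dataclass
class T2Fit:
    """Per-voxel A/C/T2 maps (signal units, signal units, ms) with residual norm."""

    A: np.ndarray
    C: np.ndarray
    T2: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    mask: np.ndarray


@dataclass
class LesionMask:
    """Connected binary lesion mask grown from a seed within [lo, hi]."""

    mask: np.ndarray
    seed: tuple[int, int, int]
    lo: float
    hi: float
    voxel_volume_mm3: float
    touches_boundary: bool = False


def _loglin_init(y: np.ndarray, tes: np.ndarray) -> tuple[float, float, float]:
    a0 = float(y.min())
    resid = y - a0
    pos = resid > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(tes[pos], np.log(resid[pos] + 1e-12), 1)
        t2 = -1.0 / slope if slope < 0 else tes[-1]
        c0 = float(np.exp(intercept))
    else:
        t2 = tes[-1] - tes[0]
        c0 = float(max(y.max() - a0, 1.0))
    t2 = float(np.clip(t2, 1e-3, 100 * tes[-1]))
    return a0, c0, t2


def fit_t2(
    multiecho: np.ndarray,
    tes: np.ndarray,
    mask: np.ndarray | None = None,
    echo_sds: np.ndarray | None = None,
) -> T2Fit:
    """Nonlinear least-squares T2 fit per in-mask voxel.

    Parameters
    ----------
    multiecho : (X, Y, Z, n_echoes) array
    tes : strictly increasing echo times in ms, >= 3 echoes
    echo_sds : optional per-echo SDs; residuals are divided by them
        (inverse-variance weighting).

    Voxels where the optimizer does not converge, or that are all-zero, are
    flagged in ``converged`` rather than silently filled.
    """
    multiecho = np.asarray(multiecho, dtype=float)
    tes = np.asarray(tes, dtype=float).ravel()
    if tes.size < 3:
        raise ValueError("need at least 3 echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if multiecho.ndim == 2 and multiecho.shape[1] == tes.size:
        multiecho = multiecho[:, None, None, :]
    if multiecho.shape[-1] != tes.size:
        raise ValueError("echo dimension does not match TE list")
    shape = multiecho.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    w = None if echo_sds is None else 1.0 / np.asarray(echo_sds, dtype=float)

    A = np.zeros(shape)
    C = np.zeros(shape)
    T2 = np.zeros(shape)
    residual = np.zeros(shape)
    converged = np.zeros(shape, dtype=bool)

    def model_resid(p: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = p[0] + p[1] * np.exp(-tes / p[2]) - y
        return r * w if w is not None else r

    for idx in np.argwhere(mask):
        i, j, k = idx
        y = multiecho[i, j, k]
        if not np.any(y):
            continue
        p0 = np.array(_loglin_init(y, tes))
        sol = least_squares(
            model_resid,
            p0,
            args=(y,),
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        A[i, j, k], C[i, j, k], T2[i, j, k] = sol.x
        residual[i, j, k] = float(np.linalg.norm(sol.fun))
        converged[i, j, k] = bool(sol.success)
    return T2Fit(A=A, C=C, T2=T2, residual=residual, converged=converged, mask=np.asarray(mask, bool))


_OFFSETS_26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)
_OFFSETS_6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


def grow_lesion(
    image: np.ndarray,
    seed: tuple[int, int, int],
    lo: float,
    hi: float,
    voxel_volume_mm3: float = 1.0,
    connectivity: int = 26,
) -> LesionMask:
    """Breadth-first region growth from ``seed`` over voxels with intensity in [lo, hi].

    Deterministic flood fill: the result is the connected component of the
    thresholded image containing the seed, so it is invariant to which voxel
    of that component is seeded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be 3D")
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, image.shape)):
        raise ValueError(f"seed {seed} outside image")
    if not (lo <= image[seed] <= hi):
        raise ValueError(
            f"seed intensity {image[seed]:.6g} outside threshold interval [{lo}, {hi}]"
        )
    if connectivity == 26:
        offsets = _OFFSETS_26
    elif connectivity == 6:
        offsets = _OFFSETS_6
    else:
        raise ValueError("connectivity must be 6 or 26")

    in_range = (image >= lo) & (image <= hi)
    mask = np.zeros(image.shape, dtype=bool)
    mask[seed] = True
    frontier = deque([seed])
    shape = image.shape
    while frontier:
        p = frontier.popleft()
        for off in offsets:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if (
                0 <= q[0] < shape[0]
                and 0 <= q[1] < shape[1]
                and 0 <= q[2] < shape[2]
                and in_range[q]
                and not mask[q]
            ):
                mask[q] = True
                frontier.append(q)
    touches = bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    return LesionMask(
        mask=mask,
        seed=seed,
        lo=float(lo),
        hi=float(hi),
        voxel_volume_mm3=float(voxel_volume_mm3),
        touches_boundary=touches,
    )


def lesion_volume(
    mask: LesionMask, brain_mask: np.ndarray | None = None
) -> dict[str, float]:
    """Lesion volume in mm^3 (voxel count x voxel volume) and % of brain volume."""
    if mask.voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    n = int(mask.mask.sum())
    vol = n * mask.voxel_volume_mm3
    out = {"n_voxels": n, "volume_mm3": vol}
    if brain_mask is not None:
        brain_vol = float(brain_mask.sum()) * mask.voxel_volume_mm3
        out["percent_of_brain"] = 100.0 * vol / brain_vol if brain_vol > 0 else float("nan")
    if n == 0:
        import warnings

        warnings.warn("empty lesion mask: volume 0", stacklevel=2)
    return out
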