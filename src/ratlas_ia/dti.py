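"""Diffusion tensor fitting and anisotropy index maps.

The model is the standard single-tensor, single-shell signal equation

    S(g, b) = S0 * exp(-b * g^T D g)

fit per voxel by log-linear least squares.  From the sorted eigenvalues
``l1 >= l2 >= l3`` (all in 1e-3 mm^2/s) the index maps are

    AD  = l1                    axial diffusivity
    RD  = (l2 + l3) / 2         radial diffusivity
    ADC = (l1 + l2 + l3) / 3    apparent diffusion coefficient / mean diffusivity
    FA  = sqrt(3/2) * sqrt(sum (l_i - ADC)^2 / sum l_i^2)

Motion-corrupted slice/frame images are screened out before fitting with a
robust per-slice median/MAD rule, mirroring automated artifact rejection in
EPI acquisitions where sporadic breathing ruins individual slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .schemes import GradientScheme

__all__ = [
    "TensorField",
    "IndexMaps",
    "screen_motion_artifacts",
    "fit_tensor",
    "compute_index_maps",
    "gaussian_smooth",
    "tensor_from_eigensystem",
    "average_repetitions",
]

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # FWHM = sigma * 2 sqrt(2 ln 2)
_LOG_FLOOR = 1e-8


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with sorted eigensystem.

    ``tensors`` is (X, Y, Z, 3, 3) in 1e-3 mm^2/s; ``evals`` is (X, Y, Z, 3)
    sorted descending; ``principal_axis`` is the eigenvector of the largest
    eigenvalue.  ``clamp_count`` reports how many negative eigenvalues were
    clamped to zero after fitting.
    """

    tensors: np.ndarray
    evals: np.ndarray
    principal_axis: np.ndarray
    mask: np.ndarray
    clamp_count: int = 0
    n_log_floored: int = 0

    def __post_init__(self) -> None:
        ev = self.evals[self.mask]
        if ev.size and np.any(np.diff(ev, axis=-1) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if ev.size and np.any(ev[..., 2] < -1e-12):
            raise ValueError("negative eigenvalues after clamping")


@dataclass
class IndexMaps:
    """FA/AD/RD/ADC volumes (diffusivities in 1e-3 mm^2/s) plus brain mask."""

    fa: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    adc: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = self.mask
        if np.any(self.fa[m] < -1e-12) or np.any(self.fa[m] > 1 + 1e-9):
            raise ValueError("FA out of [0, 1]")
        if np.any(self.ad[m] + 1e-12 < self.adc[m]) or np.any(
            self.adc[m] + 1e-12 < self.rd[m]
        ):
            raise ValueError("AD >= ADC >= RD violated")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"FA": self.fa, "AD": self.ad, "RD": self.rd, "ADC": self.adc}


def screen_motion_artifacts(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    k: float = 4.0,
    min_fraction: float = 0.1,
) -> set[tuple[int, int]]:
    """Flag (slice, frame) images whose mean in-mask signal is a per-slice outlier.

    For every axial slice the mean signal of each frame is compared with the
    across-frame median of the same slice within the same shell (b0 frames and
    diffusion frames are screened separately, their intensity scales differ).
    An image deviating by more than ``k`` scaled MADs is flagged.  Raises if
    screening would leave fewer than 6 diffusion directions or no b0 on any
    slice.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, frame)")
    if dwi.shape[3] != scheme.n_frames:
        raise ValueError("frame count does not match scheme")
    if scheme.n_frames < 2:
        raise ValueError("need at least 2 frames to screen")
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)

    nz, nf = dwi.shape[2], dwi.shape[3]
    means = np.full((nz, nf), np.nan)
    for z in range(nz):
        m = mask[:, :, z]
        if m.any():
            means[z] = dwi[:, :, z, :][m].mean(axis=0)

    flagged: set[tuple[int, int]] = set()
    for shell in (scheme.b0_mask, ~scheme.b0_mask):
        idx = np.flatnonzero(shell)
        if idx.size < 2:
            continue
        valid = ~np.isnan(means).all(axis=1)
        sub = means[:, idx]  # (nz, n_shell); rows without mask stay NaN
        # per-frame reference level: the across-slice median is robust to a
        # corrupted slice dragging the frame mean down
        ref = np.median(sub[valid], axis=0)
        ratio = sub / ref
        dev = ratio - np.median(ratio, axis=1, keepdims=True)
        pooled_mad = 1.4826 * np.median(np.abs(dev[valid]))
        # motion artifacts are gross signal changes; anatomy-by-direction
        # interaction is a few percent of the slice level, so deviations below
        # min_fraction are never screened out
        cut = max(k * pooled_mad, min_fraction)
        for z, j in np.argwhere(np.abs(dev) > cut):
            flagged.add((int(z), int(idx[j])))

    # usability check per slice
    for z in range(nz):
        kept = [f for f in range(nf) if (z, f) not in flagged]
        kept_b0 = sum(scheme.b0_mask[f] for f in kept)
        kept_dwi = [f for f in kept if not scheme.b0_mask[f]]
        if kept_b0 < 1 or np.linalg.matrix_rank(
            scheme.design_matrix()[kept_dwi, :6]
        ) < 6:
            n_vox = int(mask[:, :, z].sum())
            raise ValueError(
                f"slice {z}: screening leaves an under-determined fit "
                f"({n_vox} voxels affected)"
            )
    return flagged


def fit_tensor(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    exclusions: set[tuple[int, int]] | None = None,
) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Non-positive signals are floored at a small epsilon before the log
    (counted in ``n_log_floored``); negative eigenvalues are clamped to zero
    (counted in ``clamp_count``).  Voxels on slices where exclusions removed
    all diffusion frames are masked out rather than fit.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != scheme.n_frames:
        raise ValueError("dwi must be 4D with one frame per scheme entry")
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    exclusions = exclusions or set()

    X_full = scheme.design_matrix()
    floor = float(max(dwi.max(), 1.0)) * _LOG_FLOOR

    D = np.zeros(shape + (6,))
    out_mask = mask.copy()
    n_floored = 0

    # frames dropped by screening vary only with the slice index
    excl_by_slice: dict[int, list[int]] = {}
    for z, f in exclusions:
        excl_by_slice.setdefault(z, []).append(f)

    for z in range(shape[2]):
        m = mask[:, :, z]
        if not m.any():
            continue
        keep = np.setdiff1d(np.arange(scheme.n_frames), excl_by_slice.get(z, []))
        n_b0 = int(scheme.b0_mask[keep].sum())
        n_dwi = keep.size - n_b0
        if n_b0 < 1 or n_dwi < 6:
            out_mask[:, :, z] = False
            continue
        X = X_full[keep]
        sig = dwi[:, :, z, :][m][:, keep]
        n_floored += int((sig <= 0).sum())
        logs = np.log(np.maximum(sig, floor))
        beta, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
        D[:, :, z, :][m] = beta[:6].T

    tensors = np.zeros(shape + (3, 3))
    i, j = np.triu_indices(3)
    tensors[..., [0, 1, 2], [0, 1, 2]] = D[..., :3]
    tensors[..., 0, 1] = tensors[..., 1, 0] = D[..., 3]
    tensors[..., 0, 2] = tensors[..., 2, 0] = D[..., 4]
    tensors[..., 1, 2] = tensors[..., 2, 1] = D[..., 5]

    evals = np.zeros(shape + (3,))
    axes = np.zeros(shape + (3,))
    w, v = np.linalg.eigh(tensors[out_mask])  # ascending
    w = w[..., ::-1]
    axes_m = v[..., :, ::-1][..., :, 0]
    clamp_count = int((w < 0).sum())
    w = np.clip(w, 0.0, None)
    evals[out_mask] = w
    axes[out_mask] = axes_m
    return TensorField(
        tensors=tensors,
        evals=evals,
        principal_axis=axes,
        mask=out_mask,
        clamp_count=clamp_count,
        n_log_floored=n_floored,
    )


def compute_index_maps(tf: TensorField) -> IndexMaps:
    """FA, AD, RD and ADC maps from a fitted tensor field."""
    ev = tf.evals
    adc = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    ss = (ev**2).sum(axis=-1)
    dev = ((ev - adc[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev / ss)
    fa = np.where(ss == 0, 0.0, fa)
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)
    for arr in (fa, ad, rd, adc):
        arr[~tf.mask] = 0.0
    return IndexMaps(fa=fa, ad=ad, rd=rd, adc=adc, mask=tf.mask)


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Separable Gaussian smoothing with in-mask renormalization.

    ``fwhm_mm`` follows the SPM convention (kernel full width at half maximum);
    sigma = fwhm / 2.3548 per axis.  Voxels outside the mask contribute no
    kernel mass, so values near the mask edge are not diluted by background.
    ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    if mask is None:
        return ndimage.gaussian_filter(volume, sigma)
    m = mask.astype(float)
    num = ndimage.gaussian_filter(volume * m, sigma)
    den = ndimage.gaussian_filter(m, sigma)
    out = np.zeros_like(volume)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    out[~mask.astype(bool)] = 0.0
    return out


def average_repetitions(
    dwis: list[np.ndarray],
    mode: str = "signal",
    scheme: GradientScheme | None = None,
    mask: np.ndarray | None = None,
):
    """Combine repeated acquisitions of the same protocol.

    ``mode`` "signal" averages the raw 4D volumes before any fit (the
    default); "map" fits each repetition separately and averages the index
    maps, which requires ``scheme``.  On noiseless data the two agree.
    """
    if not dwis:
        raise ValueError("no repetitions supplied")
    shapes = {np.asarray(d).shape for d in dwis}
    if len(shapes) > 1:
        raise ValueError(f"repetitions disagree in shape: {shapes}")
    if mode == "signal":
        return np.mean([np.asarray(d, float) for d in dwis], axis=0)
    if mode != "map":
        raise ValueError("mode must be 'signal' or 'map'")
    if scheme is None:
        raise ValueError("map-space averaging needs the gradient scheme")
    maps = [compute_index_maps(fit_tensor(np.asarray(d, float), scheme, mask)) for d in dwis]
    out = {
        name: np.mean([m.as_dict()[name] for m in maps], axis=0)
        for name in ("FA", "AD", "RD", "ADC")
    }
    out["mask"] = maps[0].mask
    return out


def tensor_from_eigensystem(evals: np.ndarray, principal_axis: np.ndarray) -> np.ndarray:
    """Build a symmetric tensor with given sorted eigenvalues and principal axis.

    The two minor axes are an arbitrary (deterministic) orthonormal completion,
    which is immaterial when l2 == l3 and otherwise fixes a convention.
    """
    l1, l2, l3 = evals
    e1 = np.asarray(principal_axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return l1 * np.outer(e1, e1) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)
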