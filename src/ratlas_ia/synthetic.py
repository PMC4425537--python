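"""Synthetic phantom cohorts with known ground truth.

The generator emulates the acquisition and injury structure the pipeline was
designed for: single-shell DWI (10 non-collinear directions at b = 1000
s/mm^2 plus one b0) over a 96x96x60 grid of 0.313 mm isotropic voxels,
16-echo multi-echo T2 data at 11 ms spacing, a mirror-symmetric bilateral
label atlas, a focal edematous lesion of ~9-14 mm^3, and hemisphere-specific
shifts of FA/RD/AD in designated regions.

Every generator is a pure function of (spec, seed): identical inputs give
bit-identical outputs.  Injury effects are specified on eigenvalues so that
all derived indices change self-consistently: an "fa" effect rescales
lambda1 up and lambda2 = lambda3 down at constant trace, "rd" shifts
lambda2 and lambda3, "ad" shifts lambda1 (all in 1e-3 mm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .atlas import LabeledAtlas
from .dti import TensorField, tensor_from_eigensystem
from .registration import RigidTransform, resample
from .schemes import GradientScheme, ten_direction_scheme, _fibonacci_sphere

__all__ = [
    "InjuryEffect",
    "PhantomSpec",
    "GroundTruth",
    "small_spec",
    "full_scale_spec",
    "eigs_from_fa_trace",
    "index_values_from_eigs",
    "make_phantom_atlas",
    "make_brain_mask",
    "simulate_tensor_field",
    "simulate_dwi",
    "make_s0_map",
    "make_t2_truth",
    "simulate_multiecho",
    "simulate_cohort",
    "simulate_histology_image",
]


@dataclass(frozen=True)
class InjuryEffect:
    """One hemisphere-specific eigenvalue perturbation.

    ``index`` is "fa" (eigenvalue reshaping at constant trace, magnitude =
    target FA change), "rd" or "ad" (additive diffusivity shift in
    1e-3 mm^2/s).  ``side`` is "left" or "right".
    """

    region: str
    side: str
    index: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.index not in ("fa", "rd", "ad"):
            raise ValueError("index must be 'fa', 'rd' or 'ad'")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom: geometry, tissue, injury, noise, seed."""

    grid_shape: tuple[int, int, int] = (96, 96, 60)
    voxel_size_mm: float = 0.313
    region_names: tuple[str, ...] = ()
    region_sizes: tuple[int, ...] = ()  # voxels per side
    baseline_evals: tuple[tuple[float, float, float], ...] = ()  # 1e-3 mm^2/s
    background_adc: float = 0.7
    injury_effects: tuple[InjuryEffect, ...] = ()
    lesion_center_mm: tuple[float, float, float] | None = None
    lesion_radius_mm: float = 1.4
    s0: float = 1000.0
    noise_sigma: float = 20.0  # Rician channel SD, signal units (2% of s0)
    # mirror the baseline-signal map so hemispheres are exchangeable (exact
    # null for bilateral statistics); leave False when registration must be
    # exercised, which needs left/right intensity asymmetry
    mirror_s0: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if len(self.region_names) < 2:
            raise ValueError("need at least 2 region pairs")
        if not (
            len(self.region_names) == len(self.region_sizes) == len(self.baseline_evals)
        ):
            raise ValueError("region names/sizes/eigenvalues lengths differ")
        for ev in self.baseline_evals:
            l1, l2, l3 = ev
            if not (l1 >= l2 >= l3 > 0):
                raise ValueError(f"eigenvalues must satisfy l1>=l2>=l3>0, got {ev}")
        for eff in self.injury_effects:
            if eff.region not in self.region_names:
                raise ValueError(f"injury effect names unknown region {eff.region!r}")
        if self.lesion_center_mm is not None:
            ext = np.asarray(self.grid_shape) * self.voxel_size_mm
            c = np.asarray(self.lesion_center_mm)
            if np.any(c - self.lesion_radius_mm < 0) or np.any(
                c + self.lesion_radius_mm > ext
            ):
                raise ValueError("lesion does not fit inside the grid")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class GroundTruth:
    """What the simulation actually applied, for downstream verification."""

    region_evals: dict[tuple[str, str], tuple[float, float, float]]
    region_index_means: pd.DataFrame  # region_name, side, FA, AD, RD, ADC
    lesion_volume_mm3: float = 0.0
    lesion_mask: np.ndarray | None = None
    transforms: list[RigidTransform] = field(default_factory=list)
    subject_region_scales: list[dict[str, float]] = field(default_factory=list)


def eigs_from_fa_trace(fa: float, trace: float) -> tuple[float, float, float]:
    """Prolate (l1, l2, l2) eigenvalues with the given FA and trace.

    For a cylindrically symmetric tensor FA = (l1 - l2) / sqrt(l1^2 + 2 l2^2).
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    if trace <= 0:
        raise ValueError("trace must be positive")
    if fa == 0:
        v = trace / 3
        return (v, v, v)

    def f(l2: float) -> float:
        l1 = trace - 2 * l2
        return (l1 - l2) / np.sqrt(l1**2 + 2 * l2**2) - fa

    l2 = brentq(f, 1e-9, trace / 3)
    return (trace - 2 * l2, l2, l2)


def index_values_from_eigs(ev: tuple[float, float, float]) -> dict[str, float]:
    l1, l2, l3 = ev
    adc = (l1 + l2 + l3) / 3
    ss = l1**2 + l2**2 + l3**2
    fa = 0.0 if ss == 0 else float(
        np.sqrt(1.5 * ((l1 - adc) ** 2 + (l2 - adc) ** 2 + (l3 - adc) ** 2) / ss)
    )
    return {"FA": fa, "AD": l1, "RD": (l2 + l3) / 2, "ADC": adc}


# ---------------------------------------------------------------------------
# canonical specs

_KEY_REGIONS: list[tuple[str, float, float]] = [
    # (name, contralateral FA, trace in 1e-3 mm^2/s) for designated regions
    ("central amygdala", 0.414, 1.730),
    ("laterodorsal thalamus", 0.436, 2.098),
    ("CA1 dorsal hippocampus", 0.336, 2.100),
    ("lateral amygdala", 0.262, 1.756),
    ("somatosensory ctx secondary", 0.220, 2.100),
]

_GENERIC_FA, _GENERIC_TRACE = 0.30, 2.10


def small_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom: 24^3 grid, 3 bilateral region pairs."""
    names = tuple(n for n, _, _ in _KEY_REGIONS[:3])
    evs = tuple(eigs_from_fa_trace(fa, tr) for _, fa, tr in _KEY_REGIONS[:3])
    defaults = dict(
        grid_shape=(24, 24, 24),
        voxel_size_mm=0.313,
        region_names=names,
        region_sizes=(23, 40, 57),
        baseline_evals=evs,
        lesion_center_mm=(3.756, 2.504, 3.756),
        lesion_radius_mm=1.4,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def full_scale_spec(n_regions: int = 150, **overrides) -> PhantomSpec:
    """Full-scale phantom: 96x96x60 at 0.313 mm, 150 bilateral region pairs.

    Region sizes cycle so that roughly 20,000 voxels are assigned to regions,
    with the designated "central amygdala" pair totalling ~46 voxels.
    """
    names = [n for n, _, _ in _KEY_REGIONS]
    names += [f"region_{i:03d}" for i in range(len(names), n_regions)]
    sizes = [23] + [(35, 50, 67, 84, 99)[i % 5] for i in range(n_regions - 1)]
    evs = [eigs_from_fa_trace(fa, tr) for _, fa, tr in _KEY_REGIONS[:n_regions]]
    evs += [
        eigs_from_fa_trace(_GENERIC_FA, _GENERIC_TRACE)
        for _ in range(n_regions - len(evs))
    ]
    defaults = dict(
        grid_shape=(96, 96, 60),
        voxel_size_mm=0.313,
        region_names=tuple(names),
        region_sizes=tuple(sizes),
        baseline_evals=tuple(evs),
        lesion_center_mm=(20.0, 8.0, 12.0),
        lesion_radius_mm=1.4,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


# ---------------------------------------------------------------------------
# atlas construction

def _blob_offsets(n: int) -> np.ndarray:
    """First ``n`` integer offsets from the origin ordered by distance (ties
    broken lexicographically): a deterministic near-spherical blob."""
    r = int(np.ceil((3 * n / (4 * np.pi)) ** (1 / 3))) + 2
    ax = np.arange(-r, r + 1)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    d2 = (offs**2).sum(axis=1)
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], d2))
    return offs[order[:n]]


def make_phantom_atlas(spec: PhantomSpec) -> LabeledAtlas:
    """Mirror-symmetric bilateral label volume plus region table.

    Left-hemisphere blobs are placed on a lattice ordered by distance from
    the hemisphere centre; the right hemisphere is the exact mirror about the
    mid-sagittal plane, so left/right voxel counts are equal per pair by
    construction.  Label 0 is background; region i gets labels (2i+1, 2i+2).
    """
    W, H, D = spec.grid_shape
    max_n = max(spec.region_sizes)
    r_max = int(np.ceil((3 * max_n / (4 * np.pi)) ** (1 / 3))) + 1
    step = 2 * r_max + 1
    xs = np.arange(r_max + 1, W // 2 - r_max, step)
    ys = np.arange(r_max + 1, H - r_max, step)
    zs = np.arange(r_max + 1, D - r_max, step)
    slots = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    if slots.shape[0] < spec.n_regions:
        raise ValueError(
            f"cannot place {spec.n_regions} non-overlapping region pairs on a "
            f"{spec.grid_shape} grid ({slots.shape[0]} slots)"
        )
    hemi_center = np.array([(W // 2 - 1) / 2.0, (H - 1) / 2.0, (D - 1) / 2.0])
    d2 = ((slots - hemi_center) ** 2).sum(axis=1)
    order = np.lexsort((slots[:, 2], slots[:, 1], slots[:, 0], d2))
    slots = slots[order[: spec.n_regions]]

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    rows = []
    for i, (name, size) in enumerate(zip(spec.region_names, spec.region_sizes)):
        offs = _blob_offsets(size)
        vox = slots[i] + offs
        left_label, right_label = 2 * i + 1, 2 * i + 2
        lx, ly, lz = vox[:, 0], vox[:, 1], vox[:, 2]
        if np.any(labels[lx, ly, lz] != 0):
            raise ValueError(f"region {name!r} overlaps a previously placed region")
        labels[lx, ly, lz] = left_label
        rx = W - 1 - lx
        if np.any(labels[rx, ly, lz] != 0):
            raise ValueError(f"mirrored region {name!r} overlaps")
        labels[rx, ly, lz] = right_label
        rows.append(
            {"region_name": name, "left_label": left_label, "right_label": right_label}
        )
    table = pd.DataFrame(rows, columns=["region_name", "left_label", "right_label"])
    return LabeledAtlas(
        labels=labels,
        table=table,
        voxel_size_mm=spec.voxel_size_mm,
        affine=spec.affine,
    )


def make_brain_mask(spec: PhantomSpec, atlas: LabeledAtlas | None = None) -> np.ndarray:
    """Ellipsoidal 'brain' covering the grid interior, unioned with all regions."""
    shape = np.asarray(spec.grid_shape, float)
    center = (shape - 1) / 2.0
    semi = 0.46 * shape
    grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    mask = r2 <= 1.0
    if atlas is not None:
        mask |= atlas.labels > 0
    return mask


# ---------------------------------------------------------------------------
# tensors and DWI

def _region_axis(i: int) -> np.ndarray:
    return _fibonacci_sphere(64)[i % 64]


def _perturb_evals(
    ev: tuple[float, float, float], effect: InjuryEffect
) -> tuple[float, float, float]:
    l1, l2, l3 = ev
    if effect.index == "fa":
        base = index_values_from_eigs(ev)
        target = base["FA"] + effect.magnitude
        if not 0 <= target < 1:
            raise ValueError(f"FA effect drives FA to {target:.3f}, outside [0, 1)")
        out = eigs_from_fa_trace(target, l1 + l2 + l3)
    elif effect.index == "rd":
        out = (l1, l2 + effect.magnitude, l3 + effect.magnitude)
    else:  # ad
        out = (l1 + effect.magnitude, l2, l3)
    if out[2] <= 0 or out[0] < out[1] or out[1] < out[2]:
        raise ValueError(
            f"injury effect {effect} produces invalid eigenvalues {out}"
        )
    return out


def simulate_tensor_field(
    atlas: LabeledAtlas,
    spec: PhantomSpec,
    region_scales: dict[str, float] | None = None,
) -> tuple[TensorField, GroundTruth]:
    """Piecewise-constant tensor field over the atlas with injury effects applied.

    ``region_scales`` optionally multiplies all eigenvalues of a region
    bilaterally (subject-level random effect).  Unlabeled in-brain tissue is
    isotropic at ``spec.background_adc``.
    """
    mask = make_brain_mask(spec, atlas)
    shape = spec.grid_shape
    tensors = np.zeros(shape + (3, 3))
    evals = np.zeros(shape + (3,))
    axes = np.zeros(shape + (3,))

    bg = spec.background_adc
    iso = np.eye(3) * bg
    tensors[mask] = iso
    evals[mask] = bg
    axes[mask] = np.array([1.0, 0.0, 0.0])

    effects = {(e.region, e.side): e for e in spec.injury_effects}
    region_evals: dict[tuple[str, str], tuple[float, float, float]] = {}
    truth_rows = []
    for i, (name, base_ev) in enumerate(zip(spec.region_names, spec.baseline_evals)):
        scale = 1.0 if region_scales is None else region_scales.get(name, 1.0)
        axis = _region_axis(i)
        for side in ("left", "right"):
            ev = tuple(v * scale for v in base_ev)
            if (name, side) in effects:
                ev = _perturb_evals(ev, effects[(name, side)])
            region_evals[(name, side)] = ev
            D = tensor_from_eigensystem(np.asarray(ev), axis)
            sel = atlas.region_mask(name, side)
            tensors[sel] = D
            evals[sel] = ev
            axes[sel] = axis
            truth_rows.append(
                {"region_name": name, "side": side, **index_values_from_eigs(ev)}
            )

    tf = TensorField(
        tensors=tensors, evals=evals, principal_axis=axes, mask=mask
    )
    gt = GroundTruth(
        region_evals=region_evals,
        region_index_means=pd.DataFrame(truth_rows),
    )
    return tf, gt


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2)."""
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_dwi(
    tf: TensorField,
    scheme: GradientScheme,
    s0: float | np.ndarray = 1000.0,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Noisy 4D DWI: S = S0 exp(-b g^T D g) with Rician noise, seed-reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = scheme.bvecs
    quad = np.einsum("ni,...ij,nj->...n", g, tf.tensors, g)
    signal = np.exp(-(scheme.bvals * 1e-3) * quad)
    s0_arr = np.asarray(s0, dtype=float)
    if s0_arr.ndim == 0:
        s0_map = np.where(tf.mask, float(s0_arr), 0.0)
    else:
        s0_map = s0_arr
    signal = s0_map[..., None] * signal
    signal[~tf.mask] = 0.0
    return rician(signal, sigma, rng)


def make_s0_map(atlas: LabeledAtlas, spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Baseline-signal map with deterministic per-region contrast.

    The region-dependent proton-density variation gives the b0 image internal
    structure, which is what makes rigid registration well-posed.
    """
    s0 = np.where(mask, spec.s0, 0.0)
    golden = 0.6180339887498949
    for i, row in atlas.table.iterrows():
        # deliberately different left/right contrast: perfect mirror symmetry
        # would make the rotation cost landscape degenerate
        f_left = 0.80 + 0.4 * ((i * golden) % 1.0)
        f_right = 0.80 + 0.4 * (((i + 7) * golden) % 1.0)
        s0[atlas.labels == row.left_label] = spec.s0 * f_left
        s0[atlas.labels == row.right_label] = spec.s0 * f_right
    # smooth, asymmetric proton-density texture: a band-limited deterministic
    # random field.  Without it the phantom is nearly rotation-invariant and
    # the registration cost has no rotational curvature.  The texture is part
    # of the anatomy: identical for every subject sharing the atlas.
    from scipy import ndimage

    tex_rng = np.random.default_rng(0xA71A5)
    tex = ndimage.gaussian_filter(tex_rng.normal(size=spec.grid_shape), 1.5)
    s0 = s0 * (1.0 + 0.25 * tex / tex.std())
    # mild partial-volume blur so the image, like a real b0, is band-limited
    s0 = ndimage.gaussian_filter(s0, 0.8)
    if spec.mirror_s0:
        # exchangeable hemispheres: identical SNR left/right, hence identical
        # noise-induced index bias — the exact null for paired statistics
        s0 = 0.5 * (s0 + s0[::-1])
    return s0


# ---------------------------------------------------------------------------
# multi-echo T2

def make_t2_truth(
    spec: PhantomSpec, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(T2 map ms, amplitude map C, true lesion mask) for the edema phantom.

    Healthy brain: T2 = 50 ms, C = 6500.  Lesion sphere: T2 = 90 ms, C =
    8500 (edema = more free water), which puts its first-echo intensity in
    the absolute segmentation window while healthy tissue stays below it.
    """
    t2 = np.full(spec.grid_shape, 1.0)
    C = np.zeros(spec.grid_shape)
    t2[mask] = 50.0
    C[mask] = 6500.0
    lesion = np.zeros(spec.grid_shape, dtype=bool)
    if spec.lesion_center_mm is not None:
        grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
        c_vox = np.asarray(spec.lesion_center_mm) / spec.voxel_size_mm
        r2 = sum((g - c) ** 2 for g, c in zip(grids, c_vox))
        lesion = (r2 <= (spec.lesion_radius_mm / spec.voxel_size_mm) ** 2) & mask
        t2[lesion] = 90.0
        C[lesion] = 8500.0
    return t2, C, lesion


def simulate_multiecho(
    t2_map: np.ndarray,
    A: float,
    C: float | np.ndarray,
    tes: np.ndarray,
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """4D multi-echo volume: y(t) = A + C exp(-t/T2) + Gaussian noise."""
    tes = np.asarray(tes, dtype=float).ravel()
    if tes.size < 3:
        raise ValueError("need at least 3 echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")
    t2 = np.asarray(t2_map, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive everywhere")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C_arr = np.broadcast_to(np.asarray(C, dtype=float), t2.shape)
    y = A + C_arr[..., None] * np.exp(-tes / t2[..., None])
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, y.shape)
    return y


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class SubjectData:
    dwi: np.ndarray
    scheme: GradientScheme
    s0_map: np.ndarray
    transform: RigidTransform
    region_scales: dict[str, float]


@dataclass
class CohortData:
    subjects: list[SubjectData]
    atlas: LabeledAtlas
    brain_mask: np.ndarray
    spec: PhantomSpec
    truth: GroundTruth


def simulate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    inter_subject_sd: float = 0.05,
    seed: int = 0,
    displacement: bool = True,
) -> CohortData:
    """Cohort of subjects sharing one atlas/injury structure.

    Each subject gets (i) a bilateral per-region eigenvalue scale drawn from
    N(1, inter_subject_sd) — a subject-level random effect that cancels in
    the within-animal left/right pairing, (ii) an independent Rician noise
    draw, and (iii), if ``displacement``, a recorded random rigid transform
    limited to +/-2 voxels and +/-5 degrees.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    atlas = make_phantom_atlas(spec)
    mask = make_brain_mask(spec, atlas)
    scheme = ten_direction_scheme()
    s0_map = make_s0_map(atlas, spec, mask)
    master = np.random.default_rng(spec.seed * 1_000_003 + seed)

    subjects = []
    transforms = []
    scales_list = []
    truth_ref = None
    for _ in range(n_subjects):
        rng = np.random.default_rng(master.integers(2**31))
        scales = {
            name: float(1.0 + rng.normal(0.0, inter_subject_sd))
            for name in spec.region_names
        }
        tf, gt = simulate_tensor_field(atlas, spec, region_scales=scales)
        if truth_ref is None:
            tf0, truth_ref = simulate_tensor_field(atlas, spec)
        clean = simulate_dwi(tf, scheme, s0=s0_map, sigma=0.0, seed=rng)
        if displacement:
            ang = rng.uniform(-5.0, 5.0, 3)
            tr = rng.uniform(-2.0, 2.0, 3) * spec.voxel_size_mm
            center = tuple(
                (np.asarray(spec.grid_shape, float) - 1) / 2.0 * spec.voxel_size_mm
            )
            xform = RigidTransform(tuple(ang), tuple(tr), center)
            moved = np.empty_like(clean)
            for f in range(clean.shape[-1]):
                moved[..., f] = resample(
                    clean[..., f], xform, spec.affine, spec.affine,
                    spec.grid_shape, mode="trilinear",
                )
            clean = moved
        else:
            xform = RigidTransform()
        dwi = rician(clean, spec.noise_sigma, rng)
        subjects.append(
            SubjectData(
                dwi=dwi, scheme=scheme, s0_map=s0_map,
                transform=xform, region_scales=scales,
            )
        )
        transforms.append(xform)
        scales_list.append(scales)

    truth = GroundTruth(
        region_evals=truth_ref.region_evals,
        region_index_means=truth_ref.region_index_means,
        transforms=transforms,
        subject_region_scales=scales_list,
    )
    return CohortData(
        subjects=subjects, atlas=atlas, brain_mask=mask, spec=spec, truth=truth
    )


# ---------------------------------------------------------------------------
# histology

def simulate_histology_image(
    background_level: float = 100.0,
    roi_effect_fold: float = 2.0,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    stain_density: float = 0.05,
    roi_size: tuple[int, int] = (40, 40),
) -> tuple[np.ndarray, dict]:
    """Synthetic stained section with ipsilateral/contralateral ROI boxes.

    Stained pixels appear at 2.5x background with Bernoulli density
    ``stain_density`` in the contralateral ROI and ``roi_effect_fold`` times
    that in the ipsilateral ROI, so the above-2x-background pixel count is
    fold-elevated in expectation.  Fixed seed gives a byte-identical image.
    """
    if roi_effect_fold < 0:
        raise ValueError("fold must be >= 0")
    h, w = shape
    rw, rh = roi_size
    if rw + 8 > w // 2 or rh + 16 > h:
        raise ValueError("ROI does not fit inside the image")
    rng = np.random.default_rng(seed)
    img = background_level + rng.normal(0.0, 0.02 * background_level, shape)

    rois = {
        "background": {"x": 4, "y": 4, "width": w // 8, "height": 8},
        "contra": {"x": w // 4 - rw // 2, "y": h // 2 - rh // 2, "width": rw, "height": rh},
        "ipsi": {"x": 3 * w // 4 - rw // 2, "y": h // 2 - rh // 2, "width": rw, "height": rh},
    }
    for key, dens in (("contra", stain_density), ("ipsi", min(1.0, roi_effect_fold * stain_density))):
        r = rois[key]
        sl = (slice(r["y"], r["y"] + r["height"]), slice(r["x"], r["x"] + r["width"]))
        stained = rng.random((r["height"], r["width"])) < dens
        patch = img[sl]
        patch[stained] = 2.5 * background_level
        img[sl] = patch
    return img, rois
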