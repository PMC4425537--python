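"""Rigid registration, resampling and atlas region bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from ratlas_ia.atlas import LabeledAtlas, map_voxels_to_regions, region_side_means
from ratlas_ia.registration import (
    RigidTransform,
    estimate_rigid,
    resample,
    transform_errors,
)
from ratlas_ia.synthetic import make_s0_map


@pytest.fixture(scope="module")
def template(spec_mod, atlas_mod, mask_mod):
    return make_s0_map(atlas_mod, spec_mod, mask_mod)


# module-scoped copies of the session fixtures (cheap to rebuild)
@pytest.fixture(scope="module")
def spec_mod():
    from ratlas_ia.synthetic import small_spec

    return small_spec()


@pytest.fixture(scope="module")
def atlas_mod(spec_mod):
    from ratlas_ia.synthetic import make_phantom_atlas

    return make_phantom_atlas(spec_mod)


@pytest.fixture(scope="module")
def mask_mod(spec_mod, atlas_mod):
    from ratlas_ia.synthetic import make_brain_mask

    return make_brain_mask(spec_mod, atlas_mod)


def test_rigid_matrix_is_orthonormal_with_unit_det():
    xf = RigidTransform((10.0, -20.0, 30.0), (1.0, 2.0, 3.0), (5.0, 5.0, 5.0))
    R = xf.matrix[:3, :3]
    assert R @ R.T == pytest.approx(np.eye(3), abs=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)
    assert xf.matrix @ xf.inverse_matrix() == pytest.approx(np.eye(4), abs=1e-12)


def test_self_registration_returns_identity(template, spec_mod):
    est, cost = estimate_rigid(template, template, spec_mod.affine, spec_mod.affine)
    err = transform_errors(est, RigidTransform())
    assert err["rotation_deg"] < 0.05
    assert err["translation_mm"] < 0.01
    assert cost < -0.999


def test_known_displacement_recovered(template, spec_mod):
    center = tuple((np.array(spec_mod.grid_shape) - 1) / 2 * spec_mod.voxel_size_mm)
    truth = RigidTransform((3.0, -1.0, 2.0), (1.5 * spec_mod.voxel_size_mm, -0.2, 0.3), center)
    moved = resample(template, truth, spec_mod.affine, spec_mod.affine, spec_mod.grid_shape, "trilinear")
    est, _ = estimate_rigid(moved, template, spec_mod.affine, spec_mod.affine)
    err = transform_errors(est, truth)
    assert err["rotation_deg"] <= 0.25
    assert err["translation_mm"] <= 0.1 * spec_mod.voxel_size_mm


def test_transform_composition_consistency(template, spec_mod):
    """Estimating on a further-displaced image composes with the extra transform."""
    center = tuple((np.array(spec_mod.grid_shape) - 1) / 2 * spec_mod.voxel_size_mm)
    T = RigidTransform((2.0, 1.0, -1.5), (0.2, -0.4, 0.1), center)
    moved = resample(template, T, spec_mod.affine, spec_mod.affine, spec_mod.grid_shape, "trilinear")
    est, _ = estimate_rigid(moved, template, spec_mod.affine, spec_mod.affine)
    # est should invert T: the composition is close to identity
    M = est.matrix @ T.matrix
    assert np.abs(M[:3, :3] - np.eye(3)).max() < 5e-3
    assert np.abs(M[:3, 3]).max() < 0.05


def test_resample_identity_and_value_set_preservation(template, spec_mod, atlas_mod):
    ident = RigidTransform()
    out = resample(template, ident, spec_mod.affine, spec_mod.affine, spec_mod.grid_shape, "trilinear")
    assert out == pytest.approx(template, abs=1e-9)
    binary = (template > template.mean()).astype(float)
    xf = RigidTransform((4.0, -3.0, 2.0), (0.4, 0.1, -0.2), (3.0, 3.0, 3.0))
    near = resample(binary, xf, spec_mod.affine, spec_mod.affine, spec_mod.grid_shape, "nearest")
    assert set(np.unique(near)) <= {0.0, 1.0}
    labels_near = resample(
        atlas_mod.labels.astype(float), xf, spec_mod.affine, spec_mod.affine,
        spec_mod.grid_shape, "nearest",
    )
    assert set(np.unique(labels_near)) <= set(np.unique(atlas_mod.labels).astype(float))


def test_trilinear_on_integer_labels_raises(atlas_mod, spec_mod):
    with pytest.raises(ValueError, match="nearest"):
        resample(
            atlas_mod.labels, RigidTransform(), spec_mod.affine, spec_mod.affine,
            spec_mod.grid_shape, "trilinear",
        )


def test_one_voxel_shift_equals_rolled_array(template, spec_mod):
    v = spec_mod.voxel_size_mm
    xf = RigidTransform((0.0, 0.0, 0.0), (v, 0.0, 0.0))
    out = resample(template, xf, spec_mod.affine, spec_mod.affine, spec_mod.grid_shape, "nearest")
    rolled = np.roll(template, 1, axis=0)
    assert out[1:, :, :] == pytest.approx(rolled[1:, :, :], abs=1e-9)


def test_nonoverlapping_volumes_raise(template, spec_mod):
    far = RigidTransform((0.0, 0.0, 0.0), (1000.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="overlap"):
        estimate_rigid(template, template, spec_mod.affine, spec_mod.affine, init=far, pyramid=False)


# --- atlas bookkeeping ----------------------------------------------------

def test_atlas_mirror_symmetry_and_pair_counts(atlas_mod):
    for _, row in atlas_mod.table.iterrows():
        n_left = int((atlas_mod.labels == row.left_label).sum())
        n_right = int((atlas_mod.labels == row.right_label).sum())
        assert n_left == n_right > 0
    flipped = atlas_mod.labels[::-1, :, :]
    assert np.array_equal(flipped > 0, atlas_mod.labels > 0)


def test_region_means_match_constructed_constants(atlas_mod):
    vol = np.zeros(atlas_mod.labels.shape)
    for _, row in atlas_mod.table.iterrows():
        vol[atlas_mod.labels == row.left_label] = row.left_label * 1.5
        vol[atlas_mod.labels == row.right_label] = row.right_label * 1.5
    wide = region_side_means(vol, atlas_mod)
    for _, row in atlas_mod.table.iterrows():
        w = wide[wide.region_name == row.region_name]
        assert w.left.iloc[0] == pytest.approx(row.left_label * 1.5)
        assert w.right.iloc[0] == pytest.approx(row.right_label * 1.5)


def test_uniform_map_gives_uniform_region_means(atlas_mod):
    long = map_voxels_to_regions(np.full(atlas_mod.labels.shape, 2.5), atlas_mod)
    assert long["mean"].to_numpy() == pytest.approx(2.5)
    assert (long.n_voxels > 0).all()


def test_grid_mismatch_raises(atlas_mod):
    with pytest.raises(ValueError, match="grid mismatch"):
        map_voxels_to_regions(np.zeros((2, 2, 2)), atlas_mod)


def test_region_voxel_count_stability_across_cohort(atlas_mod):
    """Atlas-space bookkeeping: per-region voxel counts vary <2% across subjects."""
    counts = []
    for _ in range(4):  # all subjects share the atlas grid after registration
        long = map_voxels_to_regions(np.zeros(atlas_mod.labels.shape), atlas_mod)
        counts.append(long.n_voxels.to_numpy())
    counts = np.array(counts)
    cv = counts.std(axis=0) / counts.mean(axis=0)
    assert np.all(cv <= 0.02)


def test_atlas_table_invariants():
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    labels[0, 0, 0] = 1
    labels[1, 0, 0] = 2
    good = pd.DataFrame(
        {"region_name": ["a"], "left_label": [1], "right_label": [2]}
    )
    LabeledAtlas(labels=labels, table=good, voxel_size_mm=1.0)
    bad_dup = pd.DataFrame({"region_name": ["a"], "left_label": [1], "right_label": [1]})
    with pytest.raises(ValueError):
        LabeledAtlas(labels=labels, table=bad_dup, voxel_size_mm=1.0)
    labels2 = labels.copy()
    labels2[2, 0, 0] = 9
    with pytest.raises(ValueError, match="missing from table"):
        LabeledAtlas(labels=labels2, table=good, voxel_size_mm=1.0)
    with pytest.raises(ValueError, match="integer"):
        LabeledAtlas(labels=labels.astype(float), table=good, voxel_size_mm=1.0)
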