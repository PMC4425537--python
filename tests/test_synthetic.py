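"""Phantom generators: determinism, ground-truth consistency, injury structure."""

import numpy as np
import pytest

from ratlas_ia.dti import compute_index_maps, fit_tensor
from ratlas_ia.synthetic import (
    InjuryEffect,
    PhantomSpec,
    eigs_from_fa_trace,
    index_values_from_eigs,
    make_brain_mask,
    make_phantom_atlas,
    make_t2_truth,
    full_scale_spec,
    simulate_cohort,
    simulate_dwi,
    simulate_histology_image,
    simulate_multiecho,
    simulate_tensor_field,
    small_spec,
)


def test_spec_validation():
    with pytest.raises(ValueError, match="2 region pairs"):
        small_spec(region_names=("a",), region_sizes=(10,), baseline_evals=((1, 1, 1),))
    with pytest.raises(ValueError, match="l1>=l2>=l3"):
        small_spec(baseline_evals=((0.5, 1.0, 0.2),) * 3)
    with pytest.raises(ValueError, match="lesion"):
        small_spec(lesion_center_mm=(0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="unknown region"):
        small_spec(injury_effects=(InjuryEffect("nope", "right", "fa", 0.1),))


def test_eigs_from_fa_trace_round_trip():
    for fa, tr in [(0.0, 2.1), (0.414, 1.73), (0.83, 1.5)]:
        ev = eigs_from_fa_trace(fa, tr)
        vals = index_values_from_eigs(ev)
        assert sum(ev) == pytest.approx(tr, rel=1e-9)
        assert vals["FA"] == pytest.approx(fa, abs=1e-9)
        assert ev[0] >= ev[1] >= ev[2] > 0


def test_atlas_determinism_and_mirror_symmetry():
    spec = small_spec()
    a1 = make_phantom_atlas(spec)
    a2 = make_phantom_atlas(spec)
    assert np.array_equal(a1.labels, a2.labels)
    # right labels are the exact mirror of left labels
    for _, row in a1.table.iterrows():
        left = a1.labels == row.left_label
        right = a1.labels == row.right_label
        assert np.array_equal(left[::-1, :, :], right)


def test_small_atlas_has_seven_labels_with_equal_pair_counts():
    a = make_phantom_atlas(small_spec())
    labels, counts = np.unique(a.labels, return_counts=True)
    assert len(labels) == 7  # background + 3 pairs
    by_label = dict(zip(labels.tolist(), counts.tolist()))
    for _, row in a.table.iterrows():
        assert by_label[row.left_label] == by_label[row.right_label]


def test_full_scale_atlas_bookkeeping():
    spec = full_scale_spec()
    a = make_phantom_atlas(spec)
    labeled = int((a.labels > 0).sum())
    assert abs(labeled - 20000) / 20000 <= 0.10
    ca = a.table[a.table.region_name == "central amygdala"].iloc[0]
    n_pair = int((a.labels == ca.left_label).sum() + (a.labels == ca.right_label).sum())
    assert n_pair == pytest.approx(46, abs=4)
    assert len(a.table) == 150


def test_too_many_regions_for_grid_raises():
    with pytest.raises(ValueError, match="cannot place"):
        spec = small_spec(
            region_names=tuple(f"r{i}" for i in range(60)),
            region_sizes=(40,) * 60,
            baseline_evals=(eigs_from_fa_trace(0.3, 2.1),) * 60,
        )
        make_phantom_atlas(spec)


def test_isotropic_baseline_gives_zero_fa_everywhere():
    iso = (0.8, 0.8, 0.8)
    spec = small_spec(baseline_evals=(iso,) * 3, noise_sigma=0.0)
    atlas = make_phantom_atlas(spec)
    tf, _ = simulate_tensor_field(atlas, spec)
    maps = compute_index_maps(tf)
    assert maps.fa[tf.mask] == pytest.approx(0.0, abs=1e-12)


def test_ad_shift_moves_right_lambda1_exactly():
    eff = (InjuryEffect("central amygdala", "right", "ad", 0.2),)
    spec = small_spec(injury_effects=eff, noise_sigma=0.0)
    atlas = make_phantom_atlas(spec)
    tf, gt = simulate_tensor_field(atlas, spec)
    left = tf.evals[atlas.region_mask("central amygdala", "left")][:, 0].mean()
    right = tf.evals[atlas.region_mask("central amygdala", "right")][:, 0].mean()
    assert right - left == pytest.approx(0.2, abs=1e-12)
    truth = gt.region_index_means
    row_r = truth[(truth.region_name == "central amygdala") & (truth.side == "right")]
    row_l = truth[(truth.region_name == "central amygdala") & (truth.side == "left")]
    assert row_r.AD.iloc[0] - row_l.AD.iloc[0] == pytest.approx(0.2)


def test_negative_eigenvalue_perturbation_raises():
    eff = (InjuryEffect("central amygdala", "right", "rd", -5.0),)
    spec = small_spec(injury_effects=eff)
    atlas = make_phantom_atlas(spec)
    with pytest.raises(ValueError, match="invalid eigenvalues"):
        simulate_tensor_field(atlas, spec)


def test_dwi_closed_form_isotropic(scheme):
    spec = small_spec(baseline_evals=((0.7, 0.7, 0.7),) * 3, background_adc=0.7, noise_sigma=0.0)
    atlas = make_phantom_atlas(spec)
    tf, _ = simulate_tensor_field(atlas, spec)
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=0.0)
    inside = tf.mask
    # S = S0 * exp(-b * d) for every direction
    expected = 1000.0 * np.exp(-1000.0 * 0.7e-3)
    assert dwi[inside][:, 1:] == pytest.approx(expected)
    assert dwi[inside][:, 0] == pytest.approx(1000.0)


def test_dwi_round_trip_and_seed_reproducibility(scheme, atlas, spec):
    tf, _ = simulate_tensor_field(atlas, spec)
    a = simulate_dwi(tf, scheme, sigma=15.0, seed=42)
    b = simulate_dwi(tf, scheme, sigma=15.0, seed=42)
    c = simulate_dwi(tf, scheme, sigma=15.0, seed=43)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_multiecho_closed_form_and_validation():
    tes = 11.0 * np.arange(1, 17)
    t2 = np.full((2, 2, 2), 50.0)
    vol = simulate_multiecho(t2, A=0.0, C=1000.0, tes=tes, sigma=0.0)
    assert vol[0, 0, 0, 0] == pytest.approx(1000.0 * np.exp(-11.0 / 50.0))
    with pytest.raises(ValueError, match="positive"):
        simulate_multiecho(np.zeros((2, 2, 2)), 0.0, 1000.0, tes)


def test_t2_truth_lesion_volume_is_sphere_count(spec, atlas, brain_mask):
    t2, C, lesion = make_t2_truth(spec, brain_mask)
    vol = lesion.sum() * spec.voxel_volume_mm3
    analytic = 4.0 / 3.0 * np.pi * spec.lesion_radius_mm**3
    shell = 4.0 * np.pi * spec.lesion_radius_mm**2 * spec.voxel_size_mm
    assert abs(vol - analytic) <= shell
    assert 9.0 <= vol <= 14.0  # mild-to-moderate contusion scale
    assert np.all(t2[lesion] > t2[brain_mask & ~lesion].min())


def test_cohort_identity_without_noise_or_subject_effects():
    spec = small_spec(noise_sigma=0.0)
    cohort = simulate_cohort(spec, 3, inter_subject_sd=0.0, seed=0, displacement=False)
    assert np.array_equal(cohort.subjects[0].dwi, cohort.subjects[1].dwi)
    assert np.array_equal(cohort.subjects[1].dwi, cohort.subjects[2].dwi)


def test_cohort_displacements_are_recorded_and_bounded():
    spec = small_spec()
    cohort = simulate_cohort(spec, 3, seed=4, displacement=True)
    for t in cohort.truth.transforms:
        assert np.all(np.abs(t.angles_deg) <= 5.0)
        assert np.all(np.abs(t.translation_mm) <= 2.0 * spec.voxel_size_mm)


def test_cohort_region_mean_sd_below_ten_percent(scheme):
    """Across-subject SD of region means stays under 10% of the mean."""
    from ratlas_ia.pipeline import analyze_cohort

    spec = small_spec(mirror_s0=True)
    cohort = simulate_cohort(spec, 5, inter_subject_sd=0.05, seed=9, displacement=False)
    tbl = analyze_cohort(cohort, index="FA").table
    assert np.all(tbl.contra_sd / tbl.contra_mean < 0.10)
    assert np.all(tbl.ipsi_sd / tbl.ipsi_mean < 0.10)


def test_cohort_needs_two_subjects():
    with pytest.raises(ValueError, match="2 subjects"):
        simulate_cohort(small_spec(), 1)


# --- histology phantom ----------------------------------------------------

def test_histology_image_is_seed_deterministic():
    a, rois_a = simulate_histology_image(seed=5)
    b, rois_b = simulate_histology_image(seed=5)
    assert np.array_equal(a, b) and rois_a == rois_b


def test_histology_fold_one_is_symmetric():
    diffs = []
    for seed in range(30):
        img, rois = simulate_histology_image(roi_effect_fold=1.0, seed=seed)
        thr = 2.0 * 100.0
        for key in ("ipsi", "contra"):
            r = rois[key]
            pass
        ipsi = img[rois["ipsi"]["y"]:rois["ipsi"]["y"]+40, rois["ipsi"]["x"]:rois["ipsi"]["x"]+40]
        contra = img[rois["contra"]["y"]:rois["contra"]["y"]+40, rois["contra"]["x"]:rois["contra"]["x"]+40]
        diffs.append(int((ipsi > thr).sum()) - int((contra > thr).sum()))
    # expected difference zero; binomial scale ~ sqrt(2 * area * p) ~ 12.6
    assert abs(np.mean(diffs)) < 10.0


def test_histology_roi_must_fit():
    with pytest.raises(ValueError, match="fit"):
        simulate_histology_image(shape=(32, 32), roi_size=(40, 40))
    with pytest.raises(ValueError, match="fold"):
        simulate_histology_image(roi_effect_fold=-1.0)
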