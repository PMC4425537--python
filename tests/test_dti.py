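"""Tensor fitting, index maps, motion screening and smoothing."""

import numpy as np
import pytest

from ratlas_ia.dti import (
    compute_index_maps,
    fit_tensor,
    gaussian_smooth,
    screen_motion_artifacts,
    tensor_from_eigensystem,
    TensorField,
)
from ratlas_ia.schemes import GradientScheme, load_bvals_bvecs, save_bvals_bvecs, ten_direction_scheme
from ratlas_ia.synthetic import simulate_dwi, simulate_tensor_field, small_spec


def _tf_from_evals(evals, axis=(0.0, 0.0, 1.0), shape=(1, 1, 1)):
    D = tensor_from_eigensystem(np.asarray(evals, float), np.asarray(axis))
    tensors = np.broadcast_to(D, shape + (3, 3)).copy()
    ev = np.broadcast_to(np.sort(evals)[::-1], shape + (3,)).copy()
    ax = np.broadcast_to(np.asarray(axis, float), shape + (3,)).copy()
    return TensorField(tensors=tensors, evals=ev, principal_axis=ax, mask=np.ones(shape, bool))


def _fa_oracle(l1, l2, l3):
    # brute force from the definition with plain scalar arithmetic
    adc = (l1 + l2 + l3) / 3.0
    num = (l1 - adc) ** 2 + (l2 - adc) ** 2 + (l3 - adc) ** 2
    den = l1 * l1 + l2 * l2 + l3 * l3
    return (1.5 * num / den) ** 0.5


@pytest.mark.parametrize(
    "evals, fa, ad, rd, adc",
    [
        ((1.0, 1.0, 1.0), 0.0, 1.0, 1.0, 1.0),
        ((1.0, 0.0, 0.0), 1.0, 1.0, 0.0, 1.0 / 3.0),
        ((1.7, 0.3, 0.2), _fa_oracle(1.7, 0.3, 0.2), 1.7, 0.25, 2.2 / 3.0),
    ],
)
def test_index_map_values(evals, fa, ad, rd, adc):
    maps = compute_index_maps(_tf_from_evals(evals))
    assert maps.fa.ravel()[0] == pytest.approx(fa, abs=1e-12)
    assert maps.ad.ravel()[0] == pytest.approx(ad, abs=1e-12)
    assert maps.rd.ravel()[0] == pytest.approx(rd, abs=1e-12)
    assert maps.adc.ravel()[0] == pytest.approx(adc, abs=1e-12)


def test_fa_for_anisotropic_example_matches_literature_scale():
    # (1.7, 0.3, 0.2) 1e-3 mm^2/s is strongly anisotropic white-matter-like
    assert _fa_oracle(1.7, 0.3, 0.2) == pytest.approx(0.836, abs=5e-4)


def test_fa_scale_invariance_and_monotonicity(rng):
    for _ in range(20):
        l2, l3 = np.sort(rng.uniform(0.1, 1.0, 2))[::-1]
        l1 = rng.uniform(l2, 3.0)
        fa = _fa_oracle(l1, l2, l3)
        c = rng.uniform(0.2, 5.0)
        assert _fa_oracle(c * l1, c * l2, c * l3) == pytest.approx(fa, rel=1e-12)
    # increasing l1 at fixed l2 == l3 increases FA
    fas = [_fa_oracle(l1, 0.4, 0.4) for l1 in np.linspace(0.5, 2.5, 9)]
    assert np.all(np.diff(fas) > 0)


def test_noiseless_round_trip_random_spd_tensors(scheme, rng):
    n = 40
    evals = np.sort(rng.uniform(0.2, 2.2, (n, 3)), axis=1)[:, ::-1]
    axes = rng.normal(size=(n, 3))
    tensors = np.stack(
        [tensor_from_eigensystem(e, a) for e, a in zip(evals, axes)]
    ).reshape(n, 1, 1, 3, 3)
    tf = TensorField(
        tensors=tensors,
        evals=np.broadcast_to(evals[:, None, None, :], (n, 1, 1, 3)).copy(),
        principal_axis=np.zeros((n, 1, 1, 3)),
        mask=np.ones((n, 1, 1), bool),
    )
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=0.0)
    refit = fit_tensor(dwi, scheme, mask=tf.mask)
    rel = np.abs(refit.tensors - tf.tensors).max() / np.abs(tf.tensors).max()
    assert rel < 1e-10


def test_duplicate_gradient_directions_leave_solution_unchanged(scheme, rng):
    ev = np.array([1.5, 0.6, 0.3])
    tf = _tf_from_evals(ev, axis=(1.0, 2.0, 0.5))
    dwi = simulate_dwi(tf, scheme, s0=500.0, sigma=0.0)
    dup = GradientScheme(
        np.concatenate([scheme.bvals, scheme.bvals[1:3]]),
        np.vstack([scheme.bvecs, scheme.bvecs[1:3]]),
    )
    dwi_dup = np.concatenate([dwi, dwi[..., 1:3]], axis=-1)
    fit_a = fit_tensor(dwi, scheme, mask=tf.mask)
    fit_b = fit_tensor(dwi_dup, dup, mask=tf.mask)
    # oracle: explicit pseudo-inverse solution on the unduplicated system
    X = scheme.design_matrix()
    beta = np.linalg.pinv(X) @ np.log(dwi.reshape(-1, scheme.n_frames).T)
    assert fit_a.tensors == pytest.approx(fit_b.tensors, abs=1e-12)
    assert fit_a.tensors[0, 0, 0, 0, 0] == pytest.approx(beta[0, 0], abs=1e-12)


def test_all_dwi_frames_excluded_masks_voxels_out(scheme):
    tf = _tf_from_evals((1.0, 1.0, 1.0), shape=(2, 2, 2))
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=0.0)
    excl = {(1, f) for f in range(1, scheme.n_frames)}  # all DWI frames, slice 1
    fitted = fit_tensor(dwi, scheme, mask=tf.mask, exclusions=excl)
    assert not fitted.mask[:, :, 1].any()
    assert fitted.mask[:, :, 0].all()


def test_screen_clean_phantom_flags_nothing(scheme):
    spec = small_spec(noise_sigma=0.0)
    from ratlas_ia.synthetic import make_brain_mask, make_phantom_atlas

    atlas = make_phantom_atlas(spec)
    tf, _ = simulate_tensor_field(atlas, spec)
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=0.0)
    assert screen_motion_artifacts(dwi, scheme, mask=tf.mask) == set()


def test_screen_flags_exactly_the_corrupted_slice_frame(scheme):
    spec = small_spec()
    from ratlas_ia.synthetic import make_phantom_atlas

    atlas = make_phantom_atlas(spec)
    tf, _ = simulate_tensor_field(atlas, spec)
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=10.0, seed=3)
    dwi[:, :, 12, 4] = 0.0
    flagged = screen_motion_artifacts(dwi, scheme, mask=tf.mask, k=4.0)
    assert flagged == {(12, 4)}


def test_screen_raises_when_too_few_directions_remain(scheme, rng):
    shape = (4, 4, 2)
    dwi = np.full(shape + (scheme.n_frames,), 100.0)
    dwi += rng.normal(0, 0.1, dwi.shape)
    dwi[:, :, 0, 3:9] = 1e6  # corrupt 6 of 10 directions on slice 0
    with pytest.raises(ValueError, match="under-determined"):
        screen_motion_artifacts(dwi, scheme, k=4.0)


def test_gaussian_smooth_identity_dc_and_mass(rng):
    vol = rng.random((10, 10, 10))
    assert gaussian_smooth(vol, 0.0, 0.3) == pytest.approx(vol)
    mask = np.zeros((10, 10, 10), bool)
    mask[2:8, 2:8, 2:8] = True
    const = np.where(mask, 3.7, 0.0)
    sm = gaussian_smooth(const, 0.3, 0.3, mask=mask)
    assert sm[mask] == pytest.approx(3.7, abs=1e-9)
    delta = np.zeros((21, 21, 21))
    delta[10, 10, 10] = 1.0
    assert gaussian_smooth(delta, 0.3, 0.3).sum() == pytest.approx(1.0, abs=1e-8)
    with pytest.raises(ValueError):
        gaussian_smooth(vol, -1.0, 0.3)


def test_rician_noise_positively_biases_isotropic_fa(scheme):
    tf = _tf_from_evals((0.7, 0.7, 0.7), shape=(6, 6, 6))
    fas = []
    for seed in range(50):
        dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=30.0, seed=seed)
        maps = compute_index_maps(fit_tensor(dwi, scheme, mask=tf.mask))
        fas.append(maps.fa[tf.mask].mean())
    assert np.mean(fas) > 0.0 and np.min(fas) > 0.0


def test_ad_adc_rd_ordering_on_noisy_fit(scheme, atlas, spec):
    tf, _ = simulate_tensor_field(atlas, spec)
    dwi = simulate_dwi(tf, scheme, s0=1000.0, sigma=20.0, seed=11)
    maps = compute_index_maps(fit_tensor(dwi, scheme, mask=tf.mask))
    m = maps.mask
    assert np.all(maps.ad[m] + 1e-12 >= maps.adc[m])
    assert np.all(maps.adc[m] + 1e-12 >= maps.rd[m])
    assert maps.fa[m].min() >= 0.0 and maps.fa[m].max() <= 1.0


def test_scheme_validation_and_io(tmp_path):
    with pytest.raises(ValueError, match="unit norm"):
        GradientScheme([0, 1000], [[0, 0, 0], [1, 1, 0]])
    with pytest.raises(ValueError, match="b0"):
        GradientScheme([1000] * 7, np.eye(3).tolist() + np.eye(3).tolist() + [[1, 0, 0]])
    sch = ten_direction_scheme()
    save_bvals_bvecs(sch, tmp_path / "bvals", tmp_path / "bvecs")
    back = load_bvals_bvecs(tmp_path / "bvals", tmp_path / "bvecs")
    assert back.bvals == pytest.approx(sch.bvals)
    assert back.bvecs == pytest.approx(sch.bvecs, abs=1e-9)


def test_repetition_averaging_signal_vs_map_space(scheme):
    ev = np.array([1.4, 0.5, 0.4])
    tf = _tf_from_evals(ev, axis=(0.3, 1.0, 0.2), shape=(3, 3, 3))
    from ratlas_ia.dti import average_repetitions

    clean = simulate_dwi(tf, scheme, s0=800.0, sigma=0.0)
    reps = [clean, clean.copy()]
    avg = average_repetitions(reps, mode="signal")
    assert avg == pytest.approx(clean)
    by_map = average_repetitions(reps, mode="map", scheme=scheme, mask=tf.mask)
    by_sig = compute_index_maps(fit_tensor(avg, scheme, mask=tf.mask))
    assert by_map["FA"] == pytest.approx(by_sig.fa, abs=1e-10)
    with pytest.raises(ValueError, match="scheme"):
        average_repetitions(reps, mode="map")
    with pytest.raises(ValueError, match="shape"):
        average_repetitions([clean, clean[:2]])
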