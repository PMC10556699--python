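"""Data-module tests: readers, preprocessing, phantom geometry, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoseg.data import (EchoSample, PhantomParams, ValidationError,
                          generate_phantom, generate_phantom_dataset,
                          make_split, phantom_masks, preprocess, read_sample,
                          write_mask_png)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------
def test_metaimage_roundtrip_with_mask(tmp_path, rng):
    import SimpleITK as sitk
    img = rng.integers(0, 255, size=(96, 64)).astype(np.float32)
    mask = rng.integers(0, 4, size=(96, 64)).astype(np.uint8)
    sitk.WriteImage(sitk.GetImageFromArray(img), str(tmp_path / "img.mhd"))
    sitk.WriteImage(sitk.GetImageFromArray(mask), str(tmp_path / "msk.mhd"))
    sample = read_sample(tmp_path / "img.mhd", tmp_path / "msk.mhd")
    np.testing.assert_allclose(sample.image, img)
    np.testing.assert_array_equal(sample.mask, mask)
    assert set(np.unique(sample.mask)) <= {0, 1, 2, 3}


def test_png_roundtrip_without_mask(tmp_path, rng):
    import imageio.v3 as iio
    img = rng.integers(0, 255, size=(32, 40)).astype(np.uint8)
    iio.imwrite(tmp_path / "img.png", img)
    sample = read_sample(tmp_path / "img.png")
    assert sample.mask is None
    np.testing.assert_allclose(sample.image, img)


def test_paletted_mask_png_roundtrip(tmp_path, rng):
    mask = rng.integers(0, 4, size=(20, 20))
    write_mask_png(mask, tmp_path / "m.png")
    sample = read_sample(tmp_path / "m.png", tmp_path / "m.png")
    np.testing.assert_array_equal(sample.mask, mask)


def test_missing_file_raises_io_error_naming_path(tmp_path):
    with pytest.raises(IOError, match="nope.mhd"):
        read_sample(tmp_path / "nope.mhd")


def test_invalid_mask_values_rejected(tmp_path, rng):
    import imageio.v3 as iio
    img = rng.integers(0, 255, size=(16, 16)).astype(np.uint8)
    bad = np.full((16, 16), 4, dtype=np.uint8)
    iio.imwrite(tmp_path / "img.png", img)
    iio.imwrite(tmp_path / "bad.png", bad)
    with pytest.raises(ValidationError, match=r"\[4\]"):
        read_sample(tmp_path / "img.png", tmp_path / "bad.png")


def test_mask_shape_mismatch_rejected(rng):
    with pytest.raises(ValidationError, match="shape"):
        EchoSample(image=np.zeros((8, 8)), mask=np.zeros((4, 4), int))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------
def test_preprocess_maps_range_to_plus_minus_one(rng):
    sample = EchoSample(image=rng.integers(0, 256, size=(84, 51)).astype(float))
    out = preprocess(sample, 64)
    assert out.image.shape == (64, 64)
    assert out.image.min() == pytest.approx(-1.0)
    assert out.image.max() == pytest.approx(1.0)


def test_preprocess_constant_image_maps_to_zero():
    out = preprocess(EchoSample(image=np.full((30, 30), 7.0)), 32)
    np.testing.assert_array_equal(out.image, 0.0)


def test_preprocess_is_idempotent_at_same_size(rng):
    sample = EchoSample(image=rng.normal(size=(64, 64)))
    once = preprocess(sample, 64)
    twice = preprocess(once, 64)
    assert np.abs(once.image - twice.image).max() < 1e-6


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_mask_resize_never_invents_labels(seed):
    rng = np.random.default_rng(seed)
    labels = sorted(rng.choice(4, size=rng.integers(1, 4), replace=False))
    mask = rng.choice(labels, size=(rng.integers(20, 120),
                                    rng.integers(20, 120)))
    img = rng.normal(size=mask.shape)
    out = preprocess(EchoSample(image=img, mask=mask), 64)
    assert set(np.unique(out.mask)) <= set(labels)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------
def clean_params(size=48):
    return PhantomParams(image_size=size, contrast=1.0, speckle_scale=0.0,
                         boundary_blur_sigma=0.0, truncation_prob=0.0, seed=5)


def test_phantom_fixed_seed_is_bit_reproducible():
    params = PhantomParams(image_size=64, contrast=0.7, speckle_scale=0.4,
                           boundary_blur_sigma=1.0, truncation_prob=1.0,
                           seed=11)
    a, b = generate_phantom(params), generate_phantom(params)
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)


def test_clean_phantom_matches_bruteforce_rasterization():
    """With no corruption the mask equals a per-pixel ellipse-inequality scan."""
    params = clean_params(48)
    sample = generate_phantom(params)
    s = params.image_size
    expected = np.zeros((s, s), dtype=int)
    for r in range(s):
        for c in range(s):
            def inside(center, axes):
                return (((r - center[0] * s) / (axes[0] * s)) ** 2
                        + ((c - center[1] * s) / (axes[1] * s)) ** 2) <= 1.0
            if inside(params.lv_center, params.lv_axes):
                expected[r, c] = 1
            elif inside(params.lv_center,
                        (params.lv_axes[0] + params.myo_thickness,
                         params.lv_axes[1] + params.myo_thickness)):
                expected[r, c] = 2
            elif inside(params.la_center, params.la_axes):
                expected[r, c] = 3
    np.testing.assert_array_equal(sample.mask, expected)
    # piecewise-constant image: one intensity per structure
    for label in (1, 2, 3):
        assert len(np.unique(sample.image[sample.mask == label])) == 1


def test_phantom_class_areas_equal_shape_areas():
    params = clean_params(64)
    sample = generate_phantom(params)
    shapes = phantom_masks(params)
    assert (sample.mask == 1).sum() == shapes["lv"].sum()
    assert (sample.mask == 2).sum() == (shapes["outer"] & ~shapes["lv"]).sum()
    assert (sample.mask == 3).sum() == (shapes["la"] & ~shapes["outer"]).sum()


def test_phantom_too_large_geometry_rejected():
    with pytest.raises(ValidationError, match="sector"):
        generate_phantom(PhantomParams(image_size=64, lv_axes=(0.45, 0.45)))


def test_phantom_dataset_is_preprocessed_and_deterministic():
    a = generate_phantom_dataset(6, 32, seed=3)
    b = generate_phantom_dataset(6, 32, seed=3)
    assert len(a) == 6
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.image, sb.image)
        assert sa.image.shape == (32, 32)
        assert sa.image.min() >= -1.0 and sa.image.max() <= 1.0
        assert set(np.unique(sa.mask)) <= {0, 1, 2, 3}


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------
def test_split_examples():
    ids = [f"p{i}" for i in range(8)]
    sp = make_split(ids, 0.5, 0.0, seed=1)
    assert len(sp.labeled) == 4 and len(sp.unlabeled) == 4
    full = make_split(ids, 1.0, 0.0, seed=1)
    assert full.unlabeled == []
    sp450 = make_split([f"p{i}" for i in range(450)], 0.25, 0.0, seed=0)
    assert len(sp450.labeled) in (112, 113)


def test_split_reproducible_and_patient_disjoint():
    ids = [f"p{i}" for i in range(20)]
    a = make_split(ids, 0.25, 0.2, seed=9)
    b = make_split(ids, 0.25, 0.2, seed=9)
    assert a.labeled == b.labeled and a.test == b.test


def test_split_too_few_patients_rejected():
    with pytest.raises(ValidationError):
        make_split(["only"], 0.5, 0.0, seed=0)


@given(st.integers(2, 200), st.sampled_from([0.25, 0.5, 1.0]),
       st.integers(0, 2 ** 31 - 1))
@settings(max_examples=200, deadline=None)
def test_split_invariants_hold(n, ratio, seed):
    ids = [f"p{i}" for i in range(n)]
    sp = make_split(ids, ratio, 0.2 if n >= 5 else 0.0, seed=seed)
    assert not set(sp.labeled) & set(sp.unlabeled)
    assert not (set(sp.labeled) | set(sp.unlabeled)) & set(sp.test)
    n_train = len(sp.labeled) + len(sp.unlabeled)
    assert abs(len(sp.labeled) - n_train * ratio) <= 1
    assert n_train + len(sp.test) == n
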