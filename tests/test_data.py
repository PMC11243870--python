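"""Dataset reading, letterboxing, augmentation and the lesion generator."""

import numpy as np
import pytest
from PIL import Image
from scipy import ndimage

from elanet.data import (AugmentConfig, ImageSample, SyntheticLesionSpec,
                         augment, letterbox, letterbox_geometry, load_dataset,
                         split_train_val, synthesize, synthesize_mixed,
                         write_dataset)


def make_sample(h=40, w=60, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
    mask = (rng.random((h, w)) < 0.3).astype(np.uint8)
    return ImageSample(img, mask, f"s{seed}")


# -- disk IO ---------------------------------------------------------------

def test_load_dataset_roundtrip_and_order(tmp_path):
    samples = [make_sample(seed=i) for i in (2, 0, 1)]
    write_dataset(samples, tmp_path)
    loaded = load_dataset(tmp_path / "images", tmp_path / "masks")
    assert [s.id for s in loaded] == ["s0", "s1", "s2"]  # stem order
    by_id = {s.id: s for s in samples}
    for s in loaded:
        np.testing.assert_array_equal(s.image, by_id[s.id].image)
        np.testing.assert_array_equal(s.mask, by_id[s.id].mask)
        assert set(np.unique(s.mask)) <= {0, 1}


def test_load_dataset_empty_and_unpaired(tmp_path):
    (tmp_path / "images").mkdir()
    (tmp_path / "masks").mkdir()
    assert load_dataset(tmp_path / "images", tmp_path / "masks") == []
    Image.fromarray(np.zeros((4, 4, 3), np.uint8)).save(tmp_path / "images" / "a.png")
    with pytest.raises(ValueError, match="a"):
        load_dataset(tmp_path / "images", tmp_path / "masks")


def test_mask_binarization_threshold(tmp_path):
    (tmp_path / "images").mkdir(), (tmp_path / "masks").mkdir()
    Image.fromarray(np.zeros((2, 2, 3), np.uint8)).save(tmp_path / "images" / "x.png")
    m = np.array([[0, 127], [128, 255]], dtype=np.uint8)
    Image.fromarray(m).save(tmp_path / "masks" / "x_segmentation.png")
    [s] = load_dataset(tmp_path / "images", tmp_path / "masks")
    np.testing.assert_array_equal(s.mask, [[0, 0], [1, 1]])


# -- letterbox ---------------------------------------------------------------

def test_letterbox_geometry_against_arithmetic_oracle():
    # 450h x 600w into 512h x 1024w: scale = min(1024/600, 512/450)
    scale, (ch, cw), (top, left) = letterbox_geometry((450, 600), (512, 1024))
    expect_scale = min(1024 / 600, 512 / 450)
    assert scale == pytest.approx(expect_scale)
    assert (ch, cw) == (round(450 * expect_scale), round(600 * expect_scale))
    assert (top, left) == ((512 - ch) // 2, (1024 - cw) // 2)


def test_letterbox_square_source_centers_with_gray_bands():
    s = make_sample(100, 100)
    out = letterbox(s, (512, 1024), pad_value=128)
    assert out.image.shape == (512, 1024, 3)
    # content 512x512 centered: 256-pixel gray bands left and right
    assert (out.image[:, :256] == 128).all() and (out.image[:, -256:] == 128).all()
    assert (out.mask[:, :256] == 0).all()
    assert set(np.unique(out.mask)) <= {0, 1}


def test_letterbox_identity_on_target_sized_input():
    s = make_sample(512, 1024)
    out = letterbox(s, (512, 1024))
    np.testing.assert_array_equal(out.image, s.image)
    np.testing.assert_array_equal(out.mask, s.mask)


def test_letterbox_rejects_zero_area():
    with pytest.raises(ValueError, match="zero-area"):
        letterbox_geometry((0, 10), (64, 64))


# -- augmentation -------------------------------------------------------------

def test_augment_deterministic_binary_and_divisible():
    cfg = AugmentConfig(target_size=(64, 128), seed=5)
    s = make_sample(50, 70, seed=3)
    a = augment(s, cfg, np.random.default_rng(9))
    b = augment(s, cfg, np.random.default_rng(9))
    np.testing.assert_array_equal(a.image, b.image)
    np.testing.assert_array_equal(a.mask, b.mask)
    assert a.image.shape == (64, 128, 3)
    assert set(np.unique(a.mask)) <= {0, 1}
    assert a.image.shape[0] % 8 == 0 and a.image.shape[1] % 8 == 0


def test_horizontal_flip_is_an_involution():
    s = make_sample(16, 16, seed=1)
    flipped = ImageSample(s.image[:, ::-1].copy(), s.mask[:, ::-1].copy(), s.id)
    np.testing.assert_array_equal(flipped.image[:, ::-1], s.image)
    np.testing.assert_array_equal(flipped.mask[:, ::-1], s.mask)


def test_augment_geometry_applied_identically_to_image_and_mask():
    """A mask painted into the image must stay aligned with the mask."""
    h, w = 48, 48
    mask = np.zeros((h, w), np.uint8)
    mask[10:30, 15:35] = 1
    img = np.stack([mask * 255] * 3, axis=-1)
    cfg = AugmentConfig(target_size=(64, 64), blur_sigma_range=(0.0, 0.0))
    out = augment(ImageSample(img, mask, "x"), cfg, np.random.default_rng(2))
    painted = (out.image[:, :, 0] > 200).astype(np.uint8)  # gray padding is 128
    agreement = (painted == out.mask).mean()
    assert agreement > 0.98  # edge pixels may differ due to interpolation


def test_augment_config_rejects_bad_target():
    with pytest.raises(ValueError, match="divisible by 8"):
        AugmentConfig(target_size=(50, 64))


# -- synthesis ----------------------------------------------------------------

def test_oversized_masks_exceed_half_the_frame():
    for s in synthesize(SyntheticLesionSpec(size=(64, 64), case="oversized", seed=7), 4):
        assert s.mask.mean() > 0.5


def test_synthesis_is_deterministic_per_seed():
    spec = SyntheticLesionSpec(size=(48, 64), case="blurred", seed=3)
    a = synthesize(spec, 2)
    b = synthesize(spec, 2)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.image, y.image)
        np.testing.assert_array_equal(x.mask, y.mask)
    c = synthesize(SyntheticLesionSpec(size=(48, 64), case="blurred", seed=4), 1)
    assert not np.array_equal(a[0].mask, c[0].mask)


def test_masks_are_single_connected_components():
    """Flood-fill (connected-component labelling) finds exactly one blob."""
    for case in ("oversized", "irregular", "blurred"):
        for s in synthesize(SyntheticLesionSpec(size=(56, 72), case=case, seed=11), 3):
            _, n = ndimage.label(s.mask)
            assert n == 1


def test_area_fractions_fall_inside_spec_interval():
    spec = SyntheticLesionSpec(size=(48, 48), case="irregular",
                               lesion_area_fraction=(0.15, 0.35), seed=0)
    fractions = [s.mask.mean() for s in synthesize(spec, 100)]
    assert all(0.15 - 0.02 <= f <= 0.35 + 0.02 for f in fractions)


def test_infeasible_oversized_spec_is_rejected():
    with pytest.raises(ValueError, match="0.5"):
        SyntheticLesionSpec(case="oversized", lesion_area_fraction=(0.2, 0.4))
    with pytest.raises(ValueError, match="case"):
        SyntheticLesionSpec(case="giant")
    with pytest.raises(ValueError, match="interval"):
        SyntheticLesionSpec(lesion_area_fraction=(0.0, 0.99))


def test_blurred_case_softens_image_but_not_mask():
    spec_b = SyntheticLesionSpec(size=(64, 64), case="blurred", seed=5)
    spec_i = SyntheticLesionSpec(size=(64, 64), case="irregular", seed=5)
    blurred, = synthesize(spec_b, 1)
    crisp, = synthesize(spec_i, 1)
    assert set(np.unique(blurred.mask)) <= {0, 1}
    # boundary contrast: mean gradient magnitude along the mask edge
    def edge_grad(s):
        gray = s.image.mean(axis=2)
        gy, gx = np.gradient(gray)
        edge = ndimage.binary_dilation(s.mask) ^ s.mask.astype(bool)
        return np.hypot(gy, gx)[edge].mean()
    assert edge_grad(blurred) < edge_grad(crisp)


def test_split_is_deterministic_and_disjoint():
    samples = synthesize_mixed((32, 32), 10, seed=2)
    tr1, va1 = split_train_val(samples, 0.2, seed=3)
    tr2, va2 = split_train_val(samples, 0.2, seed=3)
    assert [s.id for s in tr1] == [s.id for s in tr2]
    assert [s.id for s in va1] == [s.id for s in va2]
    assert len(va1) == 2 and len(tr1) == 8
    assert not {s.id for s in tr1} & {s.id for s in va1}
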