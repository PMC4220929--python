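import numpy as np
import pytest

from slidequant import (
    StainBasis,
    ThresholdSpec,
    identify_primary_objects,
    otsu_three_class,
    render_overlay,
    resolve_threshold,
    rgb_to_od,
    segment_tissue,
    unmix,
)
from slidequant.detection import (
    DegenerateInputError,
    declump_by_intensity,
    measure_tile,
)


from _oracles import otsu3_oracle, random_histogram_values


@pytest.mark.parametrize("criterion", ["entropy", "variance"])
def test_otsu3_matches_bruteforce_oracle(criterion):
    rng = np.random.default_rng(0)
    for _ in range(8):
        vals = random_histogram_values(rng)
        got = otsu_three_class(vals, criterion=criterion, bins=64)
        expected = otsu3_oracle(vals, criterion=criterion, bins=64)
        assert got == pytest.approx(expected, abs=0)


def test_otsu3_trimodal_thresholds_between_peaks():
    rng = np.random.default_rng(1)
    vals = np.clip(
        np.concatenate([rng.normal(m, 0.02, 3000) for m in (0.1, 0.5, 0.9)]), 0, 1
    )
    t_low, t_high = otsu_three_class(vals, criterion="entropy")
    # thresholds separate the three modes; exact values frozen from the
    # brute-force oracle (the criterion is flat across empty histogram gaps,
    # ties resolving to the lowest boundary pair)
    assert 0.1 < t_low < 0.5 < t_high < 0.9
    assert (t_low, t_high) == pytest.approx((0.17578125, 0.58203125))


def test_otsu3_degenerate_input_rejected():
    with pytest.raises(DegenerateInputError):
        otsu_three_class(np.array([0.0, 1.0, 0.0, 1.0]))


# --- optical density and unmixing ------------------------------------------

def test_rgb_to_od_reference_points():
    od = rgb_to_od(np.array([[[255, 255, 255]]], dtype=np.uint8))
    np.testing.assert_allclose(od, 0.0)
    od = rgb_to_od(np.array([[[25, 25, 25]]], dtype=np.uint8))
    np.testing.assert_allclose(od, -np.log10(26 / 256), rtol=1e-12)
    # brighter than background clips to zero
    od = rgb_to_od(np.array([[[255, 255, 255]]], dtype=np.uint8), (200, 200, 200))
    np.testing.assert_allclose(od, 0.0)


def _forward_pixels(c_dab, c_hema, basis):
    od = c_dab[..., None] * basis.vector("dab") + c_hema[..., None] * basis.vector("hematoxylin")
    return 256.0 * np.power(10.0, -od) - 1.0  # exact inverse of rgb_to_od


def test_unmix_recovers_forward_rendered_concentrations():
    basis = StainBasis()
    rng = np.random.default_rng(3)
    c_dab = rng.uniform(0, 0.9, (64, 64))
    c_hema = rng.uniform(0, 0.45, (64, 64))
    pixels = _forward_pixels(c_dab, c_hema, basis)
    conc = unmix(rgb_to_od(pixels), basis, c_max=1.5)
    np.testing.assert_allclose(conc["dab"].values, c_dab / 1.5, atol=1e-6)
    np.testing.assert_allclose(conc["hematoxylin"].values, c_hema / 1.5, atol=1e-6)


def test_unmix_noise_rms_bounded():
    basis = StainBasis()
    rng = np.random.default_rng(4)
    c_dab = rng.uniform(0, 0.9, (128, 128))
    c_hema = rng.uniform(0, 0.45, (128, 128))
    pixels = _forward_pixels(c_dab, c_hema, basis) + rng.normal(0, 2.0, (128, 128, 3))
    conc = unmix(rgb_to_od(np.clip(pixels, 0, 255)), basis, c_max=1.5)
    rms = np.sqrt(np.mean((conc["dab"].values - c_dab / 1.5) ** 2))
    assert rms < 0.02


def test_unmix_pure_stains():
    basis = StainBasis()
    od = 0.75 * basis.vector("dab") * np.ones((4, 4, 1))
    conc = unmix(od, basis, c_max=1.5)
    np.testing.assert_allclose(conc["dab"].values, 0.5, atol=1e-9)
    np.testing.assert_allclose(conc["hematoxylin"].values, 0.0, atol=1e-9)
    white = unmix(np.zeros((4, 4, 3)), basis)
    np.testing.assert_allclose(white["dab"].values, 0.0)


def test_singular_basis_rejected():
    with pytest.raises(ValueError):
        StainBasis(names=("a", "b"), vectors=np.array([[1.0, 0, 0], [1.0, 0, 0]]))


# --- threshold resolution ---------------------------------------------------

@pytest.mark.parametrize(
    "t_low,expected",
    [(0.30, 0.5), (0.50, 0.65), (0.90, 1.0)],
)
def test_resolve_threshold_correction_and_bounds(t_low, expected):
    spec = ThresholdSpec()  # factor 1.3, bounds [0.5, 1.0], middle -> foreground
    assert resolve_threshold(spec, (t_low, 0.95)) == pytest.approx(expected)


# --- object identification ---------------------------------------------------

def _disk_channel(shape, centers, diameters, value=0.8):
    out = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cx, cy), d in zip(centers, diameters):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        out = np.maximum(out, np.where(r2 <= (d / 2.0) ** 2, value, 0.0))
    return out


def test_single_disk_identified_with_diameter():
    ch = _disk_channel((64, 64), [(32, 32)], [16])
    objs = identify_primary_objects(ch, 0.5)
    assert objs.count == 1
    assert objs.table["equivalent_diameter"].iloc[0] == pytest.approx(16, abs=1)


def test_small_disk_discarded_by_gate():
    ch = _disk_channel((64, 64), [(32, 32)], [4])
    assert identify_primary_objects(ch, 0.5).count == 0
    big = _disk_channel((128, 128), [(64, 64)], [40])
    assert identify_primary_objects(big, 0.5).count == 0
    assert identify_primary_objects(np.zeros((32, 32)), 0.5).count == 0


def test_declump_splits_dumbbell_keeps_single():
    # two overlapping 14-px disks with distinct intensity peaks
    yy, xx = np.mgrid[0:48, 0:64]
    ch = np.zeros((48, 64))
    for cx in (26, 36):
        rho2 = ((xx - cx) ** 2 + (yy - 24) ** 2) / 49.0
        ch = np.maximum(ch, np.where(rho2 <= 1, 0.7 * (1 + 0.3 * (1 - rho2)), 0.0))
    objs = declump_by_intensity(ch >= 0.5, ch, suppression_radius=4)
    assert objs.count == 2
    single = _disk_channel((48, 48), [(24, 24)], [14])
    assert declump_by_intensity(single >= 0.5, single, suppression_radius=4).count == 1
    empty = declump_by_intensity(np.zeros((16, 16), bool), np.zeros((16, 16)), 4)
    assert empty.count == 0


def test_segment_tissue_threshold_and_gate():
    white = np.full((128, 128, 3), 255, dtype=np.uint8)
    assert segment_tissue(white).count == 0
    # faint blob: gray 0.9 -> inverted 0.1 >= 0.03, 200 px diameter passes gate
    px = np.full((256, 256, 3), 255, dtype=np.uint8)
    yy, xx = np.mgrid[0:256, 0:256]
    px[((xx - 128) ** 2 + (yy - 128) ** 2) <= 100**2] = 230
    tissue = segment_tissue(px)
    assert tissue.count == 1
    # dark speck of 10 px diameter removed by the 40 px gate
    speck = np.full((128, 128, 3), 255, dtype=np.uint8)
    speck[((xx[:128, :128] - 64) ** 2 + (yy[:128, :128] - 64) ** 2) <= 5**2] = 0
    assert segment_tissue(speck).count == 0


def test_measure_tile_counts_only_nuclei_on_tissue(small_slide):
    slide, truth = small_slide
    meas, tissue, dab = measure_tile(slide.layers[0])
    assert meas.dab_object_count == truth.count
    assert meas.tissue_area > 0 and meas.dab_area > 0
    # blank tile
    blank = np.full((256, 256, 3), 255, dtype=np.uint8)
    m2, _, _ = measure_tile(blank)
    assert (m2.tissue_area, m2.dab_object_count, m2.dab_area) == (0, 0, 0)


def test_measure_tile_is_deterministic(small_slide):
    slide, _ = small_slide
    tile = slide.layers[0].pixels[:512, :512]
    a, _, _ = measure_tile(tile)
    b, _, _ = measure_tile(tile.copy())
    assert (a.tissue_area, a.dab_object_count, a.dab_area) == (
        b.tissue_area, b.dab_object_count, b.dab_area,
    )


def test_overlay_outlines_colors(small_slide):
    slide, _ = small_slide
    tile = slide.layers[0].pixels[:512, :512]
    meas, tissue, dab = measure_tile(tile)
    out = render_overlay(tile, tissue, dab)
    assert out.shape == tile.shape
    green = (out == np.array([0, 255, 0])).all(axis=2)
    blue = (out == np.array([0, 0, 255])).all(axis=2)
    assert green.sum() > 0 and blue.sum() > 0
    # empty object sets leave the tile unchanged
    from slidequant.detection import _object_set_from_labels

    empty = _object_set_from_labels(np.zeros((512, 512), dtype=np.int32))
    np.testing.assert_array_equal(render_overlay(tile, empty, empty), tile)
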