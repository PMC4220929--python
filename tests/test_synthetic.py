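import numpy as np
import pytest

from slidequant import (
    StainBasis,
    SyntheticSlideSpec,
    add_artifacts,
    render_replicate,
    render_slide,
)
from slidequant.detection import measure_tile, rgb_to_od, unmix
from slidequant.synthetic import PlacementError, block_mean_downsample


def test_render_is_deterministic_per_seed():
    spec = SyntheticSlideSpec(seed=1, canvas=(256, 256), nucleus_count=10, noise_sigma=2.0)
    s1, t1 = render_slide(spec)
    s2, t2 = render_slide(spec)
    for a, b in zip(s1.layers, s2.layers):
        np.testing.assert_array_equal(a.pixels, b.pixels)
    np.testing.assert_array_equal(t1.positions, t2.positions)


def test_zero_nucleus_slide_yields_zero_detections():
    spec = SyntheticSlideSpec(seed=2, canvas=(512, 512), nucleus_count=0, noise_sigma=2.0)
    slide, truth = render_slide(spec)
    assert truth.count == 0
    meas, _, _ = measure_tile(slide.layers[0])
    assert meas.dab_object_count == 0
    assert meas.tissue_area > 0  # tissue is still there


def test_pyramid_levels_are_exact_block_means():
    spec = SyntheticSlideSpec(seed=3, canvas=(256, 256), nucleus_count=10, noise_sigma=2.0)
    slide, _ = render_slide(spec)
    top = slide.layers[0].pixels
    np.testing.assert_array_equal(slide.layers[1].pixels, block_mean_downsample(top, 2))
    np.testing.assert_array_equal(slide.layers[2].pixels, block_mean_downsample(top, 32))
    assert slide.magnifications == [20.0, 10.0, 0.625]


def test_forward_inverse_consistency_with_detection_basis():
    spec = SyntheticSlideSpec(seed=4, canvas=(256, 256), nucleus_count=8, noise_sigma=0.0)
    slide, truth = render_slide(spec)
    conc = unmix(rgb_to_od(slide.layers[0].pixels), StainBasis())
    dab = conc["dab"].values * conc["dab"].c_max
    # nucleus centers carry the peaked profile (1.3 * dab_od), quantized
    # tolerance covers uint8 quantization plus the +1 regularization in the
    # OD conversion (the renderer is purely physical: I = I0 * 10^-OD)
    for (x, y), d in zip(truth.positions, truth.diameters):
        assert dab[int(round(y)), int(round(x))] == pytest.approx(
            1.3 * spec.dab_od, abs=0.04
        )
    # background is stain-free
    assert dab[0, 0] == pytest.approx(0.0, abs=0.01)


def test_nuclei_lie_on_tissue_and_inside_gate():
    spec = SyntheticSlideSpec(seed=5, canvas=(512, 512), nucleus_count=40, clump_fraction=0.2)
    _, truth = render_slide(spec)
    assert truth.count == 40
    lo, hi = spec.nucleus_diameter_range
    assert ((truth.diameters >= lo) & (truth.diameters <= hi)).all()


def test_overcrowded_spec_raises_placement_error():
    spec = SyntheticSlideSpec(
        seed=6, canvas=(64, 64), nucleus_count=60,
        nucleus_diameter_range=(8.0, 12.0), tissue_coverage=0.3,
    )
    with pytest.raises(PlacementError):
        render_slide(spec)


def test_artifacts_record_regions_and_preserve_truth():
    spec = SyntheticSlideSpec(seed=7, canvas=(512, 512), nucleus_count=20, noise_sigma=0.0)
    slide, truth = render_slide(spec)
    out, new_truth = add_artifacts(
        slide, truth, {"air_bubble", "pen_mark", "coverslip_shadow"}
    )
    assert set(new_truth.artifact_regions) == {"air_bubble", "pen_mark", "coverslip_shadow"}
    assert new_truth.count == truth.count
    np.testing.assert_array_equal(new_truth.positions, truth.positions)
    # bubble and pen mark never overwrite nucleus disks
    top_before = slide.layers[0].pixels
    bubble_pen, _ = add_artifacts(slide, truth, {"air_bubble", "pen_mark"})
    for (x, y), d in zip(truth.positions, truth.diameters):
        r = int(d // 2)
        yi, xi = int(round(y)), int(round(x))
        np.testing.assert_array_equal(
            bubble_pen.layers[0].pixels[yi - r : yi + r, xi - r : xi + r],
            top_before[yi - r : yi + r, xi - r : xi + r],
        )
    with pytest.raises(ValueError):
        add_artifacts(slide, truth, set())


def test_replicate_zero_noise_identity():
    spec = SyntheticSlideSpec(seed=8, canvas=(256, 256), nucleus_count=10, noise_sigma=0.0)
    base, _ = render_slide(spec)
    rep = render_replicate(spec, rescan_noise_sigma=0.0, rescan_seed=99,
                           illumination_scaling=False)
    for a, b in zip(base.layers, rep.layers):
        np.testing.assert_array_equal(a.pixels, b.pixels)


def test_replicate_densities_agree_within_two_percent():
    spec = SyntheticSlideSpec(seed=9, canvas=(1024, 1024), nucleus_count=120,
                              clump_fraction=0.1)
    densities = []
    for rescan_seed in (1001, 2002):
        slide = render_replicate(spec, rescan_noise_sigma=2.0, rescan_seed=rescan_seed)
        meas, _, _ = measure_tile(slide.layers[0])
        densities.append(meas.dab_object_count / meas.tissue_area)
    rel = abs(densities[0] - densities[1]) / max(densities)
    assert rel < 0.02


def test_replicate_of_empty_slide_stays_empty():
    spec = SyntheticSlideSpec(seed=10, canvas=(256, 256), nucleus_count=0)
    slide = render_replicate(spec, rescan_noise_sigma=2.0, rescan_seed=5)
    meas, _, _ = measure_tile(slide.layers[0])
    assert meas.dab_object_count == 0
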