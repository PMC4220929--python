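import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slidequant import (
    ReplicatePair,
    bland_altman,
    combine_slide,
    icc_two_way_mixed_single,
    transform_density,
)
from slidequant.detection import TileMeasurement
from slidequant.stats import icc_two_way_mixed_single_absolute

from _oracles import icc31_oracle


def _tiles(*pairs):
    return [TileMeasurement(f"t{i}", area, count, 0) for i, (area, count) in enumerate(pairs)]


def test_combine_uses_totals_not_mean_of_ratios():
    m = combine_slide(_tiles((100, 2), (300, 10)))
    assert m.density == pytest.approx(12 / 400)  # not (0.02 + 0.0333)/2
    assert m.total_dab_count == 12 and m.total_tissue_area == 400


def test_combine_single_tile_and_zero_tissue():
    assert combine_slide(_tiles((50, 5))).density == pytest.approx(0.1)
    flagged = combine_slide(_tiles((0, 0), (0, 0)))
    assert flagged.density is None and not flagged.density_defined
    with pytest.raises(ValueError):
        combine_slide([])


def test_transform_density_reference_values():
    assert transform_density(0.0) == pytest.approx(math.log(1e-4))
    # the offset is tiny once x reaches order 1: ln(0.0001 + 1) = ln(1.0001)
    assert transform_density(1.0) == pytest.approx(math.log(1.0001))
    assert transform_density(0.9999) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        transform_density(-0.1)


@given(st.floats(0, 1e3), st.floats(0, 1e3))
@settings(max_examples=50, derandomize=True)
def test_transform_density_strictly_monotone(x1, x2):
    if x1 < x2:
        assert transform_density(x1) < transform_density(x2)


def test_icc_identical_columns_is_one():
    data = np.column_stack([np.arange(5.0), np.arange(5.0)])
    assert icc_two_way_mixed_single(data).icc == pytest.approx(1.0)


def test_icc_pure_rater_offset_is_one():
    data = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
    res = icc_two_way_mixed_single(data)
    assert res.icc == pytest.approx(1.0)
    assert res.ms_error == pytest.approx(0.0, abs=1e-12)
    # the absolute-agreement variant penalizes the offset
    assert icc_two_way_mixed_single_absolute(data).icc < 1.0


def test_icc_null_simulation_near_zero():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(1000, 2))
    assert abs(icc_two_way_mixed_single(data).icc) < 0.1


def test_icc_matches_anova_oracle_on_random_matrices():
    rng = np.random.default_rng(1)
    for _ in range(20):
        data = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1)) * rng.uniform(0, 3)
        ours = icc_two_way_mixed_single(data).icc
        assert ours == pytest.approx(icc31_oracle(data), abs=1e-10)


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(5)
    data = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1)) * 2.0
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": data.ravel(),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    expected = float(table.loc[table["Type"] == "ICC(C,1)", "ICC"].iloc[0])
    assert icc_two_way_mixed_single(data).icc == pytest.approx(expected, abs=1e-9)
    from slidequant.stats import icc_two_way_mixed_single_absolute

    expected_abs = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert icc_two_way_mixed_single_absolute(data).icc == pytest.approx(expected_abs, abs=1e-9)


def test_icc_shift_and_scale_invariance():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1)) * 2.0
    base = icc_two_way_mixed_single(data).icc
    shifted = data.copy()
    shifted[:, 1] += 3.7
    assert icc_two_way_mixed_single(shifted).icc == pytest.approx(base, abs=1e-12)
    assert icc_two_way_mixed_single(data * 4.2).icc == pytest.approx(base, abs=1e-12)


def test_icc_converges_to_one_as_noise_vanishes():
    rng = np.random.default_rng(3)
    x = rng.normal(size=200)
    prev = -1.0
    for sd in (1.0, 0.3, 0.1, 0.01):
        data = np.column_stack([x, x + rng.normal(0, sd, 200)])
        icc = icc_two_way_mixed_single(data).icc
        assert icc > prev
        prev = icc
    assert prev > 0.999


def test_icc_input_guards():
    with pytest.raises(ValueError):
        icc_two_way_mixed_single(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        icc_two_way_mixed_single(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


def _pairs(a, b):
    return [ReplicatePair(f"s{i}", x, y) for i, (x, y) in enumerate(zip(a, b))]


def test_bland_altman_identical_runs():
    x = [0.1, 0.2, 0.3, 0.4]
    res = bland_altman(_pairs(x, x))
    assert res.bias == 0.0
    assert res.loa_low == res.loa_high == 0.0
    assert res.outliers == []


def test_bland_altman_flags_large_log_difference():
    x = [0.10, 0.20, 0.30, 0.40]
    y = list(x)
    y[2] = x[2] * math.exp(0.6)  # 0.6 on the log scale
    res = bland_altman(_pairs(x, y))
    assert res.outliers == ["s2"]


def test_bland_altman_bias_is_mean_difference():
    rng = np.random.default_rng(4)
    a = rng.uniform(-2.0, 2.0, 50)
    delta = 0.25
    b = a - delta  # constant shift on the analysis scale
    res = bland_altman(_pairs(a, b), transform=False)
    assert res.bias == pytest.approx(delta, abs=1e-12)
    assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-9)
    # bias is exactly the mean difference
    res2 = bland_altman(_pairs(a, rng.uniform(-2, 2, 50)), transform=False)
    assert res2.bias == pytest.approx(np.mean(res2.differences), abs=0)
    with pytest.raises(ValueError):
        bland_altman(_pairs([1.0], [1.0]))


def test_bland_altman_loa_cover_95_percent():
    rng = np.random.default_rng(6)
    a = rng.uniform(0.1, 1.0, 4000)
    b = a * np.exp(rng.normal(0, 0.1, 4000))
    res = bland_altman(_pairs(a, b))
    inside = (res.differences >= res.loa_low) & (res.differences <= res.loa_high)
    assert 0.94 < inside.mean() < 0.96
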