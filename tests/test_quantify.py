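"""Background models, ring statistic and CDK2 activity."""

import numpy as np
import pytest

from conftest import disk_mask
from cyclemap.quantify import (
    BackgroundError, QuantParams, cdk2_activity, cytoplasmic_ring_mean,
    global_background, local_background_subtract, measure_frame,
)

P = QuantParams(pixel_size=1.0)


def scene(nucleus_value=500.0, background=100.0, radius=6, shape=(60, 60)):
    mask = disk_mask(shape, (30, 30), radius).astype(np.int32)
    img = np.full(shape, background)
    img[mask > 0] = nucleus_value
    return img, mask


class TestLocalBackground:
    def test_uniform_background_subtracted_exactly(self):
        img, mask = scene(500, 120)
        assert local_background_subtract(img, mask, 1, P) == pytest.approx(380.0)

    def test_zero_background_returns_raw_mean(self):
        img, mask = scene(500, 0)
        assert local_background_subtract(img, mask, 1, P) == pytest.approx(500.0)

    def test_negative_result_clipped(self):
        img, mask = scene(50, 120)
        assert local_background_subtract(img, mask, 1, P) == 0.0

    def test_missing_label_raises(self):
        img, mask = scene()
        with pytest.raises(KeyError):
            local_background_subtract(img, mask, 7, P)

    def test_no_local_pixels_falls_back_to_global(self):
        img, mask = scene()
        params = QuantParams(pixel_size=1.0, local_bg_expand=0.4)
        with pytest.warns(UserWarning):
            v = local_background_subtract(img, mask, 1, params, global_bg=100.0)
        assert v == pytest.approx(400.0)


class TestGlobalBackground:
    def test_constant_background(self):
        img, mask = scene(500, 100, shape=(160, 160))
        assert global_background(img, mask, P) == pytest.approx(100.0)

    def test_noisy_background_mode(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 5, (256, 256))
        mask = np.zeros((256, 256), dtype=np.int32)
        assert abs(global_background(img, mask, P) - 100.0) <= 1.0

    def test_fully_covered_field_raises(self):
        img, mask = scene(shape=(40, 40))  # 50 um dilation swallows 40 px
        with pytest.raises(BackgroundError):
            global_background(img, mask, P)


class TestRingMean:
    def test_top_half_of_four_values(self):
        # ring of exactly four pixels valued 1..4: top-50% mean = 3.5
        mask = np.zeros((11, 11), dtype=np.int32)
        mask[5, 5] = 1
        img = np.zeros((11, 11))
        params = QuantParams(pixel_size=1.0, ring_inner_offset=0.5,
                             ring_width=0.6)
        for val, (r, c) in zip([1, 2, 3, 4],
                               [(4, 5), (6, 5), (5, 4), (5, 6)]):
            img[r, c] = val
        assert cytoplasmic_ring_mean(img, mask, 1, params) == pytest.approx(3.5)

    def test_uniform_ring_minus_background(self):
        img, mask = scene(500, 0)
        img[(mask == 0)] = 5.0
        assert cytoplasmic_ring_mean(img, mask, 1, P, global_bg=2.0) == \
            pytest.approx(3.0)

    def test_other_nuclei_excluded(self):
        mask = disk_mask((60, 60), (30, 30), 6).astype(np.int32)
        mask[disk_mask((60, 60), (30, 39), 4)] = 2
        img = np.zeros((60, 60))
        img[mask == 2] = 1e6  # bright neighbour must not leak into the ring
        img[(mask == 0)] = 10.0
        assert cytoplasmic_ring_mean(img, mask, 1, P) == pytest.approx(10.0)

    def test_empty_ring_returns_nan(self):
        mask = np.ones((8, 8), dtype=np.int32)
        assert np.isnan(cytoplasmic_ring_mean(np.ones((8, 8)), mask, 1, P))


class TestActivity:
    def test_ratio(self):
        img, mask = scene(500, 0, shape=(160, 160))
        img[mask == 0] = 250.0
        img[79:83, :] = 0.0  # keep a zero-mode background region
        a = cdk2_activity(img, mask, 1, P, global_bg=0.0)
        assert a == pytest.approx(250.0 / 500.0)

    def test_zero_cytoplasm_gives_zero(self):
        img, mask = scene(500, 0, shape=(160, 160))
        assert cdk2_activity(img, mask, 1, P, global_bg=0.0) == 0.0

    def test_scale_invariance(self):
        img, mask = scene(500, 0, shape=(160, 160))
        img[mask == 0] = 300.0
        img[120:160, :] = 0.0
        a1 = cdk2_activity(img, mask, 1, P, global_bg=0.0)
        a2 = cdk2_activity(3.7 * img, mask, 1, P, global_bg=0.0)
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_dim_nucleus_flagged_missing(self):
        img, mask = scene(3.0, 0, shape=(160, 160))
        assert np.isnan(cdk2_activity(img, mask, 1, P, global_bg=0.0))


class TestMeasureFrame:
    def test_offset_invariance_of_background_subtraction(self):
        img, mask = scene(500, 100, shape=(200, 200))
        a = measure_frame(img, img, mask, P)
        b = measure_frame(img + 50.0, img + 50.0, mask, P)
        assert b.total_h2b.iloc[0] == pytest.approx(a.total_h2b.iloc[0], rel=1e-6)
        assert b.nuclear_mean.iloc[0] == pytest.approx(a.nuclear_mean.iloc[0],
                                                       rel=1e-6)

    def test_batch_matches_per_cell_operations(self):
        # the vectorized frame measurement must agree with the single-cell
        # reference operations on an isolated cell
        rng = np.random.default_rng(3)
        shape = (200, 200)
        mask = disk_mask(shape, (100, 100), 6).astype(np.int32)
        h2b = np.full(shape, 100.0) + rng.normal(0, 2, shape)
        h2b[mask > 0] += 600.0
        sensor = np.full(shape, 50.0)
        sensor[mask > 0] += 200.0
        ring = disk_mask(shape, (100, 100), 11) & ~disk_mask(shape, (100, 100), 7)
        sensor[ring] += 260.0
        obs = measure_frame(h2b, sensor, mask, P).iloc[0]

        nuc = local_background_subtract(h2b, mask, 1, P)
        assert obs.total_h2b == pytest.approx(nuc * obs.area, rel=0.01)
        gbg = global_background(sensor, mask, P)
        cyto = cytoplasmic_ring_mean(sensor, mask, 1, P, gbg)
        act = cdk2_activity(sensor, mask, 1, P, gbg)
        assert obs.cyto_mean == pytest.approx(cyto, rel=0.02)
        assert obs.cdk2_activity == pytest.approx(act, rel=0.02)

    def test_empty_mask(self):
        out = measure_frame(np.ones((20, 20)), np.ones((20, 20)),
                            np.zeros((20, 20), dtype=np.int32), P)
        assert len(out) == 0
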