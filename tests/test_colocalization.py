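"""C_R definition, scale behaviour, Pearson comparison and area bias."""

import numpy as np
import pytest

from conftest import make_condition, make_image
from lipoquant import (
    ImagingScenario,
    area_bias_check,
    binarize,
    colocalization_ratio,
    condition_colocalization,
    condition_threshold,
    generate_imaging_condition,
    pearson_coloc,
    summarize_condition,
)
from lipoquant.segmentation import LiposomeMask


def _mask(arr, image_id="img0"):
    arr = np.asarray(arr, bool)
    return LiposomeMask(mask=arr, coverage=float(arr.mean()), image_id=image_id)


def _loop_cr(dna, mask):
    """Independent oracle: explicit per-pixel means."""
    s_in = n_in = s_out = n_out = 0
    for i in range(dna.shape[0]):
        for j in range(dna.shape[1]):
            if mask[i, j]:
                s_in += float(dna[i, j])
                n_in += 1
            else:
                s_out += float(dna[i, j])
                n_out += 1
    return (s_in / n_in) / (s_out / n_out)


class TestColocalizationRatio:
    def test_constant_dna_gives_unity(self):
        dna = np.full((10, 10), 800, np.uint16)
        img = make_image(np.arange(100, dtype=np.uint16).reshape(10, 10), dna)
        m = np.zeros((10, 10), bool)
        m[:3] = True
        assert colocalization_ratio(img, _mask(m)).C_R == 1.0

    def test_two_level_dna_gives_exact_ratio(self):
        m = np.zeros((8, 8), bool)
        m[2:4, 2:4] = True
        dna = np.where(m, 200, 100).astype(np.uint16)
        img = make_image(dna, dna)
        res = colocalization_ratio(img, _mask(m))
        assert res.C_R == 2.0
        assert (res.F_dna_lipid, res.F_dna_background) == (200.0, 100.0)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(77)
        for k in range(10):
            dna = rng.integers(1, 4000, (24, 24)).astype(np.uint16)
            m = rng.random((24, 24)) < 0.2
            if not 0 < m.sum() < m.size:
                m[0, 0] = True
            img = make_image(dna, dna, image_id=f"i{k}")
            res = colocalization_ratio(img, _mask(m, f"i{k}"))
            assert res.C_R == pytest.approx(_loop_cr(dna, m), rel=1e-12)

    def test_scale_invariant_but_offset_sensitive(self):
        m = np.zeros((8, 8), bool)
        m[::2] = True
        rng = np.random.default_rng(1)
        dna = rng.integers(100, 400, (8, 8)).astype(np.float64)
        base = colocalization_ratio(make_image(dna, dna), _mask(m)).C_R
        scaled = colocalization_ratio(make_image(dna, dna * 7.5), _mask(m)).C_R
        offset = colocalization_ratio(make_image(dna, dna + 500.0), _mask(m)).C_R
        assert scaled == pytest.approx(base, rel=1e-12)
        assert offset != pytest.approx(base, rel=1e-6)

    def test_empty_regions_are_errors_not_nan(self):
        img = make_image(np.ones((4, 4), np.uint16), np.ones((4, 4), np.uint16))
        with pytest.raises(ValueError, match="liposome"):
            colocalization_ratio(img, _mask(np.zeros((4, 4), bool)))
        with pytest.raises(ValueError, match="background"):
            colocalization_ratio(img, _mask(np.ones((4, 4), bool)))

    def test_manders_fractions_bounded_and_enriched(self, small_condition):
        cond, gt = small_condition
        thr = condition_threshold(cond)
        res = colocalization_ratio(cond.images[0], binarize(cond.images[0], thr))
        assert 0 <= res.manders_m1 <= 1 and 0 <= res.manders_m2 <= 1
        # with rho = 2 the DNA fraction inside the mask exceeds the area fraction
        assert res.manders_m1 > res.coverage


class TestPearson:
    def test_perfect_correlation(self):
        a = np.arange(64, dtype=np.uint16).reshape(8, 8)
        assert pearson_coloc(make_image(a, a)) == pytest.approx(1.0)
        assert pearson_coloc(make_image(a, (1000 - a).astype(np.uint16))) == pytest.approx(-1.0)

    def test_independent_channels_uncorrelated(self):
        rng = np.random.default_rng(5)
        lipid = rng.integers(0, 4000, (256, 256)).astype(np.uint16)
        dna = rng.integers(0, 4000, (256, 256)).astype(np.uint16)
        assert abs(pearson_coloc(make_image(lipid, dna))) < 0.05

    def test_zero_variance_channel_rejected(self):
        flat = np.full((8, 8), 7, np.uint16)
        varying = np.arange(64, dtype=np.uint16).reshape(8, 8)
        with pytest.raises(ValueError, match="variance"):
            pearson_coloc(make_image(flat, varying))


class TestSummaries:
    def test_condition_summary_mean_sd(self):
        imgs = []
        for k, level in enumerate((150, 200, 250)):
            m = np.zeros((6, 6), bool)
            m[:2] = True
            dna = np.where(m, level, 100).astype(np.uint16)
            imgs.append((make_image(dna, dna, image_id=f"i{k}"), _mask(m, f"i{k}")))
        results = [colocalization_ratio(i, m) for i, m in imgs]
        s = summarize_condition(results)
        vals = [1.5, 2.0, 2.5]
        assert s.mean_C_R == pytest.approx(np.mean(vals))
        assert s.sd_C_R == pytest.approx(np.std(vals, ddof=1))
        assert s.n_images == 3
        single = summarize_condition(results[:1])
        assert single.sd_C_R == 0.0

    def test_null_condition_calibrates_to_unity(self):
        sc = ImagingScenario(n_images=6, enrichment_rho=1.0, seed=31, condition_id="null")
        cond, _ = generate_imaging_condition(sc)
        _, summary = condition_colocalization(cond)
        assert 0.98 <= summary.mean_C_R <= 1.04

    def test_condition_mean_monotone_in_enrichment(self):
        means = []
        for rho in (1.0, 1.5, 2.0, 3.0):
            sc = ImagingScenario(
                n_images=4, enrichment_rho=rho, seed=13, condition_id=f"rho{rho}"
            )
            cond, _ = generate_imaging_condition(sc)
            _, summary = condition_colocalization(cond)
            means.append(summary.mean_C_R)
        assert np.all(np.diff(means) > 0)


class TestAreaBias:
    def test_constant_metric_has_zero_slope(self):
        results = []
        for k in range(12):
            m = np.zeros((10, 10), bool)
            m[: k % 5 + 1] = True
            dna = np.full((10, 10), 100, np.uint16)
            lipid = np.arange(100, dtype=np.uint16).reshape(10, 10)
            results.append(colocalization_ratio(make_image(lipid, dna, image_id=f"i{k}"), _mask(m, f"i{k}")))
        rep = area_bias_check(results)
        assert rep.per_metric["C_R"].slope == 0.0
        assert rep.per_metric["C_R"].ci95 == (0.0, 0.0)
        assert rep.per_metric["C_R"].unbiased

    def test_degenerate_coverage_rejected(self):
        m = np.zeros((10, 10), bool)
        m[:2] = True
        dna = np.where(m, 200, 100).astype(np.uint16)
        results = [
            colocalization_ratio(make_image(dna, dna, image_id=f"i{k}"), _mask(m, f"i{k}"))
            for k in range(12)
        ]
        with pytest.raises(ValueError, match="coverage"):
            area_bias_check(results)

    def test_requires_ten_images(self):
        m = np.zeros((10, 10), bool)
        m[:2] = True
        dna = np.where(m, 200, 100).astype(np.uint16)
        results = [colocalization_ratio(make_image(dna, dna), _mask(m))] * 5
        with pytest.raises(ValueError, match=">= 10"):
            area_bias_check(results)
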