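"""Per-pixel quantifications against brute-force loop oracles and planted truth."""

import numpy as np
import pytest

from conftest import corrected_intensity_oracle, pearson_oracle

from ecmquant import (
    MultiChannelImage,
    ROIMask,
    corrected_intensity,
    fret_group_compare,
    fret_ratio_image,
    fret_region_mean,
    max_project,
    pixel_colocalization,
)
from ecmquant.errors import UndefinedStatisticError, ZeroVarianceError
from ecmquant.synth import gen_coloc_pair, gen_fret_stack, gen_worm_image


def _full_roi(shape):
    return ROIMask(mask=np.ones(shape, bool), role="region")


class TestCorrectedIntensity:
    def test_autofluorescence_fully_cancelled(self):
        a = np.full((8, 8), 37.0)
        img = MultiChannelImage(channels={"green": a, "red": a.copy()})
        res = corrected_intensity(img, _full_roi((8, 8)), threshold=0)
        assert res.total == 0 and res.pixel_count == 0

    def test_constant_arithmetic(self):
        img = MultiChannelImage(
            channels={"green": np.full((2, 5), 100.0), "red": np.zeros((2, 5))}
        )
        res = corrected_intensity(img, _full_roi((2, 5)), threshold=50)
        assert res.total == 1000 and res.pixel_count == 10 and res.mean_per_pixel == 100

    def test_plain_green_sum_identity(self, rng):
        green = rng.uniform(1, 50, (16, 16))
        img = MultiChannelImage(channels={"green": green, "red": np.zeros((16, 16))})
        roi = ROIMask(mask=rng.uniform(size=(16, 16)) < 0.6, role="body")
        res = corrected_intensity(img, roi, threshold=0)
        assert res.total == pytest.approx(green[roi.mask].sum(), abs=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pixel_loop_oracle_on_phantoms(self, seed):
        img, body, _ = gen_worm_image(seed=seed, shape=(48, 96))
        threshold = float(seed % 4) * 20.0
        res = corrected_intensity(img, body, threshold=threshold)
        total, count = corrected_intensity_oracle(
            img.channel("green"), img.channel("red"), body.mask, threshold
        )
        assert res.total == pytest.approx(total, rel=0, abs=1e-9)
        assert res.pixel_count == count

    def test_monotone_in_channels(self, rng):
        green = rng.uniform(10, 100, (10, 10))
        red = rng.uniform(0, 50, (10, 10))
        img = MultiChannelImage(channels={"green": green, "red": red})
        roi = _full_roi((10, 10))
        base = corrected_intensity(img, roi, threshold=5).total
        brighter = MultiChannelImage(channels={"green": green + 3, "red": red})
        redder = MultiChannelImage(channels={"green": green, "red": red + 3})
        assert corrected_intensity(brighter, roi, threshold=5).total >= base
        assert corrected_intensity(redder, roi, threshold=5).total <= base


class TestFretRatio:
    def test_identity_ratio(self):
        d = np.full((6, 6), 200.0)
        img = MultiChannelImage(channels={"donor": d, "acceptor": d.copy()})
        ri = fret_ratio_image(img, donor_threshold=10)
        assert ri.valid.all()
        np.testing.assert_allclose(ri.ratio, 1.0)

    def test_all_below_threshold_errors_on_region_mean(self):
        img = MultiChannelImage(
            channels={"donor": np.full((4, 4), 5.0), "acceptor": np.full((4, 4), 5.0)}
        )
        ri = fret_ratio_image(img, donor_threshold=50)
        assert not ri.valid.any()
        with pytest.raises(UndefinedStatisticError):
            fret_region_mean(ri)

    def test_planted_region_ratios_recovered(self):
        stack, masks, truth = gen_fret_stack(seed=3, region_ratios=(0.5, 2.0))
        ri = fret_ratio_image(max_project(stack), donor_threshold=50)
        for m, planted in zip(masks, truth["region_ratios"]):
            assert fret_region_mean(ri, m) == pytest.approx(planted, abs=1e-2)

    def test_scale_invariance_of_region_means(self, rng):
        donor = rng.uniform(100, 300, (12, 12))
        acceptor = rng.uniform(50, 200, (12, 12))
        img = MultiChannelImage(channels={"donor": donor, "acceptor": acceptor})
        scaled = MultiChannelImage(channels={"donor": 3 * donor, "acceptor": 3 * acceptor})
        m1 = fret_region_mean(fret_ratio_image(img, donor_threshold=10, background={"donor": 5, "acceptor": 2}))
        m2 = fret_region_mean(fret_ratio_image(scaled, donor_threshold=30, background={"donor": 15, "acceptor": 6}))
        assert m1 == pytest.approx(m2, rel=1e-12)


class TestFretGroupCompare:
    def test_identical_groups_null(self):
        delta, p = fret_group_compare([1.0, 1.2, 0.8], [1.0, 1.2, 0.8])
        assert delta == 0 and p == pytest.approx(1.0)

    def test_degenerate_zero_variance_convention(self):
        with pytest.warns(UserWarning):
            delta, p = fret_group_compare([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert delta == -1 and p == 0.0

    def test_matches_independent_reference(self, rng):
        """Welch p-value cross-checked against statsmodels on planted-shift samples."""
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        a = rng.normal(1.0, 0.3, 20)
        b = rng.normal(1.3, 0.3, 20)
        delta, p = fret_group_compare(a, b)
        _, p_ref, _ = sm_ttest(a, b, usevar="unequal")
        assert delta == pytest.approx(a.mean() - b.mean())
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestColocalization:
    def test_perfect_linear_relation(self, rng):
        red = rng.uniform(10, 100, (10, 10))
        img = MultiChannelImage(channels={"red": red, "green": 2 * red + 5})
        assert pixel_colocalization(img, _full_roi((10, 10))).r == pytest.approx(1.0)

    def test_constant_channel_errors(self):
        img = MultiChannelImage(
            channels={"red": np.full((5, 5), 7.0), "green": np.arange(25.0).reshape(5, 5)}
        )
        with pytest.raises(ZeroVarianceError, match="red"):
            pixel_colocalization(img, _full_roi((5, 5)))

    def test_planted_correlation_recovered(self):
        img, roi, truth = gen_coloc_pair(seed=4, rho=0.6, shape=(100, 100))
        res = pixel_colocalization(img, roi)
        assert res.n_pixels == 10000
        assert res.r == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pearson_oracle(self, seed):
        img, roi, _ = gen_coloc_pair(seed=seed, rho=0.3, shape=(20, 20))
        res = pixel_colocalization(img, roi)
        oracle = pearson_oracle(img.channel("red")[roi.mask], img.channel("green")[roi.mask])
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        red = rng.uniform(10, 100, (12, 12))
        green = rng.uniform(10, 100, (12, 12))
        roi = _full_roi((12, 12))
        r0 = pixel_colocalization(MultiChannelImage(channels={"red": red, "green": green}), roi).r
        r1 = pixel_colocalization(
            MultiChannelImage(channels={"red": 2.5 * red + 7, "green": green}), roi
        ).r
        assert r1 == pytest.approx(r0, abs=1e-12)
        flipped = MultiChannelImage(channels={"red": red.max() - red + 1, "green": green})
        assert pixel_colocalization(flipped, roi).r == pytest.approx(-r0, abs=1e-12)
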