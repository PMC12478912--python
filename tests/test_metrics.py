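"""Quality-metric suite: closed forms, oracles, invariances."""

import numpy as np
import pytest

from curvefuse import gaussian_smooth, report
from curvefuse.metrics import (
    COLUMNS,
    ag,
    api,
    corr,
    entropy,
    fs1,
    joint_histogram,
    mif,
    mutual_information,
    qabf,
    quantize_u8,
    sd,
    sf,
)


def naive_mi(f, a):
    """Brute-force double loop over the 256x256 joint distribution."""
    qf, qa = quantize_u8(f), quantize_u8(a)
    n = qf.size
    total = 0.0
    for i in range(256):
        for j in range(256):
            pij = np.sum((qf == i) & (qa == j)) / n
            if pij > 0:
                pi = np.sum(qf == i) / n
                pj = np.sum(qa == j) / n
                total += pij * np.log2(pij / (pi * pj))
    return total


class TestIntensityStatistics:
    def test_api_closed_forms(self, fixtures):
        assert api(fixtures["constant"]) == 40.0
        assert api(fixtures["checkerboard"]) == 127.5

    def test_sd_closed_forms(self, fixtures):
        assert sd(fixtures["constant"]) == 0.0
        assert sd(fixtures["checkerboard"]) == 127.5

    def test_sd_two_level_image(self):
        # equiprobable levels {0, a} have deviation a/2 everywhere
        a = 120.0
        img = np.array([[0.0, a], [a, 0.0], [0.0, a], [a, 0.0]])
        assert sd(img) == pytest.approx(a / 2)

    def test_sd_sf_offset_invariant(self, rng):
        img = rng.uniform(0, 200, (32, 32))
        assert sd(img + 30) == pytest.approx(sd(img))
        assert sf(img + 30) == pytest.approx(sf(img))


class TestGradientStatistics:
    def test_ag_constant_is_zero(self, fixtures):
        assert ag(fixtures["constant"]) == 0.0

    def test_ag_unit_ramp_valid_normalization(self, fixtures):
        assert ag(fixtures["ramp"], divisor="valid") == pytest.approx(1.0)

    def test_ag_decreases_under_smoothing(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        assert ag(gaussian_smooth(img, 3.0)) <= ag(img)

    def test_sf_constant_and_checkerboard(self, fixtures):
        assert sf(fixtures["constant"]) == 0.0
        # two valid differences of 255 per direction over MN=4 pixels
        assert sf(fixtures["checkerboard"]) == pytest.approx(255.0)

    def test_bad_divisor_rejected(self, fixtures):
        with pytest.raises(ValueError):
            ag(fixtures["constant"], divisor="bogus")
        with pytest.raises(ValueError):
            sf(fixtures["constant"], divisor="bogus")


class TestEntropyAndInformation:
    def test_entropy_closed_forms(self):
        assert entropy(np.full((16, 16), 7.0)) == 0.0
        uniform = np.repeat(np.arange(256.0), 4).reshape(32, 32)
        assert entropy(uniform) == pytest.approx(8.0)
        two_level = np.array([[0.0, 255.0]] * 8)
        assert entropy(two_level) == pytest.approx(1.0)

    def test_joint_histogram_marginals(self, rng):
        a = rng.uniform(0, 255, (16, 16))
        b = rng.uniform(0, 255, (16, 16))
        joint = joint_histogram(a, b)
        assert joint.sum() == a.size
        assert np.array_equal(
            joint.sum(axis=1), np.bincount(quantize_u8(a).ravel(), minlength=256)
        )
        assert np.array_equal(
            joint.sum(axis=0), np.bincount(quantize_u8(b).ravel(), minlength=256)
        )

    def test_mi_self_equals_entropy(self, noisy_pair):
        f = noisy_pair[0]
        assert mutual_information(f, f) == pytest.approx(entropy(f), abs=1e-9)

    def test_mi_symmetry(self, noisy_pair):
        a, b = noisy_pair
        assert mutual_information(a, b) == pytest.approx(
            mutual_information(b, a), abs=1e-12
        )

    def test_mi_independent_noise_near_zero(self):
        # the plug-in MI estimator from a 256x256-bin joint histogram is
        # biased upward by about (255*255)/(2*N*ln 2) bits for N samples;
        # independent noise must sit at that bias level and vanish with N
        rng = np.random.default_rng(7)
        small = [rng.uniform(0, 255, (256, 256)) for _ in range(2)]
        large = [rng.uniform(0, 255, (1024, 1024)) for _ in range(2)]
        bias_small = 255 * 255 / (2 * small[0].size * np.log(2))
        mi_small = mutual_information(*small)
        mi_large = mutual_information(*large)
        assert mi_small <= 1.5 * bias_small
        assert mi_large < mi_small
        assert mi_large <= 0.05

    def test_mi_matches_brute_force_on_small_images(self, rng):
        f = rng.integers(0, 8, (4, 4)).astype(float)
        a = rng.integers(0, 8, (4, 4)).astype(float)
        assert mutual_information(f, a) == pytest.approx(naive_mi(f, a), abs=1e-12)

    def test_mif_additivity_and_self(self, noisy_pair):
        a, b = noisy_pair
        assert mif(a, a, b) == pytest.approx(
            mutual_information(a, a) + mutual_information(a, b), abs=1e-12
        )
        assert mif(a, a, a) == pytest.approx(2 * entropy(a), abs=1e-9)


class TestFusionSymmetry:
    def test_identical_sources(self, noisy_pair):
        a = noisy_pair[0]
        assert fs1(a, a, a, variant="printed") == pytest.approx(0.0)
        assert fs1(a, a, a) == pytest.approx(2.0)

    def test_hand_arithmetic_three_to_one_split(self, monkeypatch):
        import curvefuse.metrics as m

        values = {"a": 3.0, "b": 1.0}
        monkeypatch.setattr(
            m, "mutual_information", lambda f, s: values["a" if s is A else "b"]
        )
        A, B = object(), object()
        assert m.fs1(None, A, B, variant="printed") == pytest.approx(0.5)
        assert m.fs1(None, A, B) == pytest.approx(1.75)

    def test_table_scale_bounds(self, rng):
        for _ in range(5):
            f = rng.uniform(0, 255, (32, 32))
            a = rng.uniform(0, 255, (32, 32))
            b = rng.uniform(0, 255, (32, 32))
            assert 1.5 <= fs1(f, a, b) <= 2.0


class TestCorrelation:
    def test_self_correlation_is_one(self, noisy_pair):
        a, b = noisy_pair
        assert corr(a, a, b, mode="a") == pytest.approx(1.0)

    def test_negated_image_fully_anticorrelated(self, noisy_pair):
        a, b = noisy_pair
        assert corr(255.0 - a, a, b, mode="a") == pytest.approx(-1.0)

    def test_mean_mode_averages_pairings(self, noisy_pair):
        a, b = noisy_pair
        f = 0.5 * (a + b)
        expected = 0.5 * (corr(f, a, b, mode="a") + corr(f, a, b, mode="b"))
        assert corr(f, a, b) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, noisy_pair):
        a, b = noisy_pair
        f = 0.5 * (a + b)
        assert corr(2.0 * f + 10.0, a, b) == pytest.approx(corr(f, a, b), abs=1e-9)

    def test_constant_image_rejected(self, noisy_pair):
        a, b = noisy_pair
        with pytest.raises(ValueError):
            corr(np.full_like(a, 9.0), a, b)


class TestEdgePreservation:
    def test_perfect_copy_scores_one(self, noisy_pair):
        a = noisy_pair[0]
        assert qabf(a, a, a) == pytest.approx(1.0, abs=1e-6)

    def test_constant_fused_scores_zero(self, noisy_pair):
        a, b = noisy_pair
        assert qabf(np.full_like(a, 50.0), a, b) < 0.01

    def test_invariant_under_joint_negation(self, noisy_pair):
        a, b = noisy_pair
        f = 0.5 * (a + b)
        assert qabf(255.0 - f, 255.0 - a, 255.0 - b) == pytest.approx(
            qabf(f, a, b), abs=1e-9
        )

    def test_bounded_in_unit_interval(self, rng):
        f = rng.uniform(0, 255, (32, 32))
        a = rng.uniform(0, 255, (32, 32))
        b = rng.uniform(0, 255, (32, 32))
        assert 0.0 <= qabf(f, a, b) <= 1.0


class TestReport:
    def test_row_columns_and_composition(self, noisy_pair):
        a, b = noisy_pair
        f = 0.5 * (a + b)
        rep = report(f, a, b)
        row = rep.as_row()
        assert list(row) == COLUMNS
        assert row["API"] == pytest.approx(api(f))
        assert row["SF"] == pytest.approx(sf(f))
        assert row["QABF"] == pytest.approx(qabf(f, a, b))
        assert 0.0 <= row["Entropy"] <= 8.0
        assert -1.0 <= row["Corr"] <= 1.0
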