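import numpy as np
import pytest

from fundustex.glcm_texture import (
    ANGLES,
    FEATURE_NAMES,
    CoocMatrix,
    HaralickVector,
    cooccurrence,
    directional_average,
    haralick_features,
    quantize,
    vessel_texture_profile,
)

# ---------------------------------------------------------------------------
# independent oracles: exhaustive pair enumeration and direct summation
# ---------------------------------------------------------------------------

BRUTE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(levels: np.ndarray, n: int, d: int, theta: int) -> np.ndarray:
    """Count co-occurring pairs with an explicit double loop."""
    dr, dc = BRUTE_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = levels.shape
    counts = np.zeros((n, n))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts


def brute_force_features(p: np.ndarray) -> dict:
    """Direct-summation reference for all eight features (base-2 logs)."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum((i + 1) * px[i] for i in range(n))
    mu_y = sum((j + 1) * py[j] for j in range(n))
    sigma_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(n)) ** 0.5
    sigma_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(n)) ** 0.5
    log2 = lambda v: np.log2(v) if v > 0 else 0.0

    energy = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if sigma_x * sigma_y > 0:
        correlation = sum(
            (i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j] for i in range(n) for j in range(n)
        ) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    variance = sum((i + 1 - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    pxy = {}
    for i in range(n):
        for j in range(n):
            pxy[i + j + 2] = pxy.get(i + j + 2, 0.0) + p[i, j]
    sum_average = sum(k * v for k, v in pxy.items())
    sum_variance = sum((k - sum_average) ** 2 * v for k, v in pxy.items())
    sum_entropy = -sum(v * log2(v) for v in pxy.values())
    entropy = -sum(p[i, j] * log2(p[i, j]) for i in range(n) for j in range(n))
    return dict(
        energy=energy,
        contrast=contrast,
        correlation=correlation,
        variance=variance,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        entropy=entropy,
    )


def random_glcm(rng, n=16):
    m = rng.random((n, n))
    return m / m.sum()


# ---------------------------------------------------------------------------


class TestQuantize:
    @pytest.mark.parametrize(
        "value,n,expected",
        [(0, 16, 1), (255, 16, 16), (15, 16, 1), (16, 16, 2), (127, 2, 1), (128, 2, 2)],
    )
    def test_bin_edges(self, value, n, expected):
        q = quantize(np.array([[value]]), n_levels=n)
        assert q.levels[0, 0] == expected

    def test_levels_in_range(self, rng):
        q = quantize(rng.integers(0, 256, (32, 32)), n_levels=16)
        assert q.levels.min() >= 1 and q.levels.max() <= 16

    def test_invalid_limits(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), gray_limits=(10, 10))
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), n_levels=1)


class TestCooccurrence:
    def test_single_pair(self):
        q = quantize(np.array([[0, 16]]), n_levels=16)
        m = cooccurrence(q, d=1, theta=0)
        assert m.pair_count == 1
        expected = np.zeros((16, 16))
        expected[0, 1] = 1.0
        np.testing.assert_array_equal(m.probabilities, expected)

    def test_constant_image(self):
        from fundustex.glcm_texture import QuantizedImage

        q = QuantizedImage(levels=np.full((8, 8), 5), n_levels=16)
        for theta in ANGLES:
            m = cooccurrence(q, theta=theta)
            assert m.probabilities[4, 4] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        from fundustex.glcm_texture import QuantizedImage

        for _ in range(10):
            levels = rng.integers(1, 17, (16, 16))
            q = QuantizedImage(levels=levels, n_levels=16)
            for theta in ANGLES:
                m = cooccurrence(q, d=1, theta=theta)
                counts = brute_force_glcm(levels, 16, 1, theta)
                np.testing.assert_array_equal(
                    m.probabilities * m.pair_count, counts
                )
                assert m.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_image_smaller_than_offset(self):
        from fundustex.glcm_texture import QuantizedImage

        q = QuantizedImage(levels=np.ones((1, 1)), n_levels=16)
        with pytest.raises(ValueError):
            cooccurrence(q, d=1, theta=0)

    def test_bad_orientation(self):
        from fundustex.glcm_texture import QuantizedImage

        q = QuantizedImage(levels=np.ones((4, 4)), n_levels=16)
        with pytest.raises(ValueError):
            cooccurrence(q, theta=30)


class TestHaralickFeatures:
    def test_degenerate_constant_matrix(self):
        p = np.zeros((16, 16))
        p[3, 3] = 1.0
        with pytest.warns(UserWarning):  # sigma_x * sigma_y = 0
            f = haralick_features(p)
        assert f.energy == 1.0
        assert f.contrast == 0.0
        assert f.entropy == 0.0
        assert f.sum_entropy == 0.0
        assert f.variance == 0.0
        assert f.correlation == 0.0

    def test_uniform_matrix_closed_form(self):
        p = np.full((4, 4), 1 / 16)
        f = haralick_features(p)
        assert f.energy == pytest.approx(1 / 16)
        assert f.entropy == pytest.approx(4.0)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            p = random_glcm(rng)
            ours = haralick_features(p).as_dict()
            ref = brute_force_features(p)
            for name in FEATURE_NAMES:
                assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            haralick_features(np.full((4, 4), 1.0))

    def test_sum_average_marginal_identity(self, rng):
        # mu_{x+y} from P_{x+y} equals sum(i Px) + sum(j Py)
        for _ in range(10):
            p = random_glcm(rng)
            f = haralick_features(p)
            i = np.arange(1, 17)
            expected = float(i @ p.sum(axis=1) + i @ p.sum(axis=0))
            assert f.sum_average == pytest.approx(expected, abs=1e-10)

    def test_feature_bounds(self, rng):
        n = 16
        for _ in range(20):
            f = haralick_features(random_glcm(rng, n))
            assert 0 < f.energy <= 1
            assert 0 <= f.contrast <= (n - 1) ** 2
            assert -1 - 1e-12 <= f.correlation <= 1 + 1e-12
            assert 0 <= f.entropy <= 2 * np.log2(n)
            assert f.sum_entropy >= 0

    def test_natural_log_mode(self, rng):
        p = random_glcm(rng)
        f2 = haralick_features(p, log_base=2.0)
        fe = haralick_features(p, log_base=np.e)
        assert fe.entropy == pytest.approx(f2.entropy * np.log(2.0))


class TestDirectionalAverage:
    def test_identical_vectors(self):
        v = HaralickVector(0.5, 1, 0.2, 3, 4, 5, 0.6, 0.7)
        assert directional_average([v] * 4) == v

    def test_energy_mean(self):
        vecs = [
            HaralickVector(e, 0, 0, 0, 0, 0, 0, 0) for e in (0.2, 0.4, 0.6, 0.8)
        ]
        assert directional_average(vecs).energy == pytest.approx(0.5)

    def test_order_invariance(self):
        vecs = [
            HaralickVector(e, e, e, e, e, e, e, e) for e in (0.1, 0.9, 0.3, 0.5)
        ]
        fwd = directional_average(vecs).as_array()
        rev = directional_average(vecs[::-1]).as_array()
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)

    @pytest.mark.parametrize("count", [3, 5, 0])
    def test_wrong_count(self, count):
        v = HaralickVector(1, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            directional_average([v] * count)


class TestVesselTextureProfile:
    def test_empty_mask_degenerate(self, one_sample):
        with pytest.warns(UserWarning):
            f = vessel_texture_profile(
                one_sample.image, np.zeros_like(one_sample.mask)
            )
        assert f.energy == pytest.approx(1.0)
        assert f.contrast == 0.0

    def test_group_direction(self, healthy_cohort, pathological_cohort):
        h = np.stack(
            [vessel_texture_profile(s.image, s.mask).as_array() for s in healthy_cohort]
        )
        p = np.stack(
            [
                vessel_texture_profile(s.image, s.mask).as_array()
                for s in pathological_cohort
            ]
        )
        hm, pm = h.mean(axis=0), p.mean(axis=0)
        idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
        assert hm[idx["energy"]] < pm[idx["energy"]]
        for name in ("entropy", "variance", "sum_variance"):
            assert hm[idx[name]] > pm[idx[name]]

    def test_size_invariance_on_stationary_texture(self, rng):
        small = rng.integers(0, 256, (128, 128)).astype(np.uint8)
        large = rng.integers(0, 256, (256, 256)).astype(np.uint8)
        f_small = vessel_texture_profile(small, np.ones_like(small)).as_array()
        f_large = vessel_texture_profile(large, np.ones_like(large)).as_array()
        diff = np.abs(f_small - f_large)
        rel = diff / np.abs(f_large)
        # near-zero features (correlation of iid noise) use an absolute bound
        assert np.all((rel < 0.05) | (diff < 0.01))

    def test_mask_mismatch(self, one_sample):
        with pytest.raises(ValueError):
            vessel_texture_profile(one_sample.image, np.zeros((4, 4)))
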