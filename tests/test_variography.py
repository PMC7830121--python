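import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldpgen.fixtures import bernoulli_field, brute_force_variogram
from ldpgen.image_io import BinaryMask
from ldpgen.variography import (
    AXES,
    LagSpec,
    default_max_lag,
    empirical_variogram,
    variograms_xyz,
)


def random_mask(seed, shape=None, p=None, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    if shape is None:
        shape = tuple(rng.integers(3, 9, size=3))
    if p is None:
        p = rng.uniform(0.05, 0.95)
    data = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(data=data, spacing=spacing)


class TestAgainstBruteForceOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_bit_identical_to_triple_loop(self, seed):
        """Shift-based variograms equal the literal pair-loop on random masks."""
        mask = random_mask(seed)
        max_lag = min(6, min(mask.shape) - 1)
        for d in AXES:
            fast = empirical_variogram(mask, d, LagSpec(max_lag))
            slow = brute_force_variogram(mask, d, max_lag)
            np.testing.assert_array_equal(fast.gamma, slow.gamma)
            np.testing.assert_array_equal(fast.pair_counts, slow.pair_counts)
            np.testing.assert_array_equal(fast.distances_mm, slow.distances_mm)


class TestKnownFields:
    def test_constant_mask_zero_variogram(self):
        mask = BinaryMask(data=np.ones((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
        emp = empirical_variogram(mask, "x", LagSpec(3))
        np.testing.assert_array_equal(emp.gamma, [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(emp.pair_counts, [48, 32, 16])

    def test_alternating_planes_along_x(self):
        """0,1,0,1 planes: all lag-1/3 pairs differ (gamma 0.5), lag-2 match."""
        data = np.zeros((4, 4, 4), dtype=np.uint8)
        data[1::2, :, :] = 1
        mask = BinaryMask(data=data, spacing=(1, 1, 1))
        emp = empirical_variogram(mask, "x", LagSpec(3))
        np.testing.assert_array_equal(emp.gamma, [0.5, 0.0, 0.5])

    def test_gamma_bounded_for_binary_input(self):
        for seed in range(5):
            mask = random_mask(seed, shape=(8, 8, 8))
            for emp in variograms_xyz(mask, LagSpec(5)):
                assert np.all(emp.gamma >= 0) and np.all(emp.gamma <= 0.5)


class TestInvariances:
    @given(seed=st.integers(0, 200))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_complement_invariance(self, seed):
        """Flipping all labels 0<->1 leaves every variogram unchanged."""
        mask = random_mask(seed, shape=(6, 6, 6))
        flipped = BinaryMask(data=1 - mask.data, spacing=mask.spacing)
        for d in AXES:
            a = empirical_variogram(mask, d, LagSpec(4))
            b = empirical_variogram(flipped, d, LagSpec(4))
            np.testing.assert_array_equal(a.gamma, b.gamma)

    @given(seed=st.integers(0, 200), axis=st.integers(0, 2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_axis_flip_invariance(self, seed, axis):
        """Reversing the array along the lag axis preserves that variogram."""
        mask = random_mask(seed, shape=(6, 6, 6))
        reversed_ = BinaryMask(data=np.flip(mask.data, axis=axis), spacing=mask.spacing)
        a = empirical_variogram(mask, AXES[axis], LagSpec(4))
        b = empirical_variogram(reversed_, AXES[axis], LagSpec(4))
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_transpose_swaps_directions(self):
        mask = random_mask(11, shape=(6, 5, 4))
        swapped = BinaryMask(
            data=np.transpose(mask.data, (1, 0, 2)), spacing=(1, 1, 1)
        )
        a = empirical_variogram(mask, "x", LagSpec(3))
        b = empirical_variogram(swapped, "y", LagSpec(3))
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.pair_counts, b.pair_counts)


class TestPairCountsAndDistances:
    @pytest.mark.parametrize("shape", [(6, 5, 4), (8, 8, 8), (3, 7, 5)])
    def test_pair_count_formula(self, shape):
        mask = random_mask(2, shape=shape)
        max_lag = min(shape) - 1
        for axis, d in enumerate(AXES):
            emp = empirical_variogram(mask, d, LagSpec(max_lag))
            other = mask.data.size // shape[axis]
            expected = [(shape[axis] - k) * other for k in range(1, max_lag + 1)]
            np.testing.assert_array_equal(emp.pair_counts, expected)

    def test_distances_use_per_axis_spacing(self):
        mask = random_mask(3, shape=(6, 6, 6), spacing=(0.5, 1.0, 2.0))
        ex, ey, ez = variograms_xyz(mask, LagSpec(4))
        np.testing.assert_allclose(ex.distances_mm, [0.5, 1.0, 1.5, 2.0])
        np.testing.assert_allclose(ey.distances_mm, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(ez.distances_mm, [2.0, 4.0, 6.0, 8.0])


class TestLagSpec:
    def test_max_lag_must_fit_in_volume(self):
        mask = random_mask(4, shape=(4, 8, 8))
        with pytest.raises(ValueError, match="max_lag"):
            empirical_variogram(mask, "x", LagSpec(4))

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_max_lag(self, bad):
        with pytest.raises(ValueError):
            LagSpec(bad)

    def test_bad_direction(self, small_mask):
        with pytest.raises(ValueError, match="direction"):
            empirical_variogram(small_mask, "w", LagSpec(2))


class TestDefaultMaxLag:
    def test_fifteen_mm_rule(self):
        # 1.5 mm voxels -> 10 lags; 1.0 mm voxels -> 15 lags
        assert default_max_lag((1.5, 1.5, 1.5), (100, 100, 100)) == 10
        assert default_max_lag((1.0, 1.0, 1.0), (100, 100, 100)) == 15

    def test_coarsest_axis_governs(self):
        assert default_max_lag((1.0, 1.0, 3.0), (100, 100, 100)) == 5

    def test_clamped_to_volume(self):
        assert default_max_lag((1.0, 1.0, 1.0), (8, 100, 100)) == 7
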