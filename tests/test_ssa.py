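"""Embedding, diagonal averaging, SVD decomposition and SSA smoothing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from blinkssa import (
    DegenerateSignalError,
    InvalidWindowError,
    Signal1D,
    diagonal_average,
    eigen_ratio_group,
    embed,
    rrmse,
    ssa_decompose,
    ssa_denoise,
)
from conftest import diag_avg_loop


class TestSignal1D:
    def test_validation(self):
        with pytest.raises(ValueError):
            Signal1D([1.0], 256.0)
        with pytest.raises(ValueError):
            Signal1D([1.0, np.nan], 256.0)
        with pytest.raises(ValueError):
            Signal1D([1.0, 2.0], 0.0)

    def test_samples_are_read_only(self):
        sig = Signal1D([1.0, 2.0, 3.0], 256.0)
        with pytest.raises(ValueError):
            sig.samples[0] = 9.0

    def test_time_grid(self):
        sig = Signal1D(np.zeros(512), 256.0)
        assert sig.duration_s == 2.0
        assert sig.times[1] == pytest.approx(1 / 256)


class TestEmbed:
    def test_small_example(self):
        x = Signal1D([1, 2, 3, 4, 5], 1.0)
        assert embed(x, 2).values.tolist() == [[1, 2, 3, 4], [2, 3, 4, 5]]

    def test_epoch_shape_at_operating_point(self):
        # 10 s at 256 Hz with a 500 ms window: K = N - M + 1
        x = Signal1D(np.random.default_rng(0).standard_normal(2560), 256.0)
        tm = embed(x, 128)
        assert tm.values.shape == (128, 2433)

    def test_full_window_single_column(self):
        x = Signal1D([3.0, 1.0, 4.0, 1.0], 1.0)
        tm = embed(x, 4)
        assert tm.values.shape == (4, 1)
        np.testing.assert_array_equal(tm.values[:, 0], x.samples)

    def test_hankel_property(self):
        x = Signal1D(np.arange(12.0) ** 2, 1.0)
        v = embed(x, 5).values
        for n in range(v.shape[0] + v.shape[1] - 1):
            anti = [v[i, n - i] for i in range(v.shape[0]) if 0 <= n - i < v.shape[1]]
            assert len(set(anti)) == 1

    @pytest.mark.parametrize("bad_window", [0, 1, 6, -3])
    def test_invalid_window(self, bad_window):
        with pytest.raises(InvalidWindowError):
            embed(Signal1D([1, 2, 3, 4, 5], 1.0), bad_window)


class TestDiagonalAverage:
    def test_round_trip_exact_integers(self):
        x = Signal1D([1, 2, 3, 4, 5], 1.0)
        np.testing.assert_array_equal(
            diagonal_average(embed(x, 3)), [1, 2, 3, 4, 5]
        )

    def test_cross_matrix(self):
        np.testing.assert_array_equal(
            diagonal_average(np.array([[1.0, 0.0], [0.0, 1.0]])), [1, 0, 1]
        )

    def test_matches_brute_force_loop_exactly(self):
        a = np.random.default_rng(1).standard_normal((4, 6))
        np.testing.assert_array_equal(diagonal_average(a), diag_avg_loop(a))

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        alpha, beta = 0.7, -2.5
        np.testing.assert_allclose(
            diagonal_average(alpha * a + beta * b),
            alpha * diagonal_average(a) + beta * diagonal_average(b),
            atol=1e-10,
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diagonal_average(np.empty((0, 3)))

    @given(
        st.integers(2, 30).flatmap(
            lambda n: st.tuples(
                st.lists(
                    st.floats(-1e6, 1e6, allow_nan=False, width=64),
                    min_size=n,
                    max_size=n,
                ),
                st.integers(2, n),
            )
        )
    )
    def test_round_trip_property(self, case):
        samples, m = case
        x = Signal1D(np.asarray(samples), 1.0)
        back = diagonal_average(embed(x, m))
        np.testing.assert_allclose(back, x.samples, rtol=1e-12, atol=1e-12)


class TestDecomposition:
    def test_ratios_probability_vector(self):
        x = Signal1D(np.random.default_rng(3).standard_normal(200), 1.0)
        dec = ssa_decompose(x, 20)
        assert np.all(dec.ratios >= 0)
        assert dec.ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dec.eigenvalues) <= 0)

    def test_completeness_sum_of_components(self):
        x = Signal1D(np.random.default_rng(4).standard_normal(60), 1.0)
        dec = ssa_decompose(x, 8)
        total = dec.reconstruct(np.arange(dec.rank))
        np.testing.assert_allclose(total, embed(x, 8).values, atol=1e-10)

    def test_sinusoid_has_rank_two(self):
        t = np.arange(1024) / 256.0
        dec = ssa_decompose(Signal1D(np.sin(2 * np.pi * 10 * t), 256.0), 64)
        assert int((dec.ratios > 0.01).sum()) == 2

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSignalError):
            ssa_decompose(Signal1D(np.zeros(50), 1.0), 10)

    def test_components_match_independent_eigh_oracle(self):
        """Rank-one terms agree with an eigendecomposition of the lag covariance."""
        rng = np.random.default_rng(5)
        x = Signal1D(rng.standard_normal(48), 1.0)
        m = 12
        dec = ssa_decompose(x, m)
        a = embed(x, m).values
        lam, u = np.linalg.eigh(a @ a.T)  # independent route: covariance eigh
        order = np.argsort(lam)[::-1]
        lam, u = lam[order], u[:, order]
        np.testing.assert_allclose(dec.eigenvalues, lam, atol=1e-8)
        for i in range(m):
            expected = np.outer(u[:, i], u[:, i]) @ a  # u_i u_i^T A
            np.testing.assert_allclose(
                dec.component_matrix(i), expected, atol=1e-8
            )


class TestGrouping:
    def test_threshold_selection(self):
        class Fake:
            rank = 4
            ratios = np.array([0.9, 0.09, 0.009, 0.001])

        assert eigen_ratio_group(Fake(), 0.01).tolist() == [0, 1]

    def test_zero_threshold_retains_everything(self):
        x = Signal1D(np.random.default_rng(7).standard_normal(100), 1.0)
        dec = ssa_decompose(x, 10)
        assert eigen_ratio_group(dec, 0.0).size == dec.rank

    def test_flat_spectrum_fallback_keeps_largest(self):
        class Flat:
            rank = 8
            ratios = np.full(8, 1 / 8)

        assert eigen_ratio_group(Flat(), 0.2).tolist() == [0]

    def test_threshold_range_validated(self):
        class Flat:
            rank = 2
            ratios = np.array([0.5, 0.5])

        with pytest.raises(ValueError):
            eigen_ratio_group(Flat(), 1.0)


class TestDenoise:
    def test_zero_threshold_is_identity(self):
        x = Signal1D(np.random.default_rng(8).standard_normal(300), 256.0)
        out = ssa_denoise(x, 32, 0.0)
        np.testing.assert_allclose(out.samples, x.samples, rtol=1e-9, atol=1e-9)

    def test_noiseless_low_frequency_tone_preserved(self):
        t = np.arange(512) / 256.0
        tone = np.sin(2 * np.pi * 2 * t)
        out = ssa_denoise(Signal1D(tone, 256.0), 64, 0.01)
        assert rrmse(tone, out.samples) < 1.0

    def test_smooths_noisy_blink_bump(self):
        rng = np.random.default_rng(3)
        n = 512
        bump = np.zeros(n)
        bump[200:280] = 50 * np.sin(np.pi * np.arange(80) / 80) ** 2
        noise = rng.standard_normal(n) * np.sqrt((bump**2).mean()) / 10  # 20 dB
        noisy = Signal1D(bump + noise, 256.0)
        out = ssa_denoise(noisy, 64, 0.01)
        assert rrmse(bump, out.samples) < rrmse(bump, noisy.samples)

    def test_preserves_grid(self):
        x = Signal1D(np.random.default_rng(9).standard_normal(256), 128.0)
        out = ssa_denoise(x, 16, 0.01)
        assert out.n_samples == x.n_samples and out.fs == x.fs
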