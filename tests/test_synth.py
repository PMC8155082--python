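"""Synthetic EEG / blink generator: reproducibility, band limits, morphology."""

import numpy as np
import pytest
from scipy.signal import welch

from blinkssa import katz_fd, mix
from blinkssa.synth import (
    generate_benchmark,
    generate_clean_eeg,
    generate_epoch,
    generate_eyeblink,
)


class TestCleanEEG:
    def test_reproducible(self):
        a = generate_clean_eeg(seed=0)
        b = generate_clean_eeg(seed=0)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, generate_clean_eeg(seed=1).samples)

    def test_default_grid(self):
        sig = generate_clean_eeg()
        assert sig.n_samples == 2560 and sig.fs == 256.0

    def test_zero_mean_and_scale(self):
        sig = generate_clean_eeg(seed=2, amplitude_sd_uv=10.0)
        assert abs(sig.samples.mean()) < 0.1 * sig.samples.std()
        assert sig.samples.std() == pytest.approx(10.0)

    def test_band_limited(self):
        sig = generate_clean_eeg(seed=3)
        freqs, psd = welch(sig.samples, fs=sig.fs, nperseg=512)
        total = np.trapezoid(psd, freqs)
        high = np.trapezoid(psd[freqs > 35.0], freqs[freqs > 35.0])
        in_band = np.trapezoid(
            psd[(freqs >= 1.0) & (freqs <= 30.0)],
            freqs[(freqs >= 1.0) & (freqs <= 30.0)],
        )
        assert high / total < 0.01
        assert in_band / total > 0.95

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_clean_eeg(duration_s=0.5)


class TestEyeblink:
    def test_support_length_matches_duration(self):
        blink = generate_eyeblink(2560, 256.0, onsets=[500], durations_ms=[300.0])
        support = np.flatnonzero(blink.samples)
        assert support.size == 77  # round(0.3 * 256)
        assert support[0] == 500 and support[-1] == 576
        assert not np.any(blink.samples[:500]) and not np.any(blink.samples[577:])

    def test_peak_amplitude_exact(self):
        blink = generate_eyeblink(
            2560, 256.0, onsets=[500], durations_ms=[250.0], peak_uv=95.0
        )
        assert blink.samples.max() == pytest.approx(95.0)

    def test_edges_continuous(self):
        blink = generate_eyeblink(2560, 256.0, onsets=[500], durations_ms=[400.0])
        first_diff = np.abs(np.diff(blink.samples))
        assert first_diff.max() < 0.15 * blink.samples.max()

    def test_smoother_than_background(self):
        clean = generate_clean_eeg(seed=4)
        blink = generate_eyeblink(
            clean.n_samples, clean.fs, onsets=[900], durations_ms=[200.0]
        )
        assert katz_fd(blink) < katz_fd(clean)

    def test_biphasic_shape(self):
        blink = generate_eyeblink(
            2560, 256.0, onsets=[500], durations_ms=[300.0], shape="biphasic"
        )
        assert blink.samples.max() > 0 > blink.samples.min()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"onsets": [500], "durations_ms": [50.0]},  # too short
            {"onsets": [500], "durations_ms": [500.0]},  # too long
            {"onsets": [2550], "durations_ms": [300.0]},  # leaves epoch
            {"onsets": [500, 530], "durations_ms": [300.0, 300.0]},  # overlap
        ],
    )
    def test_invalid_blinks_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_eyeblink(2560, 256.0, **kwargs)


class TestMixing:
    def test_exactness(self):
        epoch = generate_epoch(p=0.75, seed=5)
        np.testing.assert_array_equal(
            epoch.contaminated.samples,
            epoch.clean.samples + 0.75 * epoch.artifact.samples,
        )

    def test_zero_p_is_clean(self):
        clean = generate_clean_eeg(seed=6)
        blink = generate_eyeblink(
            clean.n_samples, clean.fs, onsets=[700], durations_ms=[150.0]
        )
        np.testing.assert_array_equal(mix(clean, blink, 0.0).samples, clean.samples)

    def test_snr_decreases_with_p(self):
        clean = generate_clean_eeg(seed=7)
        blink = generate_eyeblink(
            clean.n_samples, clean.fs, onsets=[700], durations_ms=[150.0]
        )

        def snr(p):
            x = mix(clean, blink, p)
            return np.sum(clean.samples**2) / np.sum(
                (x.samples - clean.samples) ** 2
            )

        assert snr(1.5) < snr(0.5)

    def test_grid_mismatch_rejected(self):
        clean = generate_clean_eeg(seed=8)
        other = generate_clean_eeg(duration_s=5.0, seed=8)
        with pytest.raises(ValueError):
            mix(clean, other, 1.0)


class TestEpochAndBenchmark:
    def test_epoch_reproducible(self):
        a = generate_epoch(p=1.0, seed=9)
        b = generate_epoch(p=1.0, seed=9)
        np.testing.assert_array_equal(a.contaminated.samples, b.contaminated.samples)
        assert a.blink_onsets == b.blink_onsets

    def test_epoch_invariants(self):
        epoch = generate_epoch(p=1.25, seed=10, n_blinks=2)
        support = np.flatnonzero(epoch.artifact.samples)
        mask = np.flatnonzero(epoch.truth_support)
        np.testing.assert_array_equal(support, mask)
        for dur in epoch.blink_durations_ms:
            assert 100.0 <= dur <= 400.0

    def test_no_blink_epoch(self):
        epoch = generate_epoch(p=1.0, seed=11, n_blinks=0)
        assert not np.any(epoch.artifact.samples)
        np.testing.assert_array_equal(
            epoch.contaminated.samples, epoch.clean.samples
        )

    def test_benchmark_counts_and_determinism(self):
        bench = generate_benchmark(
            n_eeg=4, n_blinks=3, p_values=(0.5, 1.0), seed=12
        )
        assert set(bench) == {0.5, 1.0}
        assert all(len(v) == 12 for v in bench.values())
        again = generate_benchmark(
            n_eeg=4, n_blinks=3, p_values=(0.5, 1.0), seed=12
        )
        np.testing.assert_array_equal(
            bench[1.0][5].contaminated.samples,
            again[1.0][5].contaminated.samples,
        )

    def test_benchmark_epochs_distinct(self):
        bench = generate_benchmark(n_eeg=3, n_blinks=1, p_values=(1.0,), seed=13)
        a, b, c = (e.clean.samples for e in bench[1.0])
        assert not np.array_equal(a, b) and not np.array_equal(b, c)

    def test_fd_separability_gate(self):
        """Generator realism: blink below / clean above the 1.4 FD threshold."""
        ok = 0
        n = 40
        for i in range(n):
            epoch = generate_epoch(p=1.0, seed=3000 + i)
            if katz_fd(epoch.artifact) < 1.4 < katz_fd(epoch.clean):
                ok += 1
        assert ok >= 0.95 * n
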