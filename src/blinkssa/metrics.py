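"""Evaluation measures for artifact removal.

Time-domain (against a known ground-truth artifact, synthetic benchmarks):

* RRMSE — relative root-mean-square error in percent,
  ``100 * sqrt(sum((a - a_hat)^2) / sum(a^2))``; 0 for a perfect estimate,
  100 for the all-zero estimator.
* CC — Pearson correlation between true and estimated artifact; 1 when
  perfect.

Frequency-domain (no ground truth needed, real recordings):

* power-spectrum ratio Gamma(f) = P_corrected(f) / P_contaminated(f) on
  integer-Hz bins 1..30.  Blinks live below ~12 Hz, so Gamma < 1 there
  after successful removal while Gamma stays ~1 in the beta band
  (12-30 Hz) if the method leaves uncontaminated EEG alone.
* band MAE — mean absolute spectral difference over a band (1-8, 8-12,
  12-30 Hz conventionally); ~0 in the beta band for a non-destructive
  method.

Detection quality:

* FPR — fraction of true non-artifact samples flagged by the binary
  template.

Spectra are Welch estimates (2-second Hann segments, 50% overlap) read off
at the bins nearest each integer frequency; the estimator settings travel
with the :class:`SpectrumPair` so ratio and MAE are always computed on a
common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .errors import DegenerateSignalError
from .ssa import Signal1D

__all__ = [
    "SpectrumPair",
    "rrmse",
    "corrcoef",
    "spectrum_pair",
    "power_spectrum_ratio",
    "mae_band",
    "mean_gamma",
    "false_positive_rate",
]

#: conventional EEG evaluation bands (Hz): slow (delta+theta), alpha, beta
BANDS = {"slow": (1.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = a.samples if isinstance(a, Signal1D) else np.asarray(a, dtype=np.float64).ravel()
    b = b.samples if isinstance(b, Signal1D) else np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return a, b


def rrmse(truth, estimate) -> float:
    """Relative RMS error in percent; 0 when estimate == truth exactly."""
    a, a_hat = _pair(truth, estimate)
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise DegenerateSignalError("RRMSE undefined for an all-zero truth signal")
    return float(100.0 * np.sqrt(np.sum((a - a_hat) ** 2) / denom))


def corrcoef(truth, estimate) -> float:
    """Pearson correlation coefficient between the two signals, in [-1, 1]."""
    a, a_hat = _pair(truth, estimate)
    if np.std(a) == 0.0 or np.std(a_hat) == 0.0:
        raise DegenerateSignalError("correlation undefined for a constant signal")
    return float(np.corrcoef(a, a_hat)[0, 1])


@dataclass(frozen=True)
class SpectrumPair:
    """Welch spectra of a contaminated / corrected signal pair on a common grid."""

    frequencies: np.ndarray
    p_x: np.ndarray
    p_s_hat: np.ndarray
    fs: float
    nperseg: int
    noverlap: int

    @property
    def gamma(self) -> np.ndarray:
        """Per-bin power ratio corrected/contaminated; NaN where p_x is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.p_x > 0.0, self.p_s_hat / self.p_x, np.nan)

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if not hi > lo:
            raise ValueError(f"band {band} is empty")
        mask = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not mask.any():
            raise ValueError(f"band {band} contains no spectral bins")
        return mask


def spectrum_pair(
    contaminated: Signal1D,
    corrected: Signal1D,
    seg_seconds: float = 2.0,
    overlap: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 30.0,
) -> SpectrumPair:
    """Welch spectra of both signals, sampled at integer-Hz bins fmin..fmax.

    Hann window, ``seg_seconds``-long segments with fractional ``overlap``;
    each integer frequency is read off the nearest Welch bin (with a 256 Hz
    rate and 2 s segments the bins fall exactly on the 0.5 Hz grid).
    """
    x, s_hat = _pair(contaminated, corrected)
    fs = contaminated.fs if isinstance(contaminated, Signal1D) else corrected.fs
    if fs < 2 * fmax:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve {fmax} Hz")
    nperseg = min(int(round(seg_seconds * fs)), x.size)
    noverlap = int(nperseg * overlap)
    freqs, p_x = welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    _, p_s = welch(s_hat, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    grid = np.arange(np.ceil(fmin), np.floor(fmax) + 1)
    idx = np.array([np.argmin(np.abs(freqs - f)) for f in grid])
    return SpectrumPair(
        frequencies=grid,
        p_x=p_x[idx],
        p_s_hat=p_s[idx],
        fs=float(fs),
        nperseg=nperseg,
        noverlap=noverlap,
    )


def power_spectrum_ratio(
    contaminated: Signal1D, corrected: Signal1D, **welch_kwargs
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma(f) on integer-Hz bins; returns (frequencies, gamma)."""
    spec = spectrum_pair(contaminated, corrected, **welch_kwargs)
    return spec.frequencies, spec.gamma


def mae_band(spec: SpectrumPair, band: tuple[float, float]) -> float:
    """Mean absolute spectral difference |p_x - p_s_hat| over a band (inclusive)."""
    mask = spec.band_mask(band)
    return float(np.mean(np.abs(spec.p_x[mask] - spec.p_s_hat[mask])))


def mean_gamma(spec: SpectrumPair, band: tuple[float, float]) -> float:
    """Mean power-spectrum ratio over a band, ignoring undefined bins."""
    mask = spec.band_mask(band)
    return float(np.nanmean(spec.gamma[mask]))


def false_positive_rate(template, truth_support, window: int | None = None) -> float:
    """Fraction of true non-artifact samples that the template flags.

    Samplewise by default: FP / (FP + TN) over the binary template versus
    the ground-truth blink support.  With ``window`` set, both masks are
    first collapsed onto disjoint blocks of that many samples (a block is
    flagged if any sample in it is) for a window-level rate.
    """
    t, truth = _pair(template, truth_support)
    t = t != 0
    truth = truth != 0
    if window is not None:
        if window < 1:
            raise ValueError("window must be a positive sample count")
        n_blocks = int(np.ceil(t.size / window))
        pad = n_blocks * window - t.size
        t = np.pad(t, (0, pad)).reshape(n_blocks, window).any(axis=1)
        truth = np.pad(truth, (0, pad)).reshape(n_blocks, window).any(axis=1)
    negatives = ~truth
    if not negatives.any():
        raise ValueError("FPR undefined: ground truth flags every sample")
    return float(np.sum(t & negatives) / np.sum(negatives))
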