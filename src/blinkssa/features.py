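"""Per-window time-domain features for blink/background separation.

Four features are computed for every column (lagged window) of the
trajectory matrix, yielding a 4 x K feature matrix F:

``f1``  signal energy, sum of squared samples (µV²),
``f2``  Hjorth mobility, sqrt of the first-difference power over the window
        variance (a normalised dominant-frequency proxy, dimensionless),
``f3``  Pearson kurtosis m4 / m2² with population moments (dimensionless),
``f4``  max{w} - |min{w}| (µV).

Eye blinks appear as high-amplitude, slow, positive deflections: windows
overlapping a blink have large f1 and f4, low f2, and heavy-tailed f3, so
the blink windows separate from background EEG in this feature space — that
separation is what the downstream k-means step exploits.

Conventions: all moments are population moments (divide by the window
length); the mobility numerator is the raw second moment of the first
difference (taken about zero — the first difference of a short window has
negligible mean, and this keeps the estimator exact for strictly
alternating sequences); constant windows get mobility 0 and, in the matrix
path, kurtosis 0, so the feature matrix is always total and finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWindowError
from .ssa import TrajectoryMatrix

__all__ = [
    "FeatureMatrix",
    "energy",
    "hjorth_mobility",
    "kurtosis",
    "range_feature",
    "compute_feature_matrix",
    "standardize_features",
]

#: row order of the feature matrix
FEATURE_NAMES = ("energy", "mobility", "kurtosis", "range")


@dataclass(frozen=True)
class FeatureMatrix:
    """4 x K matrix of per-window features; rows ordered as FEATURE_NAMES."""

    values: np.ndarray
    window_length: int

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=np.float64, copy=True)
        if values.ndim != 2 or values.shape[0] != len(FEATURE_NAMES):
            raise ValueError("feature matrix must have one row per feature")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains non-finite entries")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def n_windows(self) -> int:
        return int(self.values.shape[1])


def _window(w) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64).ravel()
    if w.size < 1:
        raise ValueError("empty window")
    return w


def energy(w) -> float:
    """Signal energy: sum of squared samples. Zero iff the window is all-zero."""
    w = _window(w)
    return float(np.sum(w * w))


def hjorth_mobility(w) -> float:
    """Hjorth mobility sqrt(P[Δw] / var(w)); 0 for constant windows.

    ``P[Δw]`` is the mean squared first difference and ``var`` the
    population variance.
    """
    w = _window(w)
    if w.size < 2:
        raise ValueError("mobility needs at least 2 samples")
    var = float(np.var(w))
    if var == 0.0:
        return 0.0
    diff = np.diff(w)
    return float(np.sqrt(np.mean(diff * diff) / var))


def kurtosis(w) -> float:
    """Pearson kurtosis m4 / m2² with population moments (Gaussian -> 3).

    Raises
    ------
    DegenerateWindowError
        For constant windows (zero variance); the matrix path maps these
        to 0 instead.
    """
    w = _window(w)
    centred = w - w.mean()
    m2 = float(np.mean(centred**2))
    if m2 == 0.0:
        raise DegenerateWindowError("kurtosis undefined on a constant window")
    m4 = float(np.mean(centred**4))
    return m4 / (m2 * m2)


def range_feature(w, mode: str = "abs_min") -> float:
    """Amplitude-range feature f4.

    ``mode="abs_min"`` (default): max{w} - |min{w}| — large and positive for
    a unimodal positive blink deflection, near zero for symmetric
    oscillations.  ``mode="plain_range"``: max{w} - min{w}.
    """
    w = _window(w)
    if mode == "abs_min":
        return float(w.max() - abs(w.min()))
    if mode == "plain_range":
        return float(w.max() - w.min())
    raise ValueError(f"unknown range mode {mode!r}")


def compute_feature_matrix(
    trajectory: TrajectoryMatrix, range_mode: str = "abs_min"
) -> FeatureMatrix:
    """Vectorised 4 x K feature matrix over the trajectory-matrix columns.

    Column j holds (f1, f2, f3, f4) of window j.  Constant windows are
    mapped to mobility 0 and kurtosis 0 so the result is always finite.
    """
    v = trajectory.values
    m = trajectory.window_length

    f1 = np.einsum("ij,ij->j", v, v)

    centred = v - v.mean(axis=0)
    m2 = np.einsum("ij,ij->j", centred, centred) / m
    ok = m2 > 0.0
    safe_m2 = np.where(ok, m2, 1.0)

    diff = np.diff(v, axis=0)
    diff_power = np.einsum("ij,ij->j", diff, diff) / max(m - 1, 1)
    f2 = np.where(ok, np.sqrt(diff_power / safe_m2), 0.0)

    m4 = np.einsum("ij,ij->j", centred * centred, centred * centred) / m
    f3 = np.where(ok, m4 / (safe_m2 * safe_m2), 0.0)

    if range_mode == "abs_min":
        f4 = v.max(axis=0) - np.abs(v.min(axis=0))
    elif range_mode == "plain_range":
        f4 = v.max(axis=0) - v.min(axis=0)
    else:
        raise ValueError(f"unknown range mode {range_mode!r}")

    return FeatureMatrix(values=np.vstack([f1, f2, f3, f4]), window_length=m)


def standardize_features(features: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature row across the K windows.

    f1 (µV²) and f3 (dimensionless) differ by orders of magnitude;
    unstandardised k-means would effectively cluster on energy alone.  Rows
    with zero spread are set to zero.
    """
    v = features.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    ok = sd > 0.0
    z = np.where(ok, (v - mean) / np.where(ok, sd, 1.0), 0.0)
    return FeatureMatrix(values=z, window_length=features.window_length)
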