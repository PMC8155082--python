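"""Fractal-dimension estimators and FD-threshold selection of blink components.

A fractal dimension (FD) measures waveform complexity: a smooth,
slowly-varying curve (an eye blink) has FD near 1, while broadband
oscillatory noise (background EEG) has FD approaching 2 (Higuchi) or well
above 1.4 (Katz).  The pipeline computes an FD per clustered component and
sums those at or below a threshold ``T_h`` into the raw blink estimate; when
no component falls at or below the threshold the epoch is declared
artifact-free.

Two standard estimators ship:

* **Katz**: FD = log10(n) / (log10(n) + log10(d / L)) with n = N-1 steps,
  L the total polyline length (sum of successive absolute differences) and
  d the maximum distance from the first sample.  Parameter-free and
  amplitude-invariant; the default, paired with the working threshold range
  T_h in [1.2, 1.4].
* **Higuchi**: slope of the log-log regression of mean curve length versus
  1/k for lags k = 1..kmax (default 10), clipped to [1, 2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ssa import Signal1D

__all__ = [
    "ComponentSelection",
    "katz_fd",
    "higuchi_fd",
    "select_artifact_components",
]


def _samples(s) -> np.ndarray:
    return s.samples if isinstance(s, Signal1D) else np.asarray(s, dtype=np.float64).ravel()


def katz_fd(s) -> float:
    """Katz fractal dimension; >= 1, equal to 1 for straight lines.

    Constant signals (zero curve length) return 1.0 by convention.
    """
    x = _samples(s)
    if x.size < 3:
        raise ValueError("katz_fd needs at least 3 samples")
    curve_length = float(np.abs(np.diff(x)).sum())
    extent = float(np.abs(x - x[0]).max())
    if curve_length == 0.0 or extent == 0.0:
        return 1.0
    log_n = np.log10(x.size - 1)
    return float(log_n / (log_n + np.log10(extent / curve_length)))


def higuchi_fd(s, kmax: int = 10) -> float:
    """Higuchi fractal dimension, clipped to [1, 2].

    Builds kmax coarse-grained curve lengths L(k) (averaged over the k
    sub-series at lag k) and returns the slope of log L(k) against
    log(1/k).  White noise approaches 2, a densely sampled smooth curve
    approaches 1.  Requires N >= 10 * kmax samples.
    """
    x = _samples(s)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    if n < 10 * kmax:
        raise ValueError(f"higuchi_fd needs at least {10 * kmax} samples, got {n}")
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        per_offset = []
        for m in range(k):
            sub = x[m::k]
            if sub.size < 2:
                continue
            norm = (n - 1) / ((sub.size - 1) * k)
            per_offset.append(np.abs(np.diff(sub)).sum() * norm / k)
        lengths[k - 1] = np.mean(per_offset)
    if np.all(lengths == 0.0):
        return 1.0  # constant signal
    ks = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / ks), np.log(lengths), 1)[0]
    return float(np.clip(slope, 1.0, 2.0))


@dataclass(frozen=True)
class ComponentSelection:
    """Outcome of FD-threshold selection over the L clustered components.

    ``selected`` indexes (0-based) the components whose FD is at or below
    the threshold; ``artifact_raw`` is their sum; ``no_artifact`` is set
    when nothing was selected, in which case ``artifact_raw`` is all-zero.
    """

    fd_values: np.ndarray
    selected: tuple[int, ...]
    artifact_raw: Signal1D
    no_artifact: bool


def select_artifact_components(
    components: Sequence[Signal1D],
    fd_threshold: float,
    fd_method: str = "katz",
    kmax: int = 10,
) -> ComponentSelection:
    """Sum the components whose fractal dimension is <= ``fd_threshold``.

    Selection is inclusive (<=) and monotone in the threshold.  All-zero
    components (empty clusters) are never selected: their FD is 1.0 only by
    the constant-signal convention and they carry no artifact energy.
    """
    if len(components) < 1:
        raise ValueError("need at least one component")
    if fd_threshold <= 0:
        raise ValueError(f"fd_threshold must be positive, got {fd_threshold}")
    if fd_method == "katz":
        estimator = katz_fd
    elif fd_method == "higuchi":
        def estimator(sig):  # noqa: E306 - tiny closure over kmax
            return higuchi_fd(sig, kmax=kmax)
    else:
        raise ValueError(f"unknown fd_method {fd_method!r}")

    fd_values = np.array([estimator(c) for c in components])
    nonzero = np.array([bool(np.any(c.samples)) for c in components])
    selected = tuple(
        int(i)
        for i in np.flatnonzero((fd_values <= fd_threshold) & nonzero)
    )
    fs = components[0].fs
    total = np.zeros(components[0].n_samples)
    for i in selected:
        total = total + components[i].samples
    return ComponentSelection(
        fd_values=fd_values,
        selected=selected,
        artifact_raw=Signal1D(total, fs),
        no_artifact=len(selected) == 0,
    )
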