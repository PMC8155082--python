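"""Singular-spectrum-analysis core: embedding, diagonal averaging, SVD, grouping.

Singular spectrum analysis (SSA) decomposes a one-dimensional series by

1. *embedding* it into an M x K Hankel "trajectory" matrix of lagged windows
   (K = N - M + 1),
2. factorising that matrix with the singular value decomposition,
3. *grouping* a subset of rank-one terms, and
4. mapping the grouped matrix back to a series by *diagonal averaging*
   (anti-diagonal means), the inverse of embedding for true Hankel matrices.

These primitives carry the whole eye-blink removal pipeline: embedding and
diagonal averaging drive the clustering-based signal decomposition, and the
full SSA chain (:func:`ssa_denoise`) strips background-EEG remnants off the
extracted blink before it is subtracted from the recording.

Numerical notes
---------------
The eigen-decomposition of the lag-covariance matrix ``A A^T`` is obtained
from the SVD of the trajectory matrix itself (squared singular values equal
the covariance eigenvalues), which avoids the conditioning loss of forming
the covariance product explicitly.  Eigenvalues are reported in descending
order with stable tie-breaking, padded with zeros up to M when the matrix
rank is below M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

from .errors import DegenerateSignalError, InvalidWindowError

__all__ = [
    "Signal1D",
    "TrajectoryMatrix",
    "SSADecomposition",
    "embed",
    "diagonal_average",
    "ssa_decompose",
    "eigen_ratio_group",
    "ssa_denoise",
]


@dataclass(frozen=True)
class Signal1D:
    """A finite, uniformly sampled real-valued signal.

    Amplitudes are in microvolts by convention; ``fs`` is the sampling rate
    in Hz.  The sample array is stored as a read-only float64 copy so that a
    ``Signal1D`` can be shared freely between pipeline stages.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.array(self.samples, dtype=np.float64, copy=True).ravel()
        if samples.size < 2:
            raise ValueError(f"a signal needs at least 2 samples, got {samples.size}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        fs = float(self.fs)
        if not (fs > 0 and np.isfinite(fs)):
            raise ValueError(f"sampling rate must be positive and finite, got {fs}")
        samples.flags.writeable = False
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", fs)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def __len__(self) -> int:
        return self.n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "Signal1D":
        """A new signal on the same time grid with different samples."""
        return Signal1D(samples, self.fs)


@dataclass(frozen=True)
class TrajectoryMatrix:
    """An M x K matrix of lagged signal windows (columns).

    Produced by :func:`embed` (in which case it is Hankel: anti-diagonals
    constant) or by zeroing columns of an embedded matrix during the
    cluster-partition step (in which case the Hankel property is lost but
    the anti-diagonal bookkeeping, ``source_length = M + K - 1``, still
    applies).
    """

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=np.float64, copy=True)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("trajectory matrix must be a non-empty 2-D array")
        m, k = values.shape
        if self.source_length != m + k - 1:
            raise ValueError(
                f"source_length {self.source_length} inconsistent with shape {m}x{k}"
            )
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def window_length(self) -> int:
        """M, the number of rows (samples per window)."""
        return int(self.values.shape[0])

    @property
    def n_windows(self) -> int:
        """K = N - M + 1, the number of lagged windows (columns)."""
        return int(self.values.shape[1])


@dataclass(frozen=True)
class SSADecomposition:
    """SVD decomposition of a trajectory matrix.

    ``eigenvalues`` are the lag-covariance eigenvalues (squared singular
    values), descending, zero-padded to length ``window``; ``left_vectors``
    holds the orthonormal M-dimensional eigenvectors u_i as columns;
    ``right_vectors`` holds the K-dimensional v_i^T as rows.  Only the
    ``rank = min(M, K)`` computed triples are stored — padded eigenvalues
    correspond to exactly-zero components.
    """

    eigenvalues: np.ndarray
    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray
    window: int

    @property
    def rank(self) -> int:
        """Number of stored singular triples, min(M, K)."""
        return int(self.singular_values.size)

    @property
    def ratios(self) -> np.ndarray:
        """Eigenvalue ratios r(i) = lambda_i / sum(lambda); a probability vector."""
        total = self.eigenvalues.sum()
        return self.eigenvalues / total

    def component_matrix(self, i: int) -> np.ndarray:
        """The rank-one trajectory matrix of component ``i``: sigma_i u_i v_i^T."""
        if not 0 <= i < self.rank:
            raise IndexError(f"component index {i} outside [0, {self.rank})")
        return self.singular_values[i] * np.outer(
            self.left_vectors[:, i], self.right_vectors[i]
        )

    def reconstruct(self, indices: np.ndarray) -> np.ndarray:
        """Sum of the rank-one trajectory matrices for ``indices``."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            return np.zeros((self.left_vectors.shape[0], self.right_vectors.shape[1]))
        scaled = self.left_vectors[:, idx] * self.singular_values[idx]
        return scaled @ self.right_vectors[idx]


def embed(x: Signal1D, window: int) -> TrajectoryMatrix:
    """Map a signal into its M x K Hankel trajectory matrix.

    Element (i, j) (0-based) is ``x[i + j]``; column j is the window of M
    consecutive samples starting at j, and K = N - M + 1.

    Raises
    ------
    InvalidWindowError
        If ``window`` is outside [2, N].
    """
    n = x.n_samples
    if not 2 <= window <= n:
        raise InvalidWindowError(
            f"window length {window} outside valid range [2, {n}]"
        )
    values = hankel(x.samples[:window], x.samples[window - 1 :])
    return TrajectoryMatrix(values=values, source_length=n)


def diagonal_average(matrix: TrajectoryMatrix | np.ndarray) -> np.ndarray:
    """Collapse an M x K matrix to a length M + K - 1 series by anti-diagonal means.

    Sample n of the output is the mean of all elements a(i, j) with
    i + j = n (0-based), i.e. the three-branch anti-diagonal mean with
    denominators n+1, M and N-n respectively in the ramp-up, full-overlap
    and ramp-down regions.  This inverts :func:`embed` exactly on Hankel
    matrices and is linear in its argument.
    """
    values = matrix.values if isinstance(matrix, TrajectoryMatrix) else np.asarray(matrix, dtype=np.float64)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("diagonal_average needs a non-empty 2-D matrix")
    m, k = values.shape
    n = m + k - 1
    # anti-diagonal index of every element, in row-major order: bincount then
    # accumulates each anti-diagonal in ascending-row order, matching a plain
    # per-diagonal summation loop bit for bit.
    idx = (np.arange(m)[:, None] + np.arange(k)[None, :]).ravel()
    sums = np.bincount(idx, weights=values.ravel(), minlength=n)
    counts = np.bincount(idx, minlength=n)
    return sums / counts


def ssa_decompose(signal: Signal1D, window: int) -> SSADecomposition:
    """SVD-based SSA decomposition of ``signal`` embedded with ``window``.

    Raises
    ------
    DegenerateSignalError
        If the signal is identically zero (no decomposition to speak of).
    InvalidWindowError
        If ``window`` is outside [2, N].
    """
    if not np.any(signal.samples):
        raise DegenerateSignalError("cannot decompose an all-zero signal")
    trajectory = embed(signal, window)
    u, s, vt = np.linalg.svd(trajectory.values, full_matrices=False)
    eigenvalues = np.zeros(window)
    eigenvalues[: s.size] = s**2
    return SSADecomposition(
        eigenvalues=eigenvalues,
        left_vectors=u,
        singular_values=s,
        right_vectors=vt,
        window=window,
    )


def eigen_ratio_group(dec: SSADecomposition, ssa_threshold: float) -> np.ndarray:
    """Indices of components whose eigenvalue ratio exceeds ``ssa_threshold``.

    Returns the retained index set in descending-eigenvalue order.  When no
    ratio exceeds the threshold (flat spectrum), the single largest component
    is retained so the smoothed estimate is never annihilated.
    """
    if not 0 <= ssa_threshold < 1:
        raise ValueError(f"ssa_threshold must lie in [0, 1), got {ssa_threshold}")
    ratios = dec.ratios[: dec.rank]
    retained = np.flatnonzero(ratios > ssa_threshold)
    if retained.size == 0:
        retained = np.array([0])
    return retained


def ssa_denoise(signal: Signal1D, window: int, ssa_threshold: float) -> Signal1D:
    """SSA smoothing: keep the dominant subspace, drop low-energy components.

    Embeds ``signal``, retains every component whose eigenvalue ratio exceeds
    ``ssa_threshold``, and diagonal-averages the retained sum back to a
    signal of the same length and sampling rate.  With ``ssa_threshold=0``
    this is the identity (all components kept, Hankel round-trip).
    """
    dec = ssa_decompose(signal, window)
    retained = eigen_ratio_group(dec, ssa_threshold)
    smoothed = diagonal_average(dec.reconstruct(retained))
    return signal.with_samples(smoothed)
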