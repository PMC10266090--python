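"""Voxelwise-correlation eigenvalue extraction and spectrum containers.

A BOLD scan, after masking to non-constant voxels, is an ``N x t`` matrix of
``N`` voxel timeseries over ``t`` volumes with ``t << N``.  The object of
interest is the spectrum of the ``N x N`` Pearson correlation matrix of the
rows.  Forming that matrix explicitly is infeasible for whole-brain data
(``N`` is routinely 10^5), but since the nonzero eigenvalues of ``Z Z^T``
equal those of ``Z^T Z``, the spectrum can be obtained from the small
``t x t`` Gram matrix of the row-standardized data at O(N t^2) cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numpy.typing import ArrayLike, NDArray


class SpectrumOrigin(str, Enum):
    """Provenance tag for an eigenvalue spectrum."""

    CORRELATION = "correlation"
    GOE = "goe"
    POISSON = "poisson"
    MANUAL = "manual"


@dataclass(frozen=True)
class TimeseriesMatrix:
    """N voxel timeseries of length t (rows = voxels, columns = volumes).

    Parameters
    ----------
    values
        Real ``(N, t)`` array of BOLD values.  Every row must be
        non-constant; zero-variance voxels are removed upstream by masking.
    meta
        Free-form provenance (preprocessing level, source image id, ...).
    """

    values: NDArray[np.float64]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected 2D matrix, got shape {arr.shape}")
        n, t = arr.shape
        if n < 2 or t < 3:
            raise ValueError(f"need N >= 2 and t >= 3, got N={n}, t={t}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("timeseries contains non-finite values")
        if np.any(arr.std(axis=1) == 0.0):
            raise ValueError("degenerate voxel: constant row in timeseries matrix")
        object.__setattr__(self, "values", arr)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EigSpectrum:
    """Sorted (ascending) eigenvalues with a provenance tag."""

    values: NDArray[np.float64]
    origin: SpectrumOrigin = SpectrumOrigin.MANUAL

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64).ravel()
        if arr.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(arr) < 0):
            arr = np.sort(arr)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "origin", SpectrumOrigin(self.origin))

    def __len__(self) -> int:
        return int(self.values.size)


def correlation_eigenvalues(ts: TimeseriesMatrix | ArrayLike) -> EigSpectrum:
    """Eigenvalues of the N x N Pearson correlation matrix of the rows of ``ts``.

    Uses the transposition identity: with ``Z`` the row-standardized data
    (each row centered and divided by its sample standard deviation), the
    correlation matrix is ``C = Z Z^T / (t - 1)`` and its nonzero eigenvalues
    equal those of the ``t x t`` matrix ``Z^T Z / (t - 1)``.  Cost and memory
    scale with ``t^2``, never ``N^2``.

    Returns the ``t`` eigenvalues of the dual problem sorted ascending; the
    remaining ``N - t`` eigenvalues of ``C`` are exactly zero and are not
    materialized.  For generic data exactly ``t - 1`` of the returned values
    exceed the numerical-precision threshold (row standardization removes one
    degree of freedom).  When ``t >= N`` the direct ``N x N`` eigenproblem is
    solved instead (same nonzero spectrum), with a warning.
    """
    if not isinstance(ts, TimeseriesMatrix):
        ts = TimeseriesMatrix(np.asarray(ts, dtype=np.float64))
    m = ts.values
    n, t = m.shape
    z = m - m.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    z /= sd
    if t >= n:
        warnings.warn(
            f"t={t} >= N={n}: falling back to direct N x N eigendecomposition",
            stacklevel=2,
        )
        corr = (z @ z.T) / (t - 1)
        vals = np.linalg.eigvalsh(corr)
    else:
        gram = (z.T @ z) / (t - 1)
        vals = np.linalg.eigvalsh(gram)
    return EigSpectrum(np.sort(vals), origin=SpectrumOrigin.CORRELATION)


def simulate_goe(n: int, seed: int) -> EigSpectrum:
    """Spectrum of one Gaussian-orthogonal-ensemble matrix of size ``n``.

    The matrix is ``(G + G^T)/2`` with ``G`` iid standard normal, giving
    off-diagonal variance 1/2 and diagonal variance 1 after symmetrization.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, n))
    h = (g + g.T) / 2.0
    return EigSpectrum(np.linalg.eigvalsh(h), origin=SpectrumOrigin.GOE)


def simulate_poisson_levels(n: int, seed: int) -> "UnfoldedSpectrum":
    """Levels with iid Exponential(1) spacings (the Poisson reference ensemble).

    Cumulative sums of ``n`` unit-mean exponential gaps; by construction the
    mean spacing is ~1, so the result is returned as an already-unfolded
    spectrum.
    """
    from .unfolding import TrimSpec, UnfoldedSpectrum

    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    levels = np.cumsum(rng.exponential(scale=1.0, size=n))
    return UnfoldedSpectrum(values=levels, degree=0, trim=TrimSpec.NONE)
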