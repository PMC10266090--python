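"""Spectral rigidity and level number variance of unfolded spectra.

Both observables average a window statistic over starting points c of
windows [c, c+L] laid over the unfolded levels:

* spectral rigidity Delta3(L): the mean squared residual of the best-fit
  straight line to the level staircase eta(lambda) within the window,
  ``min_{A,B} (1/L) \\int_c^{c+L} (eta - A lambda - B)^2 d lambda``;
* level number variance Sigma2(L): the variance over c of the number of
  levels in [c, c+L).

Reference limits: an uncorrelated (Poisson) spectrum has Delta3(L) = L/15
and Sigma2(L) = L; GOE spectra grow only logarithmically in both (level
repulsion makes the spectrum rigid); a picket fence is maximally rigid.

Window starts are drawn uniformly at random and sampled in blocks until
the estimator's own standard error (of the running mean for rigidity, of
the running sample variance for the level variance) falls below the
requested relative tolerance.  The rigidity integral itself is evaluated
in closed form piecewise over the step intervals of eta, so the only
stochastic element is the choice of window starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .unfolding import UnfoldedSpectrum

#: window lengths used for the analytic grid
L_GRID: NDArray[np.float64] = np.arange(1, 21, dtype=np.float64)

DEFAULT_TOL = 0.01
DEFAULT_MAX_CENTERS = 100_000
BLOCK = 128
MIN_BLOCKS = 4
DEFAULT_SEED = 0


@dataclass(frozen=True)
class ObservableCurve:
    """(L, value) pairs for one spectral observable.

    ``n_centers`` records how many Monte-Carlo window starts each L used and
    ``converged`` whether the running estimate stabilized below ``tol``
    before ``max_centers`` was reached.  ``achieved_tol`` is the final
    relative standard-error bound of the estimate.
    """

    kind: str
    L_grid: NDArray[np.float64]
    values: NDArray[np.float64]
    n_centers: NDArray[np.int64]
    converged: NDArray[np.bool_]
    achieved_tol: NDArray[np.float64]
    tol: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("rigidity", "level_variance"):
            raise ValueError(f"unknown observable kind {self.kind!r}")
        for name in ("L_grid", "values", "n_centers", "converged", "achieved_tol"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.values.size != self.L_grid.size:
            raise ValueError("values and L_grid length mismatch")


def _check_preconditions(e: np.ndarray, L_grid: np.ndarray) -> None:
    if np.any(L_grid <= 0):
        raise ValueError("window lengths must be positive")
    span = e[-1] - e[0]
    if np.any(L_grid >= span):
        raise ValueError(
            f"window exceeds spectrum: max L={L_grid.max():g} but span is {span:g}"
        )
    if e.size < int(np.max(L_grid)) + 10:
        raise ValueError(
            f"need at least max(L)+10={int(np.max(L_grid)) + 10} levels, got {e.size}"
        )


def _rigidity_block(e: np.ndarray, prefix: tuple, c: np.ndarray, L: float) -> np.ndarray:
    """Exact Delta3 window values for a batch of starts c.

    Coordinates are shifted per window (lambda' = lambda - c) so that every
    moment is O(L) and the closed-form piecewise integrals suffer no
    cancellation from large level indices.
    """
    p1, p2, pa = prefix
    b = c + L
    j0 = np.searchsorted(e, c, side="right")
    j1 = np.searchsorted(e, b, side="right")
    k = (j1 - j0).astype(np.float64)
    s1 = p1[j1] - p1[j0]  # sum of levels inside the window
    s2 = p2[j1] - p2[j0]
    sa = pa[j1] - pa[j0]
    sx = s1 - c * k  # sum of shifted levels x_j = e_j - c
    sx2 = s2 - 2.0 * c * s1 + c * c * k
    # sum over the window of (2 i + 1) x_j with i the local (0-based) index
    sweights = sa - c * (j1.astype(np.float64) ** 2 - j0.astype(np.float64) ** 2)
    sweights -= 2.0 * j0 * (s1 - c * k)
    # integrals of the shifted staircase eta'(x) over [0, L]
    i0 = L * k - sx
    i1 = 0.5 * (L * L * k - sx2)
    i2 = L * k * k - sweights
    # continuous least-squares line fit: moments of [0, L]
    m0, m1, m2 = L, L * L / 2.0, L**3 / 3.0
    det = L**4 / 12.0
    a = (m0 * i1 - m1 * i0) / det
    bcoef = (m2 * i0 - m1 * i1) / det
    resid = (
        i2
        - 2.0 * a * i1
        - 2.0 * bcoef * i0
        + a * a * m2
        + 2.0 * a * bcoef * m1
        + bcoef * bcoef * m0
    )
    return resid / L


def _count_block(e: np.ndarray, c: np.ndarray, L: float) -> np.ndarray:
    """Level counts in the half-open windows [c, c+L)."""
    j0 = np.searchsorted(e, c, side="left")
    j1 = np.searchsorted(e, c + L, side="left")
    return (j1 - j0).astype(np.float64)


#: z-score of the standard-error stopping rule (~95% confidence that the
#: Monte-Carlo error is below ``z * sem <= tol * estimate``)
_STOP_Z = 2.0


def _monte_carlo(
    sample_fn,
    statistic: str,
    rng: np.random.Generator,
    lo: float,
    hi: float,
    tol: float,
    max_centers: int,
    block: int,
) -> tuple[float, int, bool, float]:
    """Block-wise uniform-c sampling with a standard-error stopping rule.

    ``statistic`` is "mean" (rigidity window values) or "variance" (level
    counts).  Running power sums up to the fourth moment give the standard
    error of the estimator itself — sigma/sqrt(k) for the mean, the
    asymptotic sqrt((mu4 - sigma^4)/k) for the sample variance — and
    sampling stops once ``_STOP_Z`` standard errors drop below ``tol``
    relative to the estimate.
    """
    s1 = s2 = s3 = s4 = 0.0
    count = 0
    est, rel_err = np.nan, np.inf
    while count < max_centers:
        c = rng.uniform(lo, hi, size=min(block, max_centers - count))
        x = sample_fn(c)
        s1 += float(x.sum())
        x2 = x * x
        s2 += float(x2.sum())
        s3 += float((x2 * x).sum())
        s4 += float((x2 * x2).sum())
        count += x.size
        m = s1 / count
        var = max(s2 / count - m * m, 0.0)
        if statistic == "mean":
            est = m
            sem = np.sqrt(var / count)
        else:
            est = var
            mu4 = s4 / count - 4 * m * s3 / count + 6 * m * m * s2 / count - 3 * m**4
            sem = np.sqrt(max(mu4 - var * var, 0.0) / count)
        rel_err = _STOP_Z * sem / max(abs(est), 1e-12)
        if count >= MIN_BLOCKS * block and (rel_err <= tol or sem <= 1e-12):
            return est, count, True, rel_err
    return est, count, False, rel_err


def _run_observable(
    unf: UnfoldedSpectrum,
    L_grid,
    kind: str,
    tol: float,
    max_centers: int,
    block: int,
    seed: int | None,
) -> ObservableCurve:
    e = np.sort(np.asarray(unf.values, dtype=np.float64))
    L_arr = np.atleast_1d(np.asarray(L_grid, dtype=np.float64))
    _check_preconditions(e, L_arr)
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    if kind == "rigidity":
        n = e.size
        idx = np.arange(n, dtype=np.float64)
        prefix = (
            np.concatenate(([0.0], np.cumsum(e))),
            np.concatenate(([0.0], np.cumsum(e * e))),
            np.concatenate(([0.0], np.cumsum((2.0 * idx + 1.0) * e))),
        )
    values, centers, flags, achieved = [], [], [], []
    for L in L_arr:
        lo, hi = e[0], e[-1] - L
        if kind == "rigidity":
            fn = lambda c, L=L: _rigidity_block(e, prefix, c, L)
            stat = "mean"
        else:
            fn = lambda c, L=L: _count_block(e, c, L)
            stat = "variance"
        est, cnt, ok, change = _monte_carlo(fn, stat, rng, lo, hi, tol, max_centers, block)
        values.append(max(est, 0.0))
        centers.append(cnt)
        flags.append(ok)
        achieved.append(change)
    return ObservableCurve(
        kind=kind,
        L_grid=L_arr,
        values=np.array(values),
        n_centers=np.array(centers, dtype=np.int64),
        converged=np.array(flags, dtype=bool),
        achieved_tol=np.array(achieved),
        tol=tol,
        meta={"n_levels": e.size, "degree": unf.degree, "trim": unf.trim.value},
    )


def spectral_rigidity(
    unf: UnfoldedSpectrum,
    L_grid=L_GRID,
    *,
    tol: float = DEFAULT_TOL,
    max_centers: int = DEFAULT_MAX_CENTERS,
    block: int = BLOCK,
    seed: int | None = None,
) -> ObservableCurve:
    """Spectral rigidity Delta3(L) of an unfolded spectrum.

    For each window [c, c+L] the staircase eta (number of levels <= lambda)
    is fit with a least-squares line A lambda + B in the continuous sense,
    and the normalized squared residual (1/L) int (eta - A lambda - B)^2 is
    evaluated exactly via piecewise integration over the step intervals.
    Window starts c are drawn uniformly from [e_1, e_n - L] until the
    running mean stabilizes (see module docstring).
    """
    return _run_observable(unf, L_grid, "rigidity", tol, max_centers, block, seed)


def level_variance(
    unf: UnfoldedSpectrum,
    L_grid=L_GRID,
    *,
    tol: float = DEFAULT_TOL,
    max_centers: int = DEFAULT_MAX_CENTERS,
    block: int = BLOCK,
    seed: int | None = None,
) -> ObservableCurve:
    """Level number variance Sigma2(L) of an unfolded spectrum.

    Counts levels in half-open windows [c, c+L) for uniformly random c and
    returns the variance of the count, per L.  The half-open convention
    makes the picket-fence case exactly zero for integer L.
    """
    return _run_observable(unf, L_grid, "level_variance", tol, max_centers, block, seed)
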