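"""Eigenvalue trimming ahead of unfolding.

Four variants: identity, removal of numerically-zero eigenvalues
("precision"), removal of the cluster of anomalously large eigenvalues
found by 2-means on the log-spectrum ("largest"), and the symmetric variant
that also drops as many from the lower end ("middle").  Correlation spectra
of t << N data have t-1 meaningfully nonzero eigenvalues growing roughly
exponentially, so log-domain clustering separates the bulk from the few
dominant modes.
"""

from __future__ import annotations

import warnings
import zlib
from enum import Enum

import numpy as np
from sklearn.cluster import KMeans

from .spectra import EigSpectrum


class TrimSpec(str, Enum):
    """Which trimming procedure to apply before unfolding."""

    NONE = "none"
    PRECISION = "precision"
    LARGEST = "largest"
    MIDDLE = "middle"


def precision_threshold(values: np.ndarray) -> float:
    """Numerical-noise cutoff for a spectrum.

    The larger of two standard bounds: the matrix-rank convention
    ``n * eps * max|lambda|`` and the symmetric-eigenproblem error bound
    ``eps * ||lambda||_2``.
    """
    eps = np.finfo(np.float64).eps
    thr_rank = values.size * eps * np.max(np.abs(values))
    thr_sym = eps * float(np.linalg.norm(values))
    return max(thr_rank, thr_sym)


def _kmeans_seed(values: np.ndarray) -> int:
    # stable seed derived from the input bytes so trims are reproducible
    return zlib.crc32(np.ascontiguousarray(values).tobytes()) % (2**31)


def _largest_count(trimmed: np.ndarray) -> int:
    """Number of top eigenvalues the 2-means log-domain rule removes.

    Returns 0 when the rule degenerates (identical logs, empty removal set,
    or a removal of more than half the spectrum).
    """
    logs = np.log(trimmed).reshape(-1, 1)
    if np.ptp(logs) == 0.0:
        warnings.warn("2-means degenerate (all log-eigenvalues equal): no trim", stacklevel=3)
        return 0
    km = KMeans(n_clusters=2, n_init=10, random_state=_kmeans_seed(trimmed))
    labels = km.fit_predict(logs)
    means = [logs[labels == k].mean() for k in (0, 1)]
    top = int(np.argmax(means))
    n_top = int(np.sum(labels == top))
    if n_top == 0 or n_top > trimmed.size // 2:
        warnings.warn(
            f"largest-trim would remove {n_top}/{trimmed.size} eigenvalues: no trim",
            stacklevel=3,
        )
        return 0
    # log-eigenvalues are sorted, so the larger-mean cluster is a suffix
    return n_top


def trim(spec: EigSpectrum, how: TrimSpec | str) -> EigSpectrum:
    """Apply a trimming procedure to a sorted spectrum.

    ``none`` is the identity.  ``precision`` removes eigenvalues at or below
    the numerical-noise threshold of :func:`precision_threshold`.  ``largest``
    additionally removes the cluster with the larger mean found by 2-means on
    the natural logs of the precision-trimmed eigenvalues (the few dominant
    modes).  ``middle`` reflects that threshold, dropping equally many from
    the small end.
    """
    how = TrimSpec(how)
    values = spec.values
    if how is TrimSpec.NONE:
        return spec

    thr = precision_threshold(values)
    kept = values[values > thr]
    if kept.size == 0:
        raise ValueError("empty spectrum after trim")
    if how is TrimSpec.PRECISION:
        return EigSpectrum(kept, origin=spec.origin)

    if kept.size < 10:
        raise ValueError(
            f"need >= 10 eigenvalues above precision threshold for '{how.value}' trim, "
            f"got {kept.size}"
        )
    n_top = _largest_count(kept)
    if n_top == 0:
        return EigSpectrum(kept, origin=spec.origin)
    if how is TrimSpec.LARGEST:
        out = kept[:-n_top]
    else:  # MIDDLE: also drop the n_top smallest survivors
        out = kept[n_top:-n_top]
    if out.size == 0:
        raise ValueError("empty spectrum after trim")
    return EigSpectrum(out, origin=spec.origin)
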