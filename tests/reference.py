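"""Independent reference implementations shared by the test modules.

These are deliberately simple loop-based oracles, kept separate from the
library's vectorized code paths.
"""

import math

import numpy as np

#: raw component lengths on a fixed 100-eigenvalue spectrum with no trimming
BASE_LENGTHS_100 = {
    "eigs": 100,
    "eigs_smooth": 100,
    "savgol": 100,
    "eigs_savgol": 100,
    "unfolded": 100,
    "rigidity": 20,
    "levelvar": 20,
    "eigsminmax5": 2 * math.ceil(0.05 * 100),
    "eigsminmax10": 2 * math.ceil(0.10 * 100),
    "eigsminmax20": 2 * math.ceil(0.20 * 100),
    "eigsmiddle10": math.ceil(0.10 * 100),
    "eigsmiddle20": math.ceil(0.20 * 100),
    "eigsmiddle40": math.ceil(0.40 * 100),
}


def oracle_rigidity(e: np.ndarray, L: float, dc: float = 0.05) -> float:
    """Exhaustive dense-c evaluation of Delta3(L) on the explicit staircase.

    For each window start c, builds the step function segment by segment,
    assembles the continuous least-squares normal equations by direct
    summation over segments, and integrates the squared residual segment by
    segment.
    """
    e = np.sort(e)
    out = []
    for c in np.arange(e[0], e[-1] - L, dc):
        b = c + L
        inside = e[(e > c) & (e <= b)]
        xs = np.concatenate([[c], inside, [b]])
        etas = np.searchsorted(e, xs[:-1], side="right").astype(float)
        d = np.diff(xs)
        i0 = np.sum(etas * d)
        i1 = np.sum(etas * (xs[1:] ** 2 - xs[:-1] ** 2)) / 2.0
        i2 = np.sum(etas**2 * d)
        m0, m1, m2 = b - c, (b**2 - c**2) / 2.0, (b**3 - c**3) / 3.0
        det = m2 * m0 - m1 * m1
        A = (m0 * i1 - m1 * i0) / det
        B = (m2 * i0 - m1 * i1) / det
        resid = i2 - 2 * A * i1 - 2 * B * i0 + A * A * m2 + 2 * A * B * m1 + B * B * m0
        out.append(resid / L)
    return float(np.mean(out))


def oracle_level_variance(e: np.ndarray, L: float, dc: float = 0.02) -> float:
    """Exhaustive dense-c count variance with half-open windows [c, c+L)."""
    e = np.sort(e)
    counts = [
        int(np.sum((e >= c) & (e < c + L))) for c in np.arange(e[0], e[-1] - L, dc)
    ]
    return float(np.asarray(counts, dtype=float).var())
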