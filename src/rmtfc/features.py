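"""Eigenfeature and baseline-feature construction.

Every feature summarizes the N x t voxel-by-volume matrix of one scan.
Eigenfeatures derive from the spectrum of the voxelwise correlation matrix:
raw sorted eigenvalues, tail/central selections, smoothed variants,
polynomially unfolded levels, and the two RMT observables (spectral
rigidity and level number variance on L = 1..20).  Combined features
concatenate components; contiguous slices (first/last 5/10/20% or middle
10/20/40%) select spectrum regions.  Baseline features reduce the raw data
across voxels to a t-dimensional statistic (mean signal, percentiles,
spread measures) with optional uniform smoothing, and exist to anchor what
the spectral machinery adds over simple summaries.

The multiverse "degree" axis is the unfolding polynomial degree for RMT
components and the smoothing window for the smoothed-eigenvalue features
(both use the values 3, 5, 7, 9).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.signal import savgol_filter

from .observables import L_GRID, level_variance, spectral_rigidity
from .spectra import EigSpectrum, TimeseriesMatrix, correlation_eigenvalues
from .trimming import TrimSpec, precision_threshold
from .trimming import trim as trim_spectrum
from .unfolding import unfold

# --------------------------------------------------------------------------- #
# slicing
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SliceSpec:
    """Contiguous slice of a sorted feature vector.

    ``max``/``min`` keep the last/first ceil(f*n) elements of the
    ascending-sorted feature; ``mid`` keeps a centered run of ceil(f*n)
    elements starting at floor((n-k)/2); ``full`` is the identity.
    """

    region: str = "full"
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.region not in ("full", "max", "min", "mid"):
            raise ValueError(f"unknown slice region {self.region!r}")
        allowed = {
            "full": (1.0,),
            "max": (0.05, 0.10, 0.20),
            "min": (0.05, 0.10, 0.20),
            "mid": (0.10, 0.20, 0.40),
        }
        if self.fraction not in allowed[self.region] and not (0 < self.fraction <= 1):
            raise ValueError(f"invalid fraction {self.fraction} for region {self.region}")

    @property
    def name(self) -> str:
        if self.region == "full":
            return "full"
        return f"{self.region}-{int(round(self.fraction * 100)):02d}"


#: the ten slice choices of the analytic grid
SLICES: tuple[SliceSpec, ...] = (
    SliceSpec("full", 1.0),
    SliceSpec("min", 0.05),
    SliceSpec("min", 0.10),
    SliceSpec("min", 0.20),
    SliceSpec("max", 0.05),
    SliceSpec("max", 0.10),
    SliceSpec("max", 0.20),
    SliceSpec("mid", 0.10),
    SliceSpec("mid", 0.20),
    SliceSpec("mid", 0.40),
)


def slice_values(values: NDArray[np.float64], spec: SliceSpec) -> NDArray[np.float64]:
    """Apply a :class:`SliceSpec` to a vector (ceil rounding, never empty)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty slice: cannot slice an empty vector")
    if spec.region == "full":
        return v.copy()
    n = v.size
    k = math.ceil(spec.fraction * n)
    if spec.region == "min":
        return v[:k].copy()
    if spec.region == "max":
        return v[n - k :].copy()
    start = (n - k) // 2
    return v[start : start + k].copy()


def sliced_length(n: int, spec: SliceSpec) -> int:
    """Length of ``slice_values`` output for an input of length ``n``."""
    return n if spec.region == "full" else math.ceil(spec.fraction * n)


# --------------------------------------------------------------------------- #
# smoothing
# --------------------------------------------------------------------------- #


def smooth(values, kind: str = "uniform", window: int = 3) -> NDArray[np.float64]:
    """Smooth a vector with a uniform or Savitzky-Golay filter.

    Uniform smoothing is a centered moving average whose window shrinks at
    the boundaries (output length equals input length); Savitzky-Golay fits
    a local polynomial of order min(2, window-1).  ``window=1`` is the
    identity.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > v.size:
        raise ValueError(f"window {window} exceeds vector length {v.size}")
    if window == 1:
        return v.copy()
    if kind == "uniform":
        half_lo, half_hi = (window - 1) // 2, window // 2
        csum = np.concatenate(([0.0], np.cumsum(v)))
        idx = np.arange(v.size)
        lo = np.maximum(idx - half_lo, 0)
        hi = np.minimum(idx + half_hi, v.size - 1)
        return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    if kind == "savgol":
        return savgol_filter(v, window_length=window, polyorder=min(2, window - 1), mode="interp")
    raise ValueError(f"unknown smoothing kind {kind!r}")


# --------------------------------------------------------------------------- #
# catalog
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CatalogEntry:
    coarse: str  # eigs | rmt | tseries
    fine: str
    feature_id: str


_EIGS_IDS = [
    ("eigs", "eigs"),
    ("eigs max", "eigsminmax10"),
    ("eigs max", "eigsminmax20"),
    ("eigs max", "eigsminmax5"),
    ("eigs middle", "eigsmiddle10"),
    ("eigs middle", "eigsmiddle20"),
    ("eigs middle", "eigsmiddle40"),
    ("eigs smooth", "eigs + eigs_smooth"),
    ("eigs smooth", "eigs + savgol"),
    ("eigs smooth", "eigs_savgol"),
    ("eigs smooth", "eigs_smooth"),
]
_RMT_IDS = [
    ("rmt + eigs", "eigs + levelvar"),
    ("rmt + eigs", "eigs + rigidity"),
    ("rmt + eigs", "eigs + rigidity + levelvar"),
    ("rmt + eigs", "eigs + unfolded"),
    ("rmt + eigs", "eigs + unfolded + levelvar"),
    ("rmt + eigs", "eigs + unfolded + rigidity"),
    ("rmt only", "levelvar"),
    ("rmt only", "rigidity"),
    ("rmt only", "rigidity + levelvar"),
    ("rmt only", "unfolded"),
    ("rmt only", "unfolded + levelvar"),
    ("rmt only", "unfolded + rigidity"),
    ("rmt only", "unfolded + rigidity + levelvar"),
]
_TSERIES_IDS = [
    ("location", "T-max"),
    ("location", "T-mean"),
    ("location", "T-med"),
    ("location", "T-min"),
    ("location", "T-p05"),
    ("location", "T-p95"),
    ("scale", "T-iqr"),
    ("scale", "T-rng"),
    ("scale", "T-rrng"),
    ("scale", "T-std"),
]

CATALOG: tuple[CatalogEntry, ...] = tuple(
    [CatalogEntry("eigs", fine, fid) for fine, fid in _EIGS_IDS]
    + [CatalogEntry("rmt", fine, fid) for fine, fid in _RMT_IDS]
    + [CatalogEntry("tseries", fine, fid) for fine, fid in _TSERIES_IDS]
)

EIGENFEATURE_IDS: tuple[str, ...] = tuple(
    e.feature_id for e in CATALOG if e.coarse in ("eigs", "rmt")
)
BASELINE_IDS: tuple[str, ...] = tuple(e.feature_id for e in CATALOG if e.coarse == "tseries")


def feature_catalog() -> list[CatalogEntry]:
    """The full feature catalog: 24 eigenfeatures + 10 baseline reductions."""
    return list(CATALOG)


# --------------------------------------------------------------------------- #
# feature vectors
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class FeatureVector:
    feature_id: str
    values: NDArray[np.float64]
    slice: SliceSpec = SliceSpec()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64).ravel()
        if arr.size == 0:
            raise ValueError("empty feature vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in feature {self.feature_id!r}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


def combine(features: Sequence[FeatureVector]) -> FeatureVector:
    """Concatenate component features (slicing already applied per component)."""
    if len(features) == 0:
        raise ValueError("cannot combine an empty feature list")
    if len(features) == 1:
        return features[0]
    return FeatureVector(
        feature_id=" + ".join(f.feature_id for f in features),
        values=np.concatenate([f.values for f in features]),
        slice=features[0].slice,
        provenance={"components": [f.feature_id for f in features]},
    )


def _observable_seed(values: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(values).tobytes()) % (2**31)


def _component_values(
    spectrum: EigSpectrum,
    name: str,
    trim: TrimSpec,
    degree: int,
    cache: dict | None,
    observable_kwargs: dict,
) -> NDArray[np.float64]:
    """Raw (unsliced) values of one feature component."""
    key = (name, TrimSpec(trim).value, degree)
    if cache is not None and key in cache:
        return cache[key]

    if name in ("eigs", "eigs_smooth", "eigs_savgol", "savgol") or name.startswith(
        ("eigsminmax", "eigsmiddle")
    ):
        trimmed = trim_spectrum(spectrum, trim).values
        if name == "eigs":
            out = trimmed.copy()
        elif name == "eigs_smooth":
            out = smooth(trimmed, "uniform", degree)
        elif name in ("eigs_savgol", "savgol"):
            out = smooth(trimmed, "savgol", degree)
        elif name.startswith("eigsminmax"):
            f = int(name[len("eigsminmax") :]) / 100.0
            out = np.concatenate(
                [
                    slice_values(trimmed, SliceSpec("min", f)),
                    slice_values(trimmed, SliceSpec("max", f)),
                ]
            )
        else:  # eigsmiddle
            f = int(name[len("eigsmiddle") :]) / 100.0
            out = slice_values(trimmed, SliceSpec("mid", f))
    elif name in ("unfolded", "rigidity", "levelvar"):
        ukey = ("_unfolded", TrimSpec(trim).value, degree)
        if cache is not None and ukey in cache:
            unf = cache[ukey]
        else:
            unf = unfold(spectrum, degree, trim)
            if cache is not None:
                cache[ukey] = unf
        if name == "unfolded":
            out = unf.values.copy()
        else:
            kwargs = dict(observable_kwargs)
            kwargs.setdefault("seed", _observable_seed(unf.values))
            fn = spectral_rigidity if name == "rigidity" else level_variance
            out = fn(unf, L_GRID, **kwargs).values
    else:
        raise ValueError(f"unknown feature component {name!r}")

    if cache is not None:
        cache[key] = out
    return out


def compute_feature(
    ts: TimeseriesMatrix | EigSpectrum,
    feature_id: str,
    *,
    trim: TrimSpec | str = TrimSpec.NONE,
    degree: int = 9,
    slice: SliceSpec = SliceSpec(),  # noqa: A002 - domain vocabulary
    window: int = 1,
    cache: dict | None = None,
    observable_kwargs: dict | None = None,
) -> FeatureVector:
    """Compute one catalog feature for a scan.

    Eigenfeatures accept either the scan matrix or a precomputed spectrum;
    baseline (``T-*``) features require the scan matrix and use ``window``
    (``trim``/``degree``/``slice`` do not apply to them).  For combined
    eigenfeatures the slice is applied to each component before
    concatenation.  Parameters irrelevant to a feature are accepted and
    recorded in the provenance.
    """
    if feature_id in BASELINE_IDS:
        if not isinstance(ts, TimeseriesMatrix):
            raise TypeError(f"baseline feature {feature_id!r} requires a TimeseriesMatrix")
        return timeseries_reduction(ts, BaselineSpec(stat=_BASELINE_STATS[feature_id], window=window))
    if feature_id not in EIGENFEATURE_IDS:
        raise ValueError(f"unknown feature id {feature_id!r}")

    spectrum = ts if isinstance(ts, EigSpectrum) else correlation_eigenvalues(ts)
    obs_kwargs = observable_kwargs or {}
    parts = [p.strip() for p in feature_id.split("+")]
    sliced = [
        slice_values(
            _component_values(spectrum, part, TrimSpec(trim), degree, cache, obs_kwargs), slice
        )
        for part in parts
    ]
    return FeatureVector(
        feature_id=feature_id,
        values=np.concatenate(sliced),
        slice=slice,
        provenance={"trim": TrimSpec(trim).value, "degree": degree, "slice": slice.name},
    )


# --------------------------------------------------------------------------- #
# baseline timeseries reductions
# --------------------------------------------------------------------------- #

_BASELINE_STATS = {
    "T-mean": "mean",
    "T-med": "median",
    "T-max": "max",
    "T-min": "min",
    "T-p95": "p95",
    "T-p05": "p05",
    "T-std": "std",
    "T-rng": "range",
    "T-rrng": "robust_range",
    "T-iqr": "iqr",
}

#: smoothing windows tested for baseline features (1 = no smoothing)
BASELINE_WINDOWS: tuple[int, ...] = (1, 2, 4, 8, 16)


@dataclass(frozen=True)
class BaselineSpec:
    """One baseline reduction: a voxelwise statistic plus a smoothing window."""

    stat: str
    window: int = 1

    def __post_init__(self) -> None:
        if self.stat not in set(_BASELINE_STATS.values()):
            raise ValueError(f"unknown baseline statistic {self.stat!r}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")


def timeseries_reduction(ts: TimeseriesMatrix, spec: BaselineSpec) -> FeatureVector:
    """Reduce the scan along the voxel axis to a t-dimensional feature.

    Each statistic is computed across all N voxels at every time point
    (T-mean is the usual global mean signal), then uniformly smoothed with
    the requested window.  Percentiles use linear interpolation.
    """
    m = ts.values
    stat = spec.stat
    if stat == "mean":
        red = m.mean(axis=0)
    elif stat == "median":
        red = np.median(m, axis=0)
    elif stat == "max":
        red = m.max(axis=0)
    elif stat == "min":
        red = m.min(axis=0)
    elif stat == "p95":
        red = np.percentile(m, 95, axis=0)
    elif stat == "p05":
        red = np.percentile(m, 5, axis=0)
    elif stat == "std":
        red = m.std(axis=0, ddof=1)
    elif stat == "range":
        red = m.max(axis=0) - m.min(axis=0)
    elif stat == "robust_range":
        red = np.percentile(m, 95, axis=0) - np.percentile(m, 5, axis=0)
    else:  # iqr
        red = np.percentile(m, 75, axis=0) - np.percentile(m, 25, axis=0)
    fid = next(k for k, v in _BASELINE_STATS.items() if v == stat)
    return FeatureVector(
        feature_id=fid,
        values=smooth(red, "uniform", spec.window),
        provenance={"stat": stat, "window": spec.window},
    )


# --------------------------------------------------------------------------- #
# normalization
# --------------------------------------------------------------------------- #


def log_transform(values: NDArray[np.float64]) -> NDArray[np.float64]:
    """Natural log of an eigenfeature, clipping non-positive values.

    Eigenfeatures are positive after precision trimming; any residual value
    <= 0 (possible with ``trim='none'``) is clipped to the spectrum's
    numerical-precision threshold before the log.
    """
    v = np.asarray(values, dtype=np.float64)
    if np.any(v <= 0):
        if not np.any(v > 0):
            raise ValueError("cannot log-transform: no positive values")
        thr = precision_threshold(v[v > 0])
        # static message so repeated occurrences dedup under default filters
        warnings.warn(
            "non-positive eigenfeature values clipped to the precision threshold before log",
            stacklevel=2,
        )
        v = np.clip(v, thr, None)
    return np.log(v)


class FeatureScaler:
    """Log + optional min-max normalization with train-fold-only statistics.

    Eigenfeatures always receive a natural log; min-max maps each feature
    dimension to [0, 1] using minima/maxima estimated on the training fold
    only.  Baseline features skip the log.  Constant dimensions map to 0.
    """

    def __init__(self, method: str = "raw", is_eigenfeature: bool = True) -> None:
        if method not in ("raw", "minmax"):
            raise ValueError(f"unknown normalization method {method!r}")
        self.method = method
        self.is_eigenfeature = is_eigenfeature
        self._min: NDArray[np.float64] | None = None
        self._range: NDArray[np.float64] | None = None

    def _pre(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        X = np.asarray(X, dtype=np.float64)
        return log_transform(X) if self.is_eigenfeature else X.copy()

    def fit(self, X: NDArray[np.float64]) -> "FeatureScaler":
        Xp = self._pre(X)
        if self.method == "minmax":
            self._min = Xp.min(axis=0)
            rng = Xp.max(axis=0) - self._min
            if np.any(rng == 0):
                warnings.warn("constant feature dimension under min-max: mapped to 0", stacklevel=2)
            self._range = np.where(rng == 0, 1.0, rng)
        return self

    def transform(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        Xp = self._pre(X)
        if self.method == "minmax":
            if self._min is None:
                raise RuntimeError("scaler not fitted")
            Xp = (Xp - self._min) / self._range
        return Xp

    def fit_transform(self, X: NDArray[np.float64]) -> NDArray[np.float64]:
        return self.fit(X).transform(X)


def normalize(
    fv: FeatureVector | NDArray[np.float64],
    method: str = "raw",
    is_eigenfeature: bool = True,
) -> FeatureVector | NDArray[np.float64]:
    """Stateless convenience wrapper: log (eigenfeatures) + optional min-max.

    Min-max statistics here are fit on the supplied values themselves; in
    cross-validation use :class:`FeatureScaler` so statistics come from the
    training fold only.
    """
    values = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=np.float64)
    # a lone vector is treated as n samples of one dimension so min-max
    # attains its endpoints; matrices are (samples, dims) as in CV
    X = values[:, None] if values.ndim == 1 else values
    out = FeatureScaler(method, is_eigenfeature).fit_transform(X)
    out = out.reshape(np.shape(values))
    if isinstance(fv, FeatureVector):
        return FeatureVector(fv.feature_id, out, fv.slice, {**fv.provenance, "normalization": method})
    return out
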