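"""NIfTI ingestion, voxel masking, manifests, and synthetic 4D data.

The synthetic generator stands in for real multi-site fMRI collections so
the whole pipeline — masking, spectra, eigenfeatures, multiverse CV — can
be exercised end to end.  Each synthetic scan is a low-rank latent-signal
model: every voxel timeseries is a random loading combination of a few
shared smooth latent signals plus iid noise.  Two groups differ by a
controllable planted effect that scales group B's latent-signal strength;
``effect = 0`` makes the groups exchangeable (the null).  Each scan is
emitted at four "preprocessing levels", realized as labelled variants with
level-dependent drift and temporal smoothing, so the preprocessing axis of
the analytic grid is exercised without running an actual fMRI pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from numpy.typing import NDArray

from .spectra import TimeseriesMatrix

# --------------------------------------------------------------------------- #
# NIfTI ingestion and masking
# --------------------------------------------------------------------------- #


def load_bold_4d(path: str | Path) -> tuple[NDArray[np.float64], dict]:
    """Load a 4D BOLD NIfTI image.

    Returns the (x, y, z, t) array and header metadata (voxel sizes, TR).
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()
    meta = {"voxel_sizes": tuple(float(z) for z in zooms[:3]),
            "tr": float(zooms[3]) if len(zooms) > 3 else None,
            "shape": tuple(int(s) for s in img.shape)}
    return data, meta


def extract_voxel_matrix(
    img: NDArray[np.float64], eps_var: float = 0.0, meta: dict | None = None
) -> TimeseriesMatrix:
    """Flatten a 4D image to the N x t matrix of non-constant voxel timeseries.

    Voxels whose timeseries variance is <= ``eps_var`` (default: exactly
    constant, which covers zero-filled background) are dropped; N therefore
    varies by image.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError(f"expected 4D array, got {arr.ndim}D")
    flat = arr.reshape(-1, arr.shape[-1])
    keep = flat.var(axis=1) > eps_var
    if not np.any(keep):
        raise ValueError("no usable voxels: every voxel timeseries is constant")
    return TimeseriesMatrix(flat[keep], meta=dict(meta or {}))


# --------------------------------------------------------------------------- #
# manifests
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ScanRecord:
    """One row of a dataset manifest."""

    path: str
    subject: str
    label: int
    preprocessing_level: int


def write_manifest(records: list[ScanRecord], path: str | Path) -> None:
    """Write a tab-delimited manifest with header (path, subject, label, level)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["path", "subject", "label", "level"])
        for r in records:
            writer.writerow([r.path, r.subject, r.label, r.preprocessing_level])


def read_manifest(path: str | Path) -> list[ScanRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            ScanRecord(row["path"], row["subject"], int(row["label"]), int(row["level"]))
            for row in reader
        ]


# --------------------------------------------------------------------------- #
# synthetic generator
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic two-group dataset.

    Defaults give N = 8*8*8 = 512 voxels and t = 48 volumes, so t << N and
    scan spectra are long enough (t - 1 = 47 levels) for the RMT
    observables on L <= 20.  Latent loadings have variance 1/n_latent,
    putting per-voxel signal variance on par with the unit noise variance.
    """

    n_per_group: int = 20
    shape: tuple[int, int, int, int] = (8, 8, 8, 48)
    n_latent: int = 5
    effect: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ValueError(f"invalid shape {self.shape}")
        if self.shape[3] < 3:
            raise ValueError("need t >= 3 volumes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


def _smooth_latents(rng: np.random.Generator, n_latent: int, t: int) -> NDArray[np.float64]:
    """Slowly varying unit-variance latent signals (random low-frequency Fourier sums)."""
    tt = np.arange(t)
    signals = np.zeros((n_latent, t))
    n_freq = 4
    freqs = rng.uniform(0.5, 4.0, size=(n_latent, n_freq))
    phases = rng.uniform(0, 2 * np.pi, size=(n_latent, n_freq))
    amps = rng.uniform(0.5, 1.0, size=(n_latent, n_freq))
    for k in range(n_latent):
        for f, p, a in zip(freqs[k], phases[k], amps[k]):
            signals[k] += a * np.sin(2 * np.pi * f * tt / t + p)
    signals -= signals.mean(axis=1, keepdims=True)
    signals /= signals.std(axis=1, keepdims=True)
    return signals


def _spatially_smooth_loadings(
    rng: np.random.Generator, grid: tuple[int, int, int], n_latent: int
) -> NDArray[np.float64]:
    """Spatially correlated loading maps: white maps blurred along each axis."""
    maps = rng.standard_normal((n_latent, *grid))
    # separable 3-tap blur (periodic edges) along each spatial axis
    for axis in (1, 2, 3):
        maps = (
            0.5 * maps
            + 0.25 * np.roll(maps, 1, axis=axis)
            + 0.25 * np.roll(maps, -1, axis=axis)
        )
    flat = maps.reshape(n_latent, -1)
    flat /= flat.std(axis=1, keepdims=True)
    return flat / np.sqrt(n_latent)


def synthesize_scan(
    spec: SyntheticSpec, rng: np.random.Generator, group: int
) -> NDArray[np.float64]:
    """One raw synthetic 4D scan (level-1 data) for the given group (0 or 1)."""
    x, y, z, t = spec.shape
    n_vox = x * y * z
    latents = _smooth_latents(rng, spec.n_latent, t)
    loadings = _spatially_smooth_loadings(rng, (x, y, z), spec.n_latent)
    strength = 1.0 + spec.effect if group == 1 else 1.0
    signal = strength * loadings.T @ latents  # (n_vox, t)
    noise = spec.noise_sd * rng.standard_normal((n_vox, t))
    return (signal + noise).reshape(x, y, z, t)


def preprocessing_variant(
    img: NDArray[np.float64], level: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Labelled preprocessing-level variant of a raw scan.

    Level 1 is the raw scan.  Higher levels emulate progressively cleaner
    data: low-frequency drift shrinking with level, plus mild temporal
    smoothing.  These are perturbation labels, not a real fMRI pipeline.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"preprocessing level must be in 1..4, got {level}")
    if level == 1:
        return img.copy()
    t = img.shape[-1]
    drift_amp = 0.5 * (4 - level) / 3.0
    drift = drift_amp * np.linspace(-1, 1, t) * rng.standard_normal(img.shape[:3])[..., None]
    out = img + drift
    # temporal moving average of width `level` (shrinking at the edges)
    csum = np.concatenate([np.zeros(img.shape[:3] + (1,)), np.cumsum(out, axis=-1)], axis=-1)
    idx = np.arange(t)
    lo = np.maximum(idx - (level - 1) // 2, 0)
    hi = np.minimum(idx + level // 2, t - 1)
    return (csum[..., hi + 1] - csum[..., lo]) / (hi - lo + 1)


def synthesize_group_timeseries(
    spec: SyntheticSpec,
) -> tuple[dict[int, list[TimeseriesMatrix]], NDArray[np.int64]]:
    """In-memory synthetic dataset: scans per preprocessing level, plus labels.

    Scans are ordered group 0 first, then group 1; all four level variants
    of one scan share its latent signals and noise.  Deterministic for a
    given spec (seed included).
    """
    root = np.random.SeedSequence([spec.seed, spec.n_per_group, spec.shape[3]])
    scan_seeds = root.spawn(2 * spec.n_per_group)
    labels = np.repeat([0, 1], spec.n_per_group)
    scans: dict[int, list[TimeseriesMatrix]] = {lvl: [] for lvl in (1, 2, 3, 4)}
    for i, (label, ss) in enumerate(zip(labels, scan_seeds)):
        rng = np.random.default_rng(ss)
        raw = synthesize_scan(spec, rng, group=int(label))
        drift_seed = ss.spawn(1)[0]
        for lvl in (1, 2, 3, 4):
            var = preprocessing_variant(raw, lvl, np.random.default_rng(drift_seed))
            scans[lvl].append(
                extract_voxel_matrix(var, meta={"scan": i, "label": int(label), "level": lvl})
            )
    return scans, labels


def synthesize_group_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> list[ScanRecord]:
    """Write a synthetic two-group dataset as NIfTI files plus a manifest.

    Emits four preprocessing-level variants per scan under ``out_dir`` and a
    tab-delimited ``manifest.tsv``; identical specs reproduce identical
    files.  Returns the scan records.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence([spec.seed, spec.n_per_group, spec.shape[3]])
    scan_seeds = root.spawn(2 * spec.n_per_group)
    labels = np.repeat([0, 1], spec.n_per_group)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    records: list[ScanRecord] = []
    for i, (label, ss) in enumerate(zip(labels, scan_seeds)):
        rng = np.random.default_rng(ss)
        raw = synthesize_scan(spec, rng, group=int(label))
        drift_rng_seed = ss.spawn(1)[0]
        for lvl in (1, 2, 3, 4):
            var = preprocessing_variant(raw, lvl, np.random.default_rng(drift_rng_seed))
            fname = out / f"sub-{i:03d}_grp-{label}_lvl-{lvl}.nii.gz"
            nib.save(nib.Nifti1Image(var.astype(np.float32), affine), str(fname))
            records.append(ScanRecord(str(fname), f"sub-{i:03d}", int(label), lvl))
    write_manifest(records, out / "manifest.tsv")
    return records
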