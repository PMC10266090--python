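"""Multiverse evaluation: analytic grid x classifiers x fivefold CV.

Rather than committing to one analytic pipeline, every defensible
combination of choices is evaluated and the distribution of outcomes is
reported.  The eigenfeature grid crosses 4 preprocessing levels x 2
normalizations x 4 trimmings x 4 unfolding/smoothing degrees x 10 slices
(1280 cells); the baseline grid crosses 4 preprocessing levels x 2
normalizations x 5 smoothing windows (40 cells).  Each cell is scored with
stratified fivefold cross-validation; the headline metric is the mean area
under the ROC curve across folds (mAUROC, 0.5 = guessing), with accuracy,
adjusted accuracy (accuracy minus the majority-class proportion) and F1
collected alongside.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import (
    BASELINE_IDS,
    EIGENFEATURE_IDS,
    SLICES,
    BaselineSpec,
    FeatureScaler,
    SliceSpec,
    compute_feature,
)
from .spectra import EigSpectrum, TimeseriesMatrix
from .trimming import TrimSpec
from .unfolding import DEGREES

PREPROCESSING_LEVELS: tuple[int, ...] = (1, 2, 3, 4)
NORMALIZATIONS: tuple[str, ...] = ("raw", "minmax")
BASELINE_WINDOWS: tuple[int, ...] = (1, 2, 4, 8, 16)
CLASSIFIER_IDS: tuple[str, ...] = ("gbt", "rf", "svc_rbf", "knn3", "knn5", "knn9")

#: the 11 binary classification tasks of the study design (7 datasets; osteo
#: contributes three pairwise contrasts and attention three median splits)
TASKS: tuple[str, ...] = (
    "aging:older_v_younger",
    "bilingual:mono_v_bilingual",
    "depress:depress_v_control",
    "learn:task_v_rest",
    "osteo:nopain_v_duloxetine",
    "osteo:nopain_v_pain",
    "osteo:pain_v_duloxetine",
    "park:park_v_ctrl",
    "attention:vigilant_v_nonvigilant",
    "attention:trait_attend_v_nonattend",
    "attention:task_attend_v_nonattend",
)


# --------------------------------------------------------------------------- #
# grid
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GridPoint:
    """One cell of the analytic grid.

    Eigenfeature cells carry (trim, degree, slice); baseline cells carry a
    smoothing window instead.
    """

    kind: str  # "eigenfeature" | "baseline"
    preprocessing_level: int
    normalization: str
    trim: TrimSpec | None = None
    degree: int | None = None
    slice: SliceSpec | None = None
    window: int | None = None

    def key(self) -> tuple:
        if self.kind == "eigenfeature":
            return (
                self.preprocessing_level,
                self.normalization,
                self.trim.value,
                self.degree,
                self.slice.name,
            )
        return (self.preprocessing_level, self.normalization, self.window)


def enumerate_grid(kind: str) -> list[GridPoint]:
    """Deterministic, duplicate-free enumeration of the analytic grid.

    Canonical order is lexicographic over (preprocessing, normalization,
    trim, degree, slice) for eigenfeatures and (preprocessing,
    normalization, window) for baselines.
    """
    points: list[GridPoint] = []
    if kind == "eigenfeature":
        for level in PREPROCESSING_LEVELS:
            for norm in NORMALIZATIONS:
                for trim in TrimSpec:
                    for degree in DEGREES:
                        for slc in SLICES:
                            points.append(
                                GridPoint("eigenfeature", level, norm, trim, degree, slc)
                            )
    elif kind == "baseline":
        for level in PREPROCESSING_LEVELS:
            for norm in NORMALIZATIONS:
                for window in BASELINE_WINDOWS:
                    points.append(GridPoint("baseline", level, norm, window=window))
    else:
        raise ValueError(f"unknown grid kind {kind!r}")
    return points


def total_evaluation_count(
    n_tasks: int = len(TASKS), n_classifiers: int = len(CLASSIFIER_IDS)
) -> int:
    """Total multiverse size: every (task, classifier, feature, grid cell)."""
    n_eig = len(enumerate_grid("eigenfeature")) * len(EIGENFEATURE_IDS)
    n_base = len(enumerate_grid("baseline")) * len(BASELINE_IDS)
    return (n_eig + n_base) * n_tasks * n_classifiers


# --------------------------------------------------------------------------- #
# metrics and cross-validation
# --------------------------------------------------------------------------- #


def adjusted_accuracy(accuracy: float, labels: NDArray) -> float:
    """Accuracy minus the majority-class proportion of the whole dataset.

    Positive values beat majority-vote guessing.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    _, counts = np.unique(labels, return_counts=True)
    return float(accuracy) - counts.max() / labels.size


def _make_classifier(classifier_id: str, seed: int):
    # library-default hyperparameters throughout; only stochastic models
    # receive the seed
    if classifier_id == "gbt":
        return GradientBoostingClassifier(random_state=seed)
    if classifier_id == "rf":
        return RandomForestClassifier(random_state=seed)
    if classifier_id == "svc_rbf":
        return SVC(kernel="rbf")
    if classifier_id.startswith("knn"):
        return KNeighborsClassifier(n_neighbors=int(classifier_id[3:]))
    raise ValueError(f"unknown classifier id {classifier_id!r}")


def _continuous_scores(model, X: NDArray) -> NDArray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass(frozen=True)
class EvalResult:
    """Fivefold CV outcome for one (task, classifier, feature, grid cell)."""

    task_id: str
    classifier_id: str
    feature_id: str
    grid_point: GridPoint | None
    fold_aurocs: NDArray[np.float64]
    mauroc: float
    accuracy: float
    adjusted_accuracy: float
    f1: float
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def crossval_evaluate(
    features: NDArray[np.float64],
    labels: NDArray,
    classifier_id: str,
    *,
    seed: int = 0,
    normalization: str = "raw",
    is_eigenfeature: bool = True,
    task_id: str = "",
    feature_id: str = "",
    grid_point: GridPoint | None = None,
    groups: NDArray | None = None,
) -> EvalResult:
    """Stratified fivefold cross-validated evaluation of one feature matrix.

    Per fold the classifier is fit on the training split and scored with
    continuous class-1 scores (predict_proba or decision_function) on the
    validation split; normalization statistics (log + optional min-max) are
    fit on the training fold only.  A constant feature matrix is flagged
    degenerate and scored mAUROC = 0.5.  Passing ``groups`` (e.g. subject
    ids for multi-run datasets) keeps all scans of one group in the same
    fold.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need a binary task with >= 2 samples per class")
    if np.all(np.ptp(X, axis=0) == 0.0):
        maj = counts.max() / y.size
        return EvalResult(
            task_id, classifier_id, feature_id, grid_point,
            fold_aurocs=np.full(5, 0.5), mauroc=0.5, accuracy=maj,
            adjusted_accuracy=0.0, f1=float("nan"), degenerate=True,
            meta={"reason": "constant feature matrix"},
        )

    split_seed, n_folds = seed, 5
    for attempt in range(10):
        cls = StratifiedKFold if groups is None else StratifiedGroupKFold
        skf = cls(n_splits=n_folds, shuffle=True, random_state=split_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            folds = list(skf.split(X, y, groups))
        if all(np.unique(y[va]).size == 2 and np.unique(y[tr]).size == 2 for tr, va in folds):
            break
        split_seed += 1  # re-split with the next seed; logged in meta
    else:
        raise ValueError("could not produce folds containing both classes")

    aurocs, accs, adj_accs, f1s = [], [], [], []
    for tr, va in folds:
        scaler = FeatureScaler(normalization, is_eigenfeature)
        Xtr = scaler.fit_transform(X[tr])
        Xva = scaler.transform(X[va])
        model = _make_classifier(classifier_id, seed)
        model.fit(Xtr, y[tr])
        scores = _continuous_scores(model, Xva)
        pred = model.predict(Xva)
        aurocs.append(roc_auc_score(y[va] == classes[1], scores))
        acc = accuracy_score(y[va], pred)
        accs.append(acc)
        adj_accs.append(adjusted_accuracy(acc, y))
        f1s.append(f1_score(y[va], pred, pos_label=classes[1], zero_division=0))
    return EvalResult(
        task_id, classifier_id, feature_id, grid_point,
        fold_aurocs=np.asarray(aurocs),
        mauroc=float(np.mean(aurocs)),
        accuracy=float(np.mean(accs)),
        adjusted_accuracy=float(np.mean(adj_accs)),
        f1=float(np.mean(f1s)),
        meta={"split_seed": split_seed},
    )


# --------------------------------------------------------------------------- #
# grid runner
# --------------------------------------------------------------------------- #


def _cell_seed(root_seed: int, feature_id: str, gp: GridPoint, classifier_id: str) -> int:
    h = zlib.crc32(repr((feature_id, gp.key(), classifier_id)).encode())
    return int(np.random.SeedSequence([root_seed, h]).generate_state(1)[0] % (2**31))


def _stack_center_crop(vectors: list[NDArray[np.float64]]) -> NDArray[np.float64]:
    """Stack per-scan feature vectors, center-cropping to the common length.

    Per-matrix trimming can leave scans with slightly different feature
    lengths in one cell; the centered crop keeps the shared spectral region.
    """
    m = min(v.size for v in vectors)
    rows = [v[(v.size - m) // 2 : (v.size - m) // 2 + m] for v in vectors]
    return np.vstack(rows)


def evaluate_dataset(
    scans_by_level: dict[int, Sequence[TimeseriesMatrix | EigSpectrum]],
    labels: NDArray,
    feature_id: str,
    grid_points: Iterable[GridPoint],
    classifier_ids: Sequence[str] = ("knn5",),
    *,
    seed: int = 0,
    task_id: str = "synthetic",
    observable_kwargs: dict | None = None,
) -> list[EvalResult]:
    """Evaluate one feature over a set of grid cells for one labelled dataset.

    ``scans_by_level`` maps each preprocessing level to the scans (or
    precomputed spectra for eigenfeatures) in dataset order matching
    ``labels``.  Feature components are cached per scan so shared work
    (spectra, unfoldings, observables) is done once per (trim, degree).
    Results are deterministic for a given seed regardless of cell order:
    each cell derives its own seed from the root seed and its provenance.
    """
    labels = np.asarray(labels).ravel()
    is_eig = feature_id in EIGENFEATURE_IDS
    caches: dict[int, list[dict]] = {
        lvl: [dict() for _ in scans] for lvl, scans in scans_by_level.items()
    }
    results: list[EvalResult] = []
    for gp in grid_points:
        scans = scans_by_level[gp.preprocessing_level]
        if len(scans) != labels.size:
            raise ValueError("labels and scans length mismatch")
        vectors = []
        for scan, cache in zip(scans, caches[gp.preprocessing_level]):
            if is_eig:
                fv = compute_feature(
                    scan, feature_id, trim=gp.trim, degree=gp.degree, slice=gp.slice,
                    cache=cache, observable_kwargs=observable_kwargs,
                )
            else:
                fv = compute_feature(scan, feature_id, window=gp.window)
            vectors.append(fv.values)
        X = _stack_center_crop(vectors)
        for clf in classifier_ids:
            results.append(
                crossval_evaluate(
                    X, labels, clf,
                    seed=_cell_seed(seed, feature_id, gp, clf),
                    normalization=gp.normalization,
                    is_eigenfeature=is_eig,
                    task_id=task_id, feature_id=feature_id, grid_point=gp,
                )
            )
    return results


# --------------------------------------------------------------------------- #
# summaries
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SummaryRow:
    """Seven-number summary of an mAUROC distribution."""

    feature_id: str
    mean: float
    min: float
    p05: float
    p50: float
    p95: float
    max: float
    std: float


def summarize_distribution(maurocs: NDArray[np.float64], feature_id: str = "") -> SummaryRow:
    """Mean/min/5%/50%/95%/max/std of a set of mAUROCs (linear-interp percentiles)."""
    v = np.asarray(maurocs, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty mAUROC vector")
    return SummaryRow(
        feature_id=feature_id,
        mean=float(v.mean()),
        min=float(v.min()),
        p05=float(np.percentile(v, 5)),
        p50=float(np.percentile(v, 50)),
        p95=float(np.percentile(v, 95)),
        max=float(v.max()),
        std=float(v.std(ddof=1)) if v.size > 1 else 0.0,
    )


def results_to_frame(results: Sequence[EvalResult]) -> "pd.DataFrame":
    """Tidy results table: one row per evaluation with full provenance."""
    import pandas as pd

    rows = []
    for r in results:
        gp = r.grid_point
        rows.append(
            {
                "task": r.task_id,
                "classifier": r.classifier_id,
                "feature": r.feature_id,
                "preprocessing_level": gp.preprocessing_level if gp else None,
                "normalization": gp.normalization if gp else None,
                "trim": gp.trim.value if gp and gp.trim else None,
                "degree": gp.degree if gp else None,
                "slice": gp.slice.name if gp and gp.slice else None,
                "window": gp.window if gp else None,
                "mauroc": r.mauroc,
                "accuracy": r.accuracy,
                "adjusted_accuracy": r.adjusted_accuracy,
                "f1": r.f1,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def summary_table(results: Sequence[EvalResult]) -> "pd.DataFrame":
    """Seven-column per-feature summary, sorted by 95th percentile (robust
    max) descending with ties broken by the mean."""
    import pandas as pd

    df = results_to_frame(results)
    rows = [
        summarize_distribution(sub["mauroc"].to_numpy(), feature_id=fid).__dict__
        for fid, sub in df.groupby("feature", sort=True)
    ]
    out = pd.DataFrame(rows)
    return out.sort_values(["p95", "mean"], ascending=False, ignore_index=True)


def kde_mode(values: NDArray[np.float64], n_grid: int = 512) -> float:
    """Argmax of a Gaussian KDE with Silverman bandwidth."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if np.ptp(v) == 0.0:
        return float(v[0])
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def predictability(
    maurocs: NDArray[np.float64],
    *,
    center_tol: float = 0.02,
    skew_tol: float = 0.2,
    min_values: int = 30,
) -> tuple[bool, str]:
    """Decide whether an mAUROC distribution shows evidence of solvability.

    NOT predictable when the distribution is (1) roughly symmetric with mean
    and median close to 0.5 (performance looks random), or (2) has both
    median and KDE mode below 0.5 (systematically worse than guessing).
    Returns (predictable, reason).
    """
    v = np.asarray(maurocs, dtype=np.float64).ravel()
    if v.size < min_values:
        return True, "insufficient evidence (too few values)"
    mean, median = v.mean(), np.median(v)
    skew = 0.0 if np.ptp(v) == 0.0 else float(stats.skew(v))
    if abs(mean - 0.5) < center_tol and abs(median - 0.5) < center_tol and abs(skew) < skew_tol:
        return False, "symmetric with mean and median ~0.5"
    if median < 0.5 and kde_mode(v) < 0.5:
        return False, "median and mode below 0.5"
    return True, "distribution shifted above 0.5"
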