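"""Mini multiverse: one feature evaluated across analytic choices.

Generates a two-group synthetic dataset with a planted connectivity
difference, evaluates the raw-eigenvalue feature over a slice x trim x
normalization grid with cross-validated classifiers, and summarizes the
resulting mAUROC distribution.
"""

import numpy as np

from rmtfc import (
    SyntheticSpec,
    correlation_eigenvalues,
    enumerate_grid,
    evaluate_dataset,
    predictability,
    summarize_distribution,
    synthesize_group_timeseries,
)

spec = SyntheticSpec(n_per_group=15, effect=1.0, seed=5)
scans, labels = synthesize_group_timeseries(spec)
spectra = {1: [correlation_eigenvalues(s) for s in scans[1]]}

grid = [
    gp for gp in enumerate_grid("eigenfeature")
    if gp.preprocessing_level == 1 and gp.degree == 9
]
print(f"evaluating 'eigs' over {len(grid)} grid cells x 2 classifiers ...")
results = evaluate_dataset(
    spectra, labels, "eigs", grid, ["knn5", "svc_rbf"], seed=5
)

maurocs = np.array([r.mauroc for r in results])
row = summarize_distribution(maurocs, "eigs")
print(f"\nmAUROC over {maurocs.size} evaluations "
      f"(mean {row.mean:.3f}, 5% {row.p05:.3f}, median {row.p50:.3f}, "
      f"95% {row.p95:.3f}, max {row.max:.3f})")
ok, reason = predictability(maurocs)
print(f"predictable: {ok} ({reason})")
print(
    "With a planted effect of 1.0 the task is solvable from the correlation "
    "spectrum alone across most analytic choices; 0.5 would mean guessing."
)
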