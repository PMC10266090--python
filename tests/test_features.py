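"""Feature catalog, slicing, smoothing, combination, normalization, baselines."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmtfc import (
    BASELINE_IDS,
    EIGENFEATURE_IDS,
    SLICES,
    BaselineSpec,
    FeatureScaler,
    FeatureVector,
    SliceSpec,
    TimeseriesMatrix,
    combine,
    compute_feature,
    feature_catalog,
    normalize,
    slice_values,
    smooth,
    timeseries_reduction,
)
from rmtfc.features import sliced_length


class TestCatalog:
    def test_size_and_grouping_counts(self):
        cat = feature_catalog()
        assert len(cat) == 34
        assert sum(1 for e in cat if e.coarse == "eigs") == 11
        assert sum(1 for e in cat if e.coarse == "rmt") == 13
        assert sum(1 for e in cat if e.fine == "rmt + eigs") == 6
        assert sum(1 for e in cat if e.fine == "rmt only") == 7
        assert sum(1 for e in cat if e.coarse == "tseries") == 10
        assert len(EIGENFEATURE_IDS) == 24

    def test_ids_unique(self):
        ids = [e.feature_id for e in feature_catalog()]
        assert len(set(ids)) == len(ids)

    def test_specific_rows(self):
        by_id = {e.feature_id: e for e in feature_catalog()}
        assert by_id["eigs + unfolded + rigidity"].coarse == "rmt"
        assert by_id["eigs + unfolded + rigidity"].fine == "rmt + eigs"
        assert by_id["rigidity + levelvar"].fine == "rmt only"
        assert by_id["T-rrng"].fine == "scale"


class TestSlicing:
    def test_ten_distinct_slices(self):
        assert len(set(SLICES)) == 10
        assert sum(1 for s in SLICES if s.region == "full") == 1
        assert sum(1 for s in SLICES if s.region == "mid") == 3

    def test_max20_keeps_top_fifth(self):
        v = np.arange(1.0, 101.0)
        out = slice_values(v, SliceSpec("max", 0.20))
        assert np.array_equal(out, np.arange(81.0, 101.0))

    def test_full_is_identity(self):
        v = np.arange(7.0)
        assert np.array_equal(slice_values(v, SliceSpec()), v)

    def test_mid40_of_20_centers_eight(self):
        v = np.arange(1.0, 21.0)
        out = slice_values(v, SliceSpec("mid", 0.40))
        # k = 8 elements at 1-based indices 7..14
        assert np.array_equal(out, np.arange(7.0, 15.0))

    def test_ceil_never_empty(self):
        out = slice_values(np.arange(3.0), SliceSpec("max", 0.05))
        assert out.size == 1

    @settings(max_examples=50, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=200),
        st.sampled_from(list(SLICES)),
    )
    def test_slicing_idempotent_and_bookkept(self, n, spec):
        v = np.arange(float(n))
        out = slice_values(v, spec)
        assert out.size == sliced_length(n, spec)
        # re-slicing with full is the identity
        assert np.array_equal(slice_values(out, SliceSpec()), out)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=1, max_value=200), st.sampled_from([0.05, 0.10, 0.20]))
    def test_min_max_slices_disjoint(self, n, f):
        v = np.arange(float(n))
        lo = slice_values(v, SliceSpec("min", f))
        hi = slice_values(v, SliceSpec("max", f))
        if 2 * math.ceil(f * n) <= n:
            assert set(lo) & set(hi) == set()


class TestSmoothing:
    def test_window_one_is_identity(self):
        v = np.array([3.0, 1.0, 4.0])
        assert np.array_equal(smooth(v, "uniform", 1), v)

    @pytest.mark.parametrize("kind", ["uniform", "savgol"])
    @pytest.mark.parametrize("window", [3, 5, 7, 9])
    def test_constants_preserved(self, kind, window):
        v = np.full(20, 2.5)
        assert np.allclose(smooth(v, kind, window), v)

    def test_hand_computed_moving_average(self):
        """Edge-truncated centered mean of (1..5), window 3."""
        out = smooth(np.array([1.0, 2, 3, 4, 5]), "uniform", 3)
        assert np.allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_savgol_reproduces_quadratic_interior(self):
        x = np.arange(30.0)
        v = 2.0 + 0.5 * x - 0.1 * x**2
        out = smooth(v, "savgol", 7)
        assert np.allclose(out[3:-3], v[3:-3], atol=1e-9)

    def test_length_preserved(self):
        for w in (2, 4, 8, 16):
            assert smooth(np.arange(40.0), "uniform", w).size == 40

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth(np.arange(4.0), "uniform", 9)


class TestCombine:
    def test_concatenation_order_and_length(self):
        a = FeatureVector("a", np.arange(3.0))
        b = FeatureVector("b", np.arange(5.0))
        out = combine([a, b])
        assert len(out) == 8
        assert np.array_equal(out.values[:3], a.values)

    def test_single_component_identity(self):
        a = FeatureVector("a", np.arange(4.0))
        assert combine([a]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine([])

    def test_quarter_slices_concatenate(self):
        """max-25% of two 8-dim components -> 2 + 2 = 4 dims."""
        v = np.arange(8.0)
        parts = [
            FeatureVector(n, slice_values(v, SliceSpec("max", 0.25)))
            for n in ("f1", "f2")
        ]
        assert len(combine(parts)) == 4


class TestBookkeeping:
    """Combined-feature lengths follow the per-component ceil rule."""

    def test_all_ids_and_slices(self, fixture_spectrum_100):
        """Independent enumeration of expected lengths over 24 ids x 10 slices."""
        from .reference import BASE_LENGTHS_100

        cache: dict = {}
        for fid in EIGENFEATURE_IDS:
            parts = [p.strip() for p in fid.split("+")]
            for slc in SLICES:
                expected = sum(
                    sliced_length(BASE_LENGTHS_100[p], slc) for p in parts
                )
                fv = compute_feature(
                    fixture_spectrum_100, fid, trim="none", degree=5, slice=slc,
                    cache=cache,
                )
                assert len(fv) == expected, (fid, slc.name)


class TestNormalization:
    def test_log_of_exponential_ladder(self):
        e = np.exp(1.0)
        out = normalize(np.array([e, e**2, e**3]), "raw", is_eigenfeature=True)
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_baseline_raw_unchanged(self):
        v = np.array([-2.0, 0.0, 5.0])
        assert np.array_equal(normalize(v, "raw", is_eigenfeature=False), v)

    def test_minmax_attains_endpoints_per_dimension(self, rng):
        X = rng.uniform(1.0, 9.0, size=(30, 4))
        out = FeatureScaler("minmax", is_eigenfeature=False).fit_transform(X)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_minmax_statistics_come_from_training_fold(self, rng):
        train = rng.uniform(0.0, 1.0, size=(20, 3))
        scaler = FeatureScaler("minmax", is_eigenfeature=False).fit(train)
        val = train.max(axis=0) * 3.0  # outside the training range
        out = scaler.transform(val[None, :])
        assert np.all(out > 1.0)  # not re-fit on validation data

    def test_constant_dimension_maps_to_zero(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            out = FeatureScaler("minmax", is_eigenfeature=False).fit_transform(X)
        assert np.all(out[:, 0] == 0.0)

    def test_nonpositive_eigenfeature_values_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = normalize(np.array([-1e-18, 1.0, 2.0]), "raw", is_eigenfeature=True)
        assert np.all(np.isfinite(out))

    def test_log_preserves_rank_order(self, rng):
        v = np.sort(rng.uniform(1e-6, 1e6, 50))
        out = normalize(v, "raw", is_eigenfeature=True)
        assert np.all(np.diff(out) >= 0)


class TestBaselines:
    def test_mean_and_range_hand_example(self):
        # three voxels whose values double then triple over t = 3 volumes
        ts = TimeseriesMatrix(np.array([[1.0, 2.0, 3.0], [3.0, 6.0, 9.0], [5.0, 10.0, 15.0]]))
        assert np.array_equal(
            timeseries_reduction(ts, BaselineSpec("mean")).values, [3.0, 6.0, 9.0]
        )
        assert np.array_equal(
            timeseries_reduction(ts, BaselineSpec("range")).values, [4.0, 8.0, 12.0]
        )

    def test_near_constant_image_has_zero_std(self):
        # rows must be non-constant, so vary one entry microscopically per row
        m = np.ones((5, 4))
        m[:, 0] += 1e-9
        red = timeseries_reduction(TimeseriesMatrix(m), BaselineSpec("std")).values
        assert np.allclose(red, 0.0, atol=1e-8)

    def test_p95_matches_order_statistics(self, rng):
        m = np.column_stack([rng.uniform(0, 1, 101)])
        m = np.hstack([m, m + 1e-6, m + 2e-6])  # t=3 so rows vary
        red = timeseries_reduction(TimeseriesMatrix(m), BaselineSpec("p95")).values
        assert abs(red[0] - 0.95) < 0.07

    def test_robust_range_is_p95_minus_p05(self, rng):
        m = rng.standard_normal((200, 6))
        ts = TimeseriesMatrix(m)
        rr = timeseries_reduction(ts, BaselineSpec("robust_range")).values
        p95 = timeseries_reduction(ts, BaselineSpec("p95")).values
        p05 = timeseries_reduction(ts, BaselineSpec("p05")).values
        assert np.allclose(rr, p95 - p05)

    def test_length_is_t_and_smoothing_applies(self, rng):
        ts = TimeseriesMatrix(rng.standard_normal((50, 32)))
        for window in (1, 2, 4, 8, 16):
            fv = timeseries_reduction(ts, BaselineSpec("median", window))
            assert len(fv) == 32

    @pytest.mark.parametrize("fid", BASELINE_IDS)
    def test_voxel_permutation_invariance(self, fid, rng):
        m = rng.standard_normal((40, 8))
        perm = rng.permutation(40)
        a = compute_feature(TimeseriesMatrix(m), fid, window=2).values
        b = compute_feature(TimeseriesMatrix(m[perm]), fid, window=2).values
        assert np.allclose(a, b)


class TestComputeFeature:
    def test_eigs_is_the_trimmed_spectrum(self, rng):
        ts = TimeseriesMatrix(rng.standard_normal((300, 20)))
        fv = compute_feature(ts, "eigs", trim="precision")
        assert len(fv) == 19  # t - 1 nonzero eigenvalues

    def test_eigsmiddle20_on_100_levels(self, fixture_spectrum_100):
        fv = compute_feature(fixture_spectrum_100, "eigsmiddle20", trim="none")
        mid = np.sort(fixture_spectrum_100.values)[40:60]
        assert np.array_equal(fv.values, mid)

    def test_combined_slice_applied_per_component(self, fixture_spectrum_100):
        """eigs + rigidity at max-20%: top 20 of 100 eigenvalues plus the
        top 4 of the 20 rigidity values."""
        cache: dict = {}
        fv = compute_feature(
            fixture_spectrum_100, "eigs + rigidity",
            trim="none", degree=5, slice=SliceSpec("max", 0.20), cache=cache,
        )
        assert len(fv) == 24

    def test_unknown_id_rejected(self, fixture_spectrum_100):
        with pytest.raises(ValueError, match="unknown feature id"):
            compute_feature(fixture_spectrum_100, "not-a-feature")

    def test_provenance_recorded(self, fixture_spectrum_100):
        fv = compute_feature(
            fixture_spectrum_100, "eigs", trim="precision", degree=7,
            slice=SliceSpec("min", 0.10),
        )
        assert fv.provenance == {"trim": "precision", "degree": 7, "slice": "min-10"}
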