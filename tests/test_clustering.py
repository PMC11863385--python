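import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketcv import (
    allocate_cluster_counts,
    cluster_ensemble,
    extract_representatives,
    hierarchical_seed_clusters,
    kmeans_refine,
    make_labeled_cv_series,
    slice_by_rog,
)
from pocketcv.clustering import standardize
from pocketcv.cvs import CVSeries


def series_from(values, names=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    names = names or [f"cv{i}" for i in range(values.shape[1])]
    return CVSeries(values=values, names=names,
                    times=np.arange(len(values), dtype=float))


class TestSlicing:
    def test_equal_width_bins(self):
        series = series_from(np.linspace(10.0, 13.0, 301))
        slices = slice_by_rog(series, 0, n_slices=30)
        widths = np.diff(slices.boundaries)
        assert np.allclose(widths, 0.1)
        assert slices.sizes.sum() == 301

    def test_boundary_goes_to_higher_slice(self):
        series = series_from([0.0, 1.0, 2.0, 3.0, 4.0])
        slices = slice_by_rog(series, 0, n_slices=4)
        # value 1.0 sits exactly on the first internal boundary
        assert slices.slice_of_frame[1] == 2

    def test_maximum_lands_in_last_slice(self):
        series = series_from(np.linspace(5.0, 8.0, 50))
        slices = slice_by_rog(series, 0, n_slices=10)
        assert slices.slice_of_frame[-1] == 10

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            slice_by_rog(series_from(np.ones(40)), 0)


def allocation_oracle(sizes, base=100, increment=10):
    """Literal restatement of the allocation rule, kept independent of
    the implementation: proportional rounding, singleton slices exempt,
    inflate the total budget by 10 until every populated slice keeps at
    least two clusters."""
    sizes = list(sizes)
    n_tot = sum(sizes)
    n_c = base
    while True:
        xs = []
        ok = True
        for n_i in sizes:
            if n_i < 2:
                xs.append(n_i)
                continue
            x = int(np.floor(n_i / n_tot * n_c + 0.5))
            x = min(x, n_i)
            xs.append(x)
            if x < 2:
                ok = False
        if ok:
            return n_c, xs
        n_c += increment


class TestAllocation:
    def test_exact_proportions(self):
        alloc = allocate_cluster_counts([500, 300, 200], base_n_c=100)
        assert list(alloc.counts) == [50, 30, 20]
        assert alloc.final_n_c == 100

    def test_inflation_path(self):
        """Strongly unbalanced slices force the budget up in steps of 10
        until the small slices keep two clusters each."""
        alloc = allocate_cluster_counts([980, 10, 10], base_n_c=100)
        assert alloc.final_n_c == 150
        assert list(alloc.counts) == [147, 2, 2]
        assert alloc.total == 151

    def test_singleton_slice_exempt(self):
        with pytest.warns(UserWarning, match="single frame"):
            alloc = allocate_cluster_counts([200, 1, 200], base_n_c=20)
        assert alloc.counts[1] == 1
        assert np.all(alloc.counts[[0, 2]] >= 2)

    def test_matches_brute_force_on_random_size_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(2, 12)
            sizes = rng.integers(0, 400, size=k)
            if sizes.sum() == 0:
                sizes[0] = 5
            alloc = allocate_cluster_counts(sizes, base_n_c=100)
            n_c, xs = allocation_oracle(sizes, base=100)
            assert alloc.final_n_c == n_c
            assert list(alloc.counts) == xs

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1,
                    max_size=8))
    @settings(deadline=None, max_examples=100)
    def test_every_populated_slice_keeps_two_clusters(self, sizes):
        if sum(sizes) == 0:
            sizes = [3]
        alloc = allocate_cluster_counts(sizes, base_n_c=50)
        for n_i, x_i in zip(alloc.sizes, alloc.counts):
            if n_i >= 2:
                assert 2 <= x_i <= n_i
            else:
                assert x_i == n_i


def two_group_series(seed=0, gap=50.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, size=(20, 2))
    b = rng.normal(gap, 0.5, size=(20, 2)) * [1, -1]
    values = np.vstack([a, b])
    values[:, 0] += 10.0  # keep the RoG-like column positive
    return series_from(values), np.array([0] * 20 + [1] * 20)


class TestHierarchicalSeeding:
    def test_recovers_separated_groups_within_slice(self):
        series, truth = two_group_series()
        slices = slice_by_rog(series, 0, n_slices=1)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=2)
        result = hierarchical_seed_clusters(series, slices, alloc)
        assert result.n_clusters == 2
        # perfect recovery up to label permutation
        assert len(set(zip(result.labels, truth))) == 2

    def test_budget_equal_to_frames_gives_singletons(self):
        rng = np.random.default_rng(1)
        series = series_from(10 + rng.uniform(0, 1, size=(12, 2)))
        slices = slice_by_rog(series, 0, n_slices=1)
        alloc = allocate_cluster_counts([12], base_n_c=12)
        result = hierarchical_seed_clusters(series, slices, alloc)
        assert result.n_clusters == 12

    def test_duplicate_frames_share_a_label(self):
        values = np.array([[10.0, 1.0], [10.0, 1.0], [13.0, 5.0], [13.0, 5.0]])
        series = series_from(values)
        slices = slice_by_rog(series, 0, n_slices=2)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=4)
        result = hierarchical_seed_clusters(series, slices, alloc)
        assert result.labels[0] == result.labels[1]
        assert result.labels[2] == result.labels[3]


class TestKMeansRefinement:
    def test_fixed_point_unchanged(self):
        series, _ = two_group_series()
        slices = slice_by_rog(series, 0, n_slices=1)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=2)
        seeds = hierarchical_seed_clusters(series, slices, alloc)
        refined = kmeans_refine(series, seeds)
        assert np.array_equal(refined.labels, seeds.labels)

    def test_recovers_planted_modes(self):
        means = np.array([[10.0, 0.0], [14.0, 5.0], [18.0, -4.0],
                          [22.0, 2.0], [26.0, 8.0]])
        series, truth = make_labeled_cv_series(
            400, means, [0.05] * 5, [0.2] * 5, seed=5)
        result, _manifest, _alloc, _slices = cluster_ensemble(
            series, base_n_c=5, n_slices=5)
        # refined centroids (back in raw units) near the planted modes
        raw_centroids = []
        for c in range(result.n_clusters):
            raw_centroids.append(series.values[result.labels == c].mean(axis=0))
        raw_centroids = np.array(raw_centroids)
        for mode in means:
            assert np.min(np.linalg.norm(raw_centroids - mode, axis=1)) < 0.5

    def test_inertia_never_increases(self):
        rng = np.random.default_rng(8)
        series = series_from(10 + rng.uniform(0, 5, size=(60, 3)))
        slices = slice_by_rog(series, 0, n_slices=3)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=6)
        seeds = hierarchical_seed_clusters(series, slices, alloc)

        def inertia(labels, centroids):
            z = standardize(series.values)
            return sum(np.sum((z[labels == c] - centroids[c]) ** 2)
                       for c in range(len(centroids)))

        refined = kmeans_refine(series, seeds)
        assert inertia(refined.labels, refined.centroids) <= \
            inertia(seeds.labels, seeds.centroids) + 1e-9


class TestRepresentatives:
    def test_singleton_cluster_returns_its_frame(self):
        series, _ = two_group_series()
        slices = slice_by_rog(series, 0, n_slices=1)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=2)
        result = kmeans_refine(series,
                               hierarchical_seed_clusters(series, slices, alloc))
        result, manifest = extract_representatives(result, series)
        for c in range(result.n_clusters):
            rep = result.representatives[c]
            assert result.labels[rep] == c

    def test_tie_broken_by_earliest_frame(self):
        values = np.array([[10.0, 0.0], [12.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        series = series_from(values)
        slices = slice_by_rog(series, 0, n_slices=2)
        alloc = allocate_cluster_counts(slices.sizes, base_n_c=2)
        result = kmeans_refine(series,
                               hierarchical_seed_clusters(series, slices, alloc))
        result, manifest = extract_representatives(result, series)
        cluster_of_0 = result.labels[0]
        # frames 0 and 2 are identical; the earlier one must represent
        members = np.flatnonzero(result.labels == cluster_of_0)
        if set(members) >= {0, 2}:
            assert result.representatives[cluster_of_0] in (0, 1)


@pytest.fixture(scope="module")
def pipeline(toy, open_close_traj):
    from pocketcv import build_binding_site_cvs, evaluate_cv_series

    rog, cips, _f, _ = build_binding_site_cvs(toy.structure, toy.site)
    series = evaluate_cv_series(open_close_traj.coords, [rog, *cips],
                                times=open_close_traj.times)
    return series, cluster_ensemble(series, base_n_c=10, n_slices=8)


class TestPipeline:
    def test_budget_met_and_slices_covered(self, pipeline):
        series, (result, manifest, alloc, slices) = pipeline
        assert result.n_clusters >= 10
        for s in range(1, slices.n_slices + 1):
            frames = slices.frames_in(s)
            if len(frames) >= 2:
                assert len(np.unique(result.labels[frames])) >= 1

    def test_representatives_span_rog_range(self, pipeline):
        """Slice-stratified selection keeps representatives spread over
        at least 90% of the sampled gyration-radius range."""
        series, (result, manifest, alloc, slices) = pipeline
        rog = series.column("rog_bs")
        rep_rog = rog[result.representatives]
        span = (rep_rog.max() - rep_rog.min()) / (rog.max() - rog.min())
        assert span >= 0.9

    def test_deterministic_end_to_end(self, pipeline):
        series, (result, manifest, alloc, slices) = pipeline
        result2, manifest2, _, _ = cluster_ensemble(series, base_n_c=10,
                                                    n_slices=8)
        assert np.array_equal(result.labels, result2.labels)
        assert manifest.equals(manifest2)

    def test_mixture_with_rare_modes_inflates_budget(self):
        means = np.array([[10.0, 0.0], [20.0, 3.0], [30.0, -3.0]])
        series, _ = make_labeled_cv_series(
            500, means, [0.1, 0.1, 0.1], [0.98, 0.01, 0.01], seed=3)
        _result, _manifest, alloc, _slices = cluster_ensemble(
            series, base_n_c=20, n_slices=10)
        assert alloc.final_n_c > 20
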