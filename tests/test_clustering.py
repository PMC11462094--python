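"""K-means core: seeding, Lloyd iterations, silhouettes, K and feature
selection, labelling. Independent oracles: exhaustive partition enumeration,
direct-formula silhouettes, and scikit-learn as a reference cross-check."""

import itertools
from datetime import date, timedelta

import numpy as np
import pytest

from actiphen import (
    ActivityWindow,
    KMeansParams,
    feature_subset_search,
    kmeanspp_init,
    label_clusters,
    lloyd,
    select_k,
    silhouette,
    sse_scan,
)
from actiphen.clustering import scale_features


def _blobs(rng, centres, n_per, scale=0.5):
    pts = np.vstack([rng.normal(c, scale, size=(n_per, len(c))) for c in centres])
    labels = np.repeat(np.arange(len(centres)), n_per)
    return pts, labels


# ---------------------------------------------------------------------------
# k-means++ seeding

def test_seeding_with_k_equal_n_is_a_permutation():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 2))
    centroids = kmeanspp_init(pts, 6, rng)
    matched = {tuple(c) for c in centroids}
    assert matched == {tuple(p) for p in pts}


def test_seeding_k1_returns_one_point():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(10, 3))
    centroids = kmeanspp_init(pts, 1, rng)
    assert centroids.shape == (1, 3)
    assert any(np.allclose(centroids[0], p) for p in pts)


def test_seeding_spreads_across_separated_pairs():
    """D^2 seeding: with two far-apart pairs the second seed lands in the
    other pair almost always (squared-distance proposal law)."""
    pts = np.array([[0.0, 0.0], [0.1, 0.0], [100.0, 0.0], [100.1, 0.0]])
    same_pair = 0
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        c = kmeanspp_init(pts, 2, rng)
        same_pair += abs(c[0, 0] - c[1, 0]) < 1.0
    assert same_pair / 1000 < 0.05


def test_seeding_rejects_k_above_n():
    with pytest.raises(ValueError):
        kmeanspp_init(np.zeros((3, 2)), 4, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Lloyd iterations

def _exhaustive_best_sse(pts, k=2):
    n = len(pts)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        sse = 0.0
        for j in range(k):
            members = pts[[i for i, a in enumerate(assignment) if a == j]]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def test_k_equals_n_gives_zero_sse():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(5, 2))
    model = lloyd(pts, KMeansParams(k=5, n_init=20, seed=0))
    assert model.sse == pytest.approx(0.0, abs=1e-12)


def test_k1_closed_form():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(40, 3))
    model = lloyd(pts, KMeansParams(k=1, seed=0))
    assert np.allclose(model.centroids[0], pts.mean(axis=0))
    assert model.sse == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())


def test_small_instances_reach_global_optimum():
    """On tiny instances best-of-50 Lloyd's matches exhaustive enumeration."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        pts = rng.normal(size=(n, 2))
        model = lloyd(pts, KMeansParams(k=2, n_init=50, seed=int(rng.integers(2**31))))
        assert model.sse <= _exhaustive_best_sse(pts) + 1e-9


def test_sse_non_increasing_within_run():
    rng = np.random.default_rng(5)
    pts, _ = _blobs(rng, [(0, 0), (4, 4), (8, 0)], 40)
    model = lloyd(pts, KMeansParams(k=3, n_init=1, seed=9))
    diffs = np.diff(model.sse_history)
    assert np.all(diffs <= 1e-9)


def test_best_of_n_init_beats_single_runs():
    rng = np.random.default_rng(6)
    pts, _ = _blobs(rng, [(0, 0), (5, 5), (10, 0), (5, -5)], 30)
    best = lloyd(pts, KMeansParams(k=4, n_init=10, seed=1)).sse
    singles = [lloyd(pts, KMeansParams(k=4, n_init=1, seed=s)).sse for s in range(10)]
    assert best <= min(singles) + 1e-9


def test_fixed_seed_bit_identical():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(60, 3))
    a = lloyd(pts, KMeansParams(k=3, seed=42))
    b = lloyd(pts, KMeansParams(k=3, seed=42))
    assert np.array_equal(a.centroids, b.centroids)
    assert np.array_equal(a.assignments, b.assignments)
    assert a.sse == b.sse


def test_non_finite_input_rejected():
    pts = np.array([[0.0, 1.0], [np.nan, 2.0]])
    with pytest.raises(ValueError):
        lloyd(pts, KMeansParams(k=1))


def test_matches_reference_implementation_on_blobs():
    sklearn_cluster = pytest.importorskip("sklearn.cluster")
    rng = np.random.default_rng(8)
    pts, _ = _blobs(rng, [(0, 0), (6, 6), (12, 0)], 50)
    ours = lloyd(pts, KMeansParams(k=3, n_init=10, seed=3))
    ref = sklearn_cluster.KMeans(n_clusters=3, n_init=10, random_state=3).fit(pts)
    assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)


# ---------------------------------------------------------------------------
# silhouettes

def _silhouette_oracle(pts, labels):
    n = len(pts)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(pts[i] - pts[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) - {labels[i]}
        )
        s[i] = (b - a) / max(a, b)
    return s


def test_hand_computed_two_pair_example():
    pts = np.array([[0.0], [0.1], [10.0], [10.1]])
    terms = silhouette(pts, [0, 0, 1, 1])
    assert terms.s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-12)
    assert round(terms.s[0], 4) == 0.9900


def test_singleton_cluster_convention():
    pts = np.array([[0.0], [0.2], [5.0]])
    terms = silhouette(pts, [0, 0, 1])
    assert terms.s[2] == 0.0


def test_random_points_match_direct_formula_oracle():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(12, 2))
    labels = rng.integers(0, 3, size=12)
    while len(set(labels.tolist())) < 2:  # pragma: no cover
        labels = rng.integers(0, 3, size=12)
    terms = silhouette(pts, labels)
    assert np.allclose(terms.s, _silhouette_oracle(pts, labels), atol=1e-12)


def test_silhouette_matches_reference_implementation():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(10)
    pts = rng.normal(size=(50, 3))
    labels = rng.integers(0, 4, size=50)
    terms = silhouette(pts, labels)
    assert terms.overall_mean == pytest.approx(
        sklearn_metrics.silhouette_score(pts, labels), abs=1e-10
    )


def test_single_cluster_is_an_error():
    with pytest.raises(ValueError):
        silhouette(np.zeros((4, 1)), [0, 0, 0, 0])


# ---------------------------------------------------------------------------
# K selection and elbow

def test_elbow_terminates_at_zero_and_warm_start_monotone():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(12, 2))
    table = sse_scan(pts, range(1, 13), KMeansParams(n_init=5, seed=2), warm_start=True)
    values = [table[k] for k in sorted(table)]
    assert values[-1] == pytest.approx(0.0, abs=1e-9)
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))


def test_elbow_drop_largest_at_planted_k():
    rng = np.random.default_rng(12)
    pts, _ = _blobs(rng, [(0, 0), (10, 10), (20, 0)], 60, scale=0.8)
    table = sse_scan(pts, range(1, 7), KMeansParams(n_init=5, seed=4))
    ks = sorted(table)
    ratios = {k1: table[k1] / table[k0] for k0, k1 in zip(ks, ks[1:])}
    assert min(ratios, key=ratios.get) == 3  # largest relative drop going to K=3


def test_select_k_on_planted_blobs():
    rng = np.random.default_rng(13)
    params = KMeansParams(n_init=5, seed=5)
    pts3, _ = _blobs(rng, [(0, 0), (8, 8), (16, 0)], 50)
    assert select_k(pts3, params=params)[0] == 3
    pts2, _ = _blobs(rng, [(0, 0), (10, 0)], 60)
    assert select_k(pts2, params=params)[0] == 2


def test_select_k_degenerate_range():
    rng = np.random.default_rng(14)
    pts = rng.normal(size=(30, 2))
    k, scores = select_k(pts, k_min=4, k_max=4, params=KMeansParams(n_init=3, seed=6))
    assert k == 4 and set(scores) == {4}


# ---------------------------------------------------------------------------
# feature-subset search and labelling

def _make_windows(matrix, names):
    from actiphen.clustering import FEATURE_ATTRS

    windows = []
    base = date(2019, 1, 7)
    for i, row in enumerate(matrix):
        w = ActivityWindow(
            participant_id=f"p{i}",
            questionnaire_date=base + timedelta(days=43),
            window_start=base,
            window_end=base + timedelta(days=41),
            days_used=40,
            weekday_days_used=29,
            weekend_days_used=11,
        )
        for name, value in zip(names, row):
            setattr(w, FEATURE_ATTRS[name], float(value))
        windows.append(w)
    return windows


def test_subset_count_is_all_subsets_of_size_two_plus():
    rng = np.random.default_rng(15)
    matrix = rng.normal(loc=50, scale=5, size=(40, 6)).clip(min=0)
    names = ("steps", "distance", "mvpa_minutes", "calories", "weekday_days", "weekend_days")
    windows = _make_windows(matrix, names)
    _, ranking = feature_subset_search(windows, names, KMeansParams(k=2, n_init=2, seed=7))
    assert len(ranking) == 2**6 - 6 - 1  # 57


def test_noise_feature_excluded_from_winning_subset():
    """Structure planted in steps/distance/MVPA with independent-noise
    calories: the winning subset must not contain calories (majority over
    five seeds)."""
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        centres = [(5000, 2.2, 21), (8200, 3.7, 41), (12300, 5.5, 73)]
        structured = np.vstack(
            [rng.normal(c, (500, 0.3, 8), size=(40, 3)) for c in centres]
        )
        calories = rng.normal(520, 170, size=(120, 1))  # no cluster structure
        matrix = np.hstack([structured, calories]).clip(min=0)
        names = ("steps", "distance", "mvpa_minutes", "calories")
        windows = _make_windows(matrix, names)
        best, _ = feature_subset_search(windows, names, KMeansParams(k=3, n_init=3, seed=seed))
        wins += "calories" not in best
    assert wins >= 3


def test_single_candidate_subset_trivially_selected():
    rng = np.random.default_rng(16)
    matrix = rng.normal(loc=(5000, 3.5), scale=(1000, 1.0), size=(30, 2)).clip(min=0)
    windows = _make_windows(matrix, ("steps", "distance"))
    best, ranking = feature_subset_search(
        windows, ("steps", "distance"), KMeansParams(k=2, n_init=2, seed=8)
    )
    assert best == ("steps", "distance") and len(ranking) == 1


def test_empty_candidates_rejected():
    with pytest.raises(ValueError):
        feature_subset_search([], (), KMeansParams())


def test_labels_ordered_by_centroid_steps():
    rng = np.random.default_rng(17)
    centres = [(12319.4, 5.5), (5000.3, 2.2), (8229.5, 3.7)]  # deliberately unordered
    pts = np.vstack([rng.normal(c, (300, 0.2), size=(30, 2)) for c in centres])
    model = lloyd(pts, KMeansParams(k=3, n_init=5, seed=9), feature_names=("steps", "distance"))
    label_clusters(model)
    steps_by_label = {
        label: model.centroids[idx, 0] for idx, label in enumerate(model.labels)
    }
    assert steps_by_label["low"] < steps_by_label["moderate"] < steps_by_label["high"]


def test_label_fallback_for_other_k():
    rng = np.random.default_rng(18)
    pts = np.vstack([rng.normal((1000, 1), 10, (20, 2)), rng.normal((9000, 9), 10, (20, 2))])
    model = lloyd(pts, KMeansParams(k=2, n_init=3, seed=10), feature_names=("steps", "distance"))
    label_clusters(model)
    assert set(model.labels) == {"level_1", "level_2"}


def test_scaling_helpers():
    rng = np.random.default_rng(19)
    matrix = rng.normal(size=(50, 3)) * (1000, 1, 10) + (8000, 3.5, 40)
    z = scale_features(matrix, "zscore")
    assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(z.std(axis=0), 1, atol=1e-12)
    mm = scale_features(matrix, "minmax")
    assert mm.min() == pytest.approx(0.0) and mm.max() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        scale_features(matrix, "robust")
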