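"""Purity, threshold annealing, ranking, k-means and evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegdyn import (FEATURE_NAMES, AnnealSchedule, anneal_thresholds,
                    evaluate_clustering, kmeans_assign, parameter_sweep,
                    purity, rank_features, threshold_assign)


def grid_search_purity(values, labels):
    """Exhaustive optimum over all midpoint threshold pairs (test oracle)."""
    v = np.asarray(values, float)
    u = np.sort(np.unique(v))
    candidates = np.concatenate([[u[0] - 1.0],
                                 (u[:-1] + u[1:]) / 2.0,
                                 [u[-1] + 1.0]])
    best = 0.0
    for t1, t2 in itertools.combinations_with_replacement(candidates, 2):
        best = max(best, purity(threshold_assign(v, t1, t2), labels))
    return best


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def test_purity_examples():
    assert purity([0, 1, 2], ["a", "b", "c"]) == 1.0
    assert purity([0, 0, 1], ["a", "b", "b"]) == pytest.approx(2 / 3)
    assert purity([0] * 8, ["a"] * 5 + ["b"] * 3) == pytest.approx(5 / 8)
    assert purity(np.arange(7), ["a", "a", "b", "b", "c", "c", "c"]) == 1.0


def test_purity_never_increases_when_merging_mixed_clusters(rng):
    for _ in range(20):
        labels = rng.choice(["a", "b", "c"], size=30)
        assign = rng.integers(0, 4, size=30)
        p0 = purity(assign, labels)
        merged = np.where(assign == 3, 2, assign)
        assert purity(merged, labels) <= p0 + 1e-12


def test_purity_input_validation():
    with pytest.raises(ValueError):
        purity([0, 1], ["a"])


# ---------------------------------------------------------------------------
# threshold assignment
# ---------------------------------------------------------------------------

def test_threshold_assign_cases():
    assert list(threshold_assign([1.0, 2.0, 3.0], 1.5, 2.5)) == [0, 1, 2]
    # equal thresholds: the middle half-open bin [t, t) is empty
    assert 1 not in threshold_assign([1.0, 2.0, 3.0], 2.0, 2.0)
    assert len(set(threshold_assign([5.0] * 4, 1.0, 2.0))) == 1
    with pytest.raises(ValueError, match="t1 must be <= t2"):
        threshold_assign([1.0], 2.0, 1.0)


def test_threshold_bins_are_lower_inclusive():
    out = threshold_assign([1.0, 2.0, 3.0], 2.0, 3.0)
    assert list(out) == [0, 1, 2]


# ---------------------------------------------------------------------------
# annealed threshold search
# ---------------------------------------------------------------------------

def test_anneal_reaches_purity_one_on_separable_values(rng):
    values = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(5, 6, 10),
                             rng.uniform(10, 11, 10)])
    labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    sol = anneal_thresholds(values, labels, seed=0)
    assert sol.achieved_purity == 1.0
    t1, t2 = sol.thresholds
    assert t1 <= t2


@pytest.mark.parametrize("instance_seed", range(8))
def test_anneal_matches_exhaustive_grid_search(instance_seed):
    rng = np.random.default_rng(instance_seed)
    n = int(rng.integers(12, 40))
    values = rng.normal(0, 1, n) + rng.choice([0.0, 1.2, 2.5], size=n)
    labels = rng.choice(["a", "b", "c"], size=n)
    sol = anneal_thresholds(values, labels, seed=instance_seed)
    assert sol.achieved_purity == pytest.approx(
        grid_search_purity(values, labels), abs=1e-12)


def test_anneal_deterministic_given_seed(rng):
    values = rng.normal(0, 1, 30)
    labels = rng.choice(["a", "b", "c"], 30)
    a = anneal_thresholds(values, labels, seed=3)
    b = anneal_thresholds(values, labels, seed=3)
    assert a.thresholds == b.thresholds
    assert a.achieved_purity == b.achieved_purity


def test_anneal_never_below_percentile_initialization(rng):
    for seed in range(5):
        values = rng.normal(0, 1, 25)
        labels = rng.choice(["a", "b"], 25)
        t1, t2 = np.percentile(values, [33, 67])
        init_p = purity(threshold_assign(values, t1, t2), labels)
        sol = anneal_thresholds(values, labels, seed=seed)
        assert sol.achieved_purity >= init_p


# ---------------------------------------------------------------------------
# feature ranking
# ---------------------------------------------------------------------------

def _feature_table(rng, n=30):
    return pd.DataFrame(rng.normal(0, 1, (n, 36)), columns=FEATURE_NAMES)


def test_perfectly_separating_feature_ranks_first(rng):
    table = _feature_table(rng)
    labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    table["cdm_sharpness_delta"] = np.concatenate(
        [rng.uniform(0, 1, 10), rng.uniform(2, 3, 10), rng.uniform(4, 5, 10)])
    ranked = rank_features(table, labels, seed=0,
                           schedule=AnnealSchedule(iterations=400, chains=1))
    assert len(ranked.ranking) == 36
    assert ranked.ranking[0] == ("cdm_sharpness_delta", 1.0)


def test_identical_columns_tie_broken_in_canonical_order(rng):
    table = _feature_table(rng)
    labels = np.array(["a"] * 15 + ["b"] * 15)
    sep = np.concatenate([rng.uniform(0, 1, 15), rng.uniform(2, 3, 15)])
    table["cdm_mean_broadband"] = sep
    table["pdm_mean_broadband"] = sep
    ranked = rank_features(table, labels, seed=0,
                           schedule=AnnealSchedule(iterations=400, chains=1))
    top2 = [ranked.ranking[0][0], ranked.ranking[1][0]]
    assert top2 == ["cdm_mean_broadband", "pdm_mean_broadband"]


def test_nan_features_rejected(rng):
    table = _feature_table(rng)
    table.iloc[3, 5] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        rank_features(table, ["a"] * 15 + ["b"] * 15, seed=0)


# ---------------------------------------------------------------------------
# k-means and evaluation
# ---------------------------------------------------------------------------

def test_kmeans_recovers_separated_blobs(rng):
    centers = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    X = np.vstack([c + 0.05 * rng.normal(0, 1, (20, 2)) for c in centers])
    labels = np.repeat(["a", "b", "c"], 20)
    assign = kmeans_assign(X, k=3, seed=0, restarts=20)
    assert purity(assign, labels) == 1.0


def test_kmeans_single_cluster_and_determinism(rng):
    X = rng.normal(0, 1, (12, 3))
    assign = kmeans_assign(X, k=1, seed=0, restarts=5)
    assert len(set(assign)) == 1
    labels = ["a"] * 8 + ["b"] * 4
    assert purity(assign, labels) == pytest.approx(8 / 12)
    a = kmeans_assign(X, k=3, seed=7, restarts=10)
    b = kmeans_assign(X, k=3, seed=7, restarts=10)
    assert np.array_equal(a, b)
    with pytest.raises(ValueError, match="exceeds"):
        kmeans_assign(X, k=13, seed=0)


def test_evaluation_perfect_clustering():
    labels = ["normal"] * 5 + ["ohtahara"] * 5 + ["west"] * 5
    assign = [0] * 5 + [1] * 5 + [2] * 5
    ev = evaluate_clustering(assign, labels, "normal")
    assert ev.purity == 1.0
    assert ev.sensitivity == 1.0 and ev.specificity == 1.0


def test_evaluation_single_abnormal_cluster():
    labels = ["abn"] * 30 + ["normal"] * 10
    ev = evaluate_clustering([0] * 40, labels, "normal")
    assert ev.sensitivity == 1.0 and ev.specificity == 0.0
    assert ev.purity == pytest.approx(30 / 40)


def test_evaluation_matches_hand_tallied_confusion():
    # cluster 0: 4 normal + 1 west -> normal; cluster 1: 3 west + 2 normal
    # -> west; cluster 2: 5 ohtahara -> ohtahara
    labels = np.array(["normal"] * 4 + ["west"]
                      + ["west"] * 3 + ["normal"] * 2
                      + ["ohtahara"] * 5)
    assign = np.array([0] * 5 + [1] * 5 + [2] * 5)
    ev = evaluate_clustering(assign, labels, "normal")
    assert ev.purity == pytest.approx(12 / 15)
    assert ev.sensitivity == pytest.approx(8 / 9)   # west in cluster 0 missed
    assert ev.specificity == pytest.approx(4 / 6)   # 2 normals in cluster 1


def test_evaluation_majority_tie_resolved_to_abnormal():
    labels = ["normal", "abn"]
    ev = evaluate_clustering([0, 0], labels, "normal")
    assert ev.cluster_to_class[0] == "abn"
    assert ev.sensitivity == 1.0 and ev.specificity == 0.0


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def _informative_table(rng, n_info=4):
    """30 segments with n_info separating features and noise elsewhere."""
    labels = np.repeat(["a", "b", "c"], 10)
    table = _feature_table(rng)
    offsets = {"a": 0.0, "b": 4.0, "c": 8.0}
    for name in list(FEATURE_NAMES)[:n_info]:
        table[name] = ([offsets[l] for l in labels]
                       + 0.4 * rng.normal(0, 1, 30))
    return table, labels


def test_sweep_has_requested_length_and_peaks_near_informative_count(rng):
    peaks = []
    for seed in range(5):
        table, labels = _informative_table(rng)
        sweep = parameter_sweep(table, labels, r_max=10, normal_class="a",
                                seed=seed, restarts=10,
                                schedule=AnnealSchedule(iterations=300,
                                                        chains=1))
        assert len(sweep) == 10
        best_r = int(sweep.loc[sweep["purity"].idxmax(), "r"])
        peaks.append(best_r)
    assert np.median(peaks) <= 6


def test_sweep_r1_matches_direct_single_feature_call(rng):
    table, labels = _informative_table(rng)
    light = AnnealSchedule(iterations=300, chains=1)
    ranked = rank_features(table, labels, seed=0, schedule=light)
    sweep = parameter_sweep(table, labels, r_max=1, normal_class="a",
                            seed=0, restarts=10, ranked=ranked)
    top = ranked.ranking[0][0]
    assign = kmeans_assign(table[[top]].to_numpy(), k=3, seed=0, restarts=10)
    ev = evaluate_clustering(assign, labels, "a")
    assert sweep.loc[0, "purity"] == pytest.approx(ev.purity)
    with pytest.raises(ValueError, match="r_max"):
        parameter_sweep(table, labels, r_max=37)
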