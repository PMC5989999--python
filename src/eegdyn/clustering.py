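"""Purity-based feature ranking and k-means clustering of EEG segments.

Each of the 36 dynamics measures is scored by how well two thresholds on it
partition the segments into three clusters matching the known groups; the
achievable purity (found by simulated annealing over the threshold pair)
ranks the measures.  Subsets of top-ranked measures then feed an unsupervised
k-means clustering, evaluated by purity and by the sensitivity/specificity of
separating normal from abnormal segments.

Purity of a clustering Omega against classes C is
``P = (1/N) * sum_k max_j |omega_k intersect c_j|``; it ranges from ~1/N
(every element misassigned) to 1 (all clusters class-pure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import FEATURE_NAMES

__all__ = [
    "ClusterEvaluation",
    "ThresholdSolution",
    "AnnealSchedule",
    "RankedFeatures",
    "purity",
    "threshold_assign",
    "anneal_thresholds",
    "rank_features",
    "kmeans_assign",
    "evaluate_clustering",
    "parameter_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule for the two-threshold search."""

    t0: float = 1.0
    cooling: float = 0.95
    iterations: int = 2000
    proposal_scale: float = 0.1   # Gaussian proposal sigma, x value range
    chains: int = 3               # independent restarts; best pair wins


@dataclass
class ThresholdSolution:
    measure_name: str
    thresholds: tuple[float, float]
    achieved_purity: float
    anneal_seed: int
    schedule: AnnealSchedule


@dataclass
class RankedFeatures:
    """Measures ordered by achievable threshold-clustering purity."""

    ranking: list[tuple[str, float]]    # (measure_name, max_purity), desc
    solutions: dict[str, ThresholdSolution] = field(default_factory=dict)


@dataclass
class ClusterEvaluation:
    assignments: np.ndarray
    purity: float
    sensitivity: float
    specificity: float
    cluster_to_class: dict[int, str] = field(default_factory=dict)


def purity(assignments, labels) -> float:
    """Fraction of elements in the majority class of their cluster."""
    a = np.asarray(assignments)
    y = np.asarray(labels)
    if a.shape != y.shape:
        raise ValueError("assignments and labels must align element-wise")
    if a.size == 0:
        raise ValueError("empty partition")
    total = 0
    for cluster in np.unique(a):
        members = y[a == cluster]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / a.size


def threshold_assign(values, t1: float, t2: float) -> np.ndarray:
    """Three clusters by two thresholds: v < t1 | t1 <= v < t2 | v >= t2."""
    if t1 > t2:
        raise ValueError(f"t1 must be <= t2, got {t1} > {t2}")
    v = np.asarray(values, dtype=float)
    return np.where(v < t1, 0, np.where(v < t2, 1, 2))


def anneal_thresholds(values, labels, schedule: AnnealSchedule | None = None,
                      seed: int = 0,
                      measure_name: str = "") -> ThresholdSolution:
    """Maximize threshold-clustering purity by simulated annealing.

    Each chain starts from the 33rd/67th percentiles; proposals perturb one
    threshold at a time with a Gaussian step; worse moves are accepted with
    probability ``exp(delta/T)`` under geometric cooling.  The best pair
    visited by any of ``schedule.chains`` independent chains is returned, so
    the result is never worse than the percentile initialization.
    Deterministic given ``seed``.
    """
    schedule = schedule or AnnealSchedule()
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size < 3:
        raise ValueError("need at least 3 labeled segments")
    if np.unique(y).size == 1:
        logger.warning("degenerate labels (single class): purity is "
                       "trivially 1 for %s", measure_name or "measure")
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo or 1.0
    sigma = schedule.proposal_scale * span

    def score(t1, t2):
        return purity(threshold_assign(v, t1, t2), y)

    # purity is piecewise constant with breakpoints at the data values;
    # global proposals draw from the midpoints between consecutive values
    u = np.unique(v)
    midpoints = np.concatenate([[u[0] - sigma], (u[:-1] + u[1:]) / 2.0,
                                [u[-1] + sigma]])

    init = np.percentile(v, [33.0, 67.0]).astype(float)
    best_t, best_p = tuple(init), score(*init)
    for chain in range(max(1, schedule.chains)):
        rng = np.random.default_rng([int(seed), 311, chain])
        if chain == 0:
            t = init.copy()
        else:
            # later chains restart from random threshold pairs so the
            # search does not depend on a single initialization basin
            t = np.sort(rng.uniform(lo, hi, size=2))
        current = score(*t)
        if current > best_p:
            best_t, best_p = tuple(t), current
        temp = schedule.t0
        for _ in range(schedule.iterations):
            prop = t.copy()
            move = rng.random()
            if move < 0.1:
                # joint global move: redraw both thresholds
                prop = midpoints[rng.integers(0, midpoints.size, size=2)]
            elif move < 0.3:
                # single global move: jump one threshold to a midpoint
                prop[rng.integers(0, 2)] = \
                    midpoints[rng.integers(0, midpoints.size)]
            else:
                prop[rng.integers(0, 2)] += sigma * rng.standard_normal()
            prop.sort()
            cand = score(*prop)
            delta = cand - current
            if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-300)):
                t, current = prop, cand
                if current > best_p:
                    best_t, best_p = tuple(t), current
            temp *= schedule.cooling
    return ThresholdSolution(measure_name=measure_name,
                             thresholds=(float(best_t[0]), float(best_t[1])),
                             achieved_purity=float(best_p),
                             anneal_seed=int(seed), schedule=schedule)


def rank_features(feature_table: pd.DataFrame, labels,
                  schedule: AnnealSchedule | None = None,
                  seed: int = 0) -> RankedFeatures:
    """Rank all 36 measures by maximal threshold-clustering purity.

    ``feature_table`` must contain the canonical measure columns.  Ties are
    broken by canonical measure-name order.
    """
    missing = [n for n in FEATURE_NAMES if n not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    sub = feature_table[list(FEATURE_NAMES)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"NaN feature cells in columns: {bad}")
    solutions = {}
    for i, name in enumerate(FEATURE_NAMES):
        solutions[name] = anneal_thresholds(
            sub[name].to_numpy(), labels, schedule=schedule,
            seed=int(seed) * 37 + i, measure_name=name)
    order = sorted(FEATURE_NAMES,
                   key=lambda n: (-solutions[n].achieved_purity,
                                  FEATURE_NAMES.index(n)))
    ranking = [(n, solutions[n].achieved_purity) for n in order]
    return RankedFeatures(ranking=ranking, solutions=solutions)


def kmeans_assign(features, k: int, seed: int = 0,
                  restarts: int = 100) -> np.ndarray:
    """k-means on per-column standardized features; best of ``restarts``."""
    from sklearn.cluster import KMeans

    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of segments {X.shape[0]}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed))
    return km.fit_predict(Z)


def evaluate_clustering(assignments, labels, normal_class: str,
                        ) -> ClusterEvaluation:
    """Purity plus normal-vs-abnormal sensitivity and specificity.

    Each cluster is mapped to its majority class; majority ties are resolved
    toward abnormal (conservative for a screening measure) and logged.
    Sensitivity = abnormal segments predicted abnormal / all abnormal;
    specificity = normal predicted normal / all normal.
    """
    a = np.asarray(assignments)
    y = np.asarray(labels)
    p = purity(a, y)
    cluster_to_class: dict[int, str] = {}
    for cluster in np.unique(a):
        members = y[a == cluster]
        classes, counts = np.unique(members, return_counts=True)
        top = counts.max()
        winners = classes[counts == top]
        if len(winners) > 1:
            abnormal = [c for c in winners if c != normal_class]
            choice = abnormal[0] if abnormal else winners[0]
            logger.warning("majority tie in cluster %s between %s; resolved "
                           "to %s", cluster, list(winners), choice)
        else:
            choice = winners[0]
        cluster_to_class[int(cluster)] = str(choice)
    predicted_abnormal = np.array(
        [cluster_to_class[int(c)] != normal_class for c in a])
    is_abnormal = y != normal_class
    n_abn = int(is_abnormal.sum())
    n_norm = int((~is_abnormal).sum())
    sensitivity = (float((predicted_abnormal & is_abnormal).sum()) / n_abn
                   if n_abn else float("nan"))
    specificity = (float((~predicted_abnormal & ~is_abnormal).sum()) / n_norm
                   if n_norm else float("nan"))
    return ClusterEvaluation(assignments=a, purity=float(p),
                             sensitivity=sensitivity, specificity=specificity,
                             cluster_to_class=cluster_to_class)


def parameter_sweep(feature_table: pd.DataFrame, labels, r_max: int = 20,
                    normal_class: str = "normal", k: int = 3, seed: int = 0,
                    restarts: int = 100,
                    ranked: RankedFeatures | None = None,
                    schedule: AnnealSchedule | None = None) -> pd.DataFrame:
    """Cluster on the top-r ranked measures for r = 1..r_max.

    Returns one row per r with purity, sensitivity and specificity against
    the known labels.
    """
    if r_max > len(FEATURE_NAMES):
        raise ValueError(f"r_max={r_max} exceeds {len(FEATURE_NAMES)} measures")
    if ranked is None:
        ranked = rank_features(feature_table, labels, schedule=schedule,
                               seed=seed)
    names = [n for n, _ in ranked.ranking]
    rows = []
    for r in range(1, r_max + 1):
        X = feature_table[names[:r]].to_numpy(dtype=float)
        a = kmeans_assign(X, k=k, seed=seed, restarts=restarts)
        ev = evaluate_clustering(a, labels, normal_class)
        rows.append({"r": r, "purity": ev.purity,
                     "sensitivity": ev.sensitivity,
                     "specificity": ev.specificity})
    return pd.DataFrame(rows)
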