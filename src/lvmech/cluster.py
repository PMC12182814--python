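"""Contraction-phenotype discovery: standardization, Ward clustering,
majority-rule cluster-count selection, and cluster characterization.

Patients are clustered on the fixed 25-feature regional-mechanics vector
(16 segmental peak radial strains plus per-slice sdTTP/SRCC/RURE), z-scored
so every metric enters with equal weight, using agglomerative clustering
with Ward's minimum-variance criterion and Euclidean distances.  The number
of clusters is chosen by majority vote of a suite of cluster-validity
indices, each voting for its own optimal k (ties go to the smallest k).

The default suite has 11 indices: Calinski-Harabasz (max), silhouette (max),
Davies-Bouldin (min), Dunn (max), C-index (min), gap statistic (Tibshirani
one-standard-error rule), Hartigan (first k with H <= 10), Krzanowski-Lai
(max), Ball-Hall (largest drop), point-biserial (max), and McClain-Rao
(min).  The suite is pluggable: pass ``indices`` to restrict or extend it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "standardize", "ward_cluster", "select_k",
           "characterize", "correlate", "run_clustering", "DEFAULT_INDICES"]


@dataclass
class ClusterResult:
    """Labels (1..k), Ward linkage, chosen k, per-index votes, z-scoring params."""

    labels: np.ndarray
    linkage: np.ndarray
    chosen_k: int
    votes: pd.DataFrame
    feature_means: pd.Series
    feature_sds: pd.Series


def standardize(table: pd.DataFrame,
                feature_columns: list[str] | tuple[str, ...]) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score the feature columns (population SD, divisor n).

    Rows with any missing feature are dropped (count logged); a feature with
    zero spread is an error naming the feature.
    """
    feats = table.loc[:, list(feature_columns)]
    n_before = len(feats)
    keep = feats.notna().all(axis=1)
    if (~keep).any():
        logger.warning("standardize: dropped %d/%d rows with missing features",
                       int((~keep).sum()), n_before)
    feats = feats.loc[keep]
    means = feats.mean()
    sds = feats.std(ddof=0)
    zero = sds[sds == 0.0]
    if len(zero):
        raise ValueError(f"feature {zero.index[0]!r} has zero standard deviation")
    z = (feats - means) / sds
    return z, means, sds


def ward_cluster(z: pd.DataFrame | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward minimum-variance agglomerative clustering; labels in 1..k."""
    X = np.asarray(z, dtype=float)
    n = len(X)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must lie in [2, n-1] = [2, {n - 1}], got {k}")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


# ---------------------------------------------------------------------------
# cluster-validity indices
# ---------------------------------------------------------------------------

def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    labs = np.unique(labels)
    diam = max(D[np.ix_(labels == a, labels == a)].max() for a in labs)
    sep = min(D[np.ix_(labels == a, labels == b)].min()
              for i, a in enumerate(labs) for b in labs[i + 1:])
    return sep / diam if diam > 0 else np.inf


def _pairwise_within_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of same-cluster pairs."""
    n = len(labels)
    same = (labels[:, None] == labels[None, :])
    iu = np.triu_indices(n, k=1)
    return same[iu]


def _c_index(d_cond: np.ndarray, d_sorted: np.ndarray, labels: np.ndarray) -> float:
    within = _pairwise_within_mask(labels)
    nw = int(within.sum())
    if nw == 0:
        return np.nan
    sw = float(d_cond[within].sum())
    smin = float(d_sorted[:nw].sum())
    smax = float(d_sorted[-nw:].sum())
    return (sw - smin) / (smax - smin) if smax > smin else 0.0


def _point_biserial(d_cond: np.ndarray, labels: np.ndarray) -> float:
    between = ~_pairwise_within_mask(labels)
    if between.all() or not between.any():
        return np.nan
    return float(stats.pointbiserialr(between.astype(float), d_cond)[0])


def _mcclain_rao(d_cond: np.ndarray, labels: np.ndarray) -> float:
    within = _pairwise_within_mask(labels)
    nw, nb = int(within.sum()), int((~within).sum())
    if nw == 0 or nb == 0:
        return np.nan
    return (d_cond[within].mean()) / (d_cond[~within].mean())


DEFAULT_INDICES: tuple[str, ...] = (
    "calinski_harabasz", "silhouette", "davies_bouldin", "dunn", "c_index",
    "gap", "hartigan", "krzanowski_lai", "ball_hall", "point_biserial",
    "mcclain_rao",
)


def select_k(z: pd.DataFrame | np.ndarray, k_range: tuple[int, int] = (2, 8),
             indices: tuple[str, ...] = DEFAULT_INDICES, seed: int = 0,
             gap_b: int = 20) -> tuple[int, pd.DataFrame]:
    """Majority-rule cluster count over a suite of validity indices.

    Each index scores Ward partitions for every k in ``k_range`` and votes
    for its optimal k by its own rule; the chosen k is the modal vote, ties
    broken to the smallest k.  The gap statistic draws ``gap_b`` uniform
    reference datasets from a fixed-seed generator, so the selection is
    deterministic given the data, suite, and seed.

    Returns the chosen k and a table with one row per index (its vote and
    per-k scores).
    """
    if not indices:
        raise ValueError("empty validity-index suite")
    X = np.asarray(z, dtype=float)
    n, p = X.shape
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(f"k_range must lie within [2, {n - 1}], got {k_range}")
    ks = list(range(k_min, k_max + 1))
    # some rules need partitions at k-1 / k+1
    k_lo, k_hi = max(1, k_min - 1), min(n - 1, k_max + 1)
    Z = linkage(X, method="ward", metric="euclidean")
    labels_at = {1: np.ones(n, dtype=int)}
    for k in range(max(2, k_lo), k_hi + 1):
        labels_at[k] = fcluster(Z, t=k, criterion="maxclust")
    W = {k: _within_ss(X, labels_at[k]) for k in labels_at}

    d_cond = pdist(X)
    D = squareform(d_cond)
    d_sorted = np.sort(d_cond)

    gap_vals, gap_se = None, None
    if "gap" in indices:
        rng = np.random.default_rng(seed)
        lo_box, hi_box = X.min(axis=0), X.max(axis=0)
        logW_ref = {k: [] for k in range(max(2, k_lo), k_hi + 1)}
        for _ in range(gap_b):
            ref = rng.uniform(lo_box, hi_box, size=(n, p))
            Zr = linkage(ref, method="ward", metric="euclidean")
            for k in logW_ref:
                lab = fcluster(Zr, t=k, criterion="maxclust")
                logW_ref[k].append(np.log(_within_ss(ref, lab)))
        gap_vals, gap_se = {}, {}
        for k in logW_ref:
            lw = np.asarray(logW_ref[k])
            gap_vals[k] = float(lw.mean() - np.log(W[k]))
            gap_se[k] = float(lw.std(ddof=0) * np.sqrt(1.0 + 1.0 / gap_b))

    rows = []
    for name in indices:
        scores: dict[int, float] = {}
        vote: int | None = None
        if name == "calinski_harabasz":
            scores = {k: calinski_harabasz_score(X, labels_at[k]) for k in ks}
            vote = max(ks, key=lambda k: (scores[k], -k))
        elif name == "silhouette":
            scores = {k: silhouette_score(X, labels_at[k]) for k in ks}
            vote = max(ks, key=lambda k: (scores[k], -k))
        elif name == "davies_bouldin":
            scores = {k: davies_bouldin_score(X, labels_at[k]) for k in ks}
            vote = min(ks, key=lambda k: (scores[k], k))
        elif name == "dunn":
            scores = {k: _dunn(D, labels_at[k]) for k in ks}
            vote = max(ks, key=lambda k: (scores[k], -k))
        elif name == "c_index":
            scores = {k: _c_index(d_cond, d_sorted, labels_at[k]) for k in ks}
            vote = min(ks, key=lambda k: (scores[k], k))
        elif name == "gap":
            scores = {k: gap_vals[k] for k in ks}
            vote = None
            for k in ks:
                nxt = k + 1
                if nxt in gap_vals and scores[k] >= gap_vals[nxt] - gap_se[nxt]:
                    vote = k
                    break
            if vote is None:
                vote = max(ks, key=lambda k: (scores[k], -k))
        elif name == "hartigan":
            scores = {k: (W[k] / W[k + 1] - 1.0) * (n - k - 1)
                      for k in ks if k + 1 in W}
            vote = None
            for k in sorted(scores):
                if scores[k] <= 10.0:
                    vote = k
                    break
            if vote is None:
                vote = min(scores, key=lambda k: (scores[k], k))
        elif name == "krzanowski_lai":
            def diff(k: int) -> float:
                return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]
            scores = {k: abs(diff(k)) / abs(diff(k + 1))
                      for k in ks if k - 1 in W and k + 1 in W and diff(k + 1) != 0}
            vote = max(scores, key=lambda k: (scores[k], -k))
        elif name == "ball_hall":
            bh = {k: W[k] / k for k in W}
            scores = {k: bh[k - 1] - bh[k] for k in ks if k - 1 in bh}
            vote = max(scores, key=lambda k: (scores[k], -k))
        elif name == "point_biserial":
            scores = {k: _point_biserial(d_cond, labels_at[k]) for k in ks}
            vote = max(ks, key=lambda k: (scores[k], -k))
        elif name == "mcclain_rao":
            scores = {k: _mcclain_rao(d_cond, labels_at[k]) for k in ks}
            vote = min(ks, key=lambda k: (scores[k], k))
        else:
            raise ValueError(f"unknown validity index {name!r}")
        rows.append({"index": name, "vote": vote,
                     **{f"k={k}": scores.get(k, np.nan) for k in ks}})
    votes = pd.DataFrame(rows)
    counts = votes["vote"].value_counts()
    top = counts.max()
    chosen_k = int(min(k for k, c in counts.items() if c == top))
    return chosen_k, votes


def characterize(table: pd.DataFrame, labels: np.ndarray,
                 continuous: list[str] | None = None,
                 categorical: list[str] | None = None,
                 alpha: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster summary with group-comparison statistics.

    Continuous variables get per-cluster mean +- SD and a one-way ANOVA p;
    categorical variables get per-cluster counts and a chi-square p.  All
    pairwise two-sided equal-variance t-tests are returned in a long table;
    significance is flagged at the fixed threshold ``alpha`` (default 0.01,
    a Bonferroni-style family-wise guard).
    """
    labels = np.asarray(labels)
    if continuous is None:
        continuous = [c for c in table.columns
                      if table[c].dtype.kind in "fi" and c not in ("true_label",)
                      and not (categorical and c in categorical)]
    categorical = categorical or []
    clusters = np.unique(labels)
    rows, pair_rows = [], []
    for col in continuous:
        groups = [table.loc[labels == c, col].dropna().to_numpy() for c in clusters]
        row = {"variable": col, "kind": "continuous"}
        for c, g in zip(clusters, groups):
            row[f"mean_{c}"] = g.mean() if len(g) else np.nan
            row[f"sd_{c}"] = g.std(ddof=1) if len(g) > 1 else np.nan
        if all(len(g) > 1 for g in groups) and len(groups) > 1:
            res = stats.f_oneway(*groups)
            pv = float(res.pvalue)
            if not np.isfinite(pv) and res.statistic <= 0:
                pv = 1.0  # identical group means: F rounds to -0 in fp
            row["p_value"] = pv
        else:
            row["p_value"] = np.nan
        row["significant"] = bool(row["p_value"] < alpha) if np.isfinite(row["p_value"]) else False
        rows.append(row)
        for i, a in enumerate(clusters):
            for b in clusters[i + 1:]:
                ga, gb = groups[i], groups[list(clusters).index(b)]
                if len(ga) > 1 and len(gb) > 1:
                    t, pv = stats.ttest_ind(ga, gb, equal_var=True)
                    pair_rows.append({"variable": col, "cluster_a": int(a),
                                      "cluster_b": int(b), "t": float(t),
                                      "p_value": float(pv),
                                      "significant": bool(pv < alpha)})
    for col in categorical:
        obs = pd.crosstab(labels, table[col])
        row = {"variable": col, "kind": "categorical"}
        for c in clusters:
            row[f"mean_{c}"] = table.loc[labels == c, col].mean()
            row[f"sd_{c}"] = np.nan
        if obs.shape[1] > 1:
            row["p_value"] = float(stats.chi2_contingency(obs).pvalue)
        else:
            row["p_value"] = np.nan
        row["significant"] = bool(row["p_value"] < alpha) if np.isfinite(row["p_value"]) else False
        rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(pair_rows)


def correlate(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson correlation with two-sided p (t transform) for each column pair."""
    rows = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        r, p = stats.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "r": float(r), "p_value": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)


def run_clustering(table: pd.DataFrame, feature_columns: list[str] | tuple[str, ...],
                   k_range: tuple[int, int] = (2, 8),
                   indices: tuple[str, ...] = DEFAULT_INDICES,
                   seed: int = 0, k: int | None = None) -> ClusterResult:
    """Standardize -> majority-rule k selection -> Ward labels at the chosen k."""
    z, means, sds = standardize(table, feature_columns)
    if k is None:
        chosen_k, votes = select_k(z, k_range=k_range, indices=indices, seed=seed)
    else:
        chosen_k = k
        votes = pd.DataFrame({"index": ["forced"], "vote": [k]})
    labels, Z = ward_cluster(z, chosen_k)
    return ClusterResult(labels=labels, linkage=Z, chosen_k=chosen_k, votes=votes,
                         feature_means=means, feature_sds=sds)
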