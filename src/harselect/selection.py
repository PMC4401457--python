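"""Classifier-independent filter feature selection.

Three filters, run per detail level and per population:

- Relief-F: relevance weights accumulated over every occurrence from the
  squared feature differences to the nearest same-class hit and the nearest
  other-class misses (one miss per contrasting class, weighted by class
  prior).  Distances are Euclidean on min-max normalised features.
- CFS: subset merit k * r_cf / sqrt(k + k(k-1) * r_ff), with feature-class
  and feature-feature correlations measured by symmetrical uncertainty on
  equal-frequency-discretised features (Pearson available behind a switch),
  searched by forward best-first with a stopping criterion of five
  consecutive fully expanded non-improving subsets.
- FCBF: ranks features by symmetrical uncertainty with the class and keeps
  only predominant ones — a kept feature removes any lower-ranked feature
  that correlates with it at least as strongly as with the class.

Relief-F does not use discretisation; the SU-based methods share the same
equal-frequency binning, which makes them invariant to strictly monotone
per-feature transforms.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class FeatureWeights:
    """Relevance weight per feature column, with provenance tags."""

    w: np.ndarray
    method: str = "relief_f"
    level: int | None = None
    population: str | None = None

    def ranking(self) -> np.ndarray:
        """Column indices from highest to lowest weight; ties -> lower index."""
        # stable sort on -w keeps lower indices first among ties
        return np.argsort(-self.w, kind="stable")


@dataclass
class FeatureSubset:
    """Selected feature columns (0-based), in selection order."""

    indices: tuple
    method: str
    merit_or_score: float | None = None
    level: int | None = None
    population: str | None = None

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate feature indices in subset")
        self.indices = idx

    def feature_ids(self) -> tuple:
        """1-based feature ids (registry numbering)."""
        return tuple(i + 1 for i in self.indices)


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0
    return (X - lo) / span


def relief_f(X, y, n_neighbors: int = 1) -> FeatureWeights:
    """Relief-F relevance weights.

    For every occurrence the squared per-feature difference to its nearest
    miss(es) minus the difference to its nearest hit(s) is accumulated.  With
    more than two classes, the nearest misses are found per contrasting
    class and combined weighted by P(c) / (1 - P(class(x))).  With
    ``n_neighbors`` > 1 the k nearest hits/misses are averaged.  All N
    occurrences are used; deterministic (neighbour ties -> lowest row index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("Relief-F needs at least 2 classes")
    if counts.min() < n_neighbors + 1:
        raise ValueError("each class needs at least n_neighbors + 1 occurrences")
    priors = dict(zip(classes, counts / len(y)))
    Xs = _minmax_scale(X)
    n, d = Xs.shape
    D = cdist(Xs, Xs, metric="euclidean")
    np.fill_diagonal(D, np.inf)

    w = np.zeros(d)
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    for j in range(n):
        cj = y[j]
        hits = idx_by_class[cj]
        hits = hits[hits != j]
        order = hits[np.argsort(D[j, hits], kind="stable")][:n_neighbors]
        hit_term = ((Xs[j] - Xs[order]) ** 2).mean(axis=0)
        miss_term = np.zeros(d)
        denom = 1.0 - priors[cj]
        for c in classes:
            if c == cj:
                continue
            cand = idx_by_class[c]
            order = cand[np.argsort(D[j, cand], kind="stable")][:n_neighbors]
            miss_term += (priors[c] / denom) * ((Xs[j] - Xs[order]) ** 2).mean(axis=0)
        w += miss_term - hit_term
    return FeatureWeights(w=w)


def top_k(weights: FeatureWeights, k: int = 10) -> FeatureSubset:
    """The k highest-weight features, ordered by rank (ties -> lower index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d = len(weights.w)
    if k > d:
        raise ValueError(f"k={k} exceeds the {d} available features")
    idx = weights.ranking()[:k]
    return FeatureSubset(
        indices=tuple(idx),
        method=f"{weights.method}_top{k}",
        merit_or_score=float(weights.w[idx].sum()),
        level=weights.level,
        population=weights.population,
    )


# ---------------------------------------------------------------------------
# symmetrical uncertainty on discretised features


@dataclass
class DiscretizedMatrix:
    """Integer-coded occurrence matrix with per-feature quantile bin edges."""

    codes: np.ndarray
    edges: list


def discretize_equal_frequency(X, n_bins: int = 10) -> DiscretizedMatrix:
    """Per-feature equal-frequency (quantile) discretisation.

    Codes are monotone in the feature value, so any strictly monotone
    per-feature transform yields identical codes.  Constant features map to
    a single code 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    codes = np.zeros((n, d), dtype=np.int64)
    edges = []
    for j in range(d):
        col = pd.Series(X[:, j])
        try:
            c, bins = pd.qcut(col, q=n_bins, labels=False, retbins=True,
                              duplicates="drop")
        except ValueError:  # constant column
            c, bins = pd.Series(np.zeros(n)), np.array([X[0, j], X[0, j]])
        codes[:, j] = np.nan_to_num(c.to_numpy(), nan=0.0).astype(np.int64)
        edges.append(np.asarray(bins, dtype=float))
    return DiscretizedMatrix(codes=codes, edges=edges)


def _entropy_from_codes(a: np.ndarray) -> float:
    _, counts = np.unique(a, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def symmetrical_uncertainty(a, b) -> float:
    """SU(a, b) = 2 I(a; b) / (H(a) + H(b)) on discrete series, in [0, 1].

    0 by convention when either series has zero entropy (constant).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    ha, hb = _entropy_from_codes(a), _entropy_from_codes(b)
    if ha <= 0 or hb <= 0:
        return 0.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    pair = ai.astype(np.int64) * (int(bi.max()) + 1) + bi
    hab = _entropy_from_codes(pair)
    mi = ha + hb - hab
    return float(max(0.0, 2.0 * mi / (ha + hb)))


class _CorrelationCache:
    """Lazy feature-class and feature-feature correlations for CFS/FCBF."""

    def __init__(self, X, y, n_bins: int = 10, corr: str = "su"):
        if corr not in ("su", "pearson"):
            raise ValueError("corr must be 'su' or 'pearson'")
        self.corr = corr
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        _, self.y_codes = np.unique(y, return_inverse=True)
        self.codes = discretize_equal_frequency(self.X, n_bins=n_bins).codes
        self._cf = {}
        self._ff = {}

    def feature_class(self, i: int) -> float:
        if i not in self._cf:
            if self.corr == "su":
                self._cf[i] = symmetrical_uncertainty(self.codes[:, i], self.y_codes)
            else:
                self._cf[i] = abs(_safe_pearson(self.X[:, i], self.y_codes))
        return self._cf[i]

    def feature_feature(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._ff:
            if self.corr == "su":
                self._ff[key] = symmetrical_uncertainty(
                    self.codes[:, key[0]], self.codes[:, key[1]]
                )
            else:
                self._ff[key] = abs(_safe_pearson(self.X[:, key[0]], self.X[:, key[1]]))
        return self._ff[key]


def _safe_pearson(a, b) -> float:
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cfs_merit(k: int, r_cf: float, r_ff: float) -> float:
    """Subset merit: k * r_cf / sqrt(k + k(k-1) * r_ff)."""
    if k == 0:
        return 0.0
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _subset_merit(subset: tuple, cache: _CorrelationCache) -> float:
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = float(np.mean([cache.feature_class(i) for i in subset]))
    if k == 1:
        return cfs_merit(1, r_cf, 0.0)
    pairs = list(itertools.combinations(subset, 2))
    r_ff = float(np.mean([cache.feature_feature(i, j) for i, j in pairs]))
    return cfs_merit(k, r_cf, r_ff)


def cfs(
    X,
    y,
    n_bins: int = 10,
    corr: str = "su",
    termination: int = 5,
    max_subset: int | None = None,
) -> FeatureSubset:
    """Correlation-based feature selection by forward best-first search.

    Expands the best-merit open subset by one feature at a time and stops
    after ``termination`` consecutive fully expanded subsets that fail to
    improve on the best merit found.  Ties in merit expand the
    earlier-generated subset first.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("CFS needs at least 2 classes")
    cache = _CorrelationCache(X, y, n_bins=n_bins, corr=corr)
    d = cache.X.shape[1]
    counter = itertools.count()
    start = ()
    open_heap = [(-0.0, next(counter), start)]
    visited = {start}
    best_subset, best_merit = start, 0.0
    non_improving = 0
    while open_heap and non_improving < termination:
        _, _, subset = heapq.heappop(open_heap)
        improved = False
        for j in range(d):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in visited:
                continue
            if max_subset is not None and len(child) > max_subset:
                continue
            visited.add(child)
            merit = _subset_merit(child, cache)
            heapq.heappush(open_heap, (-merit, next(counter), child))
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
        if improved:
            non_improving = 0
        else:
            non_improving += 1
    return FeatureSubset(
        indices=best_subset, method="cfs", merit_or_score=float(best_merit)
    )


def cfs_exhaustive(X, y, n_bins: int = 10, corr: str = "su") -> FeatureSubset:
    """Best-merit subset by exhaustive enumeration (oracle for small d)."""
    cache = _CorrelationCache(X, y, n_bins=n_bins, corr=corr)
    d = cache.X.shape[1]
    if d > 16:
        raise ValueError("exhaustive enumeration is limited to d <= 16")
    best, best_merit = (), 0.0
    for r in range(1, d + 1):
        for subset in itertools.combinations(range(d), r):
            merit = _subset_merit(subset, cache)
            if merit > best_merit + 1e-12:
                best, best_merit = subset, merit
    return FeatureSubset(indices=best, method="cfs_exhaustive",
                         merit_or_score=float(best_merit))


def fcbf(X, y, delta: float = 0.0, n_bins: int = 10) -> FeatureSubset:
    """Fast correlation-based filter.

    Ranks features by SU with the class, discards those <= ``delta``, then
    walks the ranking keeping each remaining (predominant) feature and
    removing every lower-ranked feature f' with SU(f, f') >= SU(f', class).
    Returns the kept features in rank order.  SU values are rounded to 12
    decimals before comparison so that exact ties resolve by feature index
    rather than by floating summation order.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("FCBF needs at least 2 classes")
    cache = _CorrelationCache(X, y, n_bins=n_bins, corr="su")
    d = cache.X.shape[1]
    su_class = np.array([round(cache.feature_class(i), 12) for i in range(d)])
    candidates = [i for i in range(d) if su_class[i] > delta]
    # decreasing SU, ties by lower feature index (stable sort)
    candidates.sort(key=lambda i: (-su_class[i], i))
    kept = []
    remaining = list(candidates)
    while remaining:
        f = remaining.pop(0)
        kept.append(f)
        remaining = [
            q for q in remaining
            if round(cache.feature_feature(f, q), 12) < su_class[q]
        ]
    return FeatureSubset(
        indices=tuple(kept),
        method="fcbf",
        merit_or_score=float(su_class[kept[0]]) if kept else None,
    )


# ---------------------------------------------------------------------------
# selection grid across levels and populations

METHODS = ("relief_top10", "cfs", "fcbf")


def select(method: str, X, y, k: int = 10, n_neighbors: int = 1, **kwargs):
    """Dispatch one selection method on (X, y); returns a FeatureSubset.

    ``relief_top10`` attaches the full weight vector on the returned
    subset's ``weights`` attribute.
    """
    X = np.asarray(X, dtype=float)
    if method == "relief_top10":
        weights = relief_f(X, y, n_neighbors=n_neighbors)
        subset = top_k(weights, k=min(k, X.shape[1]))
        subset.method = "relief_top10"
        subset.weights = weights
        return subset
    if method == "cfs":
        return cfs(X, y, **kwargs)
    if method == "fcbf":
        return fcbf(X, y, **kwargs)
    raise ValueError(f"unknown selection method: {method!r}")


def run_selection_grid(datasets: dict, methods=METHODS, k: int = 10, **kwargs) -> pd.DataFrame:
    """Run every method on every (population, level) dataset.

    ``datasets`` maps (population, level) -> LevelDataset.  Returns a tidy
    DataFrame with one row per (population, level, method) and the selected
    1-based feature ids.  Datasets with fewer than 2 classes are skipped.
    """
    rows = []
    for (population, level), ds in datasets.items():
        if len(set(ds.y)) < 2:
            continue
        for method in methods:
            subset = select(method, ds.X.to_numpy(), ds.y, k=k, **kwargs)
            subset.level, subset.population = level, population
            rows.append(
                {
                    "population": population,
                    "level": level,
                    "method": method,
                    "n_selected": len(subset.indices),
                    "feature_ids": subset.feature_ids(),
                    "score": subset.merit_or_score,
                    "subset": subset,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["population", "level", "method",
                 "n_selected", "feature_ids", "score", "subset"],
    )


def common_features(grid: pd.DataFrame, method: str) -> pd.DataFrame:
    """Cross-population feature intersections per level for one method.

    One row per population pair plus an all-populations row, one column per
    level — the layout of the published common-feature tables.
    """
    sub = grid[grid["method"] == method]
    populations = sorted(sub["population"].unique())
    levels = sorted(sub["level"].unique())
    sets = {
        (p, l): set(r)
        for (p, l), r in sub.set_index(["population", "level"])["feature_ids"].items()
    }
    combos = list(itertools.combinations(populations, 2))
    if len(populations) > 2:
        combos.append(tuple(populations))
    rows = []
    for combo in combos:
        row = {"populations": " & ".join(combo)}
        for l in levels:
            inter = None
            for p in combo:
                s = sets.get((p, l), set())
                inter = s if inter is None else inter & s
            row[f"level_{l}"] = (
                ", ".join(str(i) for i in sorted(inter)) if inter else "n/a"
            )
        rows.append(row)
    return pd.DataFrame(rows)
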