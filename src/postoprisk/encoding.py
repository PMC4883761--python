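"""Outcome-conditional log-likelihood-ratio encoding of nominal features.

Each level x of a nominal feature is replaced by the score

    log [ P(X = x | E = 1) / P(X = x | E = 0) ],

with the class-conditional probabilities estimated from level counts. For a
binary outcome this score is a strictly monotone transform of the level's
event rate, so sorting levels by the score makes the optimal binary split
(by Gini impurity or cross-entropy) achievable as a threshold — the reason
this encoding is preferred over arbitrary integer coding for tree- and
regression-based models.

High-cardinality features yield unreliable per-level estimates, so levels
with fewer than ``min_count`` records are pooled into an "other" group,
which is then subdivided by 1-D k-means on the per-level event proportion
(default 5 clusters); each subgroup is scored on its pooled counts.

A symmetric pseudo-count guards zero cells (the raw formula is the
smoothing -> 0 limit); scores stay finite for every level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class LevelStats:
    """Event/non-event counts for one level of a nominal feature."""

    level: str
    n1: int
    n0: int

    @property
    def total(self) -> int:
        return self.n1 + self.n0

    @property
    def p_hat(self) -> float:
        return self.n1 / self.total


def level_stats(levels: pd.Series | np.ndarray, outcomes: np.ndarray) -> list[LevelStats]:
    levels = pd.Series(levels, dtype=object).reset_index(drop=True)
    outcomes = np.asarray(outcomes)
    tab = pd.crosstab(levels, pd.Series(outcomes, name="E"))
    for cls in (0, 1):
        if cls not in tab.columns:
            tab[cls] = 0
    return [
        LevelStats(level=str(ix), n1=int(row[1]), n0=int(row[0]))
        for ix, row in tab.iterrows()
    ]


def log_likelihood_ratio(
    n1: int, n0: int, N1: int, N0: int, smoothing: float = 0.5
) -> float:
    """log of the smoothed conditional-frequency ratio for one level/group.

    With ``smoothing == 0`` and both counts positive this is exactly
    log[(n1/N1)/(n0/N0)]; a zero cell with zero smoothing raises, signalling
    that smoothing or grouping is required.
    """
    if N1 < 1 or N0 < 1:
        raise ValueError("class totals must be at least 1")
    if smoothing == 0 and (n1 == 0 or n0 == 0):
        raise ValueError("zero cell with zero smoothing gives an infinite score")
    p1 = (n1 + smoothing) / (N1 + 2 * smoothing)
    p0 = (n0 + smoothing) / (N0 + 2 * smoothing)
    return float(np.log(p1 / p0))


def group_rare_levels(
    stats: list[LevelStats], min_count: int = 100
) -> tuple[list[LevelStats], list[LevelStats]]:
    """Partition levels into (kept, other-pool) by total record count.

    Strictly-fewer-than ``min_count`` goes to the pool; the partition is
    exhaustive and disjoint.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = [s for s in stats if s.total >= min_count]
    other = [s for s in stats if s.total < min_count]
    return kept, other


def cluster_other_pool(
    pool: list[LevelStats], n_clusters: int = 5, seed: int = 0
) -> dict[str, int]:
    """1-D k-means on each pooled level's event proportion.

    The effective cluster count is min(n_clusters, number of distinct
    proportions); subgroup ids are relabelled in increasing order of their
    cluster-centre proportion, so ids are deterministic and ordered by risk.
    """
    if not pool:
        raise ValueError("other pool is empty")
    p = np.array([s.p_hat for s in pool]).reshape(-1, 1)
    k = min(n_clusters, len(np.unique(p)))
    if k == 1:
        return {s.level: 0 for s in pool}
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(p)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = {int(old): int(new) for new, old in enumerate(order)}
    return {s.level: relabel[int(lab)] for s, lab in zip(pool, km.labels_)}


@dataclass
class EncodingMap:
    """Fitted level -> (group, score) mapping for one nominal feature."""

    level_to_group: dict[str, str]
    group_scores: dict[str, float]
    fallback_score: float
    min_count: int
    n_clusters: int
    smoothing: float
    seed: int
    cluster_assignments: dict[str, int] = field(default_factory=dict)

    def score(self, level: str) -> float:
        group = self.level_to_group.get(level)
        if group is None:
            return self.fallback_score
        return self.group_scores[group]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "EncodingMap":
        return cls(**json.loads(Path(path).read_text()))


def fit_encoder(
    levels: pd.Series | np.ndarray,
    outcomes: np.ndarray,
    min_count: int = 100,
    n_clusters: int = 5,
    smoothing: float = 0.5,
    seed: int = 0,
) -> EncodingMap:
    """Fit the log-ratio encoding with rare-level grouping and clustering.

    Kept levels are scored individually; pooled "other" subgroups are scored
    on their pooled counts. The fallback for levels unseen at fit time is the
    score of the largest other-subgroup (the most populous low-count stratum);
    if no level was pooled, the whole-feature marginal score (zero) is used.
    """
    outcomes = np.asarray(outcomes)
    classes = np.unique(outcomes)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("outcome must be binary with both classes present")
    stats = level_stats(levels, outcomes)
    N1 = int(outcomes.sum())
    N0 = int(len(outcomes) - N1)

    kept, pool = group_rare_levels(stats, min_count=min_count)
    level_to_group: dict[str, str] = {}
    group_scores: dict[str, float] = {}
    for s in kept:
        level_to_group[s.level] = s.level
        group_scores[s.level] = log_likelihood_ratio(s.n1, s.n0, N1, N0, smoothing)

    cluster_assignments: dict[str, int] = {}
    fallback = 0.0
    if pool:
        cluster_assignments = cluster_other_pool(pool, n_clusters=n_clusters, seed=seed)
        by_sub: dict[int, list[LevelStats]] = {}
        for s in pool:
            by_sub.setdefault(cluster_assignments[s.level], []).append(s)
        largest_sub, largest_n = None, -1
        for sub, members in sorted(by_sub.items()):
            gname = f"__other_{sub}__"
            g1 = sum(m.n1 for m in members)
            g0 = sum(m.n0 for m in members)
            group_scores[gname] = log_likelihood_ratio(g1, g0, N1, N0, smoothing)
            for m in members:
                level_to_group[m.level] = gname
            if g1 + g0 > largest_n:
                largest_n, largest_sub = g1 + g0, gname
        fallback = group_scores[largest_sub]

    return EncodingMap(
        level_to_group=level_to_group,
        group_scores=group_scores,
        fallback_score=fallback,
        min_count=min_count,
        n_clusters=n_clusters,
        smoothing=smoothing,
        seed=seed,
        cluster_assignments=cluster_assignments,
    )


def apply_encoder(enc: EncodingMap, levels: pd.Series | np.ndarray) -> np.ndarray:
    """Elementwise score lookup with fallback for unseen levels."""
    arr = pd.Series(levels, dtype=object)
    return np.array([enc.score(v) for v in arr], dtype=float)
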