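import numpy as np
import pytest

import postoprisk as pk


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default cohort shared by read-only tests."""
    spec = pk.default_cohort_spec(n_patients=4000, seed=0)
    cohort, tm = pk.generate_cohort(spec)
    return cohort, tm


@pytest.fixture(scope="session")
def corrupted_cohort(default_cohort):
    cohort, tm = default_cohort
    c = pk.inject_missingness(cohort, 0.05, seed=101)
    c, record = pk.inject_outliers(c, 0.01, 10.0, seed=102)
    return c, tm, record


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration oracle for the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        total += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return total / (len(pos) * len(neg))


def gini_impurity(n1, n0):
    n = n1 + n0
    if n == 0:
        return 0.0
    p = n1 / n
    return 2 * p * (1 - p)


def best_partition_gini(stats):
    """Brute-force best binary partition of levels by weighted Gini impurity.

    ``stats`` is a list of (n1, n0) per level. Returns the minimum achievable
    weighted impurity over all 2^(k-1)-1 binary partitions.
    """
    k = len(stats)
    n_total = sum(a + b for a, b in stats)
    best = np.inf
    for mask in range(1, 2 ** (k - 1)):
        left1 = left0 = right1 = right0 = 0
        for i, (a, b) in enumerate(stats):
            if (mask >> i) & 1:
                left1 += a
                left0 += b
            else:
                right1 += a
                right0 += b
        nl, nr = left1 + left0, right1 + right0
        if nl == 0 or nr == 0:
            continue
        imp = (
            nl * gini_impurity(left1, left0) + nr * gini_impurity(right1, right0)
        ) / n_total
        best = min(best, imp)
    return best


def best_threshold_gini(scores_per_level, stats):
    """Best weighted Gini impurity over threshold splits of the encoded score."""
    order = np.argsort(scores_per_level)
    n_total = sum(a + b for a, b in stats)
    best = np.inf
    for cut in range(1, len(order)):
        left = [stats[i] for i in order[:cut]]
        right = [stats[i] for i in order[cut:]]
        l1 = sum(a for a, _ in left)
        l0 = sum(b for _, b in left)
        r1 = sum(a for a, _ in right)
        r0 = sum(b for _, b in right)
        imp = (
            (l1 + l0) * gini_impurity(l1, l0) + (r1 + r0) * gini_impurity(r1, r0)
        ) / n_total
        best = min(best, imp)
    return best
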