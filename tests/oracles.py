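"""Independent brute-force oracles used to verify the implementation.

These deliberately use naive enumeration / hand-rolled arithmetic and never
call the code paths they check.
"""

import math
import statistics


def brute_force_stump(x, y):
    """Exhaustively enumerate midpoint splits minimizing weighted Gini.

    Returns ``(weighted_gini, threshold)`` of the best split, or
    ``(root_gini, None)`` when no split beats the root node.  Ties pick
    the smallest threshold.
    """
    def gini(labels):
        if not labels:
            return 0.0
        p1 = sum(labels) / len(labels)
        return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)

    pairs = sorted(zip(x, y))
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    n = len(xs)
    root = gini(ys)
    best = (root, None)
    for i in range(n - 1):
        if xs[i] == xs[i + 1]:
            continue
        thr = (xs[i] + xs[i + 1]) / 2.0
        left = [ys[j] for j in range(n) if xs[j] < thr]
        right = [ys[j] for j in range(n) if xs[j] >= thr]
        w = (len(left) * gini(left) + len(right) * gini(right)) / n
        if w < best[0] - 1e-12:
            best = (w, thr)
    return best


def brute_mcc(tp, tn, fp, fn):
    """Matthews' correlation straight from the defining formula."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom


def brute_median_mad(values):
    """Sort-based median and unscaled MAD."""
    med = statistics.median(sorted(values))
    return med, statistics.median(sorted(abs(v - med) for v in values))


def brute_soft_vote(votes):
    """Accumulate (class, prob) votes; ties elect class 0."""
    score = [0.0, 0.0]
    for cls, prob in votes:
        score[cls] += prob
    return (1 if score[1] > score[0] else 0), score[0], score[1]
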