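"""Brute-force evaluation oracle, independent of the package internals.

Every statistic is recomputed by literal enumeration over all rank cutoffs
using set operations only — no shared code with csmetapred.evaluation.
"""

from __future__ import annotations


def enumerate_confusion(order, positives, n):
    """Confusion counts with the first n of `order` called positive."""
    called = set(order[:n])
    rest = set(order[n:])
    pos = set(positives)
    tp = len(called & pos)
    fp = len(called - pos)
    fn = len(rest & pos)
    tn = len(rest - pos)
    return tp, fp, tn, fn


def oracle_roc_points(order, positives):
    """(FPR, TPR) at every cutoff 0..N."""
    points = [(0.0, 0.0)]
    npos = len(set(positives))
    nneg = len(order) - npos
    for n in range(1, len(order) + 1):
        tp, fp, tn, fn = enumerate_confusion(order, positives, n)
        points.append((fp / nneg, tp / npos))
    return points


def oracle_pr_points(order, positives):
    """(recall, precision) at every cutoff where a positive is retrieved."""
    npos = len(set(positives))
    points = []
    for n in range(1, len(order) + 1):
        if order[n - 1] in set(positives):
            tp, fp, tn, fn = enumerate_confusion(order, positives, n)
            points.append((tp / npos, tp / (tp + fp)))
    return points


def oracle_aves(order, positives):
    """Sum of specificity at each catalytic residue's own rank, over Npos."""
    npos = len(set(positives))
    total = 0.0
    for n in range(1, len(order) + 1):
        if order[n - 1] in set(positives):
            tp, fp, tn, fn = enumerate_confusion(order, positives, n)
            total += tn / (tn + fp)
    return total / npos


def oracle_ap(order, positives):
    """Mean precision at each catalytic residue's retrieval rank."""
    npos = len(set(positives))
    total = 0.0
    for n in range(1, len(order) + 1):
        if order[n - 1] in set(positives):
            tp, fp, tn, fn = enumerate_confusion(order, positives, n)
            total += tp / (tp + fp)
    return total / npos
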