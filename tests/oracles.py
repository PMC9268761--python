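"""Independent straight-line oracles used by the test suite.

These deliberately avoid the package's own code paths: similarity by
explicit per-pair contingency tallies, WPGMA by a dict-based transcription
of the recurrence, locus classes by raw column sums.
"""

from __future__ import annotations

import itertools

import numpy as np


def contingency_tally(row_i, row_j):
    """(a, b, c, d) counts for two binary band profiles, one locus at a time."""
    a = b = c = d = 0
    for x, y in zip(row_i, row_j):
        if x and y:
            a += 1
        elif x and not y:
            b += 1
        elif y and not x:
            c += 1
        else:
            d += 1
    return a, b, c, d


def dice_pair(row_i, row_j):
    a, b, c, _ = contingency_tally(row_i, row_j)
    return 2 * a / (2 * a + b + c)


def jaccard_pair(row_i, row_j):
    a, b, c, _ = contingency_tally(row_i, row_j)
    return a / (a + b + c)


def simple_matching_pair(row_i, row_j):
    a, b, c, d = contingency_tally(row_i, row_j)
    return (a + d) / (a + b + c + d)


def locus_class_counts(matrix):
    """(monomorphic, polymorphic, unique) counts by raw column sums."""
    arr = np.asarray(matrix)
    n = arr.shape[0]
    sums = arr.sum(axis=0)
    mono = int((sums == n).sum())
    uniq = int((sums == 1).sum())
    poly = int(((sums >= 1) & (sums < n)).sum())
    return mono, poly, uniq


def wpgma_merges(labels, dmat):
    """Straight-line WPGMA: list of (height, side_a, side_b) per step.

    Same recurrence and tie-break convention as the implementation under
    test, written independently over plain dicts of label frozensets.
    """
    labels = list(labels)
    dmat = np.asarray(dmat, dtype=float)
    active = [frozenset([l]) for l in labels]
    idx = {l: i for i, l in enumerate(labels)}
    dist = {}
    for x, y in itertools.combinations(active, 2):
        (lx,), (ly,) = x, y
        dist[frozenset((x, y))] = dmat[idx[lx], idx[ly]]
    merges = []
    while len(active) > 1:
        def key(pair):
            x, y = sorted(pair, key=lambda c: min(c))
            return (dist[frozenset((x, y))], min(x), min(y))

        pairs = [frozenset((x, y)) for x, y in itertools.combinations(active, 2)]
        best = min(pairs, key=key)
        x, y = sorted(best, key=lambda c: min(c))
        h = dist[frozenset((x, y))] / 2.0
        merged = x | y
        merges.append((h, x, y))
        for z in active:
            if z in (x, y):
                continue
            dist[frozenset((merged, z))] = (
                dist[frozenset((x, z))] + dist[frozenset((y, z))]
            ) / 2.0
        active = [z for z in active if z not in (x, y)] + [merged]
    return merges


def wpgma_cophenetic(labels, dmat):
    """Cophenetic matrix implied by the oracle merge sequence."""
    labels = list(labels)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for h, side_a, side_b in wpgma_merges(labels, dmat):
        for a in side_a:
            for b in side_b:
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2 * h
    return out


def random_distance_matrix(rng, n):
    """Random symmetric non-negative matrix with zero diagonal."""
    a = rng.random((n, n)) * 10
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
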