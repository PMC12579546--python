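"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: explicit loops, python sorts and
full enumeration.  None of it shares code with the implementation under
test.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def gotoh_identity(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
    """Affine-gap global alignment by dynamic programming with traceback.

    Returns (identity fraction over the full alignment length, score).
    """
    n, m = len(a), len(b)
    neg = -math.inf
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM[a[i - 1], b[j - 1]])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
    # traceback counting identities and columns
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    identities = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == "M":
            if a[i - 1] == b[j - 1]:
                identities += 1
            s = float(_BLOSUM[a[i - 1], b[j - 1]])
            prev = M[state_i := i - 1][state_j := j - 1]
            for cand in ("M", "X", "Y"):
                if abs({"M": M, "X": X, "Y": Y}[cand][i - 1][j - 1] + s - M[i][j]) < 1e-9:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            if abs(M[i - 1][j] - gap_open - X[i][j]) < 1e-9:
                state = "M"
            i -= 1
        else:
            if abs(M[i][j - 1] - gap_open - Y[i][j]) < 1e-9:
                state = "M"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return identities / columns, score


def bf_average_precision(scores, labels) -> float:
    """AP by explicit rank walk (stable descending sort)."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    hits = 0
    precisions = []
    for rank, idx in enumerate(order, start=1):
        if labels[idx]:
            hits += 1
            precisions.append(hits / rank)
    assert precisions, "no positives"
    return sum(precisions) / len(precisions)


def bf_macro_ap(values, site_ids, kinase_ids, site_labels):
    per = {}
    for j, k in enumerate(kinase_ids):
        labels = [k in site_labels.get(s, set()) for s in site_ids]
        if any(labels):
            per[k] = bf_average_precision([row[j] for row in values], labels)
    return sum(per.values()) / len(per), per


def bf_phosphosite_ap(values, site_ids, kinase_ids, site_labels):
    aps = []
    for i, s in enumerate(site_ids):
        labels = [k in site_labels.get(s, set()) for k in kinase_ids]
        if any(labels):
            aps.append(bf_average_precision(list(values[i]), labels))
    return sum(aps) / len(aps)


def bf_aggregated_ap(values, site_ids, kinase_ids, site_labels, mapping):
    classes = sorted({mapping[k] for k in kinase_ids})
    pooled = []
    for row in values:
        pooled.append(
            [
                max(row[j] for j, k in enumerate(kinase_ids) if mapping[k] == c)
                for c in classes
            ]
        )
    class_labels = {
        s: {mapping[k] for k in site_labels.get(s, set())} for s in site_ids
    }
    macro, _ = bf_macro_ap(pooled, site_ids, classes, class_labels)
    return macro


def bf_masked_group_ap(values, site_ids, kinase_ids, site_labels, group_mapping):
    masked = []
    for i, s in enumerate(site_ids):
        allowed = {group_mapping[k] for k in site_labels.get(s, set())}
        masked.append(
            [
                values[i][j] if group_mapping[k] in allowed else -math.inf
                for j, k in enumerate(kinase_ids)
            ]
        )
    macro, _ = bf_macro_ap(masked, site_ids, kinase_ids, site_labels)
    return macro


def bf_hit_at_k(values, site_ids, kinase_ids, site_labels, k):
    hits = 0
    for i, s in enumerate(site_ids):
        order = sorted(range(len(kinase_ids)), key=lambda j: (-values[i][j], j))
        top = {kinase_ids[j] for j in order[:k]}
        if top & site_labels.get(s, set()):
            hits += 1
    return hits / len(site_ids)


def bf_knn_scores(site_vec, pairs, site_vectors, kinase_vectors, dark_ids, k):
    """Brute-force zero-shot k-NN: enumerate neighbours, vote, transfer."""

    def cos(u, v):
        u, v = np.asarray(u, float), np.asarray(v, float)
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

    sims = [cos(site_vec, site_vectors[s]) for s, _ in pairs]
    order = sorted(range(len(pairs)), key=lambda i: (-sims[i], i))
    neighbour_labels = [pairs[i][1] for i in order[:k]]
    counts = Counter(neighbour_labels)
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    light = winners[0] if len(winners) == 1 else neighbour_labels[0]
    return [cos(kinase_vectors[light], kinase_vectors[d]) for d in dark_ids]


def exhaustive_random_ap(site_labels, site_ids, n_kinases_total, kinase):
    """Exact expected AP of one kinase column under random per-site ranks.

    Enumerates every assignment of distinct ranks to sites?  No: under the
    random-ranking model each site independently gets a uniform score for
    the kinase; only the relative order of sites matters, and all site
    orderings are equally likely.  So the expectation is the mean of AP
    over all permutations of the site list.
    """
    labels = [kinase in site_labels.get(s, set()) for s in site_ids]
    n = len(site_ids)
    values = []
    for perm in itertools.permutations(range(n)):
        ordered = [labels[i] for i in perm]
        hits = 0
        precisions = []
        for rank, flag in enumerate(ordered, start=1):
            if flag:
                hits += 1
                precisions.append(hits / rank)
        values.append(sum(precisions) / len(precisions))
    return sum(values) / len(values)
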