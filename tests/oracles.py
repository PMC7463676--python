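"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — straight-line formula evaluation,
O(n^3) agglomeration, double loops — and shares no code with the package
paths it verifies.
"""

from __future__ import annotations

import math

import numpy as np


# ---- straight-line index formulas -----------------------------------------

def auc_trapz(times, values):
    total = 0.0
    for i in range(len(times) - 1):
        total += (times[i + 1] - times[i]) * (values[i] + values[i + 1]) / 2.0
    return total


def igi(g0, g30, i0, i30):
    return (i30 - i0) / (g30 - g0)


def matsuda_ref(g, i):
    gm = [x * 18.016 for x in g]
    im = [x / 6.0 for x in i]
    gbar = sum(gm) / 3.0
    ibar = sum(im) / 3.0
    return 10000.0 / math.sqrt(gm[0] * im[0] * gbar * ibar)


def liver_ir_ref(auc_ins_0_120, fat_mass, hdl, bmi):
    return (
        -0.091
        + math.log10(auc_ins_0_120) * 0.400
        + math.log10(fat_mass) * 0.346
        - math.log10(hdl) * 0.408
        + math.log10(bmi) * 0.435
    )


def isi_ffa_ref(auc_ins, auc_ffa):
    return 2.0 / ((auc_ins * 1e-4) * (auc_ffa / 30.0) + 1.0)


def nafld_fls_ref(mets, t2d, i0_pmol):
    return (
        -2.889
        + 1.179 * (1.0 if mets else 0.0)
        + 0.454 * (2.0 if t2d else 0.0)
        + 0.145 * (i0_pmol / 6.0)
    )


def fli_ref(tg, bmi, waist):
    lin = 0.953 * math.log(tg) + 0.139 * bmi + 0.053 * waist - 15.745
    return math.exp(lin) / (1.0 + math.exp(lin)) * 100.0


def egfr_ref(scr, age, sex):
    kappa = 0.7 if sex == "female" else 0.9
    alpha = -0.329 if sex == "female" else -0.411
    value = (
        141.0
        * min(scr / kappa, 1.0) ** alpha
        * max(scr / kappa, 1.0) ** -1.209
        * 0.993**age
    )
    return value * 1.018 if sex == "female" else value


# ---- brute-force Ward (D2 criterion) ---------------------------------------

def ward_bruteforce(X):
    """O(n^3) agglomeration minimizing the Ward.D2 merge distance
    sqrt(2|A||B|/(|A|+|B|)) * ||centroid_A - centroid_B||.

    Returns (heights, partitions) where partitions[k] is the set of
    frozensets of leaf indices forming the k-cluster partition.
    """
    X = np.asarray(X, dtype=float)
    clusters = [frozenset([i]) for i in range(len(X))]
    heights = []
    partitions = {len(clusters): set(clusters)}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A, B = clusters[a], clusters[b]
                ca = X[list(A)].mean(axis=0)
                cb = X[list(B)].mean(axis=0)
                na, nb = len(A), len(B)
                d = math.sqrt(2.0 * na * nb / (na + nb)) * float(
                    np.linalg.norm(ca - cb)
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        heights.append(d)
        partitions[len(clusters)] = set(clusters)
    return heights, partitions


# ---- double-loop silhouette -------------------------------------------------

def silhouette_bruteforce(X, labels):
    """Mean silhouette width, computed point by point; singleton clusters
    score 0 (the common convention)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.linalg.norm(X[i] - X[j])
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = math.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(D[i, j] for j in members) / len(members))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


# ---- online k-means ---------------------------------------------------------

def online_kmeans(X, init, orders, alphas, feat_w=None):
    """Sequential winner-take-all updates: per visit the nearest centroid
    (under the optionally feature-weighted squared metric) moves by
    alpha * (x - c). ``orders``: (epochs, n) visit order."""
    C = np.asarray(init, dtype=float).copy()
    X = np.asarray(X, dtype=float)
    w_ = np.ones(X.shape[1]) if feat_w is None else np.asarray(feat_w)
    for t in range(len(alphas)):
        for i in orders[t]:
            d = (w_ * (C - X[i]) ** 2).sum(axis=1)
            winner = int(np.argmin(d))
            C[winner] += alphas[t] * (X[i] - C[winner])
    return C
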