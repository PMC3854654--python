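"""Independent oracles: literal transcriptions and brute-force references.

These deliberately avoid the package's vectorised code paths: plain Python
loops over event times for the weighted test, exhaustive enumeration of
medoid subsets for PAM, and scipy's (nearest-neighbour-chain) agglomeration
for the hierarchical step.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2


def transcription_statistic(records_a, records_b, scheme="logrank"):
    """Literal loop transcription of the weighted two-sample U/V sums."""
    times = [(r.time, r.event, "a") for r in records_a] + [
        (r.time, r.event, "b") for r in records_b
    ]
    event_times = sorted({t for t, e, _ in times if e == 1})
    u = 0.0
    v = 0.0
    for tj in event_times:
        n_j = sum(1 for t, _, _ in times if t >= tj)
        n_aj = sum(1 for t, _, g in times if t >= tj and g == "a")
        d_j = sum(1 for t, e, _ in times if t == tj and e == 1)
        d_aj = sum(1 for t, e, g in times if t == tj and e == 1 and g == "a")
        if scheme == "logrank":
            w = 1.0
        elif scheme == "gehan_wilcoxon":
            w = float(n_j)
        elif scheme == "tarone_ware":
            w = float(n_j) ** 0.5
        else:
            raise ValueError(scheme)
        u += w * (d_aj - n_aj * d_j / n_j)
        if n_j > 1:
            v += (
                w * w
                * (n_aj / n_j)
                * (1 - n_aj / n_j)
                * ((n_j - d_j) / (n_j - 1))
                * d_j
            )
    if v == 0.0:
        return 0.0, 1.0, True
    stat = u * u / v
    return stat, float(chi2.sf(stat, 1)), False


def exhaustive_pam_optimum(values, k):
    """Global optimum of the k-medoid objective by enumerating all subsets."""
    n = values.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        obj = values[list(medoids), :].min(axis=0).sum()
        best = min(best, obj)
    return float(best)


def scipy_merge_tree(values, method):
    """Merge sequence (member sets + heights) from scipy's agglomeration."""
    z = scipy_linkage(squareform(values, checks=False), method=method)
    n = values.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _) in enumerate(z):
        ma, mb = members[int(a)], members[int(b)]
        merges.append((ma, mb, float(h)))
        members[n + row_idx] = ma | mb
    return merges


def naive_cophenetic(merges, n):
    values = np.zeros((n, n))
    for a, b, h in merges:
        for i in a:
            for j in b:
                values[i, j] = values[j, i] = h
    return values
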