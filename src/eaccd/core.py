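"""Ensemble consensus clustering of survival cohorts.

The method runs in three steps:

1.  **Initial dissimilarity** — pairwise weighted two-sample survival
    statistics between cohorts (``initial_dissimilarity``).
2.  **Learnt dissimilarity** — the initial matrix is repeatedly partitioned
    by PAM (k-medoids) with a random number of clusters K drawn uniformly
    from [k_min, k_max] and random initial medoids; the consensus
    dissimilarity of a pair is the fraction of the m runs that place the
    pair in *different* clusters (``ensemble_dissimilarity``).  It lies in
    [0, 1] by construction.
3.  **Hierarchical clustering** — agglomeration of the consensus matrix
    under single/complete/average linkage (``agglomerate``), producing the
    dendrogram that summarises the survival structure.

``run_eaccd`` composes the three steps and returns every intermediate.
"""

from __future__ import annotations

import enum
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .survival import CombinationCohort, WeightScheme, weighted_two_sample_test

__all__ = [
    "Linkage",
    "DissimilarityMatrix",
    "Partition",
    "EnsembleConfig",
    "MergeTree",
    "initial_dissimilarity",
    "pam_partition",
    "ensemble_dissimilarity",
    "agglomerate",
    "cut_tree",
    "cophenetic_matrix",
    "run_eaccd",
    "EaccdResult",
]

logger = logging.getLogger("eaccd")


class Linkage(str, enum.Enum):
    AVERAGE = "average"
    COMPLETE = "complete"
    SINGLE = "single"


# ---------------------------------------------------------------------------
# Dissimilarity matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric nonnegative pairwise dissimilarity over labelled items."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("entries must be nonnegative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def off_diagonal(self) -> np.ndarray:
        """Condensed vector of the strictly-upper-triangle entries."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def standardized(self) -> "DissimilarityMatrix":
        """Divide all entries by the global maximum (which becomes 1)."""
        mx = float(self.values.max())
        if mx <= 0:
            raise ValueError("no separation: all dissimilarities are zero")
        return DissimilarityMatrix(self.labels, self.values / mx)


# ---------------------------------------------------------------------------
# PAM (k-medoids)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """A k-medoids partition: assignment to clusters 1..K plus medoids.

    ``objective`` is the (unscaled) within-cluster scatter
    ``sum_i dis(x_i, medoid of cluster(x_i))``.
    """

    assignment: tuple
    medoids: tuple
    objective: float

    @property
    def k(self) -> int:
        return len(self.medoids)

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)


def _pam_assign(values: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment, ties to the lowest medoid index.

    Each medoid is always assigned to itself so every cluster is nonempty
    even when two medoids coincide at zero dissimilarity.
    """
    med = np.sort(medoids)
    rows = values[med]  # (k, n)
    nearest = rows.argmin(axis=0)  # argmin takes the first (lowest med index)
    nearest[med] = np.arange(len(med))
    obj = float(rows[nearest, np.arange(values.shape[0])].sum())
    return nearest, obj


def pam_partition(
    dis: DissimilarityMatrix,
    k: int,
    init: str = "random",
    rng: np.random.Generator | None = None,
) -> Partition:
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    ``init="random"`` draws k distinct medoids uniformly (requires ``rng``);
    ``init="build"`` uses the deterministic greedy BUILD phase (the classic
    default, as in R's ``pam``).  A steepest-descent swap phase then
    exchanges one medoid with one non-medoid while the objective strictly
    decreases; ties in swap choice and assignment break to the lowest index,
    so the result is fully determined by the initial medoid set.
    """
    n = dis.n
    values = dis.values
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if init == "random":
        if rng is None:
            raise ValueError("random init requires an rng")
        medoids = np.sort(rng.choice(n, size=k, replace=False))
    elif init == "build":
        medoids = _pam_build(values, k)
    else:
        raise ValueError(f"unknown init {init!r}")

    medoids, nearest, obj = _pam_swap(values, medoids)
    # cluster ids 1..K in ascending medoid-index order
    assignment = tuple(int(c) + 1 for c in nearest)
    return Partition(assignment=assignment, medoids=tuple(int(m) for m in medoids), objective=obj)


def _pam_build(values: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: first medoid minimises total dissimilarity, each
    further medoid maximises the resulting decrease in the objective."""
    n = values.shape[0]
    medoids = [int(values.sum(axis=1).argmin())]
    dnear = values[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - values, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(gains.argmax())  # argmax takes lowest index on ties
        medoids.append(cand)
        dnear = np.minimum(dnear, values[cand])
    return np.sort(np.array(medoids))


def _pam_swap(values: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Steepest-descent swap phase; returns (medoids, nearest, objective)."""
    n = values.shape[0]
    medoids = np.sort(np.asarray(medoids))
    k = len(medoids)
    nearest, obj = _pam_assign(values, medoids)
    if k == n:
        return medoids, nearest, obj
    while True:
        rows = values[medoids]  # (k, n)
        order = np.argsort(rows, axis=0, kind="stable")
        d1 = rows[order[0], np.arange(n)]
        which = order[0]
        d2 = rows[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        non_med = np.nonzero(~in_medoids)[0]
        best_obj = obj
        best_swap = None
        for h_pos in range(k):
            # distance to nearest medoid excluding medoid h
            base = np.where(which == h_pos, d2, d1)
            cand_obj = np.minimum(base[None, :], values[non_med]).sum(axis=1)
            j_pos = int(cand_obj.argmin())
            if cand_obj[j_pos] < best_obj - 1e-12:
                best_obj = float(cand_obj[j_pos])
                best_swap = (h_pos, int(non_med[j_pos]))
        if best_swap is None:
            break
        h_pos, j = best_swap
        medoids = np.sort(np.concatenate([np.delete(medoids, h_pos), [j]]))
        obj = best_obj
    nearest, obj = _pam_assign(values, medoids)
    return medoids, nearest, obj


# ---------------------------------------------------------------------------
# Step 1: initial dissimilarity
# ---------------------------------------------------------------------------


def initial_dissimilarity(
    cohorts: Sequence[CombinationCohort],
    test: WeightScheme | str = WeightScheme.LOGRANK,
) -> DissimilarityMatrix:
    """Pairwise survival-test statistics between cohorts.

    Entry (i, j) is the chi-square-form weighted two-sample statistic
    between cohort i and cohort j; a degenerate pair (zero variance) gets
    entry 0 and a logged warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    n = len(cohorts)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = weighted_two_sample_test(cohorts[i].records, cohorts[j].records, test)
            if res.degenerate:
                logger.warning(
                    "degenerate test between %s and %s: dissimilarity set to 0",
                    cohorts[i].label,
                    cohorts[j].label,
                )
            values[i, j] = values[j, i] = res.statistic
    return DissimilarityMatrix(tuple(c.label for c in cohorts), values)


# ---------------------------------------------------------------------------
# Step 2: learnt (consensus) dissimilarity
# ---------------------------------------------------------------------------

Partitioner = Callable[[DissimilarityMatrix, int, np.random.Generator], Partition]


def _pam_random_partitioner(
    dis: DissimilarityMatrix, k: int, rng: np.random.Generator
) -> Partition:
    return pam_partition(dis, k, init="random", rng=rng)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the consensus (dissimilarity-learning) step.

    ``m`` randomized partition runs; each run draws K uniformly from the
    inclusive integer interval [k_min, k_max] and a partitioner uniformly
    from ``partitioners`` (default: PAM with random medoid initialisation
    only).  ``seed`` makes the whole ensemble reproducible.
    """

    m: int = 10000
    k_min: int = 2
    k_max: int = 11
    partitioners: tuple = (_pam_random_partitioner,)
    seed: int = 0

    def validate(self, n: int) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (2 <= self.k_min <= self.k_max <= n - 1):
            raise ValueError(
                f"need 2 <= k_min <= k_max <= n-1; got [{self.k_min}, {self.k_max}] with n={n}"
            )
        if len(self.partitioners) == 0:
            raise ValueError("need at least one partitioner")


def ensemble_dissimilarity(
    dis0: DissimilarityMatrix, config: EnsembleConfig
) -> DissimilarityMatrix:
    """Consensus dissimilarity: fraction of runs separating each pair.

    For each of the m runs, K and a partitioner are drawn at random and the
    initial matrix is partitioned; pair (i, j) scores 1 when the run puts i
    and j in different clusters.  The output averages these indicators, so
    entries lie in [0, 1] with zero diagonal.

    PAM's outcome is fully determined by (K, initial medoid set), so
    repeated draws are memoized; this affects runtime only.
    """
    n = dis0.n
    config.validate(n)
    rng = np.random.default_rng(config.seed)
    single_pam = config.partitioners == (_pam_random_partitioner,)
    label_counts: Counter = Counter()
    cache: dict = {}
    for _ in range(config.m):
        k = int(rng.integers(config.k_min, config.k_max + 1))
        idx = int(rng.integers(len(config.partitioners))) if len(config.partitioners) > 1 else 0
        if single_pam:
            init = tuple(int(x) for x in np.sort(rng.choice(n, size=k, replace=False)))
            key = (k, init)
            if key not in cache:
                med, nearest, _ = _pam_swap(dis0.values, np.array(init))
                cache[key] = tuple(int(c) for c in nearest)
            label_counts[cache[key]] += 1
        else:
            part = config.partitioners[idx](dis0, k, rng)
            label_counts[tuple(part.assignment)] += 1

    diff = np.zeros((n, n))
    for labels, count in label_counts.items():
        lab = np.asarray(labels)
        diff += count * (lab[:, None] != lab[None, :])
    values = diff / config.m
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(dis0.labels, values)


# ---------------------------------------------------------------------------
# Step 3: hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergeTree:
    """A dendrogram as an ordered list of merges.

    Each merge is ``(members_a, members_b, height)`` with members given as
    sorted tuples of leaf indices; the sequence has ``n_leaves - 1`` entries
    and the final merge unites all leaves.  Heights are non-decreasing for
    single/complete/average linkage on a proper dissimilarity.
    """

    labels: tuple
    merges: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def topology(self) -> frozenset:
        """Set of internal-node leaf sets; equal topologies compare equal."""
        return frozenset(frozenset(a) | frozenset(b) for a, b, _ in self.merges)

    def to_json(self) -> str:
        """Serialise as a JSON list of {left, right, height} merges."""
        payload = {
            "labels": list(self.labels),
            "merges": [
                {
                    "left": [self.labels[i] for i in a],
                    "right": [self.labels[i] for i in b],
                    "height": h,
                }
                for a, b, h in self.merges
            ],
        }
        return json.dumps(payload, indent=1)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights.

        Leaves sit at height 0; a branch length is the difference between
        the parent's and the child's merge height.
        """
        node_repr: dict = {(i,): (self.labels[i], 0.0) for i in range(self.n_leaves)}
        rep = None
        for a, b, h in self.merges:
            ra, ha = node_repr.pop(tuple(a))
            rb, hb = node_repr.pop(tuple(b))
            rep = f"({ra}:{h - ha:.17g},{rb}:{h - hb:.17g})"
            node_repr[tuple(sorted(a + b))] = (rep, h)
        return rep + ";"


def _cluster_linkage(values: np.ndarray, a: tuple, b: tuple, linkage: Linkage) -> float:
    block = values[np.ix_(a, b)]
    if linkage is Linkage.AVERAGE:
        return float(block.mean())
    if linkage is Linkage.COMPLETE:
        return float(block.max())
    return float(block.min())


def agglomerate(dis: DissimilarityMatrix, linkage: Linkage | str = Linkage.AVERAGE) -> MergeTree:
    """Agglomerative hierarchical clustering of a dissimilarity matrix.

    Inter-cluster dissimilarity is the mean (average), max (complete) or min
    (single) over cross pairs, recomputed from the input matrix.  When two
    candidate merges share the minimal linkage value, the pair with the
    lexicographically smallest (smallest-leaf-index) representation merges
    first, making the tree deterministic and comparable across runs.
    """
    linkage = Linkage(linkage)
    n = dis.n
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")
    clusters: list[tuple] = [(i,) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _cluster_linkage(dis.values, clusters[i], clusters[j], linkage)
                key = (d, clusters[i][0], clusters[j][0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, d))
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(tuple(sorted(a + b)))
        clusters.sort(key=lambda c: c[0])
    return MergeTree(labels=dis.labels, merges=tuple(merges))


def cut_tree(tree: MergeTree, k: int) -> dict:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns a map label -> cluster id in 1..k, ids ordered by each
    cluster's smallest leaf index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    clusters = [(i,) for i in range(n)]
    for a, b, _ in tree.merges[: n - k]:
        clusters = [c for c in clusters if c != a and c != b]
        clusters.append(tuple(sorted(a + b)))
    clusters.sort(key=lambda c: c[0])
    assignment = {}
    for cid, members in enumerate(clusters, start=1):
        for i in members:
            assignment[tree.labels[i]] = cid
    return assignment


def cophenetic_matrix(tree: MergeTree) -> DissimilarityMatrix:
    """Height at which each leaf pair first co-merges (an ultrametric)."""
    n = tree.n_leaves
    values = np.zeros((n, n))
    for a, b, h in tree.merges:
        for i in a:
            for j in b:
                values[i, j] = values[j, i] = h
    return DissimilarityMatrix(tree.labels, values)


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EaccdResult:
    dis0: DissimilarityMatrix
    dis: DissimilarityMatrix
    tree: MergeTree


def run_eaccd(
    cohorts: Sequence[CombinationCohort],
    test: WeightScheme | str = WeightScheme.LOGRANK,
    config: EnsembleConfig | None = None,
    linkage: Linkage | str = Linkage.AVERAGE,
) -> EaccdResult:
    """Run the full ensemble clustering pipeline on survival cohorts.

    Computes the initial survival-test dissimilarity, learns the consensus
    dissimilarity from m randomized PAM partitions, agglomerates under the
    chosen linkage, and returns all intermediates.
    """
    if config is None:
        config = EnsembleConfig(k_max=len(cohorts) - 1)
    dis0 = initial_dissimilarity(cohorts, test)
    dis = ensemble_dissimilarity(dis0, config)
    tree = agglomerate(dis, linkage)
    return EaccdResult(dis0=dis0, dis=dis, tree=tree)
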