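"""Stability experiments: how the dendrogram depends on m and the seed.

With few ensemble runs the consensus dissimilarity is still a noisy random
variable and repeated executions can yield different dendrograms; as m
grows the consensus converges (at the usual 1/sqrt(m) Monte-Carlo rate) and
the tree topology stabilises.  These helpers quantify that with the
pairwise topology-agreement rate and the cophenetic correlation between
repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .core import (
    DissimilarityMatrix,
    EnsembleConfig,
    Linkage,
    MergeTree,
    agglomerate,
    cophenetic_matrix,
    ensemble_dissimilarity,
)

__all__ = ["StabilityReport", "cophenetic_correlation", "stability_experiment"]

DEFAULT_M_GRID = (10, 20, 50, 100, 500, 1000, 5000, 10000, 20000, 30000)


def cophenetic_correlation(tree_a: MergeTree, tree_b: MergeTree) -> float:
    """Pearson correlation of the two trees' cophenetic distance vectors."""
    ca = cophenetic_matrix(tree_a).off_diagonal()
    cb = cophenetic_matrix(tree_b).off_diagonal()
    if np.std(ca) == 0 or np.std(cb) == 0:
        return float("nan")
    return float(np.corrcoef(ca, cb)[0, 1])


@dataclass(frozen=True)
class StabilityReport:
    """Agreement among repeated ensemble runs at one value of m."""

    m: int
    repeats: int
    topology_agreement: float  # fraction of repeat pairs with equal topology
    mean_cophenetic_correlation: float
    max_consensus_diff: float  # max-abs consensus difference over repeat pairs


def stability_experiment(
    dis0: DissimilarityMatrix,
    m_values: Sequence[int] = DEFAULT_M_GRID,
    repeats: int = 3,
    base_config: EnsembleConfig | None = None,
    linkage: Linkage | str = Linkage.AVERAGE,
    seed: int = 0,
) -> list[StabilityReport]:
    """Repeat the consensus step at each m with distinct seeds and compare.

    Each repeat uses an independent seed derived from ``seed``; for every
    pair of repeats the tree topologies, cophenetic correlations and
    max-abs consensus-matrix differences are compared.
    """
    if base_config is None:
        base_config = EnsembleConfig(k_max=dis0.n - 1)
    ss = np.random.SeedSequence(seed)
    reports = []
    for m in m_values:
        children = ss.spawn(repeats)
        runs = []
        for child in children:
            cfg_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = EnsembleConfig(
                m=m,
                k_min=base_config.k_min,
                k_max=base_config.k_max,
                partitioners=base_config.partitioners,
                seed=cfg_seed,
            )
            dis = ensemble_dissimilarity(dis0, cfg)
            runs.append((dis, agglomerate(dis, linkage)))
        agree, coph, diffs = [], [], []
        for (da, ta), (db, tb) in combinations(runs, 2):
            agree.append(ta.topology() == tb.topology())
            coph.append(cophenetic_correlation(ta, tb))
            diffs.append(float(np.abs(da.values - db.values).max()))
        reports.append(
            StabilityReport(
                m=m,
                repeats=repeats,
                topology_agreement=float(np.mean(agree)),
                mean_cophenetic_correlation=float(np.nanmean(coph)),
                max_consensus_diff=float(np.max(diffs)),
            )
        )
    return reports
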