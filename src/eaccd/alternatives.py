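"""Baseline clustering approaches for comparison with the ensemble method.

Four alternatives, each a deliberate simplification:

* **A1** — hierarchical clustering directly on the initial survival-test
  dissimilarity, standardized to [0, 1] by its global maximum; the
  dissimilarity-learning step is omitted.  Because the test statistic grows
  with sample size, an oversized combination is pushed far from all others
  and merges last.
* **A2** — pairwise dissimilarity 1 - p from the log-rank-family test.
  For large well-separated cohorts nearly every p underflows, so most
  dissimilarities saturate at exactly 1 and the top of the dendrogram
  collapses into one narrow band.
* **A3** — covariates only: per-combination mean raw tumor size and mean
  raw node count, min-max standardized across combinations, L1 distance,
  standardized by the maximum.  Survival times are never read, so
  combinations with identical covariates but different hazards get
  distance 0.
* **A3\\*** — A3's standardized matrix fed through the consensus-learning
  and agglomeration steps of the ensemble pipeline.
* **A4** — PAM applied directly to the A1-standardized matrix (BUILD
  initialisation) for each requested number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    DissimilarityMatrix,
    EnsembleConfig,
    Linkage,
    MergeTree,
    Partition,
    agglomerate,
    ensemble_dissimilarity,
    pam_partition,
)
from .survival import CombinationCohort, WeightScheme, weighted_two_sample_test

__all__ = [
    "FactorSummary",
    "approach_a1",
    "approach_a2",
    "approach_a3",
    "approach_a3_star",
    "approach_a4",
    "covariate_dissimilarity",
]

TUMOR_SIZE = "tumor_size_cm"
NODE_COUNT = "node_count"


@dataclass(frozen=True)
class FactorSummary:
    """Per-combination covariate means and their min-max standardizations."""

    label: str
    t_hat: float  # mean raw tumor size (cm)
    n_hat: float  # mean raw involved-node count
    t_hat_s: float  # standardized to [0, 1] across combinations
    n_hat_s: float


def approach_a1(dis0: DissimilarityMatrix, linkage: Linkage | str = Linkage.AVERAGE) -> MergeTree:
    """Cluster the max-standardized initial dissimilarity directly (A1)."""
    return agglomerate(dis0.standardized(), linkage)


def approach_a2(
    cohorts: Sequence[CombinationCohort],
    test: WeightScheme | str = WeightScheme.LOGRANK,
    linkage: Linkage | str = Linkage.AVERAGE,
) -> MergeTree:
    """Cluster with 1 - p from the pairwise survival test (A2)."""
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    n = len(cohorts)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = weighted_two_sample_test(cohorts[i].records, cohorts[j].records, test)
            values[i, j] = values[j, i] = 1.0 - res.p_value
    dis = DissimilarityMatrix(tuple(c.label for c in cohorts), values)
    return agglomerate(dis, linkage)


def _factor_summaries(cohorts: Sequence[CombinationCohort]) -> list[FactorSummary]:
    t_hat, n_hat = [], []
    for c in cohorts:
        try:
            t_hat.append(float(np.mean([r.covariates[TUMOR_SIZE] for r in c.records])))
            n_hat.append(float(np.mean([r.covariates[NODE_COUNT] for r in c.records])))
        except KeyError as exc:
            raise ValueError(
                f"cohort {c.label!r} lacks required covariate {exc.args[0]!r}"
            ) from None
    t_hat = np.array(t_hat)
    n_hat = np.array(n_hat)

    def standardize(x: np.ndarray) -> np.ndarray:
        rng = x.max() - x.min()
        return np.zeros_like(x) if rng == 0 else (x - x.min()) / rng

    t_s, n_s = standardize(t_hat), standardize(n_hat)
    return [
        FactorSummary(c.label, float(t), float(nn), float(ts), float(ns))
        for c, t, nn, ts, ns in zip(cohorts, t_hat, n_hat, t_s, n_s)
    ]


def covariate_dissimilarity(cohorts: Sequence[CombinationCohort]) -> tuple[list[FactorSummary], DissimilarityMatrix]:
    """A3's standardized covariate distance matrix (and the summaries).

    L1 distance between the standardized per-combination covariate means,
    divided by its global maximum.
    """
    summaries = _factor_summaries(cohorts)
    n = len(summaries)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(summaries[i].t_hat_s - summaries[j].t_hat_s) + abs(
                summaries[i].n_hat_s - summaries[j].n_hat_s
            )
            values[i, j] = values[j, i] = d
    dis = DissimilarityMatrix(tuple(s.label for s in summaries), values)
    return summaries, dis.standardized()


def approach_a3(
    cohorts: Sequence[CombinationCohort], linkage: Linkage | str = Linkage.AVERAGE
) -> tuple[list[FactorSummary], MergeTree]:
    """Cluster on covariate means alone, ignoring survival (A3)."""
    summaries, dis = covariate_dissimilarity(cohorts)
    return summaries, agglomerate(dis, linkage)


def approach_a3_star(
    cohorts: Sequence[CombinationCohort],
    config: EnsembleConfig,
    linkage: Linkage | str = Linkage.AVERAGE,
) -> MergeTree:
    """A3's covariate distances run through the consensus-learning step."""
    _, dis = covariate_dissimilarity(cohorts)
    consensus = ensemble_dissimilarity(dis, config)
    return agglomerate(consensus, linkage)


def approach_a4(dis0: DissimilarityMatrix, k_list: Sequence[int]) -> list[Partition]:
    """PAM directly on the A1-standardized matrix for each k (A4).

    Uses the deterministic BUILD initialisation (the classic default).
    """
    dis = dis0.standardized()
    return [pam_partition(dis, k, init="build") for k in k_list]
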