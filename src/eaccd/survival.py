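"""Kaplan–Meier estimation and the weighted two-sample test family.

The tests here compare the survival experience of two patient cohorts and
supply the initial pairwise dissimilarity used by the ensemble clustering
pipeline: for two cohorts the dissimilarity is the chi-square-form statistic
``U**2 / V`` of a weighted log-rank test, which is nonnegative by
construction and grows with both the survival difference and the sample
sizes.

Conventions
-----------
* Right censoring only; a censored observation tied with an event time is
  counted as at risk at that time (the standard convention).
* Ties between events at a shared time are handled through the pooled
  hypergeometric variance; times where the pooled risk set has <= 1 subject
  contribute nothing to the variance.
* ``statistic = U**2 / V`` (chi-square with 1 df under the null), never a
  signed z score, so the dissimilarity assumes any nonnegative value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "WeightScheme",
    "PatientRecord",
    "CombinationCohort",
    "StepFunction",
    "TestResult",
    "km_estimate",
    "weighted_two_sample_test",
]


class WeightScheme(str, enum.Enum):
    """Weight w_j applied at each pooled event time t_j.

    ``logrank``          w_j = 1
    ``gehan_wilcoxon``   w_j = n_j   (pooled number at risk)
    ``tarone_ware``      w_j = sqrt(n_j)
    """

    LOGRANK = "logrank"
    GEHAN_WILCOXON = "gehan_wilcoxon"
    TARONE_WARE = "tarone_ware"


@dataclass(frozen=True)
class PatientRecord:
    """One subject: observed time, event flag, factor levels, covariates.

    ``time`` is the observed (possibly censored) follow-up time, ``event``
    is 1 if the event occurred and 0 if right-censored.  ``factors`` holds
    the categorical prognostic-factor levels (e.g. ``("T1", "N0")``) and
    ``covariates`` optional raw continuous measurements (e.g. tumor size in
    cm, involved-node count) needed by covariate-based clustering.
    """

    time: float
    event: int
    factors: tuple
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class CombinationCohort:
    """All patients sharing one level of every prognostic factor.

    This is the unit being clustered: e.g. the ``T2N1`` combination of a
    3-level tumor-size factor and a 4-level nodal-status factor.
    """

    label: str
    levels: tuple
    records: tuple

    def __post_init__(self):
        if len(self.records) == 0:
            raise ValueError(f"cohort {self.label!r} is empty")
        for r in self.records:
            if tuple(r.factors) != tuple(self.levels):
                raise ValueError(
                    f"record factors {r.factors} != cohort levels {self.levels}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def times_events(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed times and event indicators as arrays."""
        t = np.array([r.time for r in self.records], dtype=float)
        e = np.array([r.event for r in self.records], dtype=int)
        return t, e


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous survival step function S(t).

    ``times`` are the distinct uncensored event times (strictly increasing)
    and ``values`` the survival probabilities just after each; S(t) = 1 for
    t before the first event time.  With no events the function is
    identically 1.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0) or np.any(v > 1) or (v.size and np.any(np.diff(v) > 1e-12)):
            raise ValueError("values must be non-increasing within [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t: float) -> float:
        """Evaluate S(t)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.values[idx - 1])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf if never reached."""
        below = np.nonzero(self.values <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a weighted two-sample survival test.

    ``statistic`` is the chi-square-form value U^2/V (>= 0); ``degenerate``
    flags the V = 0 case (no usable events), where the statistic is defined
    as 0 with p-value 1.
    """

    statistic: float
    p_value: float
    weight_scheme: WeightScheme
    degenerate: bool = False

    def __post_init__(self):
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _as_time_event(records: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[PatientRecord]) -> StepFunction:
    """Kaplan–Meier product-limit survival estimate for one cohort.

    Steps occur only at distinct uncensored event times; censored
    observations shrink the risk set without creating a step.

    Raises
    ------
    ValueError
        If ``records`` is empty ("empty cohort").
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    times, events = _as_time_event(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return StepFunction(times=np.array([]), values=np.array([]))
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return StepFunction(times=event_times, values=surv)


def weighted_two_sample_test(
    group_a: Sequence[PatientRecord],
    group_b: Sequence[PatientRecord],
    weight_scheme: WeightScheme | str = WeightScheme.LOGRANK,
) -> TestResult:
    """Weighted log-rank family test comparing two censored cohorts.

    Over the pooled distinct event times t_j, with d_j pooled events, n_j
    pooled at risk, and d_aj / n_aj the group-a counts:

        U = sum_j w_j * (d_aj - n_aj * d_j / n_j)
        V = sum_j w_j^2 * (n_aj/n_j) * (1 - n_aj/n_j)
                   * ((n_j - d_j) / (n_j - 1)) * d_j

    with a zero variance contribution whenever n_j <= 1, and
    statistic = U^2 / V referred to chi-square(1).  The weights w_j are 1,
    n_j or sqrt(n_j) depending on ``weight_scheme`` (log-rank,
    Gehan–Wilcoxon, Tarone–Ware).

    If V = 0 (e.g. no events in the pooled data) the result is degenerate:
    statistic 0, p-value 1, ``degenerate=True``.
    """
    scheme = WeightScheme(weight_scheme)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    ta, ea = _as_time_event(group_a)
    tb, eb = _as_time_event(group_b)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])

    event_times, d_j = np.unique(t_all[e_all == 1], return_counts=True)
    if event_times.size == 0:
        return TestResult(0.0, 1.0, scheme, degenerate=True)
    d_j = d_j.astype(float)

    # Risk sets via sorted counting: n_j = #{observed time >= t_j}
    # (censored observations tied with an event time count as at risk).
    t_sorted = np.sort(t_all)
    ta_sorted = np.sort(ta)
    n_j = (t_sorted.size - np.searchsorted(t_sorted, event_times, side="left")).astype(float)
    n_aj = (ta_sorted.size - np.searchsorted(ta_sorted, event_times, side="left")).astype(float)
    d_aj = np.zeros_like(d_j)
    a_events = ta[ea == 1]
    np.add.at(d_aj, np.searchsorted(event_times, a_events), 1.0)

    if scheme is WeightScheme.LOGRANK:
        w = np.ones_like(n_j)
    elif scheme is WeightScheme.GEHAN_WILCOXON:
        w = n_j
    else:
        w = np.sqrt(n_j)

    u = float(np.sum(w * (d_aj - n_aj * d_j / n_j)))
    ok = n_j > 1
    var_terms = np.zeros_like(n_j)
    var_terms[ok] = (
        (n_aj[ok] / n_j[ok])
        * (1.0 - n_aj[ok] / n_j[ok])
        * ((n_j[ok] - d_j[ok]) / (n_j[ok] - 1.0))
        * d_j[ok]
    )
    v = float(np.sum(w**2 * var_terms))
    if v == 0.0:
        return TestResult(0.0, 1.0, scheme, degenerate=True)
    statistic = u * u / v
    p_value = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic, p_value, scheme)
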