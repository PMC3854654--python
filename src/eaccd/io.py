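"""Readers and writers for patient tables, dissimilarity matrices and trees.

The canonical patient table is a delimited file with one row per subject:

    T_level,N_level,tumor_size_cm,node_count,time_months,event

Factor columns are categorical levels, ``time_months`` a nonnegative real,
``event`` 1 for an observed event and 0 for right censoring.  Rows with
missing or unparseable required fields are rejected and reported with their
line numbers, mirroring a complete-records inclusion rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DissimilarityMatrix, MergeTree
from .survival import CombinationCohort, PatientRecord

__all__ = [
    "ColumnSpec",
    "DEFAULT_COLUMNS",
    "load_patients",
    "group_into_cohorts",
    "cohorts_to_frame",
    "write_cohorts_csv",
    "load_cohorts_csv",
    "write_dissimilarity_csv",
    "read_dissimilarity_csv",
    "write_tree",
]

logger = logging.getLogger("eaccd")


@dataclass(frozen=True)
class ColumnSpec:
    """Which columns hold the factors, time, event and raw covariates."""

    factors: tuple = ("T_level", "N_level")
    time: str = "time_months"
    event: str = "event"
    covariates: tuple = ("tumor_size_cm", "node_count")


DEFAULT_COLUMNS = ColumnSpec()


def load_patients(
    path: str | Path,
    columns: ColumnSpec = DEFAULT_COLUMNS,
    strict: bool = False,
) -> list[PatientRecord]:
    """Read patient records from a delimited file with a header row.

    Rows failing validation (missing values, negative time, event outside
    {0, 1}) are dropped and reported via a logged warning listing data line
    numbers (header = line 1); with ``strict=True`` any bad row raises.

    Raises
    ------
    ValueError
        If a required column is absent, or ``strict`` and any row is bad.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = list(columns.factors) + [columns.time, columns.event]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    covariate_cols = [c for c in columns.covariates if c in df.columns]

    records: list[PatientRecord] = []
    bad: list[int] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        r = dict(zip(df.columns, row))
        try:
            time = float(r[columns.time])
            event = r[columns.event]
            event_i = int(event)
            if (
                any(pd.isna(r[c]) for c in required)
                or np.isnan(time)
                or time < 0
                or float(event) != event_i
                or event_i not in (0, 1)
            ):
                raise ValueError
            covs = {c: float(r[c]) for c in covariate_cols if not pd.isna(r[c])}
            records.append(
                PatientRecord(
                    time=time,
                    event=event_i,
                    factors=tuple(str(r[c]) for c in columns.factors),
                    covariates=covs,
                )
            )
        except (ValueError, TypeError):
            bad.append(pos)
    if bad:
        msg = f"rejected {len(bad)} unparseable row(s) at line(s) {bad}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return records


def group_into_cohorts(records: Sequence[PatientRecord]) -> list[CombinationCohort]:
    """Group records by their factor-level tuple into labelled cohorts.

    Labels concatenate the levels (e.g. ``("T1", "N0")`` -> ``"T1N0"``);
    cohorts are ordered by level tuple.
    """
    by_levels: dict[tuple, list] = {}
    for r in records:
        by_levels.setdefault(tuple(r.factors), []).append(r)
    return [
        CombinationCohort(label="".join(levels), levels=levels, records=tuple(recs))
        for levels, recs in sorted(by_levels.items())
    ]


def cohorts_to_frame(
    cohorts: Sequence[CombinationCohort], columns: ColumnSpec = DEFAULT_COLUMNS
) -> pd.DataFrame:
    rows = []
    for c in cohorts:
        for r in c.records:
            row = dict(zip(columns.factors, c.levels))
            for cov in columns.covariates:
                if cov in r.covariates:
                    row[cov] = r.covariates[cov]
            row[columns.time] = r.time
            row[columns.event] = r.event
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohorts_csv(
    cohorts: Sequence[CombinationCohort],
    path: str | Path,
    columns: ColumnSpec = DEFAULT_COLUMNS,
) -> None:
    """Write cohorts as the canonical patient CSV (full float precision)."""
    cohorts_to_frame(cohorts, columns).to_csv(path, index=False)


def load_cohorts_csv(
    path: str | Path, columns: ColumnSpec = DEFAULT_COLUMNS
) -> list[CombinationCohort]:
    """Read the canonical patient CSV back into cohorts."""
    return group_into_cohorts(load_patients(path, columns))


def write_dissimilarity_csv(dis: DissimilarityMatrix, path: str | Path) -> None:
    """Labelled square CSV, entries rounded to 6 decimal places."""
    pd.DataFrame(dis.values, index=dis.labels, columns=dis.labels).to_csv(
        path, float_format="%.6f"
    )


def read_dissimilarity_csv(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    # symmetrize away the 6-decimal rounding asymmetry, if any
    return DissimilarityMatrix(tuple(df.columns), (values + values.T) / 2.0)


def write_tree(tree: MergeTree, newick_path: str | Path, json_path: str | Path) -> None:
    """Serialize a merge tree to Newick (full precision) and JSON."""
    Path(newick_path).write_text(tree.to_newick() + "\n")
    Path(json_path).write_text(tree.to_json() + "\n")
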