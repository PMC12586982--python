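"""Pathway-level survival comparison: Kaplan-Meier curves and log-rank test.

A sample is pathway-altered when any gene of the pathway carries a somatic
mutation or structural variant in that sample. Overall survival of altered
vs unaltered samples is summarized with the product-limit estimator and
compared with the two-group log-rank test (chi-square, 1 df). Ties at an
event time share the risk set just before that time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .prevalence import GeneAlterationMatrix

__all__ = ["pathway_altered", "km_curve", "logrank_test", "clean_survival_records"]


def pathway_altered(matrix: GeneAlterationMatrix, pathway_genes) -> pd.Series:
    """Per-sample flag: 1 iff any pathway gene is altered in the sample."""
    genes = set(pathway_genes)
    if not genes:
        raise ValueError("pathway gene set is empty")
    missing = genes - set(matrix.data.index)
    if missing:
        warnings.warn(f"pathway genes absent from matrix ignored: {sorted(missing)}",
                      stacklevel=2)
    present = sorted(genes & set(matrix.data.index))
    if not present:
        return pd.Series(0, index=matrix.data.columns, name="altered")
    return (matrix.data.loc[present].max(axis=0) > 0).astype(int).rename("altered")


def clean_survival_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records with missing follow-up, logging how many were removed."""
    ok = records["time"].notna() & records["event"].notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} records with missing follow-up", stacklevel=2)
    return records[ok].reset_index(drop=True)


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate for one set of records.

    Requires ``time`` (days) and ``event`` (1 = death observed) columns;
    returns a step table (time, survival) starting at S(0) = 1.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(records: pd.DataFrame, group_column: str = "group") -> dict:
    """Two-group log-rank test; returns the chi-square statistic and p-value."""
    groups = records[group_column].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(groups)}")
    for g in groups:
        sub = records[records[group_column] == g]
        if sub["event"].sum() == 0:
            raise ValueError(
                f"group {g!r} has no observed events; the log-rank statistic is "
                "undefined — check follow-up or merge groups")
    a = records[records[group_column] == groups[0]]
    b = records[records[group_column] == groups[1]]
    res = _lifelines_logrank(a["time"], b["time"],
                             event_observed_A=a["event"], event_observed_B=b["event"])
    return {"statistic": float(res.test_statistic), "p_value": float(res.p_value),
            "df": 1, "groups": [str(g) for g in groups]}
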