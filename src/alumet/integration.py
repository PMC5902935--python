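"""Group comparison of methylation summaries and methylation-expression
correlation within phenotypic subgroups.

Each sample's COBRA summary contributes five metrics (%mC and the four
pattern percentages). Group differences are tested metric by metric with
a two-tailed t-test and Benjamini-Hochberg adjustment across the five
metrics of one comparison; methylation-expression association is Pearson
correlation per metric within a declared sample stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cobra import MethylationSummary
from .expression import two_sample_t
from .stats import ZeroVarianceError, bh_adjust, pearson_r

__all__ = [
    "METRICS",
    "summaries_frame",
    "MethylationComparison",
    "SubgroupComparisonResults",
    "correlate_methylation_expression",
    "CorrelationResult",
]

#: Reporting order of the five methylation metrics.
METRICS = ("pct_mC", "pct_mCmC", "pct_uCmC", "pct_mCuC", "pct_uCuC")


def summaries_frame(summaries: Mapping[str, MethylationSummary] | Iterable[MethylationSummary]) -> pd.DataFrame:
    """Stack per-sample summaries into a samples x metrics DataFrame."""
    if isinstance(summaries, Mapping):
        items = summaries.items()
    else:
        items = [(s.sample_id, s) for s in summaries]
    return pd.DataFrame({sid: s.as_dict() for sid, s in items}).T[list(METRICS)]


@dataclass
class SubgroupComparisonResults:
    """Per-metric group comparison: means +- SD, raw and BH-adjusted p."""

    table: pd.DataFrame
    label: str
    alpha: float

    def summary(self) -> str:
        lines = [f"Methylation comparison — {self.label}"]
        for metric, row in self.table.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {metric:<9s} case {row['mean_case']:6.2f}±{row['sd_case']:.2f}  "
                f"control {row['mean_control']:6.2f}±{row['sd_control']:.2f}  "
                f"adj_p={row['adj_p']:.3f}{star}"
            )
        return "\n".join(lines)


class MethylationComparison:
    """Two-group comparison of the five methylation metrics.

    Parameters
    ----------
    summaries : DataFrame
        Samples x metrics (see :func:`summaries_frame`).
    labels : Series
        Sample -> group label, aligned on sample id.
    """

    def __init__(self, summaries: pd.DataFrame, labels: pd.Series, equal_var: bool = True):
        missing = set(METRICS) - set(summaries.columns)
        if missing:
            raise ValueError(f"summaries frame is missing metrics {sorted(missing)}")
        self.summaries = summaries
        self.labels = labels.reindex(summaries.index)
        self.equal_var = equal_var

    def fit(self, case_label: str, control_label: str,
            label: Optional[str] = None, alpha: float = 0.05) -> SubgroupComparisonResults:
        case_ids = self.labels.index[self.labels == case_label]
        control_ids = self.labels.index[self.labels == control_label]
        if set(case_ids) & set(control_ids):
            raise ValueError("case and control sample sets overlap")
        if len(case_ids) < 2 or len(control_ids) < 2:
            raise ValueError("need >=2 samples per group")
        rows = {}
        for metric in METRICS:
            x = self.summaries.loc[case_ids, metric].astype(float)
            y = self.summaries.loc[control_ids, metric].astype(float)
            n_dropped = int(x.isna().sum() + y.isna().sum())
            if n_dropped:
                warnings.warn(f"{metric}: dropped {n_dropped} sample(s) with undefined values")
            _, p, n1, n2 = two_sample_t(
                x.to_numpy()[None, :], y.to_numpy()[None, :], equal_var=self.equal_var
            )
            rows[metric] = {
                "mean_case": x.mean(),
                "sd_case": x.std(ddof=1),
                "mean_control": y.mean(),
                "sd_control": y.std(ddof=1),
                "n_case": int(n1[0]),
                "n_control": int(n2[0]),
                "raw_p": float(p[0]),
            }
        table = pd.DataFrame(rows).T.loc[list(METRICS)]
        table["adj_p"] = bh_adjust(table["raw_p"].to_numpy())
        table["significant"] = table["adj_p"] < alpha
        return SubgroupComparisonResults(
            table=table,
            label=label or f"{case_label} vs {control_label}",
            alpha=alpha,
        )


@dataclass
class CorrelationResult:
    """Per-metric correlation between methylation and relative expression."""

    table: pd.DataFrame
    scatter: pd.DataFrame
    stratum: str = "all"

    def summary(self) -> str:
        lines = [f"Methylation-expression correlation — stratum {self.stratum}"]
        for metric, row in self.table.iterrows():
            lines.append(f"  {metric:<9s} r={row['r']:+.4f} (n={int(row['n'])})")
        return "\n".join(lines)


def correlate_methylation_expression(
    summaries: pd.DataFrame,
    expression: pd.Series,
    stratum: Optional[Sequence[str]] = None,
    stratum_label: str = "all",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate each methylation metric with relative expression.

    ``summaries`` and ``expression`` are matched on sample id; ``stratum``
    optionally restricts to a list of sample ids (e.g. one phenotypic
    subgroup plus its matched controls). Pearson by default; ``method=
    'spearman'`` ranks both sides first for gel-derived percentages that
    may be non-normal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    ids = summaries.index.intersection(expression.index)
    if stratum is not None:
        ids = ids.intersection(pd.Index(stratum))
    if len(ids) < 3:
        raise ValueError(f"need >=3 matched samples in stratum {stratum_label!r}, got {len(ids)}")
    expr = expression.loc[ids].astype(float)
    rows = {}
    scatter = pd.DataFrame({"sample_id": ids, "rel_expr": expr.to_numpy()})
    for metric in METRICS:
        x = summaries.loc[ids, metric].astype(float)
        scatter[metric] = x.to_numpy()
        vals_x, vals_y = x.to_numpy(), expr.to_numpy()
        if method == "spearman":
            vals_x = sps.rankdata(vals_x)
            vals_y = sps.rankdata(vals_y)
        try:
            r = pearson_r(vals_x, vals_y)
        except ZeroVarianceError:
            r = np.nan
        rows[metric] = {"r": r, "n": len(ids)}
    table = pd.DataFrame(rows).T.loc[list(METRICS)]
    return CorrelationResult(table=table, scatter=scatter, stratum=stratum_label)
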