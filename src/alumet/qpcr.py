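"""Relative AluS expression from qPCR Ct tables by the 2^-ddCt method.

Each sample's replicate Ct values for the target (AluS) and the reference
(GAPDH) are averaged; dCt = mean Ct_target - mean Ct_reference removes
abundance and loading differences, and ddCt = dCt - mean(dCt of the
control group) anchors expression to the control group. The group fold
change is 2^(-mean ddCt of the case group), i.e. the geometric mean of
the per-sample relative expressions 2^-ddCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import two_sample_t
from .stats import bh_adjust

__all__ = ["CtTable", "delta_ct", "Comparison", "FoldChange", "FoldChangeResults"]

ASSAYS = ("target", "reference")

Selector = Union[str, Mapping[str, str]]


@dataclass(frozen=True)
class Comparison:
    """One case-vs-control contrast.

    ``case`` / ``control`` are either a group name (selects on the
    'group' column) or a {column: value} selector, e.g.
    ``{"subgroup": "M"}`` vs ``{"group": "control"}``.
    """

    label: str
    case: Selector
    control: Selector

    def swapped(self) -> "Comparison":
        return Comparison(label=f"{self.label} (swapped)", case=self.control, control=self.case)


class CtTable:
    """Long-form Ct measurements with sample metadata.

    Expected columns: sample_id, assay ('target' or 'reference'),
    replicate, ct, group, and optionally subgroup. Ct values must be
    positive and finite; every sample needs at least one replicate per
    assay (samples missing an assay are dropped with a warning).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "assay", "ct", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"Ct table is missing columns {sorted(missing)}")
        frame = frame.copy()
        bad_assay = ~frame["assay"].isin(ASSAYS)
        if bad_assay.any():
            raise ValueError(
                f"assay must be one of {ASSAYS}; offending values "
                f"{sorted(frame.loc[bad_assay, 'assay'].unique())}"
            )
        cts = pd.to_numeric(frame["ct"], errors="raise")
        if not np.all(np.isfinite(cts)) or (cts <= 0).any():
            raise ValueError("Ct values must be positive and finite")
        frame["ct"] = cts
        self.frame = frame

    @classmethod
    def from_csv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path))

    def sample_metadata(self) -> pd.DataFrame:
        cols = [c for c in ("group", "subgroup") if c in self.frame.columns]
        return self.frame.drop_duplicates("sample_id").set_index("sample_id")[cols]

    def delta_ct(self) -> pd.DataFrame:
        """Per-sample dCt = mean replicate Ct(target) - mean Ct(reference),
        with group/subgroup labels attached."""
        means = self.frame.groupby(["sample_id", "assay"], sort=False)["ct"].mean().unstack()
        incomplete = means[ASSAYS[0]].isna() | means[ASSAYS[1]].isna() \
            if all(a in means.columns for a in ASSAYS) \
            else pd.Series(True, index=means.index)
        if incomplete.any():
            dropped = means.index[incomplete].tolist()
            warnings.warn(f"samples missing an assay were excluded: {dropped}")
            means = means[~incomplete]
        out = pd.DataFrame({"dCt": means["target"] - means["reference"]})
        return out.join(self.sample_metadata())


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Module-level convenience wrapper over CtTable.delta_ct."""
    return table.delta_ct()


@dataclass
class FoldChangeResults:
    """Fold-change estimates for a family of comparisons.

    ``table``: one row per comparison with fold_change, log2_fc, n_case,
    n_control, raw_p (two-tailed t on dCt), adj_p (BH across the family).
    ``per_sample``: per comparison and sample: dCt, ddCt, rel_expr =
    2^-ddCt, role ('case'/'control').
    """

    table: pd.DataFrame
    per_sample: pd.DataFrame
    alpha: float

    def summary(self) -> str:
        lines = ["AluS relative expression (2^-ddCt)"]
        for _, row in self.table.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"  {row['comparison']:<28s} FC={row['fold_change']:.2f} "
                f"log2FC={row['log2_fc']:+.2f} adj_p={row['adj_p']:.3f}{star}"
            )
        return "\n".join(lines)


class FoldChange:
    """2^-ddCt fold-change model over a CtTable.

    ``aggregate='geometric'`` (default) computes FC = 2^(-mean ddCt);
    'arithmetic' instead takes the ratio of arithmetic-mean relative
    expressions. Group difference testing is on dCt values, which are
    approximately normal, not on exponentiated fold changes.
    """

    def __init__(self, table: CtTable, aggregate: str = "geometric", equal_var: bool = True):
        if aggregate not in ("geometric", "arithmetic"):
            raise ValueError("aggregate must be 'geometric' or 'arithmetic'")
        self.table = table
        self.aggregate = aggregate
        self.equal_var = equal_var
        self._dct = table.delta_ct()

    def _select(self, selector: Selector) -> pd.DataFrame:
        d = self._dct
        if isinstance(selector, str):
            selector = {"group": selector}
        mask = pd.Series(True, index=d.index)
        for col, value in selector.items():
            if col not in d.columns:
                raise ValueError(f"selector column {col!r} not in Ct table")
            mask &= d[col] == value
        return d[mask]

    def fit(self, comparisons: Sequence[Comparison], alpha: float = 0.05) -> FoldChangeResults:
        if not comparisons:
            raise ValueError("need at least one comparison")
        rows: List[dict] = []
        per_sample_frames: List[pd.DataFrame] = []
        for comp in comparisons:
            case = self._select(comp.case)
            control = self._select(comp.control)
            if len(case) < 2 or len(control) < 2:
                raise ValueError(
                    f"comparison {comp.label!r} needs >=2 samples per group "
                    f"(got {len(case)} case, {len(control)} control)"
                )
            control_mean = control["dCt"].mean()
            ddct_case = case["dCt"] - control_mean
            ddct_control = control["dCt"] - control_mean
            if self.aggregate == "geometric":
                log2_fc = float(-ddct_case.mean())
                fc = float(2.0**log2_fc)
            else:
                fc = float(
                    np.mean(2.0**-ddct_case) / np.mean(2.0**-ddct_control)
                )
                log2_fc = float(np.log2(fc))
            _, p, _, _ = two_sample_t(
                case["dCt"].to_numpy()[None, :],
                control["dCt"].to_numpy()[None, :],
                equal_var=self.equal_var,
            )
            rows.append(
                {
                    "comparison": comp.label,
                    "fold_change": fc,
                    "log2_fc": log2_fc,
                    "n_case": len(case),
                    "n_control": len(control),
                    "raw_p": float(p[0]),
                }
            )
            for role, sub, ddct in (("case", case, ddct_case), ("control", control, ddct_control)):
                per_sample_frames.append(
                    pd.DataFrame(
                        {
                            "comparison": comp.label,
                            "sample_id": sub.index,
                            "role": role,
                            "dCt": sub["dCt"].to_numpy(),
                            "ddCt": ddct.to_numpy(),
                            "rel_expr": 2.0 ** -ddct.to_numpy(),
                        }
                    )
                )
        table = pd.DataFrame(rows)
        table["adj_p"] = bh_adjust(table["raw_p"].to_numpy())
        table["significant"] = table["adj_p"] < alpha
        return FoldChangeResults(
            table=table,
            per_sample=pd.concat(per_sample_frames, ignore_index=True),
            alpha=alpha,
        )
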