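"""Differential expression on blood transcriptome matrices.

Processed gene-level microarray intensities (genes x samples, with
explicit missing values) are presence-filtered — a gene is kept when its
intensity is observed in at least 70% of samples — and then tested gene
by gene with a two-tailed two-sample t-test, Bonferroni-adjusted over the
number of genes actually tested. Missing entries are omitted pairwise and
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bonferroni_adjust

__all__ = [
    "ExpressionStudy",
    "filter_presence",
    "DifferentialExpression",
    "DEGResults",
    "two_sample_t",
    "collapse_probes",
]

GROUP_LABELS = ("case", "control")


@dataclass
class ExpressionStudy:
    """A genes x samples intensity matrix with per-sample group labels.

    ``matrix`` has unique gene identifiers as index and sample ids as
    columns (NaN marks a missing intensity). ``groups`` maps every sample
    to 'case' or 'control'; ``subgroups`` optionally maps samples to a
    phenotypic subgroup label (e.g. L, M, S or 'none').
    """

    matrix: pd.DataFrame
    groups: pd.Series
    subgroups: Optional[pd.Series] = None
    study_id: str = ""

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        self.groups = self.groups.reindex(self.matrix.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"group labels must be in {GROUP_LABELS}, got {sorted(bad)}")
        for label in GROUP_LABELS:
            if (self.groups == label).sum() < 2:
                raise ValueError(f"need >=2 '{label}' samples in study {self.study_id!r}")
        if self.subgroups is not None:
            self.subgroups = self.subgroups.reindex(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def samples_in(self, label: str) -> pd.Index:
        return self.groups.index[self.groups == label]

    @classmethod
    def from_files(cls, matrix_path, samples_path, study_id: str = "") -> "ExpressionStudy":
        """Load from an expression TSV (first column = gene, "NA" missing)
        and a sample sheet TSV (sample_id, group[, subgroup])."""
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if "sample_id" not in sheet.columns or "group" not in sheet.columns:
            raise ValueError(f"{samples_path}: needs 'sample_id' and 'group' columns")
        sheet = sheet.set_index("sample_id")
        subgroups = sheet["subgroup"] if "subgroup" in sheet.columns else None
        return cls(matrix=matrix, groups=sheet["group"], subgroups=subgroups,
                   study_id=study_id or str(matrix_path))


def filter_presence(study: ExpressionStudy, cutoff: float = 0.70) -> ExpressionStudy:
    """Keep genes observed in at least ``cutoff`` of all samples.

    The boundary is inclusive (exactly 70% present is retained; the filter
    removes genes missing in strictly more than 30% of samples). Gene
    order is preserved. An empty result warns rather than raising.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    present = study.matrix.notna().mean(axis=1)
    keep = present >= cutoff - 1e-12
    if not keep.any():
        warnings.warn(f"presence filter at {cutoff:.0%} removed every gene "
                      f"in study {study.study_id!r}")
    return replace(study, matrix=study.matrix.loc[keep])


def two_sample_t(case: np.ndarray, control: np.ndarray, equal_var: bool = True):
    """Row-wise two-tailed two-sample t-test with pairwise NaN omission.

    Returns (t, p, n_case, n_control) arrays. Degenerate rows follow the
    conventions of the pipeline: zero pooled variance with equal means
    gives p = 1, with unequal means p = 0; rows with fewer than two
    observations in either group give NaN.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1 = (~np.isnan(case)).sum(axis=1).astype(float)
    n2 = (~np.isnan(control)).sum(axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(case, axis=1)
        m2 = np.nanmean(control, axis=1)
        v1 = np.nanvar(case, axis=1, ddof=1)
        v2 = np.nanvar(control, axis=1, ddof=1)
    ok = (n1 >= 2) & (n2 >= 2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            se2_1, se2_2 = v1 / n1, v2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        t = diff / se
    p = np.full(t.shape, np.nan)
    finite = ok & (se > 0)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df[finite])
    zero_se = ok & (se == 0)
    p[zero_se & (diff == 0)] = 1.0
    p[zero_se & (diff != 0)] = 0.0
    t[zero_se & (diff == 0)] = 0.0
    p[~ok] = np.nan
    return t, p, n1, n2


@dataclass
class DEGResults:
    """Per-gene differential-expression calls for one study.

    ``table`` is indexed by gene with columns: n_case, n_control,
    mean_case, mean_control, raw_p, adj_p (Bonferroni over tested genes),
    direction ('up'/'down' by sign of case-minus-control mean), tested,
    is_deg (adj_p < alpha).
    """

    table: pd.DataFrame
    alpha: float
    study_id: str = ""
    n_tested: int = 0

    @property
    def universe(self) -> Set[str]:
        """Genes actually tested; the enrichment background."""
        return set(self.table.index[self.table["tested"]])

    def deg_genes(self, direction: str = "all") -> Set[str]:
        t = self.table
        mask = t["is_deg"]
        if direction in ("up", "down"):
            mask = mask & (t["direction"] == direction)
        elif direction != "all":
            raise ValueError(f"direction must be 'all', 'up' or 'down', got {direction!r}")
        return set(t.index[mask])

    def summary(self) -> str:
        n_up = len(self.deg_genes("up"))
        n_down = len(self.deg_genes("down"))
        lines = [
            f"Differential expression — study {self.study_id or '<unnamed>'}",
            f"  genes tested (Bonferroni m): {self.n_tested}",
            f"  DEGs at adjusted p < {self.alpha:g}: {n_up + n_down} "
            f"({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)


class DifferentialExpression:
    """Two-sample differential-expression model for one ExpressionStudy.

    Parameters
    ----------
    study : ExpressionStudy
        Should already be presence-filtered (see :func:`filter_presence`).
    equal_var : bool
        Pooled-variance Student's t by default; set False for Welch.
    """

    def __init__(self, study: ExpressionStudy, equal_var: bool = True):
        self.study = study
        self.equal_var = equal_var

    def fit(self, alpha: float = 0.05) -> DEGResults:
        study = self.study
        case = study.matrix[study.samples_in("case")].to_numpy()
        control = study.matrix[study.samples_in("control")].to_numpy()
        t, p, n1, n2 = two_sample_t(case, control, equal_var=self.equal_var)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(case, axis=1)
            m2 = np.nanmean(control, axis=1)
        tested = ~np.isnan(p)
        n_excluded = int((~tested).sum())
        if n_excluded:
            warnings.warn(
                f"study {study.study_id!r}: {n_excluded} gene(s) with <2 values "
                "in a group excluded from testing"
            )
        m = int(tested.sum())
        adj = np.full(p.shape, np.nan)
        adj[tested] = bonferroni_adjust(p[tested], m=m)
        diff = m1 - m2
        direction = np.where(diff > 0, "up", np.where(diff < 0, "down", ""))
        table = pd.DataFrame(
            {
                "n_case": n1.astype(int),
                "n_control": n2.astype(int),
                "mean_case": m1,
                "mean_control": m2,
                "raw_p": p,
                "adj_p": adj,
                "direction": direction,
                "tested": tested,
            },
            index=study.matrix.index,
        )
        table["is_deg"] = tested & (adj < alpha)
        return DEGResults(table=table, alpha=alpha, study_id=study.study_id, n_tested=m)


def collapse_probes(table: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level DEG table to gene level.

    For each gene, keeps the probe with the smallest raw p-value. Off the
    default path: inputs are assumed gene-level unless a probe map is
    supplied explicitly.
    """
    mapped = table.join(probe_to_gene.rename("gene"), how="inner")
    mapped = mapped.sort_values("raw_p", kind="stable")
    collapsed = mapped.drop_duplicates(subset="gene", keep="first")
    return collapsed.set_index("gene")
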