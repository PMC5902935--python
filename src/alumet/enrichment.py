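"""Association of DEG lists with Alu-inserted genes, and cross-study overlap.

Each study contributes a 2x2 cross-tabulation per stratum (insertion type
x DEG direction): DEGs with/without Alu insertion against non-DEGs
with/without. Fisher's exact test measures dependence; Benjamini-Hochberg
adjustment runs across the strata of one study. Genes whose
(significance-gated) study lists recur in at least ``min_support``
studies form the reproducible gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import pandas as pd

from .annotation import INSERTION_TYPES, AluInsertionTable
from .expression import DEGResults
from .stats import ContingencyTable2x2, bh_adjust, fisher_exact_two_sided

__all__ = [
    "DEFAULT_STRATA",
    "build_crosstab",
    "AluEnrichment",
    "EnrichmentResults",
    "reproducible_overlap",
    "ReproducibleGeneSet",
]

#: All five insertion-type strata crossed with the three direction strata.
DEFAULT_STRATA: Tuple[Tuple[str, str], ...] = tuple(
    product(("all",) + INSERTION_TYPES, ("all", "up", "down"))
)


def build_crosstab(degs: Set[str], universe: Set[str], alu_genes: Set[str]) -> ContingencyTable2x2:
    """Cross-tabulate DEG membership against Alu membership over a universe.

    The Alu set is intersected with the universe before counting, so genes
    absent from the annotation count as "without Alu". ``degs`` must be a
    subset of ``universe``.
    """
    stray = set(degs) - set(universe)
    if stray:
        raise ValueError(f"DEGs not in the universe: {sorted(stray)[:10]}")
    alu = set(alu_genes) & set(universe)
    a = len(degs & alu)
    b = len(degs) - a
    c = len(alu) - a
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


@dataclass
class EnrichmentResults:
    """Per-stratum enrichment table for one study.

    Columns: study, insertion_type, direction, n_deg, n_overlap, a, b, c,
    d, raw_p, adj_p (BH across the study's strata), significant, empty.
    """

    table: pd.DataFrame
    alpha: float
    study_id: str = ""

    def significant_strata(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def stratum(self, insertion_type: str, direction: str) -> pd.Series:
        t = self.table
        hit = t[(t["insertion_type"] == insertion_type) & (t["direction"] == direction)]
        if hit.empty:
            raise KeyError(f"stratum ({insertion_type}, {direction}) was not fitted")
        return hit.iloc[0]

    def summary(self) -> str:
        sig = self.significant_strata()
        lines = [
            f"Alu-insertion enrichment — study {self.study_id or '<unnamed>'}",
            f"  strata tested: {len(self.table)}; significant at BH-adjusted "
            f"p < {self.alpha:g}: {len(sig)}",
        ]
        for _, row in sig.iterrows():
            lines.append(
                f"    {row['insertion_type']:>9s} x {row['direction']:<4s} "
                f"overlap {row['n_overlap']:>5d}/{row['n_deg']:<5d} adj_p={row['adj_p']:.3g}"
            )
        return "\n".join(lines)


class AluEnrichment:
    """Fisher enrichment of a study's DEGs in Alu-inserted gene lists.

    Parameters
    ----------
    deg_results : DEGResults
        The study's per-gene calls; its tested genes are the background
        universe (enrichment conditions on testability).
    annotation : AluInsertionTable
        Alu-inserted gene lists by insertion type.
    """

    def __init__(self, deg_results: DEGResults, annotation: AluInsertionTable):
        self.deg_results = deg_results
        self.annotation = annotation

    def fit(
        self,
        strata: Sequence[Tuple[str, str]] = DEFAULT_STRATA,
        alpha: float = 0.05,
    ) -> EnrichmentResults:
        if not strata:
            raise ValueError("strata must be non-empty")
        universe = self.deg_results.universe
        rows = []
        for insertion_type, direction in strata:
            degs = self.deg_results.deg_genes(direction)
            alu = self.annotation.genes_with_type(insertion_type)
            t = build_crosstab(degs, universe, alu)
            empty = len(degs) == 0
            p = 1.0 if empty else fisher_exact_two_sided(t)
            rows.append(
                {
                    "study": self.deg_results.study_id,
                    "insertion_type": insertion_type,
                    "direction": direction,
                    "n_deg": t.a + t.b,
                    "n_overlap": t.a,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "raw_p": p,
                    "empty": empty,
                }
            )
        table = pd.DataFrame(rows)
        table["adj_p"] = bh_adjust(table["raw_p"].to_numpy())
        table["significant"] = table["adj_p"] < alpha
        return EnrichmentResults(table=table, alpha=alpha, study_id=self.deg_results.study_id)


@dataclass
class ReproducibleGeneSet:
    """Genes recurring in at least ``min_support`` study lists."""

    genes: Set[str]
    support: Dict[str, Set[str]]
    min_support: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, ",".join(sorted(self.support[g])), len(self.support[g]))
            for g in sorted(self.genes)
        ]
        return pd.DataFrame(rows, columns=["gene", "supporting_studies", "support_count"])


def reproducible_overlap(
    per_study_sets: Mapping[str, Iterable[str]],
    min_support: int = 2,
) -> ReproducibleGeneSet:
    """Intersect per-study gene lists by support count.

    Callers should pass only lists that passed their significance gate
    (the default reproducibility analysis uses the downregulated,
    all-insertion, significant study lists).
    """
    if len(per_study_sets) < 2:
        raise ValueError("need at least 2 studies to assess reproducibility")
    support: Dict[str, Set[str]] = {}
    for study_id, genes in per_study_sets.items():
        for g in genes:
            support.setdefault(g, set()).add(study_id)
    if min_support > len(per_study_sets):
        warnings.warn(
            f"min_support={min_support} exceeds the number of studies "
            f"({len(per_study_sets)}); the reproducible set is empty"
        )
    genes = {g for g, s in support.items() if len(s) >= min_support}
    return ReproducibleGeneSet(
        genes=genes, support={g: support[g] for g in genes}, min_support=min_support
    )
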