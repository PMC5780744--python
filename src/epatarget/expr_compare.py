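"""Promoter-vs-EPA comparison of target-gene expression levels.

For every motif present in both conditions with at least five targets
each, the two target sets' RPKM distributions are compared with a
two-sided Mann-Whitney rank-sum test.  A significantly higher EPA median
is a 'red' call, significantly lower is 'blue', otherwise 'grey' — the
dot-level classification used to contrast immune-like cells (enhancer
targets more expressed) with stem-like cells (less expressed).  The
summary also reports the ratio of the sums of median expression levels
between the two conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_fdr
from .targets import ExpressionTable, TargetTable

log = logging.getLogger(__name__)


def median_expression(targets: set[str], expr: ExpressionTable) -> float:
    """Standard median RPKM of a target set (mean of middle two when even)."""
    if not targets:
        raise ValueError("empty target set")
    return float(np.median([expr[t] for t in targets]))


@dataclass(frozen=True)
class MedianComparison:
    motif_id: str
    median_promoter: float
    median_epa: float
    pvalue: float
    verdict: str  # red | blue | grey


@dataclass
class ComparisonSummary:
    n_red: int
    n_blue: int
    n_grey: int
    sum_median_promoter: float
    sum_median_epa: float

    @property
    def n_compared(self) -> int:
        return self.n_red + self.n_blue + self.n_grey

    @property
    def ratio_red(self) -> float:
        return self.n_red / self.n_compared if self.n_compared else 0.0

    @property
    def ratio_blue(self) -> float:
        return self.n_blue / self.n_compared if self.n_compared else 0.0

    @property
    def sum_median_ratio(self) -> float:
        if self.sum_median_promoter == 0:
            raise ZeroDivisionError("promoter medians all zero")
        return self.sum_median_epa / self.sum_median_promoter


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact for small tie-free samples."""
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)):
        method = "asymptotic"  # exact distribution undefined with ties
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_promoter_vs_epa(
    table_promoter: TargetTable,
    table_epa: TargetTable,
    expr: ExpressionTable,
    alpha: float = 0.05,
    min_targets: int = 5,
    adjust: bool = False,
) -> tuple[list[MedianComparison], ComparisonSummary]:
    """Compare expression of each motif's targets between the two conditions.

    Only motifs present in both tables with >= ``min_targets`` targets each
    are compared (paired semantics).  ``adjust`` switches the dot-level
    alpha to BH-adjusted p-values.
    """
    prom = table_promoter.by_motif()
    epa = table_epa.by_motif()
    shared = sorted(
        m
        for m in set(prom) & set(epa)
        if len(prom[m].targets) >= min_targets and len(epa[m].targets) >= min_targets
    )
    if not shared:
        raise ValueError("no motifs shared between the two conditions")
    rows = []
    for m in shared:
        xp = np.array([expr[t] for t in sorted(prom[m].targets)])
        xe = np.array([expr[t] for t in sorted(epa[m].targets)])
        rows.append((m, float(np.median(xp)), float(np.median(xe)), _ranksum_pvalue(xe, xp)))
    pvals = [r[3] for r in rows]
    effective = bh_fdr(pvals) if adjust else np.asarray(pvals)
    comparisons = []
    n_red = n_blue = n_grey = 0
    for (m, mp, me, p), p_eff in zip(rows, effective):
        if p_eff <= alpha and me > mp:
            verdict = "red"
            n_red += 1
        elif p_eff <= alpha and me < mp:
            verdict = "blue"
            n_blue += 1
        else:
            verdict = "grey"
            n_grey += 1
        comparisons.append(MedianComparison(m, mp, me, p, verdict))
    summary = ComparisonSummary(
        n_red,
        n_blue,
        n_grey,
        sum_median_promoter=float(sum(c.median_promoter for c in comparisons)),
        sum_median_epa=float(sum(c.median_epa for c in comparisons)),
    )
    return comparisons, summary


def write_comparisons_tsv(
    comparisons: Sequence[MedianComparison], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tmedian_promoter\tmedian_epa\tpvalue\tverdict\n")
        for c in comparisons:
            fh.write(
                f"{c.motif_id}\t{c.median_promoter:.6g}\t{c.median_epa:.6g}\t"
                f"{c.pvalue:.6g}\t{c.verdict}\n"
            )
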