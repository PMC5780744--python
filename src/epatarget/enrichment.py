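"""Gene-set over-representation of per-TF target sets and the statistics
built on it.

Each (TF, database) pair is tested term-by-term with the exact
hypergeometric upper tail (the classical over-representation test), then
Benjamini-Hochberg adjusted within that pair; terms with q <= 1e-3 count as
functional enrichments.  Counts are normalized by the total number of
target genes in the condition and scaled by 1e5, which is the statistic
used to compare association rules, CTCF modes and perturbation levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .targets import TargetTable

log = logging.getLogger(__name__)

Q_THRESHOLD = 1e-3
NORMALIZATION_MULTIPLIER = 1e5


@dataclass
class AnnotationDB:
    """A flat annotation database: term_id -> (name, gene set)."""

    name: str
    terms: dict[str, tuple[str, frozenset[str]]]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.terms.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.terms)


def read_gene_sets(path: str | Path, name: str | None = None) -> AnnotationDB:
    """Read a GMT file: term_id <tab> description <tab> gene ids...

    Duplicate genes within a line are collapsed; empty terms are skipped
    with a warning; a file with no usable terms is an error.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                log.warning("%s:%d: term %s has no genes; skipped", path, lineno, fields[0])
                continue
            terms[fields[0]] = (fields[1], genes)
    if not terms:
        raise ValueError(f"{path}: no gene-set terms found")
    return AnnotationDB(name or path.stem, terms)


def write_gene_sets(db: AnnotationDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(db.terms):
            name, genes = db.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    term_id: str
    k: int  # targets annotated with the term
    K: int  # targets in the universe
    n: int  # term genes in the universe
    N: int  # universe size
    pvalue: float
    qvalue: float


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_one(
    targets: set[str], db: AnnotationDB, universe: set[str], motif_id: str = ""
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of one target set against one
    database; BH across the database's terms.

    Targets outside the universe are dropped (logged); terms with no
    overlap are omitted since their p-value is 1.
    """
    if not universe:
        raise ValueError("empty universe")
    dropped = len(targets - universe)
    if dropped:
        log.debug("%d targets outside the universe dropped", dropped)
    targets = targets & universe
    N, K = len(universe), len(targets)
    rows: list[tuple[str, int, int]] = []
    for term_id in sorted(db.terms):
        members = db.terms[term_id][1] & universe
        k = len(targets & members)
        if k >= 1:
            rows.append((term_id, k, len(members)))
    if not rows:
        return []
    pvals = [float(stats.hypergeom.sf(k - 1, N, n, K)) for _, k, n in rows]
    qvals = bh_fdr(pvals)
    return [
        EnrichmentResult(motif_id, term_id, k, K, n, N, p, q)
        for (term_id, k, n), p, q in zip(rows, pvals, qvals)
    ]


def enrich_table(
    table: TargetTable, db: AnnotationDB, universe: set[str]
) -> list[EnrichmentResult]:
    """Run :func:`enrich_one` for every motif's target set."""
    out: list[EnrichmentResult] = []
    for s in table.sets:
        out.extend(enrich_one(set(s.targets), db, universe, motif_id=s.motif_id))
    return out


def count_enrichments(
    results: Iterable[EnrichmentResult], q_threshold: float = Q_THRESHOLD
) -> tuple[int, int]:
    """(total, unique) enriched-term counts at the q threshold.

    Total counts (TF, term) pairs; unique counts distinct terms across TFs.
    """
    total = 0
    unique: set[str] = set()
    for r in results:
        if r.qvalue <= q_threshold:
            total += 1
            unique.add(r.term_id)
    return total, len(unique)


def enriched_term_tf_counts(
    results: Iterable[EnrichmentResult], q_threshold: float = Q_THRESHOLD
) -> dict[str, int]:
    """term_id -> number of TFs enriched for it (the 'No. of TF' statistic)."""
    counts: dict[str, int] = {}
    for r in results:
        if r.qvalue <= q_threshold:
            counts[r.term_id] = counts.get(r.term_id, 0) + 1
    return counts


def normalize_counts(
    count: float, total_pairs: int, multiplier: float = NORMALIZATION_MULTIPLIER
) -> float:
    """count / (total number of target genes) x 1e5."""
    if total_pairs <= 0:
        raise ValueError("total_pairs must be positive")
    return count / total_pairs * multiplier


@dataclass
class EnrichmentSummary:
    """Per-database enrichment counts for one condition."""

    condition: str
    database: str
    total_count: int
    unique_count: int
    total_pairs: int

    @property
    def normalized_total(self) -> float:
        if self.total_pairs == 0 and self.total_count == 0:
            return 0.0  # empty condition: nothing predicted, nothing enriched
        return normalize_counts(self.total_count, self.total_pairs)

    @property
    def normalized_unique(self) -> float:
        if self.total_pairs == 0 and self.unique_count == 0:
            return 0.0
        return normalize_counts(self.unique_count, self.total_pairs)


def summarize_enrichment(
    table: TargetTable,
    dbs: Sequence[AnnotationDB],
    universe: set[str],
    q_threshold: float = Q_THRESHOLD,
) -> list[EnrichmentSummary]:
    summaries = []
    for db in dbs:
        results = enrich_table(table, db, universe)
        total, unique = count_enrichments(results, q_threshold)
        summaries.append(
            EnrichmentSummary(table.condition, db.name, total, unique, table.total_pairs)
        )
    return summaries


def expression_only_enrichment(
    expressed: set[str],
    db: AnnotationDB,
    universe: set[str],
    p_threshold: float = 0.01,
) -> int:
    """Unique terms enriched in the highly expressed set itself (raw p).

    This is the per-cell baseline independent of any TF structure; raw
    p-values are thresholded at 0.01 or 0.05.
    """
    results = enrich_one(expressed, db, universe, motif_id="(expressed)")
    return sum(1 for r in results if r.pvalue <= p_threshold)


def compare_conditions(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int], factor: float = 2.0
) -> dict[str, str]:
    """Per-term verdicts between two conditions' enriched-TF counts.

    A term is 'A-more' when its count in A is at least ``factor`` times the
    count in B (and nonzero); symmetric for 'B-more'; otherwise 'unchanged'.
    """
    verdicts: dict[str, str] = {}
    for term in set(counts_a) | set(counts_b):
        a = counts_a.get(term, 0)
        b = counts_b.get(term, 0)
        if a > 0 and a >= factor * b:
            verdicts[term] = "A-more"
        elif b > 0 and b >= factor * a:
            verdicts[term] = "B-more"
        else:
            verdicts[term] = "unchanged"
    return verdicts


def condition_chi_square(
    a_enriched: int, a_total: int, b_enriched: int, b_total: int
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on
    [[a, A-a], [b, B-b]]; a zero margin returns (0, 1) with a warning."""
    if a_enriched > a_total or b_enriched > b_total:
        raise ValueError("enriched count exceeds total")
    table = np.array(
        [[a_enriched, a_total - a_enriched], [b_enriched, b_total - b_enriched]]
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        log.warning("degenerate 2x2 table (zero margin); returning p = 1")
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def zscore_table(values: Sequence[float]) -> np.ndarray:
    """Population z-scores of one database's counts across conditions.

    Constant rows map to all zeros (no variation to standardize).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 conditions")
    sd = x.std()  # population sd
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tterm_id\tk\tK\tn\tN\tpvalue\tqvalue\n")
        for r in results:
            fh.write(
                f"{r.motif_id}\t{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.pvalue:.6g}\t{r.qvalue:.6g}\n"
            )


def write_summary_tsv(summaries: Sequence[EnrichmentSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "condition\tdatabase\ttotal_count\tunique_count\ttotal_pairs\t"
            "normalized_total\tnormalized_unique\n"
        )
        for s in summaries:
            fh.write(
                f"{s.condition}\t{s.database}\t{s.total_count}\t{s.unique_count}\t"
                f"{s.total_pairs}\t{s.normalized_total:.4f}\t{s.normalized_unique:.4f}\n"
            )
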