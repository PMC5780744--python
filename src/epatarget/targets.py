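"""Per-TF target-gene sets from motif matches, regulatory domains and
expression, with the redundancy/minimum-size filters and randomized
perturbation controls.

A gene is a putative target of a motif when a match of that motif starts
inside the gene's regulatory domain and the gene is highly expressed
(top 30 % by RPKM by default).  Motifs whose target sets are identical for
the same TF are redundant and collapsed to one; motifs with fewer than
five targets are dropped.  Perturbation replaces or adds a fraction of
randomly selected highly expressed genes, the control used to show that
native target sets are the most functionally coherent.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .epa import RegulatoryDomain
from .motifs import MotifMatch

log = logging.getLogger(__name__)

PERTURB_FRACTIONS = (0.05, 0.10, 0.20, 0.40, 0.60)


class ExpressionTable:
    """transcript_id -> RPKM; replicate means are recomputed, never trusted."""

    def __init__(self, values: Mapping[str, float]) -> None:
        bad = [k for k, v in values.items() if v < 0 or not np.isfinite(v)]
        if bad:
            raise ValueError(f"negative/non-finite RPKM for {bad[:3]}...")
        self.values: dict[str, float] = dict(values)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, transcript_id: str) -> float:
        return self.values[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.values

    @staticmethod
    def read_tsv(path: str | Path) -> "ExpressionTable":
        """Read a TSV with transcript_id plus one or more RPKM columns.

        With several numeric columns (replicates) the mean is taken.
        """
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need an id column and >= 1 RPKM column")
        ids = df.iloc[:, 0].astype(str)
        rpkm = df.iloc[:, 1:].apply(pd.to_numeric).mean(axis=1)
        return ExpressionTable(dict(zip(ids, rpkm)))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\trpkm\n")
            for tid in sorted(self.values):
                fh.write(f"{tid}\t{self.values[tid]:.6g}\n")


def highly_expressed(expr: ExpressionTable, top_fraction: float = 0.30) -> set[str]:
    """The ceil(top_fraction * N) transcripts with the highest RPKM.

    Ties at the cut are broken by transcript id, so the choice is
    deterministic.
    """
    if len(expr) == 0:
        raise ValueError("empty expression table")
    n_keep = math.ceil(top_fraction * len(expr))
    ranked = sorted(expr.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return {tid for tid, _ in ranked[:n_keep]}


@dataclass(frozen=True)
class TargetSet:
    motif_id: str
    tf_symbol: str
    targets: frozenset[str]


@dataclass
class TargetTable:
    """All (motif, TF) target sets for one condition (rule × CTCF mode × cell)."""

    sets: list[TargetSet]
    condition: str = ""

    @property
    def total_pairs(self) -> int:
        return sum(len(s.targets) for s in self.sets)

    @property
    def unique_targets(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.targets
        return out

    def by_motif(self) -> dict[str, TargetSet]:
        return {s.motif_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)


def predict_targets(
    matches: Iterable[MotifMatch],
    domains: Sequence[RegulatoryDomain],
    expressed: set[str],
    motif_to_tf: Mapping[str, str | None],
    condition: str = "",
    overlap: str = "start",
) -> TargetTable:
    """Assign genes to motifs: a match inside a gene's domain makes the gene
    a target, provided the gene is highly expressed.

    ``overlap='start'`` tests the match start position only (a point cannot
    straddle two tiling domains); ``overlap='any'`` accepts any overlap
    between the match footprint and the domain.  Motifs without a mapped TF
    symbol are excluded.
    """
    if overlap not in ("start", "any"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        iv = d.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, d.transcript_id)
    per_motif: dict[str, set[str]] = {}
    skipped_unmapped: set[str] = set()
    for m in matches:
        tf = motif_to_tf.get(m.motif_id)
        if tf is None:
            skipped_unmapped.add(m.motif_id)
            continue
        tree = trees.get(m.interval.chrom)
        if tree is None:
            continue
        if overlap == "start":
            hits = tree[m.interval.start]
        else:
            hits = tree[m.interval.start : m.interval.end]
        if hits:
            genes = per_motif.setdefault(m.motif_id, set())
            for h in hits:
                if h.data in expressed:
                    genes.add(h.data)
    if skipped_unmapped:
        log.info("%d motifs without a TF symbol excluded", len(skipped_unmapped))
    sets = [
        TargetSet(mid, motif_to_tf[mid], frozenset(genes))
        for mid, genes in sorted(per_motif.items())
        if genes
    ]
    return TargetTable(sets, condition)


def remove_redundant_tfbs(table: TargetTable) -> TargetTable:
    """Collapse motifs of the same TF with identical target sets to one.

    The kept motif is the lexicographically smallest motif_id, so the
    result is deterministic.
    """
    best: dict[tuple[str, frozenset[str]], TargetSet] = {}
    for s in table.sets:
        key = (s.tf_symbol, s.targets)
        if key not in best or s.motif_id < best[key].motif_id:
            best[key] = s
    sets = sorted(best.values(), key=lambda s: s.motif_id)
    return TargetTable(sets, table.condition)


def filter_min_targets(table: TargetTable, minimum: int = 5) -> TargetTable:
    """Drop motifs with fewer than ``minimum`` targets (default: fewer than 5)."""
    return TargetTable(
        [s for s in table.sets if len(s.targets) >= minimum], table.condition
    )


@dataclass(frozen=True)
class PerturbationSpec:
    mode: str  # replace | add
    fraction: float
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("replace", "add"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not (0 <= self.fraction <= 1):
            raise ValueError("fraction must be in [0, 1]")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def perturb_targets(
    table: TargetTable, spec: PerturbationSpec, pool: set[str]
) -> TargetTable:
    """Replace or add ``round(fraction * n)`` randomly selected highly
    expressed genes per target set.

    Replacement keeps the set size; addition grows it by k.  Each
    (motif, replicate) pair gets its own RNG substream, so adding motifs to
    a run does not change other motifs' draws.
    """
    new_sets = []
    for s in table.sets:
        n = len(s.targets)
        k = _round_half_up(spec.fraction * n)
        if k == 0:
            new_sets.append(s)
            continue
        candidates = sorted(pool - s.targets)
        if len(candidates) < k:
            raise ValueError(
                f"pool exhausted for motif {s.motif_id}: need {k}, have {len(candidates)}"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(spec.seed),
                spawn_key=(zlib.crc32(s.motif_id.encode()), int(spec.replicate)),
            )
        )
        drawn = rng.choice(len(candidates), size=k, replace=False)
        incoming = {candidates[i] for i in drawn}
        if spec.mode == "replace":
            current = sorted(s.targets)
            victims = rng.choice(len(current), size=k, replace=False)
            kept = set(current) - {current[i] for i in victims}
            targets = frozenset(kept | incoming)
        else:
            targets = frozenset(s.targets | incoming)
        new_sets.append(TargetSet(s.motif_id, s.tf_symbol, targets))
    label = f"{table.condition}+{spec.mode}{spec.fraction:g}r{spec.replicate}"
    return TargetTable(new_sets, label)


def target_stats(table: TargetTable) -> dict[str, float]:
    """Mean/median target-set size, total pairs and unique target count.

    The median of an even number of sets is the lower middle value, so all
    statistics are integers when set sizes are.
    """
    sizes = sorted(len(s.targets) for s in table.sets)
    if not sizes:
        return {"n_tfbs": 0, "mean_targets": 0.0, "median_targets": 0.0,
                "total_pairs": 0, "unique_targets": 0}
    median = float(sizes[(len(sizes) - 1) // 2])
    return {
        "n_tfbs": len(sizes),
        "mean_targets": float(sum(sizes) / len(sizes)),
        "median_targets": median,
        "total_pairs": int(sum(sizes)),
        "unique_targets": len(table.unique_targets),
    }


# ---------------------------------------------------------------------------
# TSV I/O


def write_targets(table: TargetTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf_symbol\ttranscript_id\n")
        for s in sorted(table.sets, key=lambda s: s.motif_id):
            for tid in sorted(s.targets):
                fh.write(f"{s.motif_id}\t{s.tf_symbol}\t{tid}\n")


def read_targets(path: str | Path, condition: str = "") -> TargetTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets = [
        TargetSet(mid, grp["tf_symbol"].iloc[0], frozenset(grp["transcript_id"]))
        for mid, grp in df.groupby("motif_id", sort=True)
    ]
    return TargetTable(sets, condition)
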