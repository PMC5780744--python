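"""Per-gene regulatory domains under configurable enhancer-promoter
association rules, with optional shortening at CTCF-binding sites.

Four rules are supported, mirroring the GREAT-style regulatory-domain
definitions plus a promoter-only baseline:

* ``promoter`` — the ±5 kb promoter window only.
* ``rule1`` — basal plus extension: 5 kb + 5 kb basal domain, extended on
  each side to the nearest neighbour's basal domain, capped at 300 kb from
  the TSS.
* ``rule2`` — basal plus extension with a 5 kb + 1 kb basal domain and a
  1 Mb cap.
* ``rule3`` — two nearest genes: from the TSS of the nearest upstream gene
  to the TSS of the nearest downstream gene (chromosome ends when there is
  no neighbour), no cap.
* ``rule4`` — single nearest gene: to the midpoints between this gene's TSS
  and its neighbours' TSSs, no cap.  Rule-4 domains tile a chromosome.

Rules 3/4 always union in the gene's own promoter, so no domain is smaller
than the ±5 kb window.

CTCF shortening truncates a domain at CTCF sites lying strictly inside it
but outside the promoter, either at the site nearest the TSS on each side
(``nearest_any``) or only at convergently oriented sites (``fr``): on the
left the domain is cut at the most external forward-oriented site of the
first consecutive forward run encountered scanning outward from the TSS,
and symmetrically on the right for reverse-oriented sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome import GeneAnnotation, GenomicInterval, Peak, Transcript, promoter_region

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRule:
    """An enhancer-promoter association rule (basal window + extension cap)."""

    name: str
    basal_up: int
    basal_down: int
    cap: int | None  # max extension from the TSS; None = unlimited

    def basal_interval(self, t: Transcript) -> tuple[int, int]:
        """Strand-aware basal window around the TSS (unclipped)."""
        if t.strand == "+":
            return t.tss - self.basal_up, t.tss + self.basal_down
        return t.tss - self.basal_down, t.tss + self.basal_up


RULES: dict[str, AssociationRule] = {
    "promoter": AssociationRule("promoter", 5000, 5000, None),
    "rule1": AssociationRule("rule1", 5000, 5000, 300_000),
    "rule2": AssociationRule("rule2", 5000, 1000, 1_000_000),
    "rule3": AssociationRule("rule3", 5000, 5000, None),
    "rule4": AssociationRule("rule4", 5000, 5000, None),
}

PROMOTER_HALFWIDTH = 5000


@dataclass(frozen=True)
class RegulatoryDomain:
    transcript_id: str
    interval: GenomicInterval
    rule: AssociationRule
    shortening: str = "none"  # none | nearest_any | fr


@dataclass(frozen=True)
class CtcfSite:
    """A CTCF-binding site with an optional motif orientation (F or R)."""

    interval: GenomicInterval
    orientation: str | None = None  # F (forward motif), R (reverse), None
    source: str = "provided"

    def __post_init__(self) -> None:
        if self.orientation not in (None, "F", "R"):
            raise ValueError(f"invalid CTCF orientation {self.orientation!r}")


def _neighbor_tss(
    transcripts: Sequence[Transcript], index: int
) -> tuple[int | None, int | None]:
    """Nearest distinct TSS on each side of ``transcripts[index]`` (TSS-sorted)."""
    tss = transcripts[index].tss
    left = right = None
    for j in range(index - 1, -1, -1):
        if transcripts[j].tss < tss:
            left = transcripts[j].tss
            break
    for j in range(index + 1, len(transcripts)):
        if transcripts[j].tss > tss:
            right = transcripts[j].tss
            break
    return left, right


def regulatory_domains(
    annotation: GeneAnnotation,
    rule: AssociationRule | str,
    midpoint_variant: bool = False,
) -> list[RegulatoryDomain]:
    """Build one regulatory domain per transcript under an association rule.

    ``midpoint_variant`` makes the basal-plus-extension rules stop at the
    TSS midpoint with the neighbour instead of at the neighbour's basal
    boundary.
    """
    if isinstance(rule, str):
        rule = RULES[rule]
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    domains: list[RegulatoryDomain] = []
    for chrom in sorted(annotation.by_chrom):
        size = annotation.chrom_size(chrom)
        ts = annotation.by_chrom[chrom]
        for i, t in enumerate(ts):
            left_tss, right_tss = _neighbor_tss(ts, i)
            start, end = _domain_bounds(
                rule, t, ts, i, left_tss, right_tss, size, midpoint_variant
            )
            # never smaller than the promoter window
            start = min(start, max(0, t.tss - PROMOTER_HALFWIDTH))
            end = max(end, min(size, t.tss + PROMOTER_HALFWIDTH))
            start, end = max(0, start), min(size, end)
            domains.append(
                RegulatoryDomain(t.id, GenomicInterval(chrom, start, end, t.strand), rule)
            )
    return domains


def _domain_bounds(
    rule: AssociationRule,
    t: Transcript,
    ts: Sequence[Transcript],
    i: int,
    left_tss: int | None,
    right_tss: int | None,
    size: int,
    midpoint_variant: bool,
) -> tuple[int, int]:
    tss = t.tss
    if rule.name == "promoter":
        return tss - PROMOTER_HALFWIDTH, tss + PROMOTER_HALFWIDTH
    if rule.name == "rule3":
        return (left_tss if left_tss is not None else 0,
                right_tss if right_tss is not None else size)
    if rule.name == "rule4":
        left = (tss + left_tss) // 2 if left_tss is not None else 0
        right = (tss + right_tss) // 2 if right_tss is not None else size
        return left, right
    # basal plus extension (rules 1 and 2)
    basal_start, basal_end = rule.basal_interval(t)
    cap = rule.cap if rule.cap is not None else size
    if midpoint_variant:
        left_limit = (tss + left_tss) // 2 if left_tss is not None else 0
        right_limit = (tss + right_tss) // 2 if right_tss is not None else size
    else:
        left_limit, right_limit = _nearest_basal_bounds(rule, ts, i, tss)
        if left_limit is None:
            left_limit = 0
        if right_limit is None:
            right_limit = size
    start = min(basal_start, max(tss - cap, left_limit))
    end = max(basal_end, min(tss + cap, right_limit))
    return start, end


def _nearest_basal_bounds(
    rule: AssociationRule, ts: Sequence[Transcript], i: int, tss: int
) -> tuple[int | None, int | None]:
    """Boundaries imposed by the nearest neighbours' basal domains."""
    left = right = None
    for j in range(i - 1, -1, -1):
        if ts[j].tss < tss:
            left = rule.basal_interval(ts[j])[1]  # neighbour's basal end
            break
    for j in range(i + 1, len(ts)):
        if ts[j].tss > tss:
            right = rule.basal_interval(ts[j])[0]  # neighbour's basal start
            break
    return left, right


# ---------------------------------------------------------------------------
# CTCF shortening


def shorten_at_ctcf(
    domain: RegulatoryDomain,
    tss: int,
    sites: Sequence[CtcfSite],
    mode: str = "fr",
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    pair_required: bool = False,
) -> RegulatoryDomain:
    """Truncate a regulatory domain at CTCF sites.

    Only sites fully inside the domain and not overlapping the ±5 kb
    promoter are candidates.  ``nearest_any`` cuts each side at the
    candidate closest to the TSS regardless of orientation; ``fr`` cuts at
    the most external site of the first consecutive correctly-oriented run
    scanning outward from the TSS (forward on the left, reverse on the
    right).  A side with no usable candidate keeps the domain edge; with
    ``pair_required`` both sides must have one or nothing is shortened.
    """
    if mode not in ("nearest_any", "fr"):
        raise ValueError(f"unknown CTCF mode {mode!r}")
    iv = domain.interval
    prom_start, prom_end = tss - promoter_halfwidth, tss + promoter_halfwidth
    inside = [
        s
        for s in sites
        if s.interval.chrom == iv.chrom
        and s.interval.start >= iv.start
        and s.interval.end <= iv.end
        and (s.interval.end <= prom_start or s.interval.start >= prom_end)
    ]
    left_sites = sorted(
        (s for s in inside if s.interval.end <= prom_start),
        key=lambda s: (-s.interval.end, s.interval.start),  # closest to TSS first
    )
    right_sites = sorted(
        (s for s in inside if s.interval.start >= prom_end),
        key=lambda s: (s.interval.start, s.interval.start),
    )

    if mode == "nearest_any":
        new_start = left_sites[0].interval.start if left_sites else iv.start
        new_end = right_sites[0].interval.end if right_sites else iv.end
    else:
        new_start = _fr_boundary(left_sites, "F", "left")
        new_end = _fr_boundary(right_sites, "R", "right")
        if new_start is None:
            new_start = iv.start
        if new_end is None:
            new_end = iv.end
        if pair_required and (new_start == iv.start or new_end == iv.end):
            new_start, new_end = iv.start, iv.end

    return RegulatoryDomain(
        domain.transcript_id,
        GenomicInterval(iv.chrom, new_start, new_end, iv.strand),
        domain.rule,
        shortening=mode,
    )


def _fr_boundary(ordered_sites: Sequence[CtcfSite], want: str, side: str) -> int | None:
    """Boundary from the first outward run of correctly-oriented sites.

    ``ordered_sites`` are sorted closest-to-TSS first.  Sites without an
    orientation are ignored; sites with the opposite orientation break a
    run (and, before any run starts, are skipped).
    """
    run_last: CtcfSite | None = None
    for s in ordered_sites:
        if s.orientation is None:
            continue
        if s.orientation == want:
            run_last = s
        elif run_last is not None:
            break  # opposite orientation ends the first run
    if run_last is None:
        return None
    return run_last.interval.start if side == "left" else run_last.interval.end


def shorten_domains(
    domains: Sequence[RegulatoryDomain],
    annotation: GeneAnnotation,
    sites: Sequence[CtcfSite],
    mode: str = "fr",
    pair_required: bool = False,
) -> list[RegulatoryDomain]:
    """Apply :func:`shorten_at_ctcf` to every domain (sites grouped by chrom)."""
    by_chrom: dict[str, list[CtcfSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: s.interval.start)
    out = []
    for d in domains:
        tss = annotation.by_id[d.transcript_id].tss
        out.append(
            shorten_at_ctcf(
                d, tss, by_chrom.get(d.interval.chrom, []), mode, pair_required=pair_required
            )
        )
    return out


# ---------------------------------------------------------------------------
# CTCF site construction and I/O


def ctcf_sites_from_peaks(
    peaks: Iterable[Peak],
    pwm,
    sequences,
    bg=None,
    alpha: float = 1e-4,
) -> list[CtcfSite]:
    """Orient CTCF peaks by the strand of their best CTCF-motif match.

    Peaks with no match above the p-value threshold carry no orientation
    (usable in ``nearest_any`` mode only).
    """
    from .motifs import Background, scan_windows, score_distribution

    bg = bg or Background()
    dist = score_distribution(pwm, bg)
    sites = []
    for p in peaks:
        hits = scan_windows([p.interval], sequences, pwm, bg, alpha, dist=dist)
        if hits:
            best = max(hits, key=lambda m: m.score)
            orientation = "F" if best.strand == "+" else "R"
        else:
            orientation = None
        sites.append(CtcfSite(p.interval, orientation, source="motif-strand"))
    return sites


def read_ctcf_bed(path: str | Path) -> list[CtcfSite]:
    """Read CTCF sites from BED6; strand column '+' → F, '-' → R, '.' → none."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: need >= 3 BED columns")
            strand = fields[5] if len(fields) > 5 else "."
            orientation = {"+": "F", "-": "R"}.get(strand)
            sites.append(
                CtcfSite(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    orientation,
                )
            )
    return sites


def write_ctcf_bed(sites: Sequence[CtcfSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            strand = {"F": "+", "R": "-"}.get(s.orientation, ".")
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tctcf{i}\t0\t{strand}\n")


def write_domains_bed(
    domains: Sequence[RegulatoryDomain], path: str | Path
) -> None:
    from .genome import write_bed6

    write_bed6(((d.interval, d.transcript_id, 0.0) for d in domains), path)


def domain_stats(domains: Sequence[RegulatoryDomain]) -> dict[str, float]:
    import numpy as np

    lengths = np.array([len(d.interval) for d in domains])
    return {
        "n": int(len(lengths)),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
    }
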