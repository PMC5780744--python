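"""Seed-reproducible synthetic inputs with planted ground truth.

The generator emulates the statistical structure the pipeline assumes in
real data: a genome with strand-aware transcripts at well-spaced TSSs;
open-chromatin peaks whose central windows contain planted consensus words
of sharp per-TF motifs; convergent (forward-reverse) CTCF site runs
flanking each gene's intended regulatory interval; log-normal expression;
and GMT-style annotation databases in which each TF's targets are
functionally coherent to a configurable degree rho.

Two entry points matter:

* :func:`generate_dataset` — the full genome-scale bundle (sequences,
  peaks, motifs, CTCF sites, expression, annotation, ground truth) that
  the end-to-end pipeline consumes.
* :func:`generate_enrichment_dataset` — a larger-universe, sequence-free
  bundle (expression, annotation, target tables) for studying the
  enrichment statistics themselves: FDR control on null data, recovery of
  planted (TF, term) associations, and the behaviour of the normalized
  enrichment count under target randomization.

Planted motifs are near-consensus (0.9 consensus probability), so at
width >= 8 only the exact consensus word clears the 1e-5 p-value
threshold and ground truth stays exact; decoy motif occurrences are never
planted.  Outward of each planted CTCF run an opposite-orientation
blocker site is emitted, which makes the planted boundary the provable
result of first-run forward-reverse shortening no matter what decoy
sites lie further out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import epa as epa_mod
from .enrichment import AnnotationDB, write_gene_sets
from .epa import CtcfSite, RULES, regulatory_domains, write_ctcf_bed
from .genome import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    Transcript,
    write_gene_models,
    write_peaks,
)
from .motifs import (
    BASES,
    Background,
    DictSequenceProvider,
    PWM,
    pvalue_threshold_score,
    reverse_complement,
    score_distribution,
    write_meme,
)
from .targets import ExpressionTable, TargetSet, TargetTable, highly_expressed

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_chroms: int = 1
    chrom_length: int = 20_000_000
    n_genes: int = 200
    n_tfs: int = 20
    motif_width: int = 10
    peaks_per_gene: int = 8          # capacity per gene zone, not a quota
    coherence: float = 0.5           # rho: fraction of targets from planted terms
    terms_per_tf: tuple[int, int] = (1, 3)  # per-TF planted-term count range
    n_terms: int = 500
    term_size: int = 20
    expression_mu: float = 1.0       # log-RPKM mean
    expression_sigma: float = 1.0    # log-RPKM sd
    ctcf_per_domain: int = 2         # sites per planted run on each side
    expression_bias: str = "none"    # none | enhancer-high | enhancer-low
    seed: int = 0
    # secondary knobs
    targets_per_tf: int = 30
    enhancer_fraction: float = 0.5   # of each TF's targets placed outside promoters
    designated_fraction: float = 0.5  # genes carrying the expression bias
    tss_spacing: int = 20_000
    top_fraction: float = 0.30
    peak_length: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.coherence <= 1):
            raise ValueError("coherence must be in [0, 1]")
        if self.expression_bias not in ("none", "enhancer-high", "enhancer-low"):
            raise ValueError(f"unknown expression_bias {self.expression_bias!r}")
        if self.n_genes < 2 * self.n_chroms:
            raise ValueError("need at least 2 genes per chromosome")


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    target_pairs: set[tuple[str, str]] = field(default_factory=set)
    enhancer_pairs: set[tuple[str, str]] = field(default_factory=set)
    promoter_pairs: set[tuple[str, str]] = field(default_factory=set)
    motif_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    ctcf_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    designated_genes: set[str] = field(default_factory=set)
    expression_bias: str = "none"


@dataclass
class SyntheticDataset:
    cfg: SyntheticConfig
    annotation: GeneAnnotation
    sequences: dict[str, str]
    expression: ExpressionTable
    db: AnnotationDB
    pwms: list[PWM]
    peaks: list[Peak]
    ctcf_sites: list[CtcfSite]
    truth: GroundTruth
    alias_table: dict[str, list[str]]
    expressed: set[str]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.annotation.chrom_sizes

    def sequence_provider(self) -> DictSequenceProvider:
        return DictSequenceProvider(self.sequences)

    def motif_to_tf(self) -> dict[str, str]:
        return {p.motif_id: p.tf_name for p in self.pwms}


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[GeneAnnotation, dict[str, np.ndarray]]:
    """Genes at TSSs spaced >= ``tss_spacing``; i.i.d. uniform ACGT sequence.

    Returned sequences are mutable uint8 arrays (base indices into ACGT)
    so motif words can be planted in place.
    """
    margin = 50_000
    per_chrom = _split_even(cfg.n_genes, cfg.n_chroms)
    transcripts: list[Transcript] = []
    sequences: dict[str, np.ndarray] = {}
    chrom_sizes: dict[str, int] = {}
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        slack = cfg.chrom_length - 2 * margin - (n - 1) * cfg.tss_spacing
        if slack <= 0:
            raise ValueError(
                f"{n} genes with {cfg.tss_spacing} bp spacing do not fit on "
                f"a {cfg.chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.uniform(0, slack, size=n))
        tss_positions = (margin + offsets + np.arange(n) * cfg.tss_spacing).astype(int)
        for tss in tss_positions:
            gi += 1
            gene_id = f"g{gi:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2000, 10001))
            if strand == "+":
                start, end = tss, min(tss + length, cfg.chrom_length)
            else:
                start, end = max(0, tss - length + 1), tss + 1
            transcripts.append(
                Transcript(gene_id, gene_id.upper(), GenomicInterval(chrom, start, end, strand))
            )
        sequences[chrom] = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
        chrom_sizes[chrom] = cfg.chrom_length
    return GeneAnnotation(transcripts, chrom_sizes), sequences


def _split_even(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def sequences_to_str(sequences: Mapping[str, np.ndarray]) -> dict[str, str]:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return {c: lut[a].tobytes().decode() for c, a in sequences.items()}


# ---------------------------------------------------------------------------
# expression and annotation


def generate_expression(
    cfg: SyntheticConfig,
    annotation: GeneAnnotation,
    rng: np.random.Generator,
) -> tuple[ExpressionTable, set[str]]:
    """Log-normal RPKM; designated genes get the log-mean shifted by +-1
    under an enhancer-high/-low bias.  Returns (table, designated genes)."""
    ids = sorted(annotation.by_id)
    designated: set[str] = set()
    if cfg.expression_bias != "none":
        n_designated = int(round(cfg.designated_fraction * len(ids)))
        designated = set(rng.choice(ids, size=n_designated, replace=False))
    shift = {"none": 0.0, "enhancer-high": 1.0, "enhancer-low": -1.0}[cfg.expression_bias]
    values = {}
    for gid in ids:
        mu = cfg.expression_mu + (shift if gid in designated else 0.0)
        values[gid] = float(np.exp(rng.normal(mu, cfg.expression_sigma)))
    return ExpressionTable(values), designated


def generate_annotation_db(
    cfg: SyntheticConfig,
    universe: list[str],
    rng: np.random.Generator,
) -> tuple[AnnotationDB, dict[str, frozenset[str]]]:
    """n_terms random terms of term_size genes (overlaps allowed) and the
    per-TF planted-term assignment."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(cfg.n_terms):
        members = frozenset(rng.choice(universe, size=cfg.term_size, replace=False))
        terms[f"T{i:04d}"] = (f"synthetic term {i}", members)
    db = AnnotationDB("synthetic_db", terms)
    lo, hi = cfg.terms_per_tf
    motif_terms: dict[str, frozenset[str]] = {}
    term_ids = sorted(terms)
    for ti in range(cfg.n_tfs):
        motif_id = f"M{ti:03d}"
        if cfg.coherence > 0:
            count = int(rng.integers(lo, hi + 1))
            motif_terms[motif_id] = frozenset(rng.choice(term_ids, size=count, replace=False))
        else:
            motif_terms[motif_id] = frozenset()
    return db, motif_terms


def _draw_targets(
    motif_id: str,
    motif_terms: Mapping[str, frozenset[str]],
    db: AnnotationDB,
    eligible: list[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> list[str]:
    """rho of the targets from the TF's planted terms (within the highly
    expressed set), the rest uniform from the highly expressed set."""
    eligible_set = set(eligible)
    planted_pool = sorted(
        set().union(*(db.terms[t][1] for t in motif_terms[motif_id]))
        & eligible_set
    ) if motif_terms[motif_id] else []
    n_coherent = min(int(round(cfg.coherence * cfg.targets_per_tf)), len(planted_pool))
    coherent = list(rng.choice(planted_pool, size=n_coherent, replace=False)) if n_coherent else []
    rest_pool = sorted(eligible_set - set(coherent))
    n_rest = min(cfg.targets_per_tf - len(coherent), len(rest_pool))
    rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
    return coherent + rest


# ---------------------------------------------------------------------------
# regulatory landscape (peaks, motifs, CTCF)

_CTCF_SITE_LEN = 20
_CTCF_RUN_STEP = 100
_BOUNDARY_MARGIN = 300  # planted boundary offset from the rule-4 domain edge


def _sharp_pwm(motif_id: str, tf_name: str, consensus_codes: np.ndarray) -> PWM:
    w = len(consensus_codes)
    probs = np.full((w, 4), (1 - 0.9) / 3)
    probs[np.arange(w), consensus_codes] = 0.9
    return PWM(motif_id, tf_name, tuple(map(tuple, probs)))


def generate_regulatory_landscape(
    cfg: SyntheticConfig,
    annotation: GeneAnnotation,
    sequences: dict[str, np.ndarray],
    expression: ExpressionTable,
    db: AnnotationDB,
    motif_terms: dict[str, frozenset[str]],
    rng: np.random.Generator,
) -> tuple[list[PWM], list[Peak], list[CtcfSite], GroundTruth, set[str]]:
    """Plant peaks with motif consensus words, and convergent CTCF runs.

    Enhancer-zone peaks sit inside the gene's planted forward-reverse CTCF
    interval (itself inside the rule-4 domain) but outside the promoter;
    promoter peaks sit within +-5 kb of the TSS.  Under an expression
    bias, the highest- (enhancer-high) or lowest- (enhancer-low) expressed
    members of each TF's target set are the ones assigned to enhancers.
    """
    expressed = highly_expressed(expression, cfg.top_fraction)
    eligible = sorted(expressed)
    rule4 = {d.transcript_id: d for d in regulatory_domains(annotation, RULES["rule4"])}

    truth = GroundTruth(expression_bias=cfg.expression_bias)
    pwms: list[PWM] = []
    used: dict[str, list[tuple[int, int]]] = {}  # per-chrom occupied intervals

    # CTCF runs + blockers per gene, fixed before peak placement
    ctcf_sites: list[CtcfSite] = []
    enhancer_zone: dict[str, list[tuple[int, int]]] = {}
    for gid, dom in rule4.items():
        t = annotation.by_id[gid]
        iv = dom.interval
        run_span = cfg.ctcf_per_domain * _CTCF_RUN_STEP
        left_ok = t.tss - epa_mod.PROMOTER_HALFWIDTH - (iv.start + _BOUNDARY_MARGIN + run_span) > 600
        right_ok = (iv.end - _BOUNDARY_MARGIN - run_span) - (t.tss + epa_mod.PROMOTER_HALFWIDTH) > 600
        if not (left_ok and right_ok):
            continue  # too cramped to carry a planted loop; gene stays unshortened
        bl = iv.start + _BOUNDARY_MARGIN
        br_end = iv.end - _BOUNDARY_MARGIN
        for i in range(cfg.ctcf_per_domain):
            s = bl + i * _CTCF_RUN_STEP
            ctcf_sites.append(CtcfSite(GenomicInterval(iv.chrom, s, s + _CTCF_SITE_LEN), "F"))
            e = br_end - i * _CTCF_RUN_STEP
            ctcf_sites.append(CtcfSite(GenomicInterval(iv.chrom, e - _CTCF_SITE_LEN, e), "R"))
        # opposite-orientation blockers just outward of each run
        ctcf_sites.append(
            CtcfSite(GenomicInterval(iv.chrom, bl - 200, bl - 200 + _CTCF_SITE_LEN), "R")
        )
        ctcf_sites.append(
            CtcfSite(GenomicInterval(iv.chrom, br_end + 180, br_end + 180 + _CTCF_SITE_LEN), "F")
        )
        truth.ctcf_boundaries[gid] = (bl, br_end)
        enhancer_zone[gid] = [
            (bl + run_span + 100, t.tss - epa_mod.PROMOTER_HALFWIDTH - cfg.peak_length - 50),
            (t.tss + epa_mod.PROMOTER_HALFWIDTH + 50, br_end - run_span - cfg.peak_length - 100),
        ]

    # decoy CTCF sites outward of the blockers, random orientation
    for gid, dom in rule4.items():
        if gid not in truth.ctcf_boundaries:
            continue
        iv = dom.interval
        bl, br_end = truth.ctcf_boundaries[gid]
        for zone in ((iv.start + 20, bl - 260), (br_end + 260, iv.end - 40)):
            if zone[1] - zone[0] > _CTCF_SITE_LEN:
                pos = int(rng.integers(zone[0], zone[1] - _CTCF_SITE_LEN))
                orient = "F" if rng.random() < 0.5 else "R"
                ctcf_sites.append(
                    CtcfSite(GenomicInterval(iv.chrom, pos, pos + _CTCF_SITE_LEN), orient)
                )

    peaks: list[Peak] = []
    for ti in range(cfg.n_tfs):
        motif_id = f"M{ti:03d}"
        tf_name = f"TF{ti:03d}"
        codes = rng.integers(0, 4, size=cfg.motif_width)
        pwm = _sharp_pwm(motif_id, tf_name, codes)
        pwms.append(pwm)
        truth.motif_terms[motif_id] = motif_terms.get(motif_id, frozenset())
        targets = _draw_targets(motif_id, motif_terms, db, eligible, cfg, rng)
        enhancer_targets = _assign_enhancer_targets(targets, expression, cfg, rng)
        for gid in targets:
            is_enh = gid in enhancer_targets
            placed = _place_peak(
                gid, is_enh, annotation, rule4, enhancer_zone, used, sequences, codes, cfg, rng
            )
            if placed is None:
                # fall back to the other zone before giving up
                placed = _place_peak(
                    gid, not is_enh, annotation, rule4, enhancer_zone, used, sequences,
                    codes, cfg, rng,
                )
                is_enh = not is_enh if placed is not None else is_enh
            if placed is None:
                raise ValueError(f"domain of {gid} too crowded to place a peak")
            peaks.append(placed)
            truth.target_pairs.add((motif_id, gid))
            (truth.enhancer_pairs if is_enh else truth.promoter_pairs).add((motif_id, gid))

    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    ctcf_sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    _validate_consensus_passes(pwms)
    return pwms, peaks, ctcf_sites, truth, expressed


def _assign_enhancer_targets(
    targets: list[str],
    expression: ExpressionTable,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> set[str]:
    n_enh = int(round(cfg.enhancer_fraction * len(targets)))
    if cfg.expression_bias == "none":
        return set(rng.choice(sorted(targets), size=n_enh, replace=False)) if n_enh else set()
    ranked = sorted(targets, key=lambda g: (expression[g], g))
    if cfg.expression_bias == "enhancer-high":
        return set(ranked[-n_enh:]) if n_enh else set()
    return set(ranked[:n_enh]) if n_enh else set()


def _place_peak(
    gid: str,
    enhancer: bool,
    annotation: GeneAnnotation,
    rule4,
    enhancer_zone,
    used: dict[str, list[tuple[int, int]]],
    sequences: dict[str, np.ndarray],
    consensus_codes: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> Peak | None:
    t = annotation.by_id[gid]
    dom = rule4[gid].interval
    if enhancer:
        zones = enhancer_zone.get(gid, [])
    else:
        zones = [
            (
                max(dom.start, t.tss - epa_mod.PROMOTER_HALFWIDTH + 50),
                min(dom.end, t.tss + epa_mod.PROMOTER_HALFWIDTH) - cfg.peak_length - 50,
            )
        ]
    zones = [z for z in zones if z[1] > z[0]]
    occupied = used.setdefault(t.chrom, [])
    for _ in range(40):
        if not zones:
            return None
        lo, hi = zones[int(rng.integers(0, len(zones)))]
        start = int(rng.integers(lo, hi))
        end = start + cfg.peak_length
        if any(s < end + 10 and start < e + 10 for s, e in occupied):
            continue
        occupied.append((start, end))
        _plant_word(sequences[t.chrom], start, end, consensus_codes, cfg, rng)
        return Peak(
            GenomicInterval(t.chrom, start, end),
            score=100.0,
            summit_offset=cfg.peak_length // 2,
        )
    return None


def _plant_word(
    seq: np.ndarray,
    peak_start: int,
    peak_end: int,
    codes: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    """Write the consensus (or its reverse complement) into the central
    50 bp of the peak."""
    center = (peak_start + peak_end) // 2
    w = len(codes)
    lo = center - 25
    off = int(rng.integers(0, 50 - w + 1))
    pos = lo + off
    word = codes if rng.random() < 0.5 else (3 - codes)[::-1]  # revcomp in code space
    seq[pos : pos + w] = word


def _validate_consensus_passes(pwms: list[PWM]) -> None:
    """Self-check: every planted consensus clears the 1e-5 threshold."""
    bg = Background()
    for pwm in pwms:
        dist = score_distribution(pwm, bg)
        threshold = pvalue_threshold_score(dist, 1e-5)
        from .motifs import log_odds_score

        score = log_odds_score(pwm, bg, pwm.consensus())
        if score < threshold:
            raise AssertionError(
                f"planted consensus of {pwm.motif_id} scores below the threshold"
            )


# ---------------------------------------------------------------------------
# bundles


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """The full genome-scale synthetic bundle, deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    annotation, seq_arrays = generate_genome(cfg, rng)
    expression, designated = generate_expression(cfg, annotation, rng)
    db, motif_terms = generate_annotation_db(cfg, sorted(annotation.by_id), rng)
    pwms, peaks, ctcf_sites, truth, expressed = generate_regulatory_landscape(
        cfg, annotation, seq_arrays, expression, db, motif_terms, rng
    )
    truth.designated_genes = designated
    dataset = SyntheticDataset(
        cfg=cfg,
        annotation=annotation,
        sequences=sequences_to_str(seq_arrays),
        expression=expression,
        db=db,
        pwms=pwms,
        peaks=peaks,
        ctcf_sites=ctcf_sites,
        truth=truth,
        alias_table={p.tf_name: [] for p in pwms},
        expressed=expressed,
    )
    _self_validate(dataset)
    return dataset


def _self_validate(ds: SyntheticDataset) -> None:
    """Assert the emitted files agree with the recorded ground truth."""
    provider = ds.sequence_provider()
    # every planted pair has a peak window containing its consensus word
    windows_by_gene: dict[str, list[GenomicInterval]] = {}
    for p in ds.peaks:
        windows_by_gene.setdefault(p.interval.chrom, []).append(p.interval)
    consensus = {p.motif_id: p.consensus() for p in ds.pwms}
    rule4 = {d.transcript_id: d for d in regulatory_domains(ds.annotation, RULES["rule4"])}
    for motif_id, gid in ds.truth.target_pairs:
        dom = rule4[gid].interval
        word = consensus[motif_id]
        found = False
        for p in ds.peaks:
            iv = p.interval
            if iv.chrom != dom.chrom or not dom.contains(iv):
                continue
            seq = provider.fetch(iv.chrom, iv.start, iv.end)
            if word in seq or reverse_complement(word) in seq:
                found = True
                break
        if not found:
            raise AssertionError(f"planted pair ({motif_id}, {gid}) missing from peaks")
    # planted FR boundaries reproduce under the shortening rule
    shortened = epa_mod.shorten_domains(
        list(rule4.values()), ds.annotation, ds.ctcf_sites, mode="fr"
    )
    for d in shortened:
        planted = ds.truth.ctcf_boundaries.get(d.transcript_id)
        if planted is None:
            continue
        if (d.interval.start, d.interval.end) != planted:
            raise AssertionError(
                f"FR shortening of {d.transcript_id} gives "
                f"[{d.interval.start}, {d.interval.end}), planted {planted}"
            )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit every standard-format file the pipeline reads; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.knownGene.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
        "fasta": outdir / "genome.fa",
        "peaks": outdir / "peaks.narrowPeak",
        "motifs": outdir / "motifs.meme",
        "ctcf": outdir / "ctcf.bed",
        "expression": outdir / "expression.tsv",
        "gmt": outdir / "annotation.gmt",
        "truth_targets": outdir / "truth_targets.tsv",
        "truth_ctcf": outdir / "truth_ctcf.tsv",
    }
    write_gene_models(ds.annotation, paths["genes"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in sorted(ds.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(ds.sequences):
            fh.write(f">{chrom}\n")
            seq = ds.sequences[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_peaks(ds.peaks, paths["peaks"])
    write_meme(ds.pwms, paths["motifs"])
    write_ctcf_bed(ds.ctcf_sites, paths["ctcf"])
    ds.expression.write_tsv(paths["expression"])
    write_gene_sets(ds.db, paths["gmt"])
    with open(paths["truth_targets"], "w") as fh:
        fh.write("motif_id\ttranscript_id\tvia\n")
        for motif_id, gid in sorted(ds.truth.target_pairs):
            via = "enhancer" if (motif_id, gid) in ds.truth.enhancer_pairs else "promoter"
            fh.write(f"{motif_id}\t{gid}\t{via}\n")
    with open(paths["truth_ctcf"], "w") as fh:
        fh.write("transcript_id\tleft\tright\n")
        for gid, (left, right) in sorted(ds.truth.ctcf_boundaries.items()):
            fh.write(f"{gid}\t{left}\t{right}\n")
    return paths


# ---------------------------------------------------------------------------
# sequence-free enrichment bundle


@dataclass
class EnrichmentDataset:
    cfg: SyntheticConfig
    universe: list[str]
    expression: ExpressionTable
    expressed: set[str]
    db: AnnotationDB
    table: TargetTable
    truth: GroundTruth


def enrichment_study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard conditions for studying the enrichment statistics:
    a 5000-gene universe, 500 terms of 50 genes, 60 TFs with 50 targets
    each, coherence 0.5 spread over 1-3 planted terms per TF."""
    params = dict(
        n_genes=5000,
        n_tfs=60,
        n_terms=500,
        term_size=50,
        targets_per_tf=50,
        coherence=0.5,
        terms_per_tf=(1, 3),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def generate_enrichment_dataset(cfg: SyntheticConfig) -> EnrichmentDataset:
    """Target sets over a large gene universe, without sequences.

    Emulates the post-prediction state of the pipeline: per-TF target sets
    of highly expressed genes, functionally coherent to degree rho, ready
    for enrichment, perturbation and FDR studies at a universe size the
    genome-scale bundle cannot reach cheaply.
    """
    rng = np.random.default_rng(cfg.seed)
    universe = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]
    values = {
        g: float(np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma)))
        for g in universe
    }
    expression = ExpressionTable(values)
    expressed = highly_expressed(expression, cfg.top_fraction)
    db, motif_terms = generate_annotation_db(cfg, universe, rng)
    eligible = sorted(expressed)
    truth = GroundTruth()
    sets = []
    for ti in range(cfg.n_tfs):
        motif_id = f"M{ti:03d}"
        targets = _draw_targets(motif_id, motif_terms, db, eligible, cfg, rng)
        truth.motif_terms[motif_id] = motif_terms[motif_id]
        truth.target_pairs.update((motif_id, g) for g in targets)
        sets.append(TargetSet(motif_id, f"TF{ti:03d}", frozenset(targets)))
    table = TargetTable(sets, condition="synthetic")
    return EnrichmentDataset(cfg, universe, expression, expressed, db, table, truth)
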