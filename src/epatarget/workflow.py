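"""End-to-end orchestration: one configuration in, a condition-by-database
report bundle out.

A condition is an association rule optionally combined with a CTCF
shortening mode (``"rule4+fr"``, ``"rule1"``, ``"promoter"``...).  For
each condition the pipeline predicts target genes, summarizes functional
enrichment per annotation database, optionally runs the
randomized-target controls, and compares target expression against the
promoter-only baseline.  A manifest records the seed, settings, timings
and every file written, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import (
    EnrichmentSummary,
    summarize_enrichment,
    write_summary_tsv,
    zscore_table,
)
from .epa import RULES, regulatory_domains, shorten_domains, write_domains_bed
from .expr_compare import compare_promoter_vs_epa, write_comparisons_tsv
from .motifs import Background, MotifMatch, scan_windows, score_distribution, write_matches
from .genome import central_window
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .targets import (
    PERTURB_FRACTIONS,
    PerturbationSpec,
    TargetTable,
    filter_min_targets,
    perturb_targets,
    predict_targets,
    remove_redundant_tfbs,
    target_stats,
    write_targets,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    All thresholds carry the study defaults: ±5 kb promoters, central
    50 bp windows, match p ≤ 1e-5, top 30 % expression, ≥ 5 targets,
    q ≤ 1e-3, ×1e5 normalization, 5–60 % perturbation ×3 replicates.
    """

    conditions: tuple[str, ...] = ("promoter", "rule4", "rule4+fr")
    simulate: SyntheticConfig | None = None
    outdir: str | Path = "epa_run"
    seed: int = 0
    alpha_match: float = 1e-5
    top_fraction: float = 0.30
    min_targets: int = 5
    q_threshold: float = 1e-3
    alpha_expression: float = 0.05
    perturb: bool = False
    perturb_fractions: tuple[float, ...] = PERTURB_FRACTIONS
    perturb_replicates: int = 3
    window_width: int = 50

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim)
        return cfg


def parse_condition(label: str) -> tuple[str, str | None]:
    """'rule4+fr' -> ('rule4', 'fr'); 'promoter' -> ('promoter', None)."""
    rule, _, mode = label.partition("+")
    if rule not in RULES:
        raise ValueError(f"unknown association rule {rule!r}")
    if mode and mode not in ("fr", "nearest", "nearest_any"):
        raise ValueError(f"unknown CTCF mode {mode!r}")
    return rule, {"nearest": "nearest_any"}.get(mode, mode) or None


def scan_all_motifs(
    dataset: SyntheticDataset,
    alpha: float = 1e-5,
    window_width: int = 50,
) -> list[MotifMatch]:
    """FIMO-style scan of every motif over the central peak windows."""
    provider = dataset.sequence_provider()
    bg = Background()
    windows = [central_window(p, window_width) for p in dataset.peaks]
    matches: list[MotifMatch] = []
    for pwm in dataset.pwms:
        dist = score_distribution(pwm, bg)
        matches.extend(scan_windows(windows, provider, pwm, bg, alpha, dist=dist))
    return matches


def targets_for_condition(
    dataset: SyntheticDataset,
    matches: Sequence[MotifMatch],
    condition: str,
    min_targets: int = 5,
) -> TargetTable:
    """Predict, deduplicate and size-filter target sets for one condition."""
    rule, ctcf_mode = parse_condition(condition)
    domains = regulatory_domains(dataset.annotation, RULES[rule])
    if ctcf_mode is not None:
        domains = shorten_domains(domains, dataset.annotation, dataset.ctcf_sites, ctcf_mode)
    motif_to_tf = dataset.motif_to_tf()
    table = predict_targets(
        matches, domains, dataset.expressed, motif_to_tf, condition=condition
    )
    table = remove_redundant_tfbs(table)
    return filter_min_targets(table, min_targets)


def perturbation_curves(
    table: TargetTable,
    dbs,
    universe: set[str],
    pool: set[str],
    fractions: Sequence[float] = PERTURB_FRACTIONS,
    replicates: int = 3,
    seed: int = 0,
    q_threshold: float = 1e-3,
) -> dict:
    """Normalized total enrichment vs perturbation level, mean ± SE.

    The 0 % point is the native table; each (mode, fraction) cell averages
    ``replicates`` independent randomizations.
    """
    def norm_total(tbl: TargetTable) -> float:
        return float(
            sum(s.normalized_total for s in summarize_enrichment(tbl, dbs, universe, q_threshold))
        )

    native = norm_total(table)
    curves: dict = {"native": native, "modes": {}}
    for mode in ("replace", "add"):
        per_fraction = []
        for frac in fractions:
            vals = [
                norm_total(
                    perturb_targets(
                        table, PerturbationSpec(mode, frac, rep, seed), pool
                    )
                )
                for rep in range(replicates)
            ]
            arr = np.asarray(vals)
            se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            per_fraction.append(
                {"fraction": frac, "mean": float(arr.mean()), "se": se, "values": vals}
            )
        curves["modes"][mode] = per_fraction
    return curves


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage for every condition; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "settings": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(cfg).items()
            if k != "simulate"
        },
        "conditions": {},
        "timings_s": {},
    }
    t0 = time.perf_counter()
    if cfg.simulate is None:
        raise ValueError("file-based inputs: build a SyntheticDataset-like bundle "
                         "and call the stage functions directly")
    sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    dataset = generate_dataset(sim)
    manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    matches = scan_all_motifs(dataset, cfg.alpha_match, cfg.window_width)
    write_matches(matches, outdir / "matches.tsv")
    manifest["timings_s"]["scan"] = round(time.perf_counter() - t0, 3)

    universe = dataset.db.genes() & set(dataset.annotation.by_id)
    tables: dict[str, TargetTable] = {}
    summaries_by_condition: dict[str, list[EnrichmentSummary]] = {}
    for condition in cfg.conditions:
        t0 = time.perf_counter()
        cdir = outdir / condition.replace("+", "_")
        cdir.mkdir(exist_ok=True)
        table = targets_for_condition(dataset, matches, condition, cfg.min_targets)
        tables[condition] = table
        write_targets(table, cdir / "targets.tsv")
        rule, ctcf_mode = parse_condition(condition)
        domains = regulatory_domains(dataset.annotation, RULES[rule])
        if ctcf_mode:
            domains = shorten_domains(
                domains, dataset.annotation, dataset.ctcf_sites, ctcf_mode
            )
        write_domains_bed(domains, cdir / "domains.bed")
        stats = target_stats(table)
        summaries = summarize_enrichment(table, [dataset.db], universe, cfg.q_threshold)
        summaries_by_condition[condition] = summaries
        write_summary_tsv(summaries, cdir / "enrichment_summary.tsv")
        bundle = {
            "stats": stats,
            "enrichment": [dataclasses.asdict(s) for s in summaries],
            "files": ["targets.tsv", "domains.bed", "enrichment_summary.tsv"],
        }
        if cfg.perturb and len(table) > 0:
            bundle["perturbation"] = perturbation_curves(
                table,
                [dataset.db],
                universe,
                dataset.expressed,
                cfg.perturb_fractions,
                cfg.perturb_replicates,
                cfg.seed,
                cfg.q_threshold,
            )
        manifest["conditions"][condition] = bundle
        manifest["timings_s"][condition] = round(time.perf_counter() - t0, 3)

    # expression comparison of every non-promoter condition vs the baseline
    if "promoter" in tables:
        for condition, table in tables.items():
            if condition == "promoter" or len(table) == 0:
                continue
            try:
                comparisons, summary = compare_promoter_vs_epa(
                    tables["promoter"], table, dataset.expression,
                    cfg.alpha_expression, cfg.min_targets,
                )
            except ValueError:
                continue
            cdir = outdir / condition.replace("+", "_")
            write_comparisons_tsv(comparisons, cdir / "expression_comparison.tsv")
            manifest["conditions"][condition]["expression_vs_promoter"] = {
                "n_red": summary.n_red,
                "n_blue": summary.n_blue,
                "n_grey": summary.n_grey,
                "ratio_red": summary.ratio_red,
                "ratio_blue": summary.ratio_blue,
                "sum_median_ratio": summary.sum_median_ratio,
            }

    # z-scores of normalized totals across conditions, per database
    rows = {}
    for db_idx, db_name in enumerate([dataset.db.name]):
        values = [
            summaries_by_condition[c][db_idx].normalized_total for c in cfg.conditions
        ]
        rows[db_name] = dict(zip(cfg.conditions, map(float, zscore_table(values))))
    manifest["zscores"] = rows

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
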