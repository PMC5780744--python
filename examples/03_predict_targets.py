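"""Predict TF target genes on a synthetic genome and verify the planting.

Generates a small genome with planted motif matches inside open-chromatin
peaks, scans the central 50-bp peak windows, assigns targets under the
promoter-only baseline and the single-nearest-gene rule, and compares the
recovered (motif, gene) pairs with the generator's ground truth.
"""

from epatarget import SyntheticConfig, generate_dataset, target_stats
from epatarget.workflow import scan_all_motifs, targets_for_condition

cfg = SyntheticConfig(n_genes=60, chrom_length=5_000_000, n_tfs=6,
                      targets_per_tf=12, n_terms=40, term_size=8, seed=7)
ds = generate_dataset(cfg)
matches = scan_all_motifs(ds)
print(f"{len(ds.peaks)} peaks, {len(matches)} motif matches at p<=1e-5")

for condition in ("promoter", "rule4"):
    table = targets_for_condition(ds, matches, condition, min_targets=1)
    stats = target_stats(table)
    print(f"{condition:9s} {stats['n_tfbs']} motifs, mean {stats['mean_targets']:.1f} "
          f"targets, {stats['total_pairs']} pairs, {stats['unique_targets']} unique genes")

table = targets_for_condition(ds, matches, "rule4", min_targets=1)
got = {(s.motif_id, t) for s in table.sets for t in s.targets}
want = {(m, g) for m, g in ds.truth.target_pairs if g in ds.expressed}
print(f"planted pairs recovered exactly: {got == want} "
      f"({len(got & want)}/{len(want)})")
print("-> promoter-only capture misses the enhancer-placed half of the planted")
print("   pairs; the nearest-gene rule recovers all of them.")
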