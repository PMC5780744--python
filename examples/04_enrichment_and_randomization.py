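"""Functional enrichment of target sets and the randomization control.

Generates functionally coherent target sets over a 5000-gene universe
(half of each TF's targets drawn from its planted annotation terms),
counts enriched terms at q <= 1e-3, and shows that replacing or adding
randomly selected highly expressed genes lowers the normalized
enrichment count — native target sets are the most coherent.
"""

from epatarget import count_enrichments, enrich_table
from epatarget.synthetic import enrichment_study_config, generate_enrichment_dataset
from epatarget.workflow import perturbation_curves

eds = generate_enrichment_dataset(enrichment_study_config(seed=1))
universe = set(eds.universe)
results = enrich_table(eds.table, eds.db, universe)
total, unique = count_enrichments(results, q_threshold=1e-3)
planted = {(m, t) for m, ts in eds.truth.motif_terms.items() for t in ts}
flagged = {(r.motif_id, r.term_id) for r in results if r.qvalue <= 1e-3}
print(f"{len(eds.table)} TFs, {eds.table.total_pairs} target-gene pairs")
print(f"enriched (TF, term) pairs: {total} total, {unique} unique terms")
print(f"planted associations recovered: {len(flagged & planted)}/{len(planted)}")

curves = perturbation_curves(eds.table, [eds.db], universe, eds.expressed, seed=1)
print(f"\nnormalized enrichment (count / target pairs x 1e5), native: "
      f"{curves['native']:.0f}")
for mode, points in curves["modes"].items():
    row = "  ".join(f"{p['fraction']:.0%}:{p['mean']:.0f}±{p['se']:.0f}" for p in points)
    print(f"{mode:8s} {row}")
print("-> every perturbed level falls below the native value, in both modes;")
print("   the normalized count is a usable score for target-set quality.")
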