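"""Regulatory domains under the four association rules, and CTCF shortening.

Three genes on one 1-Mb chromosome; prints each rule's per-gene domain,
then shortens the middle gene's single-nearest-gene domain at convergent
(forward-reverse) CTCF sites.
"""

from epatarget import (
    CtcfSite,
    GenomicInterval,
    RULES,
    regulatory_domains,
    shorten_at_ctcf,
)
from epatarget.genome import GeneAnnotation, Transcript

ann = GeneAnnotation(
    [
        Transcript("geneA", "GENEA", GenomicInterval("chr1", 100_000, 105_000, "+")),
        Transcript("geneB", "GENEB", GenomicInterval("chr1", 500_000, 508_000, "+")),
        Transcript("geneC", "GENEC", GenomicInterval("chr1", 790_001, 800_001, "-")),
    ],
    {"chr1": 1_000_000},
)

for rule in ("promoter", "rule1", "rule2", "rule3", "rule4"):
    domains = regulatory_domains(ann, rule)
    spans = ", ".join(
        f"{d.transcript_id}:[{d.interval.start:,}-{d.interval.end:,})" for d in domains
    )
    print(f"{rule:9s} {spans}")

(rule4_b,) = [d for d in regulatory_domains(ann, "rule4") if d.transcript_id == "geneB"]
sites = [
    CtcfSite(GenomicInterval("chr1", 350_000, 350_020), "F"),
    CtcfSite(GenomicInterval("chr1", 360_000, 360_020), "F"),
    CtcfSite(GenomicInterval("chr1", 620_000, 620_020), "R"),
]
short = shorten_at_ctcf(rule4_b, tss=500_000, sites=sites, mode="fr")
print(f"\ngeneB rule4 domain {rule4_b.interval.start:,}-{rule4_b.interval.end:,} "
      f"shortened at FR CTCF sites -> {short.interval.start:,}-{short.interval.end:,}")
print("-> the left boundary is the most external site of the first forward run;")
print("   the right boundary is the end of the first reverse-oriented site.")
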