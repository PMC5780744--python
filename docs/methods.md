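# Methods

This note documents the models, defaults and design choices behind
`epatarget`, in the order the pipeline runs them.

## Coordinates and gene models

All intervals are 0-based, half-open (BED convention). knownGene-style
`txStart`/`txEnd` columns are read as-is; GTF input (1-based, closed) is
converted. The TSS of a minus-strand transcript is `end − 1`, the last base
of its half-open interval. Transcripts sharing a TSS are all retained unless
a canonical-transcript list removes them; target genes are reported by
transcript id with the gene symbol attached. Promoters are `[tss − 5 kb,
tss + 5 kb)` clipped to the chromosome; a zero-width promoter request is an
error rather than a silent empty interval.

The central window of a peak is centred on `floor((start + end) / 2)` with
length `min(50, peak length)`, clipped into the peak. The centring rule for
odd lengths is a documented fixed choice; nothing downstream is sensitive
to a 1-bp shift.

## Motif scanning and exact p-values

PWMs come from minimal MEME files (probability rows, floored at 10⁻⁴ and
renormalized) or TRANSFAC count matrices (pseudocount 0.25 per cell before
normalization — a common FIMO-adjacent default, configurable). Scoring is
log₂-odds against a background distribution, uniform by default
(configurable per run); minus-strand words are scored on the reverse
complement and reported in forward coordinates.

The null distribution of the score of a random background word is exact:
per-column score contributions are rounded to an ε = 10⁻³-bit grid and the
column distributions convolved, giving the full pmf of the discretized
score. The p ≤ 10⁻⁵ match threshold is then the minimal grid score whose
tail mass is ≤ 10⁻⁵ (tight: one grid step lower already exceeds it). The
quantization error is at most w·ε/2 in score, which tests bound by checking
that DP tails are bracketed by enumeration tails at ±10 ε. Per-strand
p-values are not corrected across strands (FIMO-like); overlapping
opposite-strand matches are both reported and deduplicated only at target
assignment. No per-match q-values, higher-order backgrounds, or motif
discovery.

Motif names map to gene symbols case-insensitively after stripping
non-alphanumerics, exact symbol match before alias match; unmapped motifs
are logged and excluded downstream.

## Regulatory domains

Four association rules plus a promoter-only baseline:

| rule | basal | extension |
|---|---|---|
| promoter | ±5 kb | none |
| rule1 | 5 kb + 5 kb | to neighbour basal domains, ≤ 300 kb from TSS |
| rule2 | 5 kb + 1 kb | to neighbour basal domains, ≤ 1 Mb from TSS |
| rule3 | ±5 kb | to nearest upstream/downstream TSS, uncapped |
| rule4 | ±5 kb | to TSS midpoints with neighbours, uncapped |

Rule 1/2 follow the basal-plus-extension convention: each side extends to
`min(TSS ± cap, neighbour basal boundary)` and never shrinks below the own
basal region; caps are measured from the TSS. A midpoint-limited variant is
available behind `midpoint_variant=True`. Rules 3/4 fall back to the
chromosome ends where a neighbour is missing, and every rule unions in the
own promoter, so domains are never smaller than ±5 kb. Rule-4 domains tile
each chromosome exactly when TSSs are distinct (midpoint `(a+b)//2` is the
exclusive end of the left domain and the inclusive start of the right one).
Neighbours are the nearest transcripts at a *distinct* TSS; co-located
transcripts share identical domains.

### CTCF shortening

Only CTCF sites fully inside a domain and not overlapping the ±5 kb
promoter are boundary candidates — a domain is never truncated into the
promoter. `nearest_any` cuts each side at the candidate closest to the TSS
(left boundary = that site's start, right = that site's end), regardless of
orientation; equidistant ties pick the lower start. `fr` mode uses motif
orientation: scanning outward from the TSS, wrongly oriented sites are
skipped until the first forward site (left side; reverse on the right), the
run of consecutive correctly oriented sites is followed, and the cut is at
the most external site of that *first* run — sites beyond an interrupting
opposite-orientation site are never reached. Shortening each side is
independent by default; `pair_required=True` demands both sides before
shortening either. Orientation comes from the strand of the best CTCF-motif
match inside each CTCF peak; unoriented peaks participate only in
`nearest_any`. "Most external within the first consecutive run" is the
implemented reading of the rule; the alternative (most external on the whole
side) is deliberately not implemented because runs are what convergent loop
anchors form.

## Targets, filters, perturbation

A gene is a target of a motif iff some match of that motif *starts* inside
the gene's domain and the gene is highly expressed. The start-position test
keeps assignment unambiguous under tiling rules (a point cannot straddle a
boundary); `overlap="any"` is available. Highly expressed = the
`ceil(0.30 · N)` transcripts with the highest mean RPKM, ties at the cut
broken by transcript id. Replicate RPKM columns are averaged on load, never
trusted from the file. Motifs of the same TF with *identical* target sets
are redundant; the lexicographically smallest motif id is kept. Motifs with
fewer than 5 targets are dropped.

Perturbation replaces or adds `round(fraction · n)` genes (half-up
rounding) sampled without replacement from the highly expressed pool minus
the current targets; replacement victims are uniform among current targets.
Each (motif, replicate) pair draws from its own seeded RNG substream, so
adding a motif to a run cannot shift another motif's draws. Fractions
default to 5/10/20/40/60 % with 3 replicates.

## Enrichment statistics

Each (TF, database) pair is tested term-by-term with the exact
hypergeometric upper tail `P(X ≥ k)` for `k` targets in the term, `K`
targets, `n` term genes, `N` universe genes, then Benjamini–Hochberg
adjusted within that pair (the smallest defensible family; a global
per-database family is a configuration switch). The universe is the
annotation's genes intersected with the gene annotation. Terms with
q ≤ 10⁻³ count as enrichments: `total` counts (TF, term) pairs, `unique`
distinct terms. The exact test deliberately stands in for the permutation
z-scores of legacy enrichment tools: it is transparent, deterministic and
testable against a combinatorial oracle. Annotation terms are flat gene sets; no
ontology DAG propagation or term pruning.

Normalized count = `count / Σ_TF |targets| × 10⁵`. Published tables that
motivate this statistic are internally consistent only in *ratios* (their
absolute normalized values imply a ~10× larger denominator than the printed
target means allow), so this package compares conditions by fold change of
normalized counts, where the denominator convention cancels.

Condition comparison calls a term "more enriched" in A when its enriched-TF
count is ≥ 2× the count in B (boundary inclusive) and nonzero. The 2×2
chi-square (Pearson, no continuity correction) uses enriched vs
non-enriched TF counts by default; a target-gene-total construction is
available via the function arguments since the published table legends are
ambiguous between the two. Z-scores across conditions use the population
standard deviation; constant rows map to zeros.

The expression-only baseline enriches the whole top-30 % set against each
database at raw p ≤ 0.01 (or 0.05), with no per-TF structure.

## Expression comparison

For each motif present in both conditions with ≥ 5 targets each, the two
target sets' RPKM values are compared with a two-sided Mann–Whitney test
(exact when both sets ≤ 20 and tie-free, asymptotic with tie correction
otherwise). Red = EPA median higher and p ≤ 0.05; blue = lower and
p ≤ 0.05; else grey. Dot-level p-values are unadjusted by default (each dot
is its own claim, mirroring per-TF significance marking); `adjust=True`
switches to BH. The summary ratio is `Σ median_EPA / Σ median_promoter`
over compared motifs, invariant to motif relabeling.

## Synthetic data

The generator is first-class, tested code; its defaults are the study
conditions and were fixed once.

**Genome** — 1 chromosome × 20 Mb, 200 genes, TSSs ≥ 20 kb apart (order
statistics over the residual slack), random strands, gene bodies 2–10 kb,
i.i.d. uniform ACGT sequence. **Expression** — RPKM ~ LogNormal(μ = 1,
σ = 1); under an enhancer bias, a designated half of the genes gets μ ± 1.
**Annotation** — 500 terms of 20 genes drawn uniformly with overlap; each
TF is planted into 1–3 terms. **Landscape** — each of 20 TFs gets a sharp
PWM (0.9 consensus probability: at width 10 only the exact consensus clears
the 10⁻⁵ threshold, so ground truth is exact; decoy occurrences are never
planted) and 30 planted targets, half drawn from its planted terms ∩
top-30 % (coherence ρ = 0.5), half uniform from the top-30 %. Half of each
TF's peaks are placed in the promoter, half in the enhancer zone between
the planted CTCF boundaries and the promoter; under an expression bias the
highest- (or lowest-) expressed targets take the enhancer slots, which is
what makes the red/blue direction recoverable. Each gene's rule-4 domain
carries convergent CTCF runs (2 forward sites inside the left edge, 2
reverse inside the right). Outward of each run sits one
*opposite*-orientation blocker site, which makes the planted boundary the
provable outcome of first-run FR shortening regardless of the
random-orientation decoy sites placed further out. The generator
self-validates before returning: planted consensus words are present in the
emitted peak windows, and FR shortening of the rule-4 domains reproduces
the planted boundaries exactly.

**Enrichment-scale bundle** — the genome bundle's 200-gene universe is too
small for q ≤ 10⁻³ enrichment to be attainable at all (with ~30 targets and
20-gene terms the best achievable tail probabilities sit near 10⁻³ before
correction), which is itself the expected behaviour of the statistic at
desk scale. The enrichment properties are therefore studied on a
sequence-free bundle with the same target-set construction over a 5000-gene
universe: 60 TFs × 50 targets, 500 terms of 50 genes, ρ = 0.5,
1–3 planted terms per TF. These sizes were chosen once, from the
hypergeometric calculation, so that TFs with one planted term are recovered
with overwhelming confidence while TFs with three planted terms sit near
the q = 10⁻³ boundary — making recovery high (≈ 0.9) *and* the normalized
count sensitive to 5 % target randomization, as the statistic must be to be
useful. In `add` mode the denominator grows, so the normalized count falls
even where raw counts do not; in `replace` mode the decrease comes entirely
from boundary terms dropping out.

**What the generator does not emulate:** realistic nucleotide composition
or conservation, chromatin-state structure, correlated expression,
DNase cut bias, overlapping genes, alternative TSSs, or motif families with
correlated PWMs. Passing tests therefore demonstrate correctness of the
*procedure* under the stated statistical structure, not performance on real
chromatin data.

## Problem sizes and determinism

Default scales (200-gene genome, 5000-gene enrichment universe, 20–200 TFs)
run each stage in seconds to ~1 minute on one CPU; they were chosen as the
smallest sizes at which every statistic of interest is non-degenerate.
Every stochastic step threads a `numpy` Generator seeded from a single
configuration seed (perturbation uses per-(motif, replicate) spawned
substreams); identical configuration + seed reproduces every output file
byte for byte, and the pipeline manifest records seed, settings and
timings.

## Known limitations

- File-based (non-simulated) pipeline runs are composed from the stage
  functions or the CLI; `run_pipeline` itself takes a simulate-block
  configuration.
- Enrichment databases are flat GMT sets; GO-style DAG propagation would
  change `n` and `N` per term.
- The Mann–Whitney exact path disables itself under ties; with heavily tied
  RPKM values small-sample p-values are approximate.
- No Hi-C/TAD awareness beyond planted convergent CTCF sites; no peak
  calling or RPKM computation from reads — peaks and expression tables are
  inputs.
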