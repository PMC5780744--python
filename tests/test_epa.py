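import numpy as np
import pytest

from epatarget import (
    CtcfSite,
    GenomicInterval,
    RULES,
    RegulatoryDomain,
    regulatory_domains,
    shorten_at_ctcf,
)
from epatarget.epa import read_ctcf_bed, write_ctcf_bed

import oracles
from conftest import make_annotation


def domain_of(domains, gid):
    (d,) = [d for d in domains if d.transcript_id == gid]
    return d


def random_genome(rng, max_genes=20, chrom_len=3_000_000):
    n = int(rng.integers(2, max_genes + 1))
    tss = np.sort(rng.choice(np.arange(6000, chrom_len - 6000), size=n, replace=False))
    strands = rng.choice(["+", "-"], size=n)
    return [(f"g{i}", int(t), s) for i, (t, s) in enumerate(zip(tss, strands))], chrom_len


class TestRules:
    def test_rule4_two_genes_tile_at_midpoint(self):
        ann = make_annotation([("a", 100_000, "+"), ("b", 200_000, "+")])
        domains = regulatory_domains(ann, "rule4")
        assert (domain_of(domains, "a").interval.start, domain_of(domains, "a").interval.end) == (0, 150_000)
        assert (domain_of(domains, "b").interval.start, domain_of(domains, "b").interval.end) == (150_000, 1_000_000)

    def test_rule1_isolated_gene_extends_to_cap(self):
        ann = make_annotation([("a", 500_000, "+")])
        (d,) = regulatory_domains(ann, "rule1")
        assert (d.interval.start, d.interval.end) == (200_000, 800_000)

    def test_rule1_extension_stops_at_neighbor_basal(self):
        ann = make_annotation([("a", 100_000, "+"), ("b", 110_000, "+")])
        domains = regulatory_domains(ann, "rule1")
        assert (domain_of(domains, "a").interval.start, domain_of(domains, "a").interval.end) == (0, 105_000)
        assert (domain_of(domains, "b").interval.start, domain_of(domains, "b").interval.end) == (105_000, 410_000)

    def test_empty_annotation_rejected(self):
        from epatarget import GeneAnnotation

        with pytest.raises(ValueError):
            regulatory_domains(GeneAnnotation([], {"chr1": 1000}), "rule4")

    @pytest.mark.parametrize("rule", ["promoter", "rule1", "rule2", "rule3", "rule4"])
    def test_intervals_match_per_base_oracle(self, rng, rule):
        """Implementation intervals equal the straight-line oracle, and
        per-base membership agrees at sampled positions."""
        for _ in range(15):
            genes, chrom_len = random_genome(rng)
            ann = make_annotation([g for g in genes], chrom_len=chrom_len)
            domains = {d.transcript_id: d.interval for d in regulatory_domains(ann, rule)}
            spec = [(t, s) for _, t, s in genes]
            for gid, tss, strand in genes:
                want = oracles.oracle_domain(rule, (tss, strand), spec, chrom_len)
                got = (domains[gid].start, domains[gid].end)
                assert got == want, (rule, gid, got, want)
            for pos in rng.integers(0, chrom_len, size=30):
                want_members = oracles.oracle_membership(rule, int(pos), spec, chrom_len)
                got_members = {
                    i for i, (gid, *_rest) in enumerate(genes)
                    if domains[gid].contains_point(int(pos))
                }
                assert got_members == want_members

    def test_rule4_tiles_chromosome(self, rng):
        genes, chrom_len = random_genome(rng, max_genes=12)
        ann = make_annotation(genes, chrom_len=chrom_len)
        ivs = sorted(
            (d.interval.start, d.interval.end) for d in regulatory_domains(ann, "rule4")
        )
        assert ivs[0][0] == 0 and ivs[-1][1] == chrom_len
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            assert e1 == s2

    def test_domains_contain_promoter_and_fit_chromosome(self, rng):
        genes, chrom_len = random_genome(rng)
        ann = make_annotation(genes, chrom_len=chrom_len)
        for rule in RULES.values():
            for d in regulatory_domains(ann, rule):
                tss = ann.by_id[d.transcript_id].tss
                assert d.interval.start <= max(0, tss - 5000)
                assert d.interval.end >= min(chrom_len, tss + 5000)
                assert 0 <= d.interval.start < d.interval.end <= chrom_len


def fr_case(domain, tss, sites, mode="fr"):
    dom = RegulatoryDomain("g", GenomicInterval("chr1", *domain, "+"), RULES["rule4"])
    site_objs = [
        CtcfSite(GenomicInterval("chr1", s, e), o) for s, e, o in sites
    ]
    out = shorten_at_ctcf(dom, tss, site_objs, mode)
    return out.interval.start, out.interval.end


CTCF_BATTERY = [
    # (domain, tss, [(start, end, orient)...])
    ((0, 1_000_000), 500_000,
     [(100_000, 100_020, "F"), (150_000, 150_020, "F"), (800_000, 800_020, "R")]),
    ((0, 1_000_000), 500_000,
     [(450_000, 450_020, "R"), (400_000, 400_020, "F"),
      (380_000, 380_020, "F"), (300_000, 300_020, "R")]),
    # one-sided: only left candidates
    ((0, 1_000_000), 500_000, [(200_000, 200_020, "F")]),
    # RF interleaving on the right
    ((0, 1_000_000), 500_000,
     [(550_000, 550_020, "F"), (600_000, 600_020, "R"),
      (650_000, 650_020, "R"), (700_000, 700_020, "F"), (750_000, 750_020, "R")]),
    # FF...R long run on the left
    ((0, 1_000_000), 500_000,
     [(470_000, 470_020, "F"), (460_000, 460_020, "F"), (440_000, 440_020, "F"),
      (430_000, 430_020, "R"), (420_000, 420_020, "F")]),
    # promoter-overlapping sites are never boundaries
    ((0, 1_000_000), 500_000,
     [(499_000, 499_020, "F"), (501_000, 501_020, "R"), (300_000, 300_020, "F")]),
    # sites outside the domain ignored
    ((400_000, 600_000), 500_000,
     [(100_000, 100_020, "F"), (900_000, 900_020, "R"), (420_000, 420_020, "F")]),
    # unoriented sites skipped in FR mode
    ((0, 1_000_000), 500_000,
     [(450_000, 450_020, None), (400_000, 400_020, "F"), (600_000, 600_020, None),
      (700_000, 700_020, "R")]),
    # no sites at all
    ((0, 1_000_000), 500_000, []),
]


class TestCtcfShortening:
    def test_fr_worked_example_consecutive_run(self):
        got = fr_case(*CTCF_BATTERY[0])
        assert got == (100_000, 800_020)

    def test_fr_first_run_most_external(self):
        got = fr_case(*CTCF_BATTERY[1])
        assert got[0] == 380_000

    def test_nearest_any_uses_closest_site(self):
        got = fr_case(
            (0, 1_000_000), 500_000,
            [(450_000, 450_020, "R"), (430_000, 430_020, "F")],
            mode="nearest_any",
        )
        assert got == (450_000, 1_000_000)

    def test_no_sites_identity(self):
        assert fr_case(*CTCF_BATTERY[8]) == (0, 1_000_000)

    @pytest.mark.parametrize("case", range(len(CTCF_BATTERY)))
    def test_battery_matches_straight_line_oracle(self, case):
        domain, tss, sites = CTCF_BATTERY[case]
        assert fr_case(domain, tss, sites) == oracles.oracle_fr_shorten(domain, tss, sites)
        got_na = fr_case(domain, tss, sites, mode="nearest_any")
        want_na = oracles.oracle_nearest_shorten(
            domain, tss, [s for s in sites]
        )
        assert got_na == want_na

    def test_random_sites_match_oracle_and_invariants(self, rng):
        """Randomized fixtures: oracle equality + nesting + nearest_any at
        least as aggressive as FR on each side."""
        for _ in range(100):
            tss = 500_000
            domain = (int(rng.integers(0, 400_000)), int(rng.integers(600_000, 1_000_000)))
            n = int(rng.integers(0, 12))
            sites = []
            for _ in range(n):
                s = int(rng.integers(domain[0], domain[1] - 40))
                o = [None, "F", "R"][int(rng.integers(0, 3))]
                sites.append((s, s + 20, o))
            sites.sort()
            fr = fr_case(domain, tss, sites)
            na = fr_case(domain, tss, sites, mode="nearest_any")
            assert fr == oracles.oracle_fr_shorten(domain, tss, sites)
            assert na == oracles.oracle_nearest_shorten(domain, tss, sites)
            # nesting: promoter <= shortened <= domain
            for lo, hi in (fr, na):
                assert domain[0] <= lo <= tss - 5000 or lo == domain[0]
                assert tss + 5000 <= hi <= domain[1] or hi == domain[1]
            assert na[0] >= fr[0] or fr[0] == domain[0]
            assert na[1] <= fr[1] or fr[1] == domain[1]

    def test_pair_required_leaves_one_sided_untouched(self):
        domain, tss, sites = CTCF_BATTERY[2]
        dom = RegulatoryDomain("g", GenomicInterval("chr1", *domain, "+"), RULES["rule4"])
        out = shorten_at_ctcf(
            dom, tss, [CtcfSite(GenomicInterval("chr1", s, e), o) for s, e, o in sites],
            "fr", pair_required=True,
        )
        assert (out.interval.start, out.interval.end) == domain


def test_ctcf_bed_roundtrip(tmp_path):
    sites = [
        CtcfSite(GenomicInterval("chr1", 100, 120), "F"),
        CtcfSite(GenomicInterval("chr1", 500, 520), "R"),
        CtcfSite(GenomicInterval("chr2", 900, 920), None),
    ]
    p = tmp_path / "ctcf.bed"
    write_ctcf_bed(sites, p)
    back = read_ctcf_bed(p)
    assert [(s.interval.chrom, s.interval.start, s.orientation) for s in back] == [
        (s.interval.chrom, s.interval.start, s.orientation) for s in sites
    ]
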