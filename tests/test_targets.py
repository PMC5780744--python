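import numpy as np
import pytest

from epatarget import (
    ExpressionTable,
    GenomicInterval,
    MotifMatch,
    PerturbationSpec,
    RULES,
    RegulatoryDomain,
    TargetSet,
    TargetTable,
    filter_min_targets,
    highly_expressed,
    perturb_targets,
    predict_targets,
    remove_redundant_tfbs,
    target_stats,
)
from epatarget.targets import read_targets, write_targets


def match(motif, pos, chrom="chr1"):
    return MotifMatch(motif, GenomicInterval(chrom, pos, pos + 10), "+", 10.0, 1e-6)


def domain(gid, start, end, chrom="chr1"):
    return RegulatoryDomain(gid, GenomicInterval(chrom, start, end, "+"), RULES["rule4"])


class TestHighlyExpressed:
    def test_top_three_of_ten(self):
        expr = ExpressionTable({f"g{i}": float(i) for i in range(1, 11)})
        assert highly_expressed(expr) == {"g8", "g9", "g10"}

    def test_equal_values_tie_broken_by_id(self):
        expr = ExpressionTable({f"g{i}": 1.0 for i in range(10)})
        assert highly_expressed(expr) == {"g0", "g1", "g2"}

    def test_ceiling_of_fraction(self):
        expr = ExpressionTable({f"g{i}": float(i) for i in range(7)})
        assert len(highly_expressed(expr)) == 3  # ceil(2.1)

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable({"g1": -1.0})

    def test_replicate_means_recomputed(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("transcript_id\trep1\trep2\ng1\t2.0\t4.0\ng2\t1.0\t1.0\n")
        expr = ExpressionTable.read_tsv(p)
        assert expr["g1"] == pytest.approx(3.0)


class TestPredictTargets:
    MOTIF_TO_TF = {"m1": "TF1", "m2": "TF2", "m_unmapped": None}

    def test_no_matches_empty_table(self):
        table = predict_targets([], [domain("a", 0, 1000)], {"a"}, self.MOTIF_TO_TF)
        assert len(table) == 0

    def test_single_match_single_target(self):
        table = predict_targets(
            [match("m1", 500)], [domain("a", 0, 1000)], {"a"}, self.MOTIF_TO_TF
        )
        assert table.by_motif()["m1"].targets == frozenset({"a"})

    def test_not_expressed_gene_excluded(self):
        table = predict_targets(
            [match("m1", 500)], [domain("a", 0, 1000)], set(), self.MOTIF_TO_TF
        )
        assert len(table) == 0

    def test_overlapping_domains_yield_both_targets(self):
        doms = [domain("a", 0, 1000), domain("b", 400, 2000)]
        table = predict_targets([match("m1", 500)], doms, {"a", "b"}, self.MOTIF_TO_TF)
        assert table.by_motif()["m1"].targets == frozenset({"a", "b"})

    def test_match_counted_once_per_gene(self):
        table = predict_targets(
            [match("m1", 500), match("m1", 600)],
            [domain("a", 0, 1000)], {"a"}, self.MOTIF_TO_TF,
        )
        assert table.total_pairs == 1

    def test_start_position_semantics_at_boundary(self):
        # match starting exactly at a tiling boundary belongs to the right domain
        doms = [domain("a", 0, 500), domain("b", 500, 1000)]
        table = predict_targets([match("m1", 500)], doms, {"a", "b"}, self.MOTIF_TO_TF)
        assert table.by_motif()["m1"].targets == frozenset({"b"})
        table_any = predict_targets(
            [match("m1", 495)], doms, {"a", "b"}, self.MOTIF_TO_TF, overlap="any"
        )
        assert table_any.by_motif()["m1"].targets == frozenset({"a", "b"})

    def test_unmapped_motif_excluded(self):
        table = predict_targets(
            [match("m_unmapped", 500)], [domain("a", 0, 1000)], {"a"}, self.MOTIF_TO_TF
        )
        assert len(table) == 0

    def test_enlarging_domain_never_removes_pairs(self, rng):
        matches = [match("m1", int(p)) for p in rng.integers(0, 10_000, size=40)]
        small = [domain("a", 2000, 4000)]
        big = [domain("a", 1000, 9000)]
        t_small = predict_targets(matches, small, {"a"}, self.MOTIF_TO_TF)
        t_big = predict_targets(matches, big, {"a"}, self.MOTIF_TO_TF)
        small_pairs = {(s.motif_id, t) for s in t_small.sets for t in s.targets}
        big_pairs = {(s.motif_id, t) for s in t_big.sets for t in s.targets}
        assert small_pairs <= big_pairs


class TestFilters:
    def test_redundant_same_tf_same_targets_collapsed(self):
        sets = [
            TargetSet("m2", "TF1", frozenset({"a", "b"})),
            TargetSet("m1", "TF1", frozenset({"a", "b"})),
            TargetSet("m3", "TF1", frozenset({"a", "c"})),
            TargetSet("m4", "TF2", frozenset({"a", "b"})),
        ]
        out = remove_redundant_tfbs(TargetTable(sets))
        assert [s.motif_id for s in out.sets] == ["m1", "m3", "m4"]

    @pytest.mark.parametrize("size,kept", [(4, False), (5, True), (6, True)])
    def test_minimum_five_targets(self, size, kept):
        table = TargetTable([TargetSet("m1", "TF1", frozenset(f"g{i}" for i in range(size)))])
        assert (len(filter_min_targets(table)) == 1) is kept

    def test_empty_table_passes_through(self):
        assert len(filter_min_targets(remove_redundant_tfbs(TargetTable([])))) == 0


class TestPerturbation:
    POOL = {f"p{i}" for i in range(200)}

    def _table(self, n=10):
        return TargetTable([TargetSet("m1", "TF1", frozenset(f"g{i}" for i in range(n)))])

    def test_zero_fraction_identity(self):
        table = self._table()
        out = perturb_targets(table, PerturbationSpec("replace", 0.0), self.POOL)
        assert out.sets[0].targets == table.sets[0].targets

    def test_replace_preserves_size_and_swaps_k(self):
        table = self._table(10)
        out = perturb_targets(table, PerturbationSpec("replace", 0.20, seed=3), self.POOL)
        new = out.sets[0].targets
        assert len(new) == 10
        assert len(new - table.sets[0].targets) == 2
        assert len(table.sets[0].targets - new) == 2

    def test_add_grows_by_rounded_k(self):
        table = self._table(10)
        out = perturb_targets(table, PerturbationSpec("add", 0.60, seed=3), self.POOL)
        assert len(out.sets[0].targets) == 16
        assert table.sets[0].targets <= out.sets[0].targets

    def test_deterministic_under_seed(self):
        table = self._table(10)
        spec = PerturbationSpec("replace", 0.4, replicate=1, seed=11)
        a = perturb_targets(table, spec, self.POOL)
        b = perturb_targets(table, spec, self.POOL)
        assert a.sets[0].targets == b.sets[0].targets

    def test_per_motif_substreams_independent(self):
        """Adding another motif must not change the first motif's draws."""
        one = self._table(10)
        two = TargetTable(one.sets + [TargetSet("m0", "TF0", frozenset(f"h{i}" for i in range(8)))])
        spec = PerturbationSpec("replace", 0.4, seed=5)
        out_one = perturb_targets(one, spec, self.POOL)
        out_two = perturb_targets(two, spec, self.POOL)
        assert out_one.by_motif()["m1"].targets == out_two.by_motif()["m1"].targets

    def test_pool_exhausted_is_an_error(self):
        table = self._table(10)
        with pytest.raises(ValueError, match="pool exhausted"):
            perturb_targets(table, PerturbationSpec("replace", 0.5), {"p0", "p1"})


class TestStats:
    def test_simple_sizes(self):
        table = TargetTable([
            TargetSet("m1", "T", frozenset(f"a{i}" for i in range(5))),
            TargetSet("m2", "T", frozenset(f"b{i}" for i in range(7))),
            TargetSet("m3", "T", frozenset(f"c{i}" for i in range(9))),
        ])
        s = target_stats(table)
        assert (s["mean_targets"], s["median_targets"], s["total_pairs"]) == (7.0, 7.0, 21)

    def test_even_count_lower_middle_median(self):
        table = TargetTable([
            TargetSet(f"m{i}", "T", frozenset(f"{i}_{j}" for j in range(n)))
            for i, n in enumerate([5, 6, 7, 100])
        ])
        assert target_stats(table)["median_targets"] == 6.0

    def test_unique_targets_deduplicated(self):
        table = TargetTable([
            TargetSet("m1", "T", frozenset({"a", "b"})),
            TargetSet("m2", "T", frozenset({"b", "c"})),
        ])
        s = target_stats(table)
        assert s["total_pairs"] == 4 and s["unique_targets"] == 3


def test_target_tsv_roundtrip(tmp_path):
    table = TargetTable([
        TargetSet("m1", "TF1", frozenset({"a", "b", "c"})),
        TargetSet("m2", "TF2", frozenset({"b"})),
    ], condition="x")
    p = tmp_path / "targets.tsv"
    write_targets(table, p)
    back = read_targets(p, "x")
    assert {s.motif_id: s.targets for s in back.sets} == {
        s.motif_id: s.targets for s in table.sets
    }
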