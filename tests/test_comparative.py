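import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dmcpg.comparative import (
    DmSet,
    classify_island_relation,
    compare_counts_fs_ps,
    compare_overlap_groups,
    context_distribution,
    direction_proportions,
    gene_set_enrichment,
    overlap,
    quartile_distribution,
    read_gmt,
)
from dmcpg.io import (
    AssociationResult,
    IslandRelation,
    IslandSet,
    MethylationDataset,
    PrandialState,
)

from conftest import make_cohort_records


def brute_force_relation(chrom, pos, islands, shore=2000, shelf=2000):
    """Per-base distance scan: independent oracle for island geography."""
    best = math.inf
    for c, start, end in islands.intervals:
        if c != chrom:
            continue
        if start <= pos < end:
            return IslandRelation.island
        if pos >= end:
            best = min(best, pos - end)
        else:
            best = min(best, start - pos - 1)
    if best < shore:
        return IslandRelation.shore
    if best < shore + shelf:
        return IslandRelation.shelf
    return IslandRelation.open_sea


class TestOverlap:
    def test_identical_sets_full_overlap(self):
        a = DmSet("a", frozenset({"p1", "p2"}))
        assert overlap(a, a, "b_count").percent == pytest.approx(100.0)

    def test_disjoint_sets(self):
        a = DmSet("a", frozenset({"p1"}))
        b = DmSet("b", frozenset({"p2"}))
        assert overlap(a, b, "min_count").percent == pytest.approx(0.0)

    def test_min_count_policy_arithmetic(self):
        a = DmSet("a", frozenset({"p1", "p2", "p3"}))
        b = DmSet("b", frozenset({"p2", "p3", "p4", "p5"}))
        ov = overlap(a, b, "min_count")
        assert (ov.shared, ov.denominator) == (2, 3)
        assert ov.percent == pytest.approx(100 * 2 / 3)

    def test_policy_asymmetry_only_in_denominator(self):
        a = DmSet("a", frozenset({"p1", "p2", "p3"}))
        b = DmSet("b", frozenset({"p2", "p3", "p4", "p5"}))
        assert overlap(a, b, "a_count").shared == overlap(b, a, "a_count").shared
        assert overlap(a, b, "b_count").denominator == 4

    def test_zero_denominator_rejected(self):
        a = DmSet("a", frozenset({"p1"}))
        with pytest.raises(ValueError, match="denominator"):
            overlap(a, DmSet("b", frozenset()), "b_count")


def _assoc(probe, direction, is_dm=True):
    return AssociationResult(
        probe_id=probe, covariate="BMI", prandial_state=PrandialState.FS,
        method="pearson", r=1.0 if direction == "hyper" else -1.0,
        p=0.01, delta_beta=0.2, direction=direction, is_dmcpg=is_dm,
    )


class TestDirections:
    def test_three_one_split(self):
        res = [_assoc(f"p{i}", "hypo") for i in range(3)] + [_assoc("p4", "hyper")]
        assert direction_proportions(res) == (pytest.approx(75.0), pytest.approx(25.0))

    def test_all_hyper(self):
        res = [_assoc(f"p{i}", "hyper") for i in range(4)]
        assert direction_proportions(res) == (pytest.approx(0.0), pytest.approx(100.0))

    def test_non_dm_rows_ignored(self):
        res = [_assoc("p1", "hyper"), _assoc("p2", "hypo", is_dm=False)]
        assert direction_proportions(res) == (0.0, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_proportions([_assoc("p1", "hyper", is_dm=False)])


class TestMannWhitney:
    def test_identical_groups_maximal_p(self):
        _, p = compare_overlap_groups([1, 2, 3], [1, 2, 3])
        assert p > 0.5

    def test_all_identical_values(self):
        _, p = compare_overlap_groups([2, 2], [2, 2])
        assert p == 1.0

    def test_complete_separation_exact(self):
        _, p = compare_overlap_groups([1, 2, 3, 4], [10, 11, 12, 13])
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_symmetry(self):
        a, b = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        assert compare_overlap_groups(a, b)[1] == pytest.approx(
            compare_overlap_groups(b, a)[1], abs=1e-12
        )

    def test_exact_matches_rank_enumeration(self):
        """Exact p equals enumeration over all rank assignments."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=5)
        b = rng.normal(0.8, 1, size=5)
        _, p = compare_overlap_groups(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n_a = len(a)
        u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        mu = n_a * len(b) / 2
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_overlap_groups([1.0], [2.0, 3.0])


class TestCountRatios:
    def test_equal_counts(self):
        ratio, p = compare_counts_fs_ps([5, 6, 7], [5, 6, 7])
        assert ratio == pytest.approx(1.0) and p == 1.0

    def test_doubling(self):
        ratio, _ = compare_counts_fs_ps([10, 20, 30], [5, 10, 15])
        assert ratio == pytest.approx(2.0)

    def test_mean_ratio_arithmetic(self):
        ratio, _ = compare_counts_fs_ps(
            [10, 20, 30, 40, 50], [5, 5, 10, 10, 25]
        )
        assert ratio == pytest.approx(3.0)

    def test_zero_ps_terms_dropped(self):
        ratio, _ = compare_counts_fs_ps([10, 20, 30, 40], [0, 5, 10, 20])
        assert ratio == pytest.approx((4 + 3 + 2) / 3)

    def test_too_few_usable_pairs(self):
        with pytest.raises(ValueError, match="usable"):
            compare_counts_fs_ps([1, 2, 3], [0, 0, 1])


class TestIslandGeography:
    islands = IslandSet([("chr1", 10_000, 11_000)])

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10_500, IslandRelation.island),
            (10_000, IslandRelation.island),
            (10_999, IslandRelation.island),
            (11_000, IslandRelation.shore),   # half-open: end is outside
            (12_999, IslandRelation.shore),
            (13_000, IslandRelation.shelf),
            (14_999, IslandRelation.shelf),
            (15_000, IslandRelation.open_sea),
            (9_999, IslandRelation.shore),
            (8_000, IslandRelation.shore),
            (7_999, IslandRelation.shelf),
            (6_000, IslandRelation.shelf),
            (5_999, IslandRelation.open_sea),
        ],
    )
    def test_boundaries(self, pos, expected):
        assert classify_island_relation(("chr1", pos), self.islands) is expected

    def test_brute_force_scan_agreement(self):
        for pos in range(9_000, 16_001):
            assert classify_island_relation(
                ("chr1", pos), self.islands
            ) is brute_force_relation("chr1", pos, self.islands)

    def test_other_chromosome_is_open_sea(self):
        assert classify_island_relation(
            ("chr2", 10_500), self.islands
        ) is IslandRelation.open_sea

    def test_random_layouts_match_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n = rng.integers(1, 5)
            starts = np.sort(rng.integers(0, 50_000, n))
            islands = IslandSet(
                [("chr1", int(s), int(s + rng.integers(100, 3000))) for s in starts]
            )
            for pos in rng.integers(0, 60_000, 40):
                got = classify_island_relation(("chr1", int(pos)), islands)
                want = brute_force_relation("chr1", int(pos), islands)
                assert got is want, (islands.intervals, pos)


class TestContextDistribution:
    def test_proportional_sample_null(self):
        cats = {f"p{i}": ("a" if i % 4 else "b") for i in range(40)}
        background = list(cats)
        dm = DmSet("dm", frozenset([f"p{i}" for i in range(0, 40, 2)]))
        # dm has 10 'a'-multiples... construct exactly proportional instead
        dm = DmSet("dm", frozenset(
            [p for p in background if cats[p] == "a"][:6]
            + [p for p in background if cats[p] == "b"][:2]
        ))
        # background: 30 a, 10 b -> proportions 3:1; dm: 6 a, 2 b
        dist = context_distribution(dm, cats, background)
        assert dist.chi2 == pytest.approx(0.0, abs=1e-12)
        assert dist.p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        """Observed (90,10) against 50/50 expectation: chi2 = 64."""
        cats = {f"a{i}": "A" for i in range(500)}
        cats.update({f"b{i}": "B" for i in range(500)})
        dm = DmSet(
            "dm", frozenset([f"a{i}" for i in range(90)] + [f"b{i}" for i in range(10)])
        )
        dist = context_distribution(dm, cats, list(cats))
        assert dist.chi2 == pytest.approx(64.0, abs=1e-12)
        assert dist.p < 1e-14

    def test_partition_additivity(self):
        rng = np.random.default_rng(2)
        cats = {f"p{i}": rng.choice(["x", "y", "z"]) for i in range(60)}
        ids = list(cats)
        full = DmSet("full", frozenset(ids[:30]))
        half_a = DmSet("a", frozenset(ids[:15]))
        half_b = DmSet("b", frozenset(ids[15:30]))
        d_full = context_distribution(full, cats, ids)
        d_a = context_distribution(half_a, cats, ids)
        d_b = context_distribution(half_b, cats, ids)
        assert d_full.categories == d_a.categories == d_b.categories
        assert np.array_equal(d_full.counts, d_a.counts + d_b.counts)

    def test_empty_dmset_rejected(self):
        with pytest.raises(ValueError):
            context_distribution(DmSet("dm", frozenset()), {"p1": "a"}, ["p1"])


class TestQuartiles:
    def _baseline(self, means):
        records = make_cohort_records()[:4]
        beta = np.tile(np.asarray(means)[:, None], (1, 4))
        probes = [f"p{i}" for i in range(len(means))]
        return MethylationDataset(probes, [r.sample_id for r in records], beta, records)

    def test_one_per_bin(self):
        ds = self._baseline([0.1, 0.3, 0.6, 0.9])
        counts = quartile_distribution(DmSet("d", frozenset(ds.probe_ids)), ds)
        assert counts.tolist() == [1, 1, 1, 1]

    def test_half_beta_in_third_bin(self):
        ds = self._baseline([0.5, 0.5, 0.5, 0.5])
        counts = quartile_distribution(DmSet("d", frozenset(ds.probe_ids)), ds)
        assert counts.tolist() == [0, 0, 4, 0]

    def test_left_closed_boundary(self):
        ds = self._baseline([0.25])
        counts = quartile_distribution(DmSet("d", frozenset(ds.probe_ids)), ds)
        assert counts.tolist() == [0, 1, 0, 0]

    def test_missing_probe_rejected(self):
        ds = self._baseline([0.5])
        with pytest.raises(ValueError, match="absent"):
            quartile_distribution(DmSet("d", frozenset({"nope"})), ds)


class TestEnrichment:
    def test_disjoint_target_not_significant(self):
        uni = {f"g{i}" for i in range(100)}
        table = gene_set_enrichment(
            {"g1", "g2"}, {"T": {"g50", "g51"}}, uni
        )
        row = table.iloc[0]
        assert row.overlap == 0 and not row.significant and row.p > 0.9

    def test_maximal_enrichment(self):
        uni = {f"g{i}" for i in range(1000)}
        dm = {f"g{i}" for i in range(10)}
        table = gene_set_enrichment(dm, {"T": dm}, uni)
        row = table.iloc[0]
        expected = 1.0 / math.comb(1000, 10)
        assert row.p == pytest.approx(expected, rel=1e-9)
        assert row.significant

    def test_exact_tail_sum(self):
        """Universe 20, dm 5, target 8, overlap 4: explicit hypergeometric sum."""
        uni = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(8)}
        dm = {"g0", "g1", "g2", "g3", "g15"}
        table = gene_set_enrichment(dm, {"T": target}, uni)
        expected = sum(
            math.comb(8, k) * math.comb(12, 5 - k) for k in range(4, 6)
        ) / math.comb(20, 5)
        assert table.iloc[0].p == pytest.approx(expected, rel=1e-12)

    def test_bh_is_monotone_and_dominates_p(self):
        rng = np.random.default_rng(3)
        uni = {f"g{i}" for i in range(200)}
        sets = {
            f"T{j}": set(rng.choice(sorted(uni), size=20, replace=False))
            for j in range(12)
        }
        dm = set(rng.choice(sorted(uni), size=30, replace=False))
        table = gene_set_enrichment(dm, sets, uni)
        assert (table.q.to_numpy() >= table.p.to_numpy() - 1e-15).all()
        assert (np.diff(table.q.to_numpy()) >= -1e-15).all()  # sorted by p

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment(set(), {"T": {"g1"}}, set())

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tg1\tg2\nS2\tdesc\tg3\n")
        sets = read_gmt(path)
        assert sets == {"S1": {"g1", "g2"}, "S2": {"g3"}}
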