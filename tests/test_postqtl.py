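"""Hotspots, cis/trans, directionality, regulators, gene-pair enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from segqtl import (
    GeneAnnotation,
    GenomeModel,
    SimConfig,
    candidate_regulator,
    classify_cis_trans,
    classify_gene_pairs,
    detect_hotspots,
    directionality,
    hotspot_regulator_vote,
    make_genome,
    pair_enrichment,
)
from segqtl.genome import P1, P2
from segqtl.postqtl import PAIR_CATEGORIES, _category_counts
from segqtl.qtl import QTLGroup, QTLRegion


def _poisson_tail_bruteforce(k, lam, terms=400):
    """Independent oracle: P(X >= k) by direct series summation."""
    return 1.0 - sum(
        math.exp(-lam) * lam ** i / math.factorial(i) for i in range(k)
    ) if k > 0 else 1.0


def _uniform_genome(n_bins=10, bin_size=50_000):
    return GenomeModel([("chr1", n_bins * bin_size)], [], [])


def _positions(counts_per_bin, bin_size=50_000, trait_prefix="t"):
    rows = []
    t = 0
    for b, n in enumerate(counts_per_bin):
        for _ in range(n):
            rows.append({"trait_id": f"{trait_prefix}{t}", "chrom": "chr1",
                         "pos": b * bin_size + 10_000})
            t += 1
    return pd.DataFrame(rows, columns=["trait_id", "chrom", "pos"])


class TestDetectHotspots:
    def test_poisson_tail_matches_bruteforce(self):
        for lam in (0.3, 1.0, 4.7):
            for k in (0, 1, 3, 10, 25):
                ours = float(stats.poisson.sf(k - 1, lam))
                assert abs(ours - _poisson_tail_bruteforce(k, lam)) < 1e-12

    def test_single_count_bin_not_significant(self):
        # 10 eQTLs in 10 bins -> lam = 1; P(X >= 1) ~ 0.632
        hs = detect_hotspots(_positions([1] * 10), _uniform_genome(10))
        assert hs == []

    def test_ten_in_one_bin_detected(self):
        # lam = 1 with one bin holding 10: P(X >= 10) ~ 1.11e-7 < 8e-4
        counts = [10] + [0] * 9
        positions = _positions(counts)
        extra = _positions([1] * 10, trait_prefix="x")
        hs = detect_hotspots(pd.concat([positions, extra[:0]]),
                             _uniform_genome(10))
        assert len(hs) == 1
        assert hs[0].count == 10
        assert hs[0].p_value == pytest.approx(
            _poisson_tail_bruteforce(10, 1.0), rel=1e-9
        )

    def test_adjacent_bins_disjoint_targets_stay_separate(self):
        # lam = 3 with two bins of 6: each significant, nothing shared
        pos = _positions([6, 6, 0, 0], bin_size=50_000)
        hs = detect_hotspots(pos, _uniform_genome(4), alpha=0.5)
        assert len(hs) == 2

    def test_adjacent_bins_shared_target_merge(self):
        pos = _positions([6, 6, 0, 0])
        pos.loc[len(pos) - 1, "trait_id"] = pos.loc[0, "trait_id"]
        hs = detect_hotspots(pos, _uniform_genome(4), alpha=0.5)
        assert len(hs) == 1
        assert hs[0].count == 12

    def test_identical_merge_rule(self):
        pos = _positions([6, 6, 0, 0])
        pos.loc[len(pos) - 1, "trait_id"] = pos.loc[0, "trait_id"]
        hs = detect_hotspots(pos, _uniform_genome(4), alpha=0.5,
                             merge_rule="identical")
        assert len(hs) == 2

    def test_no_qtls_empty(self):
        assert detect_hotspots(_positions([]), _uniform_genome(5)) == []

    def test_planted_hotspot_always_detected(self):
        # 50 targets in one 50-kb bin among <= 300 linkages, 20 seeds
        genome = make_genome(SimConfig(), seed=1)  # 2 Mb -> 40 bins
        n_bins = sum(length // 50_000 for _, length in genome.chromosomes)
        rng = np.random.default_rng(0)
        for seed in range(20):
            rows = [{"trait_id": f"h{t}", "chrom": "chr1", "pos": 525_000}
                    for t in range(50)]
            for t in range(250):
                chrom, length = genome.chromosomes[rng.integers(2)]
                rows.append({"trait_id": f"b{t}", "chrom": chrom,
                             "pos": int(rng.integers(1, length))})
            hs = detect_hotspots(pd.DataFrame(rows), genome, alpha=8e-4)
            assert any(
                h.chrom == "chr1" and h.start <= 525_000 <= h.end and
                h.count >= 50
                for h in hs
            )


MARKERS = pd.DataFrame(
    {"chrom": ["chr1"] * 10 + ["chr2"] * 10,
     "start": list(range(50_000, 550_000, 50_000)) * 2}
)
MARKERS["end"] = MARKERS["start"] + 1000


class TestClassifyCisTrans:
    def _ld(self, high=()):
        ld = np.full((20, 20), 0.05)
        np.fill_diagonal(ld, 1.0)
        for i, j in high:
            ld[i, j] = ld[j, i] = 0.95
        return ld

    def test_flanking_marker_in_qtl_is_cis(self):
        # gene between markers 3 and 4; QTL contains marker 3
        flag = classify_cis_trans([3], "chr1", (210_000, 230_000), MARKERS,
                                  self._ld())
        assert flag == "cis"

    def test_other_chromosome_low_ld_is_trans(self):
        flag = classify_cis_trans([12], "chr1", (210_000, 230_000), MARKERS,
                                  self._ld())
        assert flag == "trans"

    def test_distant_marker_high_ld_counts_as_cis(self):
        flag = classify_cis_trans([9], "chr1", (210_000, 230_000), MARKERS,
                                  self._ld(high=[(9, 3)]))
        assert flag == "cis"

    def test_gene_past_last_marker_uses_nearest(self):
        flag = classify_cis_trans([9], "chr1", (900_000, 910_000), MARKERS,
                                  self._ld())
        assert flag == "cis"

    def test_chromosome_without_markers_trans(self):
        markers = MARKERS[MARKERS["chrom"] == "chr1"].reset_index(drop=True)
        ld = np.eye(10)
        flag = classify_cis_trans([2], "chr3", (10_000, 20_000), markers, ld)
        assert flag == "trans"

    def test_invariant_to_global_allele_relabeling(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, (30, 20)).astype(float)
        from segqtl.qtl import marker_ld

        a = classify_cis_trans([3], "chr1", (210_000, 230_000), MARKERS,
                               marker_ld(m))
        b = classify_cis_trans([3], "chr1", (210_000, 230_000), MARKERS,
                               marker_ld(1 - m))
        assert a == b


class TestDirectionality:
    def test_p2_higher_is_positive(self):
        y = np.array([3, 3, 5, 5.0])
        g = np.array([P1, P1, P2, P2])
        assert directionality(y, g) == 1

    def test_equal_means_zero(self):
        y = np.array([4, 4, 4, 4.0])
        g = np.array([P1, P1, P2, P2])
        assert directionality(y, g) == 0

    def test_missing_values_excluded(self):
        y = np.array([3, np.nan, 5, 100.0])
        g = np.array([P1, P2, P2, -1])
        assert directionality(y, g) == 1

    def test_planted_negative_effect_sign_recovered(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            g = rng.integers(0, 2, 44)
            y = -0.8 * g + rng.normal(0, 0.5, 44)
            hits += directionality(y, g) == -1
        assert hits >= 38  # >= 95%


def _regulator_genome():
    genes = [
        GeneAnnotation("reg", "chr1", "+", 90, 100, 2000),
        GeneAnnotation("other", "chr1", "+", 2890, 2900, 4000),
        GeneAnnotation("target", "chr2", "+", 490, 500, 1500),
    ]
    return GenomeModel([("chr1", 10_000), ("chr2", 10_000)], genes, [])


class TestCandidateRegulator:
    GROUP = QTLGroup("target", [QTLRegion("chr1", 1, 5000, [0])], [0])

    def test_true_regulator_wins_at_snr2(self):
        genome = _regulator_genome()
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(20):
            reg = rng.normal(0, 1, 30)
            expr = pd.DataFrame(
                {"reg": reg, "other": rng.normal(0, 1, 30)}
            ).T
            target = reg + rng.normal(0, 0.5, 30)
            wins += candidate_regulator(target, self.GROUP, genome, expr,
                                        "target") == "reg"
        assert wins >= 18  # >= 90%

    def test_single_gene_qtl(self):
        genome = _regulator_genome()
        group = QTLGroup("t", [QTLRegion("chr1", 1, 2500, [0])], [0])
        rng = np.random.default_rng(4)
        expr = pd.DataFrame({"reg": rng.normal(size=10)}).T
        assert candidate_regulator(rng.normal(size=10), group, genome,
                                   expr) == "reg"

    def test_higher_r2_wins(self):
        genome = _regulator_genome()
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        expr = pd.DataFrame(
            {"reg": x + rng.normal(0, 0.2, 30),
             "other": rng.normal(size=30)}
        ).T
        assert candidate_regulator(x, self.GROUP, genome, expr) == "reg"

    def test_target_excluded_from_own_qtl(self):
        genes = [GeneAnnotation("target", "chr1", "+", 90, 100, 2000),
                 GeneAnnotation("nb", "chr1", "+", 2990, 3000, 4000)]
        genome = GenomeModel([("chr1", 10_000)], genes, [])
        group = QTLGroup("target", [QTLRegion("chr1", 1, 5000, [0])], [0])
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        expr = pd.DataFrame({"target": y, "nb": rng.normal(size=20)}).T
        assert candidate_regulator(y, group, genome, expr, "target") == "nb"

    def test_no_expressed_gene_in_qtl_returns_none(self):
        genome = _regulator_genome()
        group = QTLGroup("t", [QTLRegion("chr1", 6000, 9000, [0])], [0])
        expr = pd.DataFrame({"reg": np.zeros(5)}).T
        assert candidate_regulator(np.arange(5.0), group, genome, expr) is None


class TestHotspotVote:
    def test_modal_candidate(self):
        assert hotspot_regulator_vote(["A", "A", "B"]) == "A"

    def test_unanimous(self):
        assert hotspot_regulator_vote(["C", "C"]) == "C"

    def test_tie_breaks_by_coordinate(self):
        genome = _regulator_genome()  # reg at chr1:100 < other at chr1:2900
        assert hotspot_regulator_vote(["other", "reg"], genome) == "reg"

    def test_none_candidates_ignored(self):
        assert hotspot_regulator_vote([None, "B", None, "B", "A"]) == "B"


def _pair_genome(specs):
    """specs: list of (strand_a, strand_b, overlap) per two-gene chromosome."""
    genes, chroms = [], []
    for i, (sa, sb, ov) in enumerate(specs):
        chrom = f"c{i}"
        chroms.append((chrom, 50_000))
        a_start, a_end = 1000, 3000
        b_start = a_end - 200 if ov else a_end + 2000
        b_end = b_start + 2000
        tss_a = a_start - 50 if sa == "+" else a_end + 50
        tss_b = b_start - 50 if sb == "+" else b_end + 50
        genes.append(GeneAnnotation(f"g{i}a", chrom, sa, tss_a, a_start, a_end))
        genes.append(GeneAnnotation(f"g{i}b", chrom, sb, tss_b, b_start, b_end))
    return GenomeModel(chroms, genes, [])


class TestClassifyGenePairs:
    @pytest.mark.parametrize(
        "sa,sb,ov,expected",
        [
            ("+", "-", False, "convergent_non_overlapping"),
            ("+", "-", True, "convergent_overlapping"),
            ("-", "+", False, "divergent_non_overlapping"),
            ("+", "+", False, "tandem_non_overlapping"),
            ("-", "-", True, "tandem_overlapping"),
        ],
    )
    def test_known_orientations(self, sa, sb, ov, expected):
        pairs = classify_gene_pairs(_pair_genome([(sa, sb, ov)]))
        assert len(pairs) == 1
        assert pairs[0].category == expected

    def test_ncrna_excluded(self):
        genome = _pair_genome([("+", "-", False)])
        genome.genes[1] = GeneAnnotation(
            "nc", genome.genes[1].chrom, "-", genome.genes[1].tss,
            genome.genes[1].cds_start, genome.genes[1].cds_end, coding=False,
        )
        assert classify_gene_pairs(genome) == []

    def test_counts_cover_all_adjacencies(self, tiny_genome):
        pairs = classify_gene_pairs(tiny_genome)
        coding_per_chrom = {}
        for g in tiny_genome.genes:
            if g.coding:
                coding_per_chrom[g.chrom] = coding_per_chrom.get(g.chrom, 0) + 1
        expected = sum(max(0, n - 1) for n in coding_per_chrom.values())
        assert len(pairs) == expected

    def test_matches_bruteforce_oracle_on_random_annotations(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(2, 7))
            genes = []
            pos = 100
            for i in range(n):
                length = int(rng.integers(200, 800))
                start = pos + int(rng.integers(-150, 400))
                start = max(1, start)
                end = start + length
                strand = "+" if rng.random() < 0.5 else "-"
                tss = start - 10 if strand == "+" else end + 10
                genes.append(
                    GeneAnnotation(f"g{i}", "chr1", strand, max(1, tss),
                                   start, end)
                )
                pos = end
            genome = GenomeModel([("chr1", 100_000)], genes, [])
            got = classify_gene_pairs(genome)

            ordered = sorted(genes, key=lambda g: g.tss)
            expected = []
            for a, b in zip(ordered, ordered[1:]):
                orient = {("+", "-"): "convergent", ("-", "+"): "divergent"}.get(
                    (a.strand, b.strand), "tandem"
                )
                ov = a.cds_start <= b.cds_end and b.cds_start <= a.cds_end
                expected.append(
                    f"{orient}_{'overlapping' if ov else 'non_overlapping'}"
                )
            assert [p.category for p in got] == expected


class TestPairEnrichment:
    UNIVERSE_SPECS = [("+", "-", False)] * 4 + [("-", "+", False)] * 3 + [
        ("+", "+", False)
    ] * 3

    def test_all_targets_gives_flat_p(self):
        genome = _pair_genome(self.UNIVERSE_SPECS)
        pairs = classify_gene_pairs(genome)
        universe = [g.gene_id for g in genome.genes]
        res = pair_enrichment(universe, pairs, universe, n_perm=500, seed=1)
        assert (res["p_enrichment"] == 1.0).all()
        assert (res["p_depletion"] == 1.0).all()

    def test_exclusively_convergent_targets_maximal_statistic(self):
        genome = _pair_genome(self.UNIVERSE_SPECS)
        pairs = classify_gene_pairs(genome)
        universe = [g.gene_id for g in genome.genes]
        targets = [g.gene_id for g in genome.genes[:8]]  # 4 convergent pairs
        res = pair_enrichment(targets, pairs, universe, n_perm=400, seed=2)
        row = res.set_index("category").loc["convergent_non_overlapping"]
        assert row["p_enrichment"] == pytest.approx(1 / 401)

    def test_empty_target_set_rejected(self):
        genome = _pair_genome(self.UNIVERSE_SPECS)
        pairs = classify_gene_pairs(genome)
        with pytest.raises(ValueError):
            pair_enrichment([], pairs, [g.gene_id for g in genome.genes])

    def test_matches_hypergeometric_oracle_on_unique_pair_universe(self):
        # 10 chromosomes x 2 genes: every gene belongs to exactly one pair,
        # so the per-category count of a random draw is hypergeometric
        genome = _pair_genome(self.UNIVERSE_SPECS)
        pairs = classify_gene_pairs(genome)
        universe = [g.gene_id for g in genome.genes]  # 20 genes
        rng = np.random.default_rng(3)
        targets = list(rng.choice(universe, size=8, replace=False))
        n_perm = 20_000
        res = pair_enrichment(targets, pairs, universe, n_perm=n_perm, seed=4)
        # convergent genes: 8 of 20
        obs = _category_counts(set(targets), pairs)[
            "convergent_non_overlapping"
        ]
        exact = stats.hypergeom.sf(obs - 1, 20, 8, 8)
        got = res.set_index("category").loc["convergent_non_overlapping",
                                            "p_enrichment"]
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(got - exact) <= 2 * se + 2 / n_perm

    def test_p_values_sub_uniform_under_random_targets(self):
        genome = _pair_genome(self.UNIVERSE_SPECS)
        pairs = classify_gene_pairs(genome)
        universe = [g.gene_id for g in genome.genes]
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            targets = list(rng.choice(universe, size=8, replace=False))
            res = pair_enrichment(targets, pairs, universe, n_perm=150,
                                  seed=int(rng.integers(2**31 - 1)))
            ps.append(res["p_enrichment"].iloc[0])
        ps = np.asarray(ps)
        for alpha in (0.05, 0.10, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se + 0.01
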