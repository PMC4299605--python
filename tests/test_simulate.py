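"""Simulator: genome layout, meiosis, expression effects, reads, call noise."""

import numpy as np
import pandas as pd
import pytest

from segqtl import (
    CallParams,
    EffectConfig,
    ErrorModel,
    HotspotSpec,
    SimConfig,
    make_genome,
    reads_per_gene,
    reference_mapping_filter,
    simulate_cross,
    simulate_expression,
    simulate_genotype_calls,
    simulate_reads,
)
from segqtl.genome import P1, P2


class TestMakeGenome:
    def test_counts_echo_config_and_inversion(self, tiny_genome):
        assert len(tiny_genome.genes) == 30
        assert len(tiny_genome.variants) == 60
        assert tiny_genome.inversion is not None
        assert tiny_genome.inversion.chrom == "chr1"

    def test_variants_sorted_and_unique_within_chromosome(self, tiny_genome):
        vf = tiny_genome.variants_frame()
        for _, sub in vf.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert sub["pos"].is_unique

    def test_seed_changes_positions_not_counts(self):
        cfg = SimConfig(n_genes=40, n_variants=80)
        g1, g2 = make_genome(cfg, seed=1), make_genome(cfg, seed=2)
        assert len(g1.variants) == len(g2.variants) == 80
        p1 = [v.pos for v in g1.variants]
        p2 = [v.pos for v in g2.variants]
        assert p1 != p2

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n_genes=20, n_variants=30)
        g1, g2 = make_genome(cfg, seed=5), make_genome(cfg, seed=5)
        assert g1.variants_frame().equals(g2.variants_frame())
        assert g1.genes_frame().equals(g2.genes_frame())

    def test_convergent_overlap_pairs_exist(self, tiny_genome):
        gf = tiny_genome.genes_frame().sort_values(["chrom", "cds_start"])
        found = 0
        for (_, a), (_, b) in zip(gf.iterrows(), gf.iloc[1:].iterrows()):
            if (
                a["chrom"] == b["chrom"]
                and (a["strand"], b["strand"]) == ("+", "-")
                and b["cds_start"] <= a["cds_end"]
            ):
                found += 1
        assert found >= 2

    def test_too_many_variants_error(self):
        cfg = SimConfig(chromosomes=[("chr1", 60_000)], n_genes=5,
                        n_variants=70_000, inversion=None)
        with pytest.raises(ValueError):
            make_genome(cfg, seed=1)


class TestSimulateCross:
    def test_zero_rate_monomorphic(self, tiny_genome):
        t = simulate_cross(tiny_genome, 8, "F1", crossover_rate=0.0, seed=3)
        assert all(len(b) == 0 for b in t.breakpoints.values())
        vf = tiny_genome.variants_frame()
        for chrom in vf["chrom"].unique():
            cols = (vf["chrom"] == chrom).to_numpy()
            sub = t.matrix[:, cols]
            assert (sub == sub[:, :1]).all()

    def test_inversion_suppression_zero_blocks_breakpoints(self, tiny_genome):
        inv = tiny_genome.inversion
        for seed in range(5):
            t = simulate_cross(tiny_genome, 10, "F2", crossover_rate=6.0,
                               inversion_suppression=0.0, seed=seed)
            for bps in t.breakpoints.values():
                for chrom, pos in bps:
                    assert not (chrom == inv.chrom
                                and inv.start <= pos <= inv.end)

    def test_breakpoint_mean_matches_poisson_expectation(self, tiny_genome):
        # rate 8.5 per chromosome x 2 chromosomes, no thinning -> ~17/strain
        means = []
        for seed in range(20):
            t = simulate_cross(tiny_genome, 44, "F1", crossover_rate=8.5,
                               inversion_suppression=1.0, seed=seed)
            means.append(t.breakpoint_counts().mean())
        assert abs(np.mean(means) - 17.0) < 2.0

    def test_f2_has_more_breakpoints_than_f1(self, tiny_genome):
        f1 = [simulate_cross(tiny_genome, 30, "F1", crossover_rate=3.0,
                             seed=s).breakpoint_counts().mean()
              for s in range(5)]
        f2 = [simulate_cross(tiny_genome, 30, "F2", crossover_rate=3.0,
                             seed=s).breakpoint_counts().mean()
              for s in range(5)]
        assert np.mean(f2) > np.mean(f1)

    def test_inversion_breakpoint_density_ratio(self):
        # density inside / outside the inversion ~= suppression factor
        cfg = SimConfig(chromosomes=[("chr1", 1_200_000)], n_genes=10,
                        n_variants=20, inversion=("chr1", 100_000, 400_000))
        genome = make_genome(cfg, seed=1)
        suppression = 0.3
        inside = outside = 0
        for seed in range(50):
            t = simulate_cross(genome, 4, "F1", crossover_rate=20.0,
                               inversion_suppression=suppression, seed=seed)
            for bps in t.breakpoints.values():
                for _, pos in bps:
                    if 100_000 <= pos <= 400_000:
                        inside += 1
                    else:
                        outside += 1
        l_in, l_out = 300_000, 900_000
        ratio = (inside / l_in) / (outside / l_out)
        assert abs(ratio - suppression) < 0.06


class TestSimulateExpression:
    def test_no_effects_no_dispersion_only_library_factor(self, tiny_genome):
        t = simulate_cross(tiny_genome, 6, "F1", crossover_rate=0.0, seed=1)
        sim = simulate_expression(
            tiny_genome, t,
            EffectConfig(dispersion=0.0, library_size_sd=0.0), seed=1,
        )
        c = sim.sense_counts.to_numpy()
        assert (c == c[:, :1]).all()

    def test_cis_effect_shifts_group_means(self, tiny_genome):
        cross = simulate_cross(tiny_genome, 80, "F1", crossover_rate=2.0,
                               seed=21)
        effects = EffectConfig(cis_effects=[("g0005", 2.0)], dispersion=0.01,
                               library_size_sd=0.0)
        sim = simulate_expression(tiny_genome, cross, effects, seed=4)
        row = sim.truth.iloc[0]
        geno = cross.matrix[:, int(row["site_index"])]
        vals = np.log2(sim.sense_counts.loc["g0005"].to_numpy() + 0.5)
        n1, n2 = (geno == P1).sum(), (geno == P2).sum()
        diff = vals[geno == P2].mean() - vals[geno == P1].mean()
        # planted +2 SD with the gene's own noise SD as the unit
        mu = sim.sense_means.loc["g0005"].to_numpy()[geno == P1][0]
        sd_unit = np.sqrt(0.01 + 1.0 / (10 * 2 ** mu)) / np.log(2)
        se = sd_unit * np.sqrt(1 / n1 + 1 / n2)
        assert abs(diff - 2.0 * sd_unit) < 3 * se + 0.05

    def test_hotspot_signs_recovered(self):
        cfg = SimConfig(n_genes=200, n_variants=300, convergent_overlap_pairs=0)
        genome = make_genome(cfg, seed=9)
        truth = simulate_cross(genome, 24, "F1", crossover_rate=1.4, seed=9)
        gene_ids = [g.gene_id for g in genome.genes]
        v = genome.variants[50]
        hs = HotspotSpec((v.chrom, v.pos), sense_targets=gene_ids[:50],
                         sense_size=-1.0, antisense_targets=gene_ids[50:130],
                         antisense_size=1.0)
        sim = simulate_expression(genome, truth,
                                  EffectConfig(hotspot=hs, dispersion=0.05),
                                  seed=9)
        geno = truth.matrix[:, 50]
        ok = 0
        for g in gene_ids[:50]:
            x = np.log2(sim.sense_counts.loc[g].to_numpy() + 0.5)
            ok += x[geno == P2].mean() < x[geno == P1].mean()
        for g in gene_ids[50:130]:
            x = np.log2(sim.antisense_counts.loc[g].to_numpy() + 0.5)
            ok += x[geno == P2].mean() > x[geno == P1].mean()
        assert ok >= 0.95 * 130

    def test_truth_table_lists_all_planted_effects(self, tiny_expression):
        assert set(tiny_expression.truth["trait_id"]) == {"g0005"}
        assert (tiny_expression.truth["kind"] == "cis").all()


class TestReadsPerGene:
    @pytest.mark.parametrize(
        "expr,expected", [(0.0, 10), (-10.0, 1), (3.1, 86)]
    )
    def test_known_values(self, expr, expected):
        assert reads_per_gene(expr) == expected

    def test_monotone_and_bounded(self):
        grid = np.linspace(-15, 12, 400)
        nr = reads_per_gene(grid)
        assert (nr >= 1).all()
        assert (np.diff(nr) >= 0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            reads_per_gene(float("nan"))


class TestSimulateReads:
    def _alleles(self, genome, value=0):
        return np.full(len(genome.variants), value, dtype=np.int8)

    def test_read_count_conservation(self, tiny_genome):
        nr = {g.gene_id: 7 for g in tiny_genome.genes}
        reads = simulate_reads(tiny_genome, self._alleles(tiny_genome), nr,
                               ErrorModel.uniform(0.0), seed=2)
        assert len(reads) == 7 * len(tiny_genome.genes)
        assert (reads.groupby("gene_id").size() == 7).all()

    def test_single_read_inside_transcript(self, tiny_genome):
        g = tiny_genome.genes[0]
        reads = simulate_reads(tiny_genome, self._alleles(tiny_genome),
                               {g.gene_id: 1}, ErrorModel.uniform(0.0), seed=3)
        assert len(reads) == 1
        r = reads.iloc[0]
        assert r["end"] - r["start"] + 1 == 48
        assert r["strand"] == g.strand

    def test_zero_error_model_flags_nothing(self, tiny_genome):
        nr = {g.gene_id: 20 for g in tiny_genome.genes}
        reads = simulate_reads(tiny_genome, self._alleles(tiny_genome), nr,
                               ErrorModel.uniform(0.0), seed=4)
        assert not reads["has_error"].any()

    def test_error_fraction_matches_binomial(self, tiny_genome):
        g = tiny_genome.genes[0]
        reads = simulate_reads(tiny_genome, self._alleles(tiny_genome),
                               {g.gene_id: 10_000},
                               ErrorModel.uniform(0.01), seed=5)
        frac = reads["has_error"].mean()
        expected = 1 - 0.99 ** 48  # ~0.383
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 10_000)


class TestReferenceMappingFilter:
    def test_reference_allele_strain_identical_modes(self, tiny_genome):
        alleles = np.zeros(len(tiny_genome.variants), dtype=np.int8)
        nr = {g.gene_id: 30 for g in tiny_genome.genes}
        reads = simulate_reads(tiny_genome, alleles, nr,
                               ErrorModel.uniform(0.005), seed=6)
        a = reference_mapping_filter(reads, 3, "strain_specific")
        b = reference_mapping_filter(reads, 3, "reference")
        pd.testing.assert_frame_equal(a, b)

    def test_alt_snps_over_budget_dropped_in_reference_mode(self):
        reads = pd.DataFrame(
            {"sample_id": ["s"], "gene_id": ["g"], "chrom": ["chr1"],
             "start": [100], "end": [147], "strand": ["+"],
             "n_variant_covered": [4], "n_alt_covered": [4], "n_errors": [0]}
        )
        assert len(reference_mapping_filter(reads, 3, "strain_specific")) == 1
        assert len(reference_mapping_filter(reads, 3, "reference")) == 0

    def test_strain_specific_retains_superset(self, tiny_genome):
        alleles = np.ones(len(tiny_genome.variants), dtype=np.int8)
        nr = {g.gene_id: 40 for g in tiny_genome.genes}
        reads = simulate_reads(tiny_genome, alleles, nr,
                               ErrorModel.uniform(0.01), seed=7)
        for tol in (0, 1, 3):
            kept_ss = set(reference_mapping_filter(reads, tol,
                                                   "strain_specific").index)
            kept_ref = set(reference_mapping_filter(reads, tol,
                                                    "reference").index)
            assert kept_ref <= kept_ss


class TestSimulateGenotypeCalls:
    def test_theta_zero_no_error_equals_truth_at_intragenic_sites(
        self, tiny_genome, tiny_cross
    ):
        # uniformly high expression: every gene has counts > 0 everywhere
        sim = simulate_expression(
            tiny_genome, tiny_cross,
            EffectConfig(baseline_log2=np.full(30, 5.0), dispersion=0.0),
            seed=1,
        )
        calls = simulate_genotype_calls(
            tiny_cross, sim.sense_counts,
            CallParams(coverage_theta=0.0, error_rate=0.0), seed=1,
        )
        host = tiny_genome.variant_gene_index()
        intragenic = host >= 0
        assert (calls.alleles[:, intragenic] != -1).all()
        assert (calls.alleles[:, ~intragenic] == -1).all()
        # ref/alt codes match parental origin (P1 carries ref by default)
        expected = tiny_cross.matrix[:, intragenic]
        assert (calls.alleles[:, intragenic] == expected).all()

    def test_silenced_gene_sites_all_missing(self, tiny_genome, tiny_cross):
        baseline = np.full(30, 5.0)
        baseline[3] = -20.0  # gene g0003 silent -> zero counts
        sim = simulate_expression(
            tiny_genome, tiny_cross,
            EffectConfig(baseline_log2=baseline, dispersion=0.0), seed=1,
        )
        calls = simulate_genotype_calls(
            tiny_cross, sim.sense_counts, CallParams(coverage_theta=0.0),
            seed=1,
        )
        host = tiny_genome.variant_gene_index()
        silenced = np.flatnonzero(host == 3)
        if len(silenced):
            assert (calls.alleles[:, silenced] == -1).all()

    def test_call_error_rate_matches_discordance(self, tiny_genome, tiny_cross):
        sim = simulate_expression(
            tiny_genome, tiny_cross,
            EffectConfig(baseline_log2=np.full(30, 6.0), dispersion=0.0),
            seed=1,
        )
        calls = simulate_genotype_calls(
            tiny_cross, sim.sense_counts,
            CallParams(coverage_theta=0.0, error_rate=0.01), seed=2,
        )
        host = tiny_genome.variant_gene_index()
        intra = host >= 0
        called = calls.alleles[:, intra]
        truth = tiny_cross.matrix[:, intra]
        disc = (called != truth).mean()
        assert abs(disc - 0.01) < 0.006
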