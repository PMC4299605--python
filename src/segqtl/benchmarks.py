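"""Self-contained evaluation experiments for the pipeline's key claims.

Each function simulates its study conditions from a seed, runs the relevant
pipeline stages, and returns the measured quantities as a flat dict of
numbers.  The validation suite asserts on these numbers and the
reproduction script reports them; both therefore exercise exactly the same
code paths as a user would.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._random import substream
from .designs import (
    N_PERM_DESK,
    RF_DESK,
    RF_DESK_NULL,
    genotyping_study,
    null_study,
    qtl_study,
)
from .expression import normalize_sense, quantify
from .genotyping import (
    InheritanceMatrix,
    build_markers,
    correct_isolated_discordant,
    filter_sites,
    impute_missing,
    infer_inheritance,
)
from .genome import UNKNOWN
from .growth import GrowthCurve, growth_params
from .postqtl import (
    classify_cis_trans,
    classify_gene_pairs,
    detect_hotspots,
    pair_enrichment,
)
from .postqtl import _category_counts
from .qtl import (
    empirical_p_and_fdr,
    group_qtls,
    marker_ld,
    permutation_null,
    rf_selection_frequency,
)
from .simulate import (
    CallParams,
    EffectConfig,
    ErrorModel,
    SimConfig,
    make_genome,
    simulate_cross,
    simulate_expression,
    simulate_genotype_calls,
    simulate_reads,
    reference_mapping_filter,
)

__all__ = [
    "genotyping_recovery_exact",
    "genotyping_recovery_with_missingness",
    "qtl_recovery",
    "fdr_calibration",
    "hotspot_benchmark",
    "pair_enrichment_oracle",
    "normalization_benchmark",
    "mapping_bias_benchmark",
    "growth_recovery",
]


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def _accuracy_against_truth(final: InheritanceMatrix, genome, truth):
    vf = genome.variants_frame()
    index = {(c, p): i for i, (c, p) in enumerate(zip(vf["chrom"], vf["pos"]))}
    cols = [index[(c, p)] for c, p in
            zip(final.sites["chrom"], final.sites["pos"])]
    expected = truth.matrix[:, cols]
    called = final.matrix != UNKNOWN
    accuracy = float((final.matrix[called] == expected[called]).mean())
    return accuracy, float(called.mean())


def genotyping_recovery_exact(seed: int, n_segregants: int = 44) -> dict:
    """Recovery with zero call error and full coverage of expressed sites.

    Every gene is uniformly highly expressed, the observation model calls
    every covered site, and call error is zero; inference plus imputation
    must reproduce the true genotypes exactly at every retained site.  The
    isolated-discordance correction stage is deliberately not applied: with
    complete error-free calls an isolated discordant pattern can only be a
    genuine close double recombination, which that stage (built to remove
    call errors) would overwrite.
    """
    cfg = SimConfig()
    genome = make_genome(cfg, seed)
    truth = simulate_cross(genome, n_segregants, "F1", seed=seed)
    expr = simulate_expression(
        genome, truth,
        EffectConfig(baseline_log2=np.full(cfg.n_genes, 5.0), dispersion=0.0),
        seed=seed,
    )
    calls = simulate_genotype_calls(
        truth, expr.sense_counts,
        CallParams(coverage_theta=0.0, error_rate=0.0, quality_sd=0.0),
        seed=seed,
    )
    inh = infer_inheritance(calls)
    inh, _ = filter_sites(inh, np.ones(len(inh.sites), dtype=bool))
    inh = impute_missing(inh)
    accuracy, call_rate = _accuracy_against_truth(inh, genome, truth)
    return {
        "accuracy": accuracy,
        "call_rate": call_rate,
        "n_sites_retained": len(inh.sites),
    }


def genotyping_recovery_with_missingness(
    seed: int, n_segregants: int = 44, call_error: float = 0.0
) -> dict:
    """Full pipeline under expression-tied missingness (~50% direct calls)."""
    genome, truth, expr, calls = genotyping_study(
        seed, n_segregants=n_segregants, call_error=call_error
    )
    direct = float((calls.alleles != -1).mean())
    inh = infer_inheritance(calls)
    inh, _ = filter_sites(inh, np.ones(len(inh.sites), dtype=bool))
    inh, n_corr = correct_isolated_discordant(inh)
    inh = impute_missing(inh)
    accuracy, call_rate = _accuracy_against_truth(inh, genome, truth)
    markers = build_markers(inh)
    return {
        "direct_call_rate": direct,
        "post_impute_call_rate": call_rate,
        "accuracy": accuracy,
        "n_corrections": n_corr,
        "n_markers": len(markers),
    }


# ---------------------------------------------------------------------------
# QTL mapping
# ---------------------------------------------------------------------------

def qtl_recovery(seed: int, fdr: float = 0.10,
                 rf=RF_DESK, rf_null=RF_DESK_NULL,
                 n_perm: int = N_PERM_DESK) -> dict:
    """Planted-QTL recovery and cis/trans classification on the desk study."""
    st = qtl_study(seed)
    rng = substream(seed, "scan-seeds")
    observed = pd.DataFrame(
        [
            rf_selection_frequency(
                st.traits.loc[t].to_numpy(), st.predictors, rf,
                seed=int(rng.integers(2**31 - 1)),
            )
            for t in st.traits.index
        ],
        index=st.traits.index, columns=st.predictors.marker_ids,
    )
    null = permutation_null(st.traits, st.predictors, n_perm=n_perm,
                            config=rf_null, seed=seed)
    result = empirical_p_and_fdr(observed, null)
    linked = result.linked(fdr)

    ld = marker_ld(st.predictors.markers)
    mm = st.markers.markers
    chrom_lengths = dict(st.genome.chromosomes)
    gene_by_id = {g.gene_id: g for g in st.genome.genes}
    ids = st.predictors.marker_ids

    recovered = cis_ok = trans_ok = n_cis = n_trans = 0
    for _, row in st.planted.iterrows():
        sub = linked[linked["trait_id"] == row["trait_id"]]
        members = [ids.index(m) for m in sub["marker_id"]]
        group = group_qtls(members, mm, ld, chrom_lengths=chrom_lengths,
                           trait_id=row["trait_id"])
        if group is not None and group.contains_position(row["chrom"],
                                                         row["pos"]):
            recovered += 1
        if group is not None:
            g = gene_by_id[row["trait_id"]]
            flag = classify_cis_trans(
                group.member_markers, g.chrom, (g.cds_start, g.cds_end),
                mm, ld,
            )
            if row["kind"] == "cis":
                n_cis += 1
                cis_ok += flag == "cis"
            else:
                n_trans += 1
                trans_ok += flag == "trans"
    return {
        "n_planted": int(len(st.planted)),
        "n_recovered": recovered,
        "recovery_fraction": recovered / len(st.planted),
        "cis_correct": cis_ok,
        "cis_total": n_cis,
        "trans_correct": trans_ok,
        "trans_total": n_trans,
        "n_linkages": int(len(linked)),
        "n_markers": int(st.predictors.n_markers),
    }


def fdr_calibration(seed: int, n_traits: int = 200, n_perm: int = 20,
                    alpha: float = 0.05) -> dict:
    """Realized false-linkage proportion under the global null.

    Every trait is pure noise, so every declared linkage is false; the
    calibration run uses matched observed/null forest sizes (the estimator
    is exchangeable, so ensemble size cancels).
    """
    from .qtl import RFConfig

    st = null_study(seed, n_traits=n_traits)
    cfg = RFConfig(n_forests=1, trees_per_forest=50, n_missing_assignments=1)
    rng = substream(seed, "scan-seeds")
    observed = pd.DataFrame(
        [
            rf_selection_frequency(
                st.traits.loc[t].to_numpy(), st.predictors, cfg,
                seed=int(rng.integers(2**31 - 1)),
            )
            for t in st.traits.index
        ],
        index=st.traits.index, columns=st.predictors.marker_ids,
    )
    null = permutation_null(st.traits, st.predictors, n_perm=n_perm,
                            config=cfg, seed=seed)
    result = empirical_p_and_fdr(observed, null)
    linked = result.linked(alpha)
    n_false = int(len(linked))
    return {
        "n_traits": n_traits,
        "n_tests": int(result.q.size),
        "n_discoveries": n_false,
        # all discoveries are false under the global null; FDP = V/max(R,1)
        "realized_fdp": 0.0 if n_false == 0 else 1.0,
    }


# ---------------------------------------------------------------------------
# hotspots and gene pairs
# ---------------------------------------------------------------------------

def _poisson_tail_series(k: int, lam: float) -> float:
    """Brute-force upper tail by direct series summation (oracle)."""
    import math

    if k <= 0:
        return 1.0
    return 1.0 - sum(
        math.exp(-lam) * lam ** i / math.factorial(i) for i in range(k)
    )


def hotspot_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """Poisson-oracle agreement and planted-hotspot detection rate."""
    max_diff = 0.0
    for lam in (0.25, 1.0, 3.0, 7.5):
        for k in range(0, 30):
            ours = float(stats.poisson.sf(k - 1, lam))
            max_diff = max(max_diff, abs(ours - _poisson_tail_series(k, lam)))

    genome = make_genome(SimConfig(), seed)
    rng = substream(seed, "hotspot-background")
    detected = 0
    for _ in range(n_seeds):
        rows = [{"trait_id": f"h{t}", "chrom": "chr1", "pos": 525_000}
                for t in range(50)]
        for t in range(250):
            chrom, length = genome.chromosomes[int(rng.integers(2))]
            rows.append({"trait_id": f"b{t}", "chrom": chrom,
                         "pos": int(rng.integers(1, length))})
        hotspots = detect_hotspots(pd.DataFrame(rows), genome, alpha=8e-4)
        detected += any(
            h.chrom == "chr1" and h.start <= 525_000 <= h.end
            for h in hotspots
        )
    return {
        "poisson_oracle_max_abs_diff": max_diff,
        "detection_rate": detected / n_seeds,
        "n_seeds": n_seeds,
    }


def pair_enrichment_oracle(seed: int, n_perm: int = 20_000) -> dict:
    """Permutation p versus the exact hypergeometric tail on a toy universe.

    Twenty genes on ten two-gene chromosomes: each gene belongs to exactly
    one adjacent pair, so the count of picked genes in a category is an
    exact hypergeometric draw.
    """
    from .genome import GeneAnnotation, GenomeModel

    chroms, genes = [], []
    strands = [("+", "-")] * 4 + [("-", "+")] * 3 + [("+", "+")] * 3
    for i, (sa, sb) in enumerate(strands):
        chrom = f"c{i}"
        chroms.append((chrom, 50_000))
        tss_a = 950 if sa == "+" else 3050
        tss_b = 4950 if sb == "+" else 7050
        genes.append(GeneAnnotation(f"g{i}a", chrom, sa, tss_a, 1000, 3000))
        genes.append(GeneAnnotation(f"g{i}b", chrom, sb, tss_b, 5000, 7000))
    genome = GenomeModel(chroms, genes, [])
    pairs = classify_gene_pairs(genome)
    universe = [g.gene_id for g in genome.genes]

    rng = substream(seed, "oracle-targets")
    targets = list(rng.choice(universe, size=8, replace=False))
    res = pair_enrichment(targets, pairs, universe, n_perm=n_perm, seed=seed)
    observed = _category_counts(set(targets), pairs)[
        "convergent_non_overlapping"
    ]
    # 8 of the 20 genes sit in convergent non-overlapping pairs
    exact = float(stats.hypergeom.sf(observed - 1, 20, 8, 8))
    got = float(
        res.set_index("category").loc["convergent_non_overlapping",
                                      "p_enrichment"]
    )
    mc_se = float(np.sqrt(exact * (1 - exact) / n_perm))
    return {
        "permutation_p": got,
        "exact_hypergeometric_p": exact,
        "abs_difference": abs(got - exact),
        "two_mc_se": 2 * mc_se + 2 / n_perm,
    }


# ---------------------------------------------------------------------------
# normalization and mapping bias
# ---------------------------------------------------------------------------

def normalization_benchmark(seed: int) -> dict:
    """Batch-centering residual and exactness of the gene-drop rule."""
    genome = make_genome(SimConfig(n_genes=60, n_variants=100), seed)
    truth = simulate_cross(genome, 16, "F1", seed=seed)
    effects = EffectConfig(
        batch=["b1"] * 8 + ["b2"] * 8,
        batch_offsets={"b2": 1.0},
    )
    expr = simulate_expression(genome, truth, effects, seed=seed)
    counts = expr.sense_counts
    # silence a few genes in most samples to exercise the drop rule
    rng = substream(seed, "dropout")
    silenced = list(counts.index[:5])
    for g in silenced:
        cols = rng.choice(counts.shape[1], size=10, replace=False)
        counts.iloc[counts.index.get_loc(g), cols] = 0
    norm, dropped = normalize_sense(counts, expr.batch)

    expected_drop = sorted(counts.index[(counts == 0).mean(axis=1) > 0.5])
    residual = 0.0
    for b in ("b1", "b2"):
        members = expr.batch.index[expr.batch == b]
        residual = max(residual, float(norm[members].mean(axis=1).abs().max()))
    return {
        "max_batch_mean_residual": residual,
        "drop_rule_exact": float(sorted(dropped) == expected_drop),
        "n_dropped": len(dropped),
    }


def mapping_bias_benchmark(seed: int, n_strains: int = 4,
                           tolerance: int = 3) -> dict:
    """Reference-mode vs strain-specific quantification of simulated reads.

    For strains carrying alt alleles, reference-mode counts of genes whose
    CDS contains variants should be stochastically lower (one-sided sign
    test), and exactly equal for variant-free genes.
    """
    cfg = SimConfig(n_genes=80, n_variants=240, convergent_overlap_pairs=0)
    genome = make_genome(cfg, seed)
    truth = simulate_cross(genome, n_strains, "F1", seed=seed)
    host = genome.variant_gene_index()
    polymorphic = {genome.genes[h].gene_id for h in host if h >= 0}

    nr = {g.gene_id: 120 for g in genome.genes}
    err = ErrorModel.ramp()
    variants_of_gene = {
        gi: np.flatnonzero(host == gi) for gi in range(len(genome.genes))
    }
    lower = higher = ties = 0
    variant_free_equal = True
    for si, strain in enumerate(truth.strains):
        alleles = truth.matrix[si]
        reads = simulate_reads(genome, alleles, nr, err,
                               seed=seed + si, strain_id=strain)
        ann = genome.genes
        ss, _ = quantify(reference_mapping_filter(reads, tolerance,
                                                  "strain_specific"), ann)
        rf, _ = quantify(reference_mapping_filter(reads, tolerance,
                                                  "reference"), ann)
        for gi, g in enumerate(genome.genes):
            a = int(ss.loc[g.gene_id, strain])
            b = int(rf.loc[g.gene_id, strain])
            carries_alt = bool((alleles[variants_of_gene[gi]] == 1).any())
            if g.gene_id in polymorphic and carries_alt:
                if b < a:
                    lower += 1
                elif b > a:
                    higher += 1
                else:
                    ties += 1
            elif not carries_alt:
                variant_free_equal &= a == b
    test = stats.binomtest(lower, lower + higher, 0.5, alternative="greater") \
        if (lower + higher) else None
    return {
        "n_lower": lower,
        "n_higher": higher,
        "n_ties": ties,
        "sign_test_p": float(test.pvalue) if test else 1.0,
        "variant_free_identical": float(variant_free_equal),
    }


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def growth_recovery(seed: int = 0) -> dict:
    """Parameter recovery on closed-form exponential and logistic curves."""
    t = np.linspace(0, 8, 161)
    mu_true = 0.7
    exp_curve = GrowthCurve(t, 0.2 * np.exp(mu_true * t))
    p_exp = growth_params(exp_curve)

    r, k, od0 = 0.8, 2.0, 0.02
    tl = np.linspace(0, 16, 321)
    logistic = GrowthCurve(tl, k / (1 + (k - od0) / od0 * np.exp(-r * tl)))
    p_log = growth_params(logistic)
    r_effective = r * (1 - od0 / k)  # max specific rate of the logistic

    return {
        "mu_exponential_true": mu_true,
        "mu_exponential_est": p_exp.mu_max,
        "mu_exponential_rel_error": abs(p_exp.mu_max - mu_true) / mu_true,
        "doubling_time_identity": float(
            p_exp.doubling_time == np.log(2) / p_exp.mu_max
        ),
        "mu_logistic_true": r_effective,
        "mu_logistic_est": p_log.mu_max,
        "mu_logistic_rel_error": abs(p_log.mu_max - r_effective) / r_effective,
    }
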