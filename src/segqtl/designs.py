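"""Reference desk-scale study designs.

These functions bundle the package's canonical simulation conditions — the
sample sizes, effect sizes, noise levels and ensemble sizes used throughout
the documentation, examples and validation suite — so that every entry
point exercises the same study rather than ad-hoc parameter soups.

Three designs are provided:

* :func:`genotyping_study` — a 44-segregant cross with expression-tied
  genotype-call missingness (about half of the sites directly called),
  used to validate inference/correction/imputation;
* :func:`qtl_study` — 44 segregants, ~200 markers, 10 planted trans
  effects (1.5 trait SD) and 5 cis effects (2 SD), mapped with desk-scale
  forest ensembles (500 trees per trait over 50 missing-genotype
  assignments, 200 shared permutations);
* :func:`null_study` — the same marker panel with pure-noise traits for
  false-discovery calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random import substream
from .expression import normalize_sense
from .genotyping import build_markers, InheritanceMatrix
from .qtl import PredictorMatrix, RFConfig, kinship, structure_covariates
from .simulate import (
    CallParams,
    EffectConfig,
    SimConfig,
    TransEffect,
    TrueGenotypes,
    make_genome,
    simulate_cross,
    simulate_expression,
    simulate_genotype_calls,
)

__all__ = [
    "RF_DESK",
    "RF_DESK_NULL",
    "N_PERM_DESK",
    "genotyping_study",
    "qtl_study",
    "null_study",
    "QTLStudy",
]

#: desk-scale observed scan: 50 forests x 10 trees, one missing-genotype
#: assignment per forest (50 assignments), 500 trees total per trait
RF_DESK = RFConfig(n_forests=50, trees_per_forest=10, n_missing_assignments=50)
#: desk-scale permutation-null forests (smaller ensembles; see methods note)
RF_DESK_NULL = RFConfig(n_forests=4, trees_per_forest=50, n_missing_assignments=4)
#: shared permutations per trait at desk scale
N_PERM_DESK = 200


def genotyping_study(seed: int, n_segregants: int = 44,
                     call_error: float = 0.0):
    """Simulate the cross and call tables for genotyping validation.

    Returns (genome, truth, expression sim, calls).  With the default
    coverage model roughly half of the intragenic sites are directly
    called, mirroring a library genotyped from RNA-seq alone.
    """
    genome = make_genome(SimConfig(), seed)
    truth = simulate_cross(genome, n_segregants, "F1", seed=seed)
    expr = simulate_expression(genome, truth, EffectConfig(), seed=seed)
    calls = simulate_genotype_calls(
        truth, expr.sense_counts, CallParams(error_rate=call_error), seed=seed
    )
    return genome, truth, expr, calls


@dataclass
class QTLStudy:
    """A ready-to-map planted-QTL study."""

    genome: object
    truth: TrueGenotypes
    predictors: PredictorMatrix
    markers: object  # MarkerMap over true genotypes
    traits: pd.DataFrame  # planted trait genes x strains, normalized
    planted: pd.DataFrame  # trait_id, chrom, pos, site_index, kind, size_sd


def _predictors_from_truth(
    genome, truth: TrueGenotypes, missing_rate: float, seed: int, fixed_k: int = 8
) -> tuple[PredictorMatrix, object]:
    """Marker panel from the true genotypes with random missing entries."""
    vf = genome.variants_frame()
    inh = InheritanceMatrix(
        list(truth.strains), vf[["chrom", "pos"]].copy(), truth.matrix.copy()
    )
    markers = build_markers(inh, min_called_fraction=0.0)
    m = markers.matrix.astype(float)
    if missing_rate > 0:
        rng = substream(seed, "marker-missingness")
        m[rng.random(m.shape) < missing_rate] = np.nan
    kin = kinship(m)
    cov = structure_covariates(kin, fixed_k=fixed_k)
    pred = PredictorMatrix(
        list(truth.strains), list(markers.markers["marker_id"]), m, cov
    )
    return pred, markers


def qtl_study(
    seed: int,
    n_segregants: int = 44,
    n_variants: int = 210,
    n_trans: int = 10,
    n_cis: int = 5,
    trans_size: float = 1.5,
    cis_size: float = 2.0,
    missing_rate: float = 0.05,
) -> QTLStudy:
    """Build the planted-QTL mapping study.

    A denser crossover rate (8 per chromosome per meiosis) keeps nearly all
    variant sites segregating independently enough to remain separate
    markers (~200), and weakens long-range LD so distant trans effects stay
    distinguishable from cis.  Trans target genes are at least 200 kb from
    (or on another chromosome than) their causal site.
    """
    cfg = SimConfig(n_genes=120, n_variants=n_variants,
                    convergent_overlap_pairs=0)
    genome = make_genome(cfg, seed)
    truth = simulate_cross(genome, n_segregants, "F1", crossover_rate=8.0,
                           seed=seed)
    rng = substream(seed, "design")

    host = genome.variant_gene_index()
    hosted = sorted({genome.genes[h].gene_id for h in host if h >= 0})
    rng.shuffle(hosted)
    cis = [(g, cis_size) for g in hosted[:n_cis]]

    gene_by_id = {g.gene_id: g for g in genome.genes}
    pool = [g.gene_id for g in genome.genes if g.gene_id not in dict(cis)]
    rng.shuffle(pool)
    trans = []
    for target in pool[:n_trans]:
        tg = gene_by_id[target]
        distant = [v for v in genome.variants
                   if v.chrom != tg.chrom or abs(v.pos - tg.cds_start) > 200_000]
        v = distant[int(rng.integers(len(distant)))]
        trans.append(TransEffect((v.chrom, v.pos), [target], [trans_size]))

    effects = EffectConfig(cis_effects=cis, trans_effects=trans)
    expr = simulate_expression(genome, truth, effects, seed=seed)
    norm, _ = normalize_sense(expr.sense_counts)
    planted = expr.truth.copy()
    traits = norm.loc[[t for t in planted["trait_id"] if t in norm.index]]

    pred, markers = _predictors_from_truth(
        genome, truth, missing_rate, seed
    )
    return QTLStudy(genome, truth, pred, markers, traits, planted)


def null_study(seed: int, n_traits: int = 200, n_segregants: int = 44,
               n_variants: int = 210) -> QTLStudy:
    """Pure-noise traits over a real marker panel, for FDR calibration."""
    cfg = SimConfig(n_genes=120, n_variants=n_variants,
                    convergent_overlap_pairs=0)
    genome = make_genome(cfg, seed)
    truth = simulate_cross(genome, n_segregants, "F1", crossover_rate=8.0,
                           seed=seed)
    pred, markers = _predictors_from_truth(genome, truth, 0.0, seed)
    rng = substream(seed, "null-traits")
    traits = pd.DataFrame(
        rng.normal(size=(n_traits, n_segregants)),
        index=[f"null{t:03d}" for t in range(n_traits)],
        columns=truth.strains,
    )
    return QTLStudy(genome, truth, pred, markers, traits,
                    pd.DataFrame(columns=["trait_id", "chrom", "pos",
                                          "site_index", "kind", "size_sd"]))
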