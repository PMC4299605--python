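import numpy as np
import pandas as pd
import pytest

from segqtl import (
    EffectConfig,
    SimConfig,
    make_genome,
    simulate_cross,
    simulate_expression,
)


@pytest.fixture(scope="session")
def tiny_genome():
    """A small two-chromosome genome with convergent overlapping pairs."""
    cfg = SimConfig(
        chromosomes=[("chr1", 200_000), ("chr2", 150_000)],
        n_genes=30,
        n_variants=60,
        convergent_overlap_pairs=2,
        inversion=("chr1", 30_000, 90_000),
    )
    return make_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_cross(tiny_genome):
    return simulate_cross(tiny_genome, 12, "F1", crossover_rate=3.0, seed=11)


@pytest.fixture(scope="session")
def tiny_expression(tiny_genome, tiny_cross):
    effects = EffectConfig(cis_effects=[("g0005", 2.0)])
    return simulate_expression(tiny_genome, tiny_cross, effects, seed=11)


def inheritance_from(labels, positions, chrom="chr1", strains=None):
    """Build an InheritanceMatrix from a per-strain list of label strings.

    ``labels`` is a list of sequences over {"1", "2", "."} (P1/P2/unknown).
    """
    from segqtl.genotyping import InheritanceMatrix

    code = {"1": 0, "2": 1, ".": -1}
    mat = np.array([[code[c] for c in row] for row in labels], dtype=np.int8)
    sites = pd.DataFrame({"chrom": chrom, "pos": list(positions)})
    strains = strains or [f"S{i}" for i in range(len(labels))]
    return InheritanceMatrix(strains, sites, mat)
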