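"""Synthetic two-parent haploid crosses with expression and genotyping noise.

This module generates the study design the rest of the package analyses: two
haploid parental genomes differing at a few hundred SNP/indel sites, F1/F2
segregants produced by meiotic crossovers (with a recombination-suppressed
inversion), sense/antisense expression traits with planted cis and trans
effects plus one hotspot with opposed sense/antisense effects, short-read
placements with a position-dependent error model, and genotype-call tables
whose missingness is tied to expression level — the property that makes
RNA-seq-based genotyping of segregants hard.

Coordinates are 1-based inclusive. All randomness flows from a single master
seed through named substreams (see :mod:`segqtl._random`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import substream
from .genome import P1, P2, GeneAnnotation, GenomeModel, Inversion, VariantSite
from .genotyping import GenotypeCallMatrix

__all__ = [
    "SimConfig",
    "TrueGenotypes",
    "EffectConfig",
    "TransEffect",
    "HotspotSpec",
    "ExpressionSim",
    "ErrorModel",
    "CallParams",
    "make_genome",
    "simulate_cross",
    "simulate_expression",
    "reads_per_gene",
    "simulate_reads",
    "reference_mapping_filter",
    "simulate_genotype_calls",
]

READ_LENGTH = 48
POLYA_LENGTH = 48


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic genome.

    Defaults emulate a fission-yeast-like cross scaled to desk size: two
    chromosomes, a few hundred genes with ~85% SNP / 15% indel variants, an
    optional pericentric inversion where recombination is suppressed.
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 1_200_000), ("chr2", 800_000)]
    )
    n_genes: int = 200
    n_variants: int = 500
    frac_variants_in_cds: float = 0.9
    inversion: tuple[str, int, int] | None = ("chr1", 100_000, 400_000)
    convergent_overlap_pairs: int = 4
    cds_len_range: tuple[int, int] = (500, 2000)
    indel_fraction: float = 0.15
    max_indel_len: int = 3

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


_BASES = np.array(list("ACGT"))


def make_genome(config: SimConfig, seed: int) -> GenomeModel:
    """Lay out non-overlapping genes and sorted variant sites on the genome.

    Deterministic for a fixed seed.  ``config.convergent_overlap_pairs``
    adjacent gene pairs are turned into (+,-) pairs whose CDS ends overlap,
    emulating convergent gene pairs that exchange antisense transcription.
    """
    rng = substream(seed, "genome")
    margin = POLYA_LENGTH + 1  # keep transcripts + poly-A inside bounds

    # distribute genes over chromosomes proportionally to length
    lengths = np.array([ln for _, ln in config.chromosomes], dtype=float)
    n_per = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    n_per[0] += config.n_genes - n_per.sum()

    genes: list[GeneAnnotation] = []
    gi = 0
    for (chrom, chrom_len), n_chrom in zip(config.chromosomes, n_per):
        if n_chrom == 0:
            continue
        lo, hi = config.cds_len_range
        cds_lens = rng.integers(lo, hi + 1, size=n_chrom)
        usable = chrom_len - 2 * margin
        spare = usable - int(cds_lens.sum())
        if spare < n_chrom:
            raise ValueError(f"{chrom}: genes do not fit")
        # random gaps via an ordered uniform partition of the spare space
        cuts = np.sort(rng.integers(0, spare, size=n_chrom))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = margin
        for k in range(n_chrom):
            pos += int(gaps[k])
            start, end = pos + 1, pos + int(cds_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            d = int(rng.integers(20, 201))
            tss = max(1, start - d) if strand == "+" else min(chrom_len, end + d)
            genes.append(
                GeneAnnotation(f"g{gi:04d}", chrom, strand, tss, start, end)
            )
            pos = end
            gi += 1

    genes = _plant_convergent_overlaps(genes, config.convergent_overlap_pairs, rng)

    variants = _place_variants(config, genes, rng)
    inv = Inversion(*config.inversion) if config.inversion else None
    return GenomeModel(list(config.chromosomes), genes, variants, inv)


def _plant_convergent_overlaps(
    genes: list[GeneAnnotation], n_pairs: int, rng: np.random.Generator
) -> list[GeneAnnotation]:
    """Rewrite ``n_pairs`` adjacent same-chromosome pairs as overlapping (+,-)."""
    if n_pairs == 0:
        return genes
    genes = list(genes)
    candidates = [
        i
        for i in range(len(genes) - 1)
        if genes[i].chrom == genes[i + 1].chrom
    ]
    rng.shuffle(candidates)
    used: set[int] = set()
    made = 0
    for i in candidates:
        if made == n_pairs:
            break
        if i in used or i + 1 in used or i - 1 in used:
            continue
        a, b = genes[i], genes[i + 1]
        overlap = int(rng.integers(30, 150))
        new_b_start = a.cds_end - overlap + 1
        if new_b_start <= a.cds_start or new_b_start < 1:
            continue
        genes[i] = GeneAnnotation(
            a.gene_id, a.chrom, "+", max(1, a.cds_start - 50), a.cds_start, a.cds_end
        )
        genes[i + 1] = GeneAnnotation(
            b.gene_id, b.chrom, "-", b.cds_end + 50, new_b_start, b.cds_end
        )
        used.update({i, i + 1})
        made += 1
    return genes


def _place_variants(
    config: SimConfig, genes: list[GeneAnnotation], rng: np.random.Generator
) -> list[VariantSite]:
    n_cds = int(round(config.n_variants * config.frac_variants_in_cds))
    n_out = config.n_variants - n_cds
    positions: dict[str, set[int]] = {c: set() for c, _ in config.chromosomes}

    cds = [(g.chrom, g.cds_start, g.cds_end) for g in genes]
    weights = np.array([e - s + 1 for _, s, e in cds], dtype=float)
    if weights.sum() < n_cds:
        raise ValueError("more CDS variants requested than placeable positions")
    placed = 0
    while placed < n_cds:
        k = rng.choice(len(cds), p=weights / weights.sum())
        chrom, s, e = cds[k]
        pos = int(rng.integers(s, e + 1))
        if pos not in positions[chrom]:
            positions[chrom].add(pos)
            placed += 1
    lengths = dict(config.chromosomes)
    placed = 0
    while placed < n_out:
        chrom = config.chromosomes[int(rng.integers(len(config.chromosomes)))][0]
        pos = int(rng.integers(100, lengths[chrom] - 100))
        if pos not in positions[chrom]:
            positions[chrom].add(pos)
            placed += 1

    variants: list[VariantSite] = []
    for chrom, _ in config.chromosomes:
        for pos in sorted(positions[chrom]):
            if rng.random() < config.indel_fraction:
                ln = int(rng.integers(1, config.max_indel_len + 1))
                ins = rng.random() < 0.5
                bases = "".join(rng.choice(_BASES, size=ln))
                anchor = str(rng.choice(_BASES))
                if ins:
                    variants.append(
                        VariantSite(chrom, pos, anchor, anchor + bases, "insertion", ln)
                    )
                else:
                    variants.append(
                        VariantSite(chrom, pos, anchor + bases, anchor, "deletion", -ln)
                    )
            else:
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                variants.append(VariantSite(chrom, pos, str(ref), str(alt), "SNP", 0))
    return variants


# ---------------------------------------------------------------------------
# meiosis / cross
# ---------------------------------------------------------------------------

@dataclass
class TrueGenotypes:
    """Ground-truth parental origin of every strain at every variant site.

    ``matrix`` is strains x sites with values P1 (0) / P2 (1); ``breakpoints``
    maps a strain to its sorted list of (chrom, position) label switches.
    """

    strains: list[str]
    matrix: np.ndarray  # int8, strains x n_variants
    breakpoints: dict[str, list[tuple[str, float]]]
    genome: GenomeModel

    def breakpoint_counts(self) -> pd.Series:
        return pd.Series({s: len(b) for s, b in self.breakpoints.items()})


def _draw_crossovers(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    rate: float,
    inversion: Inversion | None,
    suppression: float,
) -> np.ndarray:
    """Crossover positions of one meiosis: Poisson count, uniform placement,
    thinned by ``suppression`` inside the inversion interval."""
    n = rng.poisson(rate)
    pos = rng.uniform(1, length, size=n)
    if inversion is not None and inversion.chrom == chrom and n:
        inside = (pos >= inversion.start) & (pos <= inversion.end)
        keep = ~inside | (rng.random(n) < suppression)
        pos = pos[keep]
    return np.sort(pos)


def _label_at(
    x: np.ndarray, crossovers: np.ndarray, start: int
) -> np.ndarray:
    """Parental label of positions ``x`` on a mosaic haplotype."""
    return (start + np.searchsorted(crossovers, x)) % 2


def simulate_cross(
    genome: GenomeModel,
    n_segregants: int,
    generation: str = "F1",
    crossover_rate: float = 1.4,
    inversion_suppression: float = 0.1,
    seed: int = 0,
) -> TrueGenotypes:
    """Simulate haploid segregants of a two-parent cross.

    ``crossover_rate`` is the expected number of crossovers per chromosome
    per meiosis.  F2 segregants go through two successive meioses (the
    second recombines two independent F1 mosaics), accumulating more
    breakpoints than F1.  Crossovers inside the inversion are retained with
    probability ``inversion_suppression``.
    """
    if n_segregants < 1:
        raise ValueError("n_segregants must be >= 1")
    if crossover_rate < 0:
        raise ValueError("crossover_rate must be >= 0")
    if generation not in ("F1", "F2"):
        raise ValueError("generation must be 'F1' or 'F2'")
    rng = substream(seed, "cross")
    vf = genome.variants_frame()
    strains = [f"S{i:03d}" for i in range(n_segregants)]
    matrix = np.empty((n_segregants, len(genome.variants)), dtype=np.int8)
    breakpoints: dict[str, list[tuple[str, float]]] = {s: [] for s in strains}

    for si, strain in enumerate(strains):
        for chrom, length in genome.chromosomes:
            mask = (vf["chrom"] == chrom).to_numpy()
            vpos = vf.loc[mask, "pos"].to_numpy()

            def meiosis():
                co = _draw_crossovers(
                    rng, chrom, length, crossover_rate,
                    genome.inversion, inversion_suppression,
                )
                return co, int(rng.integers(2))

            co_a, s_a = meiosis()
            if generation == "F1":
                labels = _label_at(vpos, co_a, s_a)
                switch_candidates = co_a

                def final(x):
                    return _label_at(np.asarray(x, dtype=float), co_a, s_a)
            else:
                co_b, s_b = meiosis()
                co_2, s_2 = meiosis()

                def final(x):
                    x = np.asarray(x, dtype=float)
                    la = _label_at(x, co_a, s_a)
                    lb = _label_at(x, co_b, s_b)
                    chooser = _label_at(x, co_2, s_2)
                    return np.where(chooser == 0, la, lb)

                labels = final(vpos)
                switch_candidates = np.sort(
                    np.concatenate([co_a, co_b, co_2])
                )
            matrix[si, mask] = labels
            if len(switch_candidates):
                eps = 1e-6
                left = final(switch_candidates - eps)
                right = final(switch_candidates + eps)
                for p, l, r in zip(switch_candidates, left, right):
                    if l != r:
                        breakpoints[strain].append((chrom, float(p)))
    return TrueGenotypes(strains, matrix, breakpoints, genome)


# ---------------------------------------------------------------------------
# expression phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TransEffect:
    """A marker site acting on one or more distant target genes."""

    site: tuple[str, int]  # (chrom, pos) of the causal variant
    targets: list[str]
    sizes: list[float]  # per target, in units of EffectConfig.trait_sd


@dataclass
class HotspotSpec:
    """One locus with opposed sense/antisense effects on many targets."""

    site: tuple[str, int]
    sense_targets: list[str]
    sense_size: float = -1.0
    antisense_targets: list[str] = field(default_factory=list)
    antisense_size: float = 1.0


@dataclass
class EffectConfig:
    """Planted genetic architecture and noise model for expression traits.

    Effect sizes are in units of the target gene's residual log2 SD: by
    default the SD implied by the count-noise model for that gene,
    sqrt(dispersion + 1/mu) / ln 2 with mu the gene's baseline mean count,
    so a size of 1.5 shifts the P2-allele group mean by 1.5 of the gene's
    own noise SDs regardless of its expression level.  Setting ``trait_sd``
    fixes a global log2 unit instead.  Counts are drawn negative-binomial
    with dispersion ``dispersion`` (variance mu + dispersion * mu^2);
    dispersion 0 yields deterministic rounded means so that noise can be
    switched off exactly.
    """

    cis_effects: list[tuple[str, float]] = field(default_factory=list)
    trans_effects: list[TransEffect] = field(default_factory=list)
    hotspot: HotspotSpec | None = None
    batch: list[str] | None = None  # per sample; default single batch
    batch_offsets: dict[str, float] = field(default_factory=dict)  # log2 units
    dispersion: float = 0.05
    trait_sd: float | None = None  # None: per-gene auto unit (see above)
    baseline_log2: np.ndarray | None = None  # per gene; drawn if None
    baseline_mean: float = 2.5
    baseline_sd: float = 2.0
    antisense_shift: float = -3.0  # antisense baseline below sense
    library_size_sd: float = 0.1  # lognormal sd of per-sample factors
    count_scale: float = 10.0  # counts per unit of 2^log2-expression


@dataclass
class ExpressionSim:
    """Simulated counts with the ground truth needed for recovery tests."""

    sense_counts: pd.DataFrame  # genes x samples, raw counts
    antisense_counts: pd.DataFrame
    sense_means: pd.DataFrame  # true log2 means (pre-noise)
    antisense_means: pd.DataFrame
    truth: pd.DataFrame  # trait_id, strand, chrom, pos, size_sd, kind
    batch: pd.Series  # per sample
    library_factors: pd.Series


def _site_index(genome: GenomeModel, site: tuple[str, int]) -> int:
    for i, v in enumerate(genome.variants):
        if (v.chrom, v.pos) == tuple(site):
            return i
    raise KeyError(f"no variant at {site}")


def nearest_variant_in_gene(genome: GenomeModel, gene_id: str) -> int:
    """Index of the variant inside the gene's CDS (or nearest on its chromosome)."""
    g = next(gg for gg in genome.genes if gg.gene_id == gene_id)
    best, best_d = -1, math.inf
    for i, v in enumerate(genome.variants):
        if v.chrom != g.chrom:
            continue
        if g.cds_start <= v.pos <= g.cds_end:
            return i
        d = min(abs(v.pos - g.cds_start), abs(v.pos - g.cds_end))
        if d < best_d:
            best, best_d = i, d
    if best < 0:
        raise ValueError(f"no variant on chromosome of {gene_id}")
    return best


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return np.rint(mu).astype(np.int64)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_expression(
    genome: GenomeModel,
    genotypes: TrueGenotypes,
    effects: EffectConfig,
    seed: int = 0,
) -> ExpressionSim:
    """Draw sense/antisense count matrices with the planted architecture.

    Per gene and sample the true log2 mean is
    ``baseline + trait_sd * sum(effects where P2 allele) + batch offset``;
    counts are negative-binomial around ``count_scale * 2^mean * library
    factor``.  Hotspot targets receive coupled effects: sense down and
    antisense up for the alt (P2) allele.
    """
    rng = substream(seed, "expression")
    gene_ids = [g.gene_id for g in genome.genes]
    gindex = {g: i for i, g in enumerate(gene_ids)}
    samples = genotypes.strains
    n_g, n_s = len(gene_ids), len(samples)

    baseline = effects.baseline_log2
    if baseline is None:
        baseline = rng.normal(effects.baseline_mean, effects.baseline_sd, size=n_g)
    baseline = np.asarray(baseline, dtype=float)

    batch = pd.Series(
        effects.batch if effects.batch is not None else ["b0"] * n_s,
        index=samples, name="batch",
    )
    offsets = batch.map(lambda b: effects.batch_offsets.get(b, 0.0)).to_numpy()

    sense_mean = np.tile(baseline[:, None], (1, n_s)) + offsets[None, :]
    anti_mean = sense_mean + effects.antisense_shift

    def _sd_unit(gene_row: int, strand: str) -> float:
        if effects.trait_sd is not None:
            return effects.trait_sd
        base = baseline[gene_row] + (
            0.0 if strand == "sense" else effects.antisense_shift
        )
        mu = effects.count_scale * 2.0 ** base
        return float(np.sqrt(effects.dispersion + 1.0 / mu) / np.log(2))

    truth_rows = []

    def _apply(target: str, site_idx: int, size: float, strand: str, kind: str):
        alt = genotypes.matrix[:, site_idx] == P2
        shift = _sd_unit(gindex[target], strand) * size * alt.astype(float)
        v = genome.variants[site_idx]
        if strand == "sense":
            sense_mean[gindex[target], :] += shift
        else:
            anti_mean[gindex[target], :] += shift
        truth_rows.append(
            {"trait_id": target, "strand": strand, "chrom": v.chrom,
             "pos": v.pos, "site_index": site_idx, "size_sd": size, "kind": kind}
        )

    for gene_id, size in effects.cis_effects:
        _apply(gene_id, nearest_variant_in_gene(genome, gene_id), size, "sense", "cis")
    for te in effects.trans_effects:
        si = _site_index(genome, te.site)
        for target, size in zip(te.targets, te.sizes):
            _apply(target, si, size, "sense", "trans")
    if effects.hotspot is not None:
        hs = effects.hotspot
        si = _site_index(genome, hs.site)
        for t in hs.sense_targets:
            _apply(t, si, hs.sense_size, "sense", "hotspot")
        for t in hs.antisense_targets:
            _apply(t, si, hs.antisense_size, "antisense", "hotspot")

    lib = pd.Series(
        np.exp(rng.normal(0.0, effects.library_size_sd, size=n_s)),
        index=samples, name="library_factor",
    )
    mu_sense = effects.count_scale * np.exp2(sense_mean) * lib.to_numpy()[None, :]
    mu_anti = effects.count_scale * np.exp2(anti_mean) * lib.to_numpy()[None, :]
    sense = _nb_draw(rng, mu_sense, effects.dispersion)
    anti = _nb_draw(rng, mu_anti, effects.dispersion)

    return ExpressionSim(
        sense_counts=pd.DataFrame(sense, index=gene_ids, columns=samples),
        antisense_counts=pd.DataFrame(anti, index=gene_ids, columns=samples),
        sense_means=pd.DataFrame(sense_mean, index=gene_ids, columns=samples),
        antisense_means=pd.DataFrame(anti_mean, index=gene_ids, columns=samples),
        truth=pd.DataFrame(truth_rows),
        batch=batch,
        library_factors=lib,
    )


# ---------------------------------------------------------------------------
# read simulation and the mapping-bias model
# ---------------------------------------------------------------------------

def reads_per_gene(norm_log_expression):
    """Number of reads to simulate for a gene from its normalized log2 level.

    ``NR = max(1, ceil(10 * 2^expression))``: the log2 value is moved back to
    the natural scale, multiplied by 10, ceiled to an integer, and floored
    at one read.  Monotone non-decreasing in expression.
    """
    x = np.asarray(norm_log_expression, dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression must not be NaN")
    nr = np.maximum(1, np.ceil(10.0 * np.exp2(x))).astype(np.int64)
    return nr if nr.ndim else int(nr)


@dataclass
class ErrorModel:
    """Per-read-position mismatch probabilities (empirical-style profile)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ValueError("error probabilities must lie in [0, 1]")

    @classmethod
    def uniform(cls, rate: float, read_length: int = READ_LENGTH) -> "ErrorModel":
        return cls(np.full(read_length, rate))

    @classmethod
    def ramp(
        cls, start: float = 0.001, end: float = 0.01, read_length: int = READ_LENGTH
    ) -> "ErrorModel":
        """Error rate rising linearly along the read, as on real sequencers."""
        return cls(np.linspace(start, end, read_length))


def simulate_reads(
    genome: GenomeModel,
    strain_alleles: np.ndarray,
    nr_per_gene: dict[str, int] | pd.Series,
    error_model: ErrorModel,
    read_length: int = READ_LENGTH,
    seed: int = 0,
    strain_id: str = "strain",
) -> pd.DataFrame:
    """Place ``NR`` reads uniformly on each gene's transcript (+ poly-A tail).

    ``strain_alleles`` gives the strain's allele (0 ref / 1 alt) at every
    genome variant; covered variant sites are counted against it so the
    mapping-bias filter can be applied downstream.  Read strand equals gene
    strand; per-base sequencing errors follow ``error_model``.
    """
    rng = substream(seed, "reads")
    probs = error_model.probs[:read_length]
    vf = genome.variants_frame()
    strain_alleles = np.asarray(strain_alleles)
    rows = []
    for g in genome.genes:
        nr = int(nr_per_gene[g.gene_id]) if g.gene_id in nr_per_gene else 0
        if nr < 1:
            continue
        tlen = g.cds_length + POLYA_LENGTH
        span = max(1, tlen - read_length + 1)
        offsets = rng.integers(0, span, size=nr)  # 0-based transcript offsets
        if g.strand == "+":
            starts = g.cds_start + offsets
        else:
            starts = g.cds_end - offsets - (read_length - 1)
        ends = starts + read_length - 1
        n_err = (rng.random((nr, read_length)) < probs[None, :]).sum(axis=1)

        vmask = (vf["chrom"] == g.chrom).to_numpy()
        vpos = vf.loc[vmask, "pos"].to_numpy()
        valle = strain_alleles[vmask]
        vdelta = vf.loc[vmask, "delta"].to_numpy()
        # mismatch-equivalents per covered alt site: a SNP is one mismatch;
        # an indel defeats ungapped alignment outright (scored as the whole
        # read so it always exceeds any mismatch budget)
        weight = np.where(vdelta == 0, 1, read_length) * (valle == 1)
        lo = np.searchsorted(vpos, starts, side="left")
        hi = np.searchsorted(vpos, ends, side="right")
        n_cov = hi - lo
        alt_cum = np.concatenate([[0], np.cumsum(weight)])
        n_alt = alt_cum[hi] - alt_cum[lo]

        rows.append(
            pd.DataFrame(
                {
                    "sample_id": strain_id,
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": starts,
                    "end": ends,
                    "strand": g.strand,
                    "n_variant_covered": n_cov,
                    "n_alt_covered": n_alt,
                    "n_errors": n_err,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "gene_id", "chrom", "start", "end", "strand",
                     "n_variant_covered", "n_alt_covered", "n_errors"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["has_error"] = out["n_errors"] > 0
    return out


def reference_mapping_filter(
    reads: pd.DataFrame, tolerance: int = 3, mode: str = "strain_specific"
) -> pd.DataFrame:
    """Mismatch-budget model of read alignment against two genome choices.

    In ``strain_specific`` mode only sequencing errors count as mismatches;
    in ``reference`` mode every covered variant site where the strain carries
    the non-reference allele adds its mismatch-equivalents (one per SNP, the
    whole read for an indel, which an ungapped aligner cannot span), so reads
    over polymorphic regions of alt-carrying strains are preferentially lost
    — the mechanism by which reference-based alignment underestimates their
    expression.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if mode == "strain_specific":
        mism = reads["n_errors"]
    elif mode == "reference":
        mism = reads["n_errors"] + reads["n_alt_covered"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reads.loc[mism <= tolerance].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype-call simulation (expression-tied missingness)
# ---------------------------------------------------------------------------

@dataclass
class CallParams:
    """Observation model for variant calls derived from RNA-seq coverage.

    A site is called with probability ``1 - exp(-count / coverage_theta)``
    where ``count`` is the host gene's read count in that sample (a site is
    never observed outside a gene); ``coverage_theta`` 0 means every site of
    an expressed gene is called.  A called allele flips to the wrong parent
    with probability ``error_rate``; call qualities are normal
    (``quality_mean``, ``quality_sd``) clipped at 0.
    """

    coverage_theta: float = 70.0
    error_rate: float = 0.0
    quality_mean: float = 60.0
    quality_sd: float = 15.0


def simulate_genotype_calls(
    true: TrueGenotypes,
    sense_counts: pd.DataFrame,
    call_params: CallParams,
    seed: int = 0,
) -> GenotypeCallMatrix:
    """Generate per-strain variant calls whose missingness tracks expression."""
    genome = true.genome
    rng = substream(seed, "calls")
    host = genome.variant_gene_index()
    vf = genome.variants_frame()
    gene_ids = [g.gene_id for g in genome.genes]
    n_strain, n_site = true.matrix.shape

    alleles = np.full((n_strain, n_site), GenotypeCallMatrix.MISSING, dtype=np.int8)
    quality = np.zeros((n_strain, n_site), dtype=float)
    p1_is_ref = vf["p1_is_ref"].to_numpy()

    counts = sense_counts.loc[:, true.strains].to_numpy()
    gene_row = {g: i for i, g in enumerate(sense_counts.index)}
    for vi in range(n_site):
        if host[vi] < 0 or gene_ids[host[vi]] not in gene_row:
            continue  # intergenic or unquantified: never observed
        c = counts[gene_row[gene_ids[host[vi]]], :].astype(float)
        if call_params.coverage_theta <= 0:
            p_called = (c > 0).astype(float)
        else:
            p_called = 1.0 - np.exp(-c / call_params.coverage_theta)
        called = rng.random(n_strain) < p_called
        if not called.any():
            continue
        truth = true.matrix[:, vi]  # P1/P2
        # translate parent of origin into ref/alt given which parent is ref
        allele = np.where(truth == P1, ~p1_is_ref[vi], p1_is_ref[vi]).astype(np.int8)
        if call_params.error_rate > 0:
            flip = rng.random(n_strain) < call_params.error_rate
            allele = np.where(flip, 1 - allele, allele).astype(np.int8)
        alleles[called, vi] = allele[called]
        quality[called, vi] = np.clip(
            rng.normal(call_params.quality_mean, call_params.quality_sd,
                       size=called.sum()),
            0, None,
        )
    sites = vf[["chrom", "pos", "ref", "alt", "p1_is_ref"]].copy()
    return GenotypeCallMatrix(list(true.strains), sites, alleles, quality)
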