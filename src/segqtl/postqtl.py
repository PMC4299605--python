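"""Downstream statistics on QTL linkages.

Hotspots (genomic bins with more linkages than a Poisson expectation),
cis/trans classification via LD with the markers flanking the target gene,
effect directionality relative to the reference parent, candidate-regulator
prediction by maximal squared correlation, and gene-pair-orientation
enrichment among antisense targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._random import substream
from .genome import P1, P2, UNKNOWN, GenomeModel

__all__ = [
    "Hotspot",
    "GenePairRecord",
    "detect_hotspots",
    "classify_cis_trans",
    "directionality",
    "candidate_regulator",
    "hotspot_regulator_vote",
    "classify_gene_pairs",
    "pair_enrichment",
    "PAIR_CATEGORIES",
]


# ---------------------------------------------------------------------------
# hotspot detection
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    """One or more merged genomic bins enriched for linkages."""

    chrom: str
    start: int
    end: int
    count: int
    expected: float
    p_value: float
    targets: set[str] = field(default_factory=set)


def _genome_bins(genome: GenomeModel, bin_size: int) -> pd.DataFrame:
    """Fixed-width bins; the last bin of each chromosome absorbs the remainder
    (end-of-chromosome bins are bigger rather than smaller)."""
    rows = []
    for chrom, length in genome.chromosomes:
        n_bins = max(1, length // bin_size)
        for b in range(n_bins):
            start = b * bin_size + 1
            end = (b + 1) * bin_size if b < n_bins - 1 else length
            rows.append({"chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


def detect_hotspots(
    qtl_positions: pd.DataFrame,
    genome: GenomeModel,
    bin_size: int = 50_000,
    alpha: float = 8e-4,
    merge_rule: str = "any_shared",
) -> list[Hotspot]:
    """Find bins containing significantly more eQTLs than expected.

    ``qtl_positions`` needs columns trait_id/chrom/pos, one row per linkage,
    ``pos`` being the linkage's peak-marker position.  The expected count
    per bin is uniform (total linkages / number of bins) and the upper-tail
    p-value is Poisson P(X >= observed).  Bins with p < ``alpha`` are kept
    and consecutive significant bins sharing at least one target trait are
    merged (``merge_rule="identical"`` requires identical target sets).
    """
    bins = _genome_bins(genome, bin_size)
    if not len(qtl_positions):
        return []
    counts = np.zeros(len(bins), dtype=int)
    targets: list[set[str]] = [set() for _ in range(len(bins))]
    for _, row in qtl_positions.iterrows():
        hit = bins.index[
            (bins["chrom"] == row["chrom"])
            & (bins["start"] <= row["pos"])
            & (bins["end"] >= row["pos"])
        ]
        if len(hit):
            counts[hit[0]] += 1
            targets[hit[0]].add(row["trait_id"])
    lam = counts.sum() / len(bins)
    # upper tail P(X >= k) = sf(k - 1)
    pvals = stats.poisson.sf(counts - 1, lam)

    sig = np.flatnonzero(pvals < alpha)
    hotspots: list[Hotspot] = []
    for b in sig:
        row = bins.iloc[b]
        hs = Hotspot(row["chrom"], int(row["start"]), int(row["end"]),
                     int(counts[b]), float(lam), float(pvals[b]),
                     set(targets[b]))
        # merge with previous hotspot when bins are consecutive and share targets
        if (
            hotspots
            and hs.chrom == hotspots[-1].chrom
            and hs.start == hotspots[-1].end + 1
            and (
                (hotspots[-1].targets & hs.targets)
                if merge_rule == "any_shared"
                else hotspots[-1].targets == hs.targets
            )
        ):
            prev = hotspots[-1]
            prev.end = hs.end
            prev.count += hs.count
            prev.p_value = min(prev.p_value, hs.p_value)
            prev.targets |= hs.targets
        else:
            hotspots.append(hs)
    return hotspots


# ---------------------------------------------------------------------------
# cis / trans classification
# ---------------------------------------------------------------------------

def _flanking_marker_indices(
    markers: pd.DataFrame, chrom: str, cds_start: int, cds_end: int
) -> list[int]:
    """Indices of the nearest marker(s) flanking (or containing) the CDS."""
    on = markers.index[markers["chrom"] == chrom]
    if not len(on):
        return []
    starts = markers.loc[on, "start"].to_numpy()
    ends = markers.loc[on, "end"].to_numpy() if "end" in markers else starts
    inside = [i for i, (s, e) in zip(on, zip(starts, ends))
              if s <= cds_end and e >= cds_start]
    if inside:
        return inside
    left = [i for i, e in zip(on, ends) if e < cds_start]
    right = [i for i, s in zip(on, starts) if s > cds_end]
    out = []
    if left:
        out.append(left[-1])
    if right:
        out.append(right[0])
    return out


def classify_cis_trans(
    qtl_members: list[int],
    gene_chrom: str,
    gene_cds: tuple[int, int],
    markers: pd.DataFrame,
    ld: np.ndarray,
    r_min: float = 0.8,
) -> str:
    """cis iff a QTL member marker is in LD > ``r_min`` with a marker
    surrounding the target gene's CDS (the nearest flanking markers).

    Genes on chromosomes carrying no marker are trans by construction; a
    gene past the last marker of its chromosome falls back on the single
    nearest marker.
    """
    surrounding = _flanking_marker_indices(markers, gene_chrom, *gene_cds)
    if not surrounding or not qtl_members:
        return "trans"
    best = max(
        (ld[m, s] for m in qtl_members for s in surrounding
         if not np.isnan(ld[m, s])),
        default=np.nan,
    )
    return "cis" if (not np.isnan(best) and best > r_min) else "trans"


def directionality(
    trait_values: np.ndarray, genotype: np.ndarray
) -> int:
    """Sign of the trait difference between allele groups, relative to P1.

    Returns +1 when the P2-allele group mean exceeds the P1 group mean,
    -1 when lower, 0 on exact ties.  Strains with missing genotype or
    trait are excluded; the linkage is assumed already significant.
    """
    y = np.asarray(trait_values, dtype=float)
    g = np.asarray(genotype)
    keep = ~np.isnan(y) & (g != UNKNOWN)
    y, g = y[keep], g[keep]
    m1 = y[g == P1].mean() if (g == P1).any() else np.nan
    m2 = y[g == P2].mean() if (g == P2).any() else np.nan
    if np.isnan(m1) or np.isnan(m2) or m1 == m2:
        return 0
    return 1 if m2 > m1 else -1


# ---------------------------------------------------------------------------
# candidate regulators
# ---------------------------------------------------------------------------

def candidate_regulator(
    target_trait: np.ndarray,
    qtl_group,
    genome: GenomeModel,
    expression: pd.DataFrame,
    target_gene_id: str | None = None,
) -> str | None:
    """Gene at the QTL most correlated (r^2) with the target trait.

    All annotated genes with expression data whose CDS falls inside a QTL
    region are candidates; the target gene itself is excluded when inside
    its own QTL.  Ties break toward the smaller genomic coordinate.
    """
    y = np.asarray(target_trait, dtype=float)
    candidates = []
    for g in genome.genes:
        if g.gene_id == target_gene_id or g.gene_id not in expression.index:
            continue
        for r in qtl_group.regions:
            if r.chrom == g.chrom and g.cds_start <= r.end and g.cds_end >= r.start:
                candidates.append(g)
                break
    best_id, best_r2, best_pos = None, -1.0, None
    for g in sorted(candidates, key=lambda g: (g.chrom, g.cds_start)):
        x = expression.loc[g.gene_id].to_numpy(dtype=float)
        keep = ~np.isnan(x) & ~np.isnan(y)
        if keep.sum() < 3 or np.std(x[keep]) == 0 or np.std(y[keep]) == 0:
            continue
        r2 = np.corrcoef(x[keep], y[keep])[0, 1] ** 2
        if r2 > best_r2:
            best_id, best_r2, best_pos = g.gene_id, r2, g.cds_start
    return best_id


def hotspot_regulator_vote(candidates: list[str | None],
                           genome: GenomeModel | None = None) -> str | None:
    """Modal candidate regulator over a hotspot's targets.

    Ties break toward the smaller genomic coordinate when a genome is
    supplied, else lexicographically.
    """
    votes = pd.Series([c for c in candidates if c is not None])
    if votes.empty:
        return None
    counts = votes.value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1 or genome is None:
        return sorted(top)[0]
    pos = {g.gene_id: (g.chrom, g.cds_start) for g in genome.genes}
    return min(top, key=lambda gid: pos.get(gid, ("~", np.inf)))


# ---------------------------------------------------------------------------
# gene-pair organization
# ---------------------------------------------------------------------------

PAIR_CATEGORIES = [
    "convergent_overlapping",
    "convergent_non_overlapping",
    "divergent_overlapping",
    "divergent_non_overlapping",
    "tandem_overlapping",
    "tandem_non_overlapping",
]


@dataclass(frozen=True)
class GenePairRecord:
    gene_a: str
    gene_b: str
    category: str


def classify_gene_pairs(genome: GenomeModel) -> list[GenePairRecord]:
    """Classify adjacent coding gene pairs into six orientation categories.

    Coding genes are ordered by TSS position per chromosome; each pair of
    successive genes is convergent (+,-), divergent (-,+) or tandem
    (+,+ / -,-), and overlapping when the CDS intervals intersect (UTR-only
    overlap does not count because antisense is evaluated over the CDS).
    """
    out: list[GenePairRecord] = []
    coding = [g for g in genome.genes if g.coding]
    by_chrom: dict[str, list] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.tss)
        for a, b in zip(genes, genes[1:]):
            if (a.strand, b.strand) == ("+", "-"):
                orient = "convergent"
            elif (a.strand, b.strand) == ("-", "+"):
                orient = "divergent"
            else:
                orient = "tandem"
            overlap = a.cds_start <= b.cds_end and b.cds_start <= a.cds_end
            suffix = "overlapping" if overlap else "non_overlapping"
            out.append(GenePairRecord(a.gene_id, b.gene_id, f"{orient}_{suffix}"))
    return out


def _category_counts(
    picked: set[str], pairs: list[GenePairRecord]
) -> pd.Series:
    """Gene-incidence counts: each picked gene adds 1 to the category of
    every adjacent pair containing it."""
    counts = pd.Series(0, index=PAIR_CATEGORIES, dtype=int)
    for p in pairs:
        counts[p.category] += (p.gene_a in picked) + (p.gene_b in picked)
    return counts


def pair_enrichment(
    targets: list[str],
    pairs: list[GenePairRecord],
    universe: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of gene-pair-category enrichment among targets.

    Draws ``n_perm`` random target sets of the same size from the trait
    universe, counts picked gene pairs per category, and reports plus-one
    empirical p-values for enrichment and depletion of the observed counts.
    """
    if not targets:
        raise ValueError("target set is empty")
    rng = substream(seed, "pair-enrichment")
    universe = list(universe)
    m = len(targets)
    observed = _category_counts(set(targets), pairs)

    # incidence matrix: gene x category membership counts
    gene_idx = {g: i for i, g in enumerate(universe)}
    cat_idx = {c: i for i, c in enumerate(PAIR_CATEGORIES)}
    inc = np.zeros((len(universe), len(PAIR_CATEGORIES)), dtype=np.int64)
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g in gene_idx:
                inc[gene_idx[g], cat_idx[p.category]] += 1

    null = np.empty((n_perm, len(PAIR_CATEGORIES)), dtype=np.int64)
    for k in range(n_perm):
        pick = rng.choice(len(universe), size=m, replace=False)
        null[k] = inc[pick].sum(axis=0)

    obs = observed.to_numpy()
    p_enrich = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    p_deplete = (1 + (null <= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    return pd.DataFrame(
        {
            "category": PAIR_CATEGORIES,
            "observed": obs,
            "null_mean": null.mean(axis=0),
            "p_enrichment": p_enrich,
            "p_depletion": p_deplete,
        }
    )
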