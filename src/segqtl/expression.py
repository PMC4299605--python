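"""Strain-specific annotation liftover, strand-specific counting, normalization.

Quantifying expression in a recombinant library against one reference genome
treats real sequence differences as mismatches and under-counts polymorphic
genes; the remedy is to count against strain-specific genomes.  Indels shift
coordinates, so annotations must be lifted over per strain.  Counting is
CDS-based and strand-specific: a read's midpoint assigns it to the CDS
containing it, same-strand reads are sense, opposite-strand reads antisense.

Normalization: genes unexpressed in more than half of the samples are
dropped; remaining zeros become 0.1 (sense) or missing (antisense); samples
are scaled to their total mapped reads; values are log2-transformed and
batch effects removed by per-gene per-batch mean-centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomeModel

__all__ = [
    "StrainGenome",
    "personalize_genome",
    "quantify",
    "normalize_sense",
    "normalize_antisense",
]


# ---------------------------------------------------------------------------
# strain-specific genomes
# ---------------------------------------------------------------------------

@dataclass
class StrainGenome:
    """Coordinate liftover and lifted annotation for one strain.

    The liftover is monotone within a chromosome and round-trips exactly for
    any position not inside a deleted segment.
    """

    strain_id: str
    reference: GenomeModel
    # per chromosome: anchor position, span of removed ref bases, length delta
    events: dict[str, pd.DataFrame] = field(default_factory=dict)
    genes: list[GeneAnnotation] = field(default_factory=list)
    n_clamped: int = 0

    def lift(self, chrom: str, pos) -> np.ndarray:
        """Reference position -> strain position (deleted bases clamp left)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        ev = self.events.get(chrom)
        if ev is None or not len(ev):
            return pos.copy()
        anchors = ev["pos"].to_numpy()
        spans = ev["ref_span"].to_numpy()  # ref bases consumed after anchor
        deltas = ev["delta"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(deltas)])
        # number of events whose anchor lies strictly before pos
        i = np.searchsorted(anchors, pos, side="left")
        out = pos + cum[i]
        # positions inside a deleted segment clamp to the anchor
        inside = (i > 0) & (pos <= np.where(i > 0, anchors[i - 1] + spans[np.maximum(i - 1, 0)], -1))
        if inside.any():
            j = i[inside] - 1
            out[inside] = anchors[j] + cum[j]
        return out

    def inverse(self, chrom: str, pos) -> np.ndarray:
        """Strain position -> reference position (inserted bases clamp left)."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        ev = self.events.get(chrom)
        if ev is None or not len(ev):
            return pos.copy()
        anchors = ev["pos"].to_numpy()
        deltas = ev["delta"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(deltas)])
        lifted_anchors = anchors + cum[:-1]
        # span consumed in strain coordinates: inserted bases for insertions
        strain_spans = np.where(deltas > 0, deltas, 0)
        i = np.searchsorted(lifted_anchors, pos, side="left")
        out = pos - cum[i]
        inside = (i > 0) & (
            pos <= np.where(i > 0, lifted_anchors[i - 1] + strain_spans[np.maximum(i - 1, 0)], -1)
        )
        if inside.any():
            j = i[inside] - 1
            out[inside] = anchors[j]
        return out

    def genes_frame(self) -> pd.DataFrame:
        return GenomeModel(
            self.reference.chromosomes, [], [], None
        ).genes_frame() if not self.genes else pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "cds_start": [g.cds_start for g in self.genes],
                "cds_end": [g.cds_end for g in self.genes],
                "coding": [g.coding for g in self.genes],
            }
        )


def personalize_genome(
    reference: GenomeModel, strain_alleles: np.ndarray, strain_id: str = "strain"
) -> StrainGenome:
    """Build the strain coordinate frame and lifted annotation.

    ``strain_alleles`` holds 0 (ref) / 1 (alt) per reference variant.  Only
    indels carried by the strain create liftover events: insertions add
    bases after their anchor, deletions remove the bases following theirs.
    SNPs change sequence only.  An annotation boundary falling inside a
    deleted segment is clamped to the deletion edge (counted in
    ``n_clamped``).
    """
    strain_alleles = np.asarray(strain_alleles)
    events: dict[str, list] = {}
    for v, allele in zip(reference.variants, strain_alleles):
        if allele != 1 or v.delta == 0:
            continue
        span = -v.delta if v.delta < 0 else 0
        events.setdefault(v.chrom, []).append((v.pos, span, v.delta))
    frames = {
        c: pd.DataFrame(rows, columns=["pos", "ref_span", "delta"])
        for c, rows in events.items()
    }
    sg = StrainGenome(strain_id, reference, frames)

    n_clamped = 0
    lifted = []
    for g in reference.genes:
        s, e, t = (
            int(sg.lift(g.chrom, g.cds_start)[0]),
            int(sg.lift(g.chrom, g.cds_end)[0]),
            int(sg.lift(g.chrom, g.tss)[0]),
        )
        back_s = int(sg.inverse(g.chrom, s)[0])
        back_e = int(sg.inverse(g.chrom, e)[0])
        if back_s != g.cds_start or back_e != g.cds_end:
            n_clamped += 1
        lifted.append(
            GeneAnnotation(g.gene_id, g.chrom, g.strand, t, s, max(s, e), g.coding)
        )
    if n_clamped:
        warnings.warn(f"{strain_id}: {n_clamped} annotation boundaries clamped "
                      "to deletion edges")
    sg.genes = lifted
    sg.n_clamped = n_clamped
    return sg


# ---------------------------------------------------------------------------
# strand-specific quantification
# ---------------------------------------------------------------------------

def quantify(
    reads: pd.DataFrame,
    annotation: list[GeneAnnotation] | pd.DataFrame,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count reads per gene, strand-specifically, by CDS midpoint assignment.

    A read increments exactly one gene per strand orientation: the CDS
    containing the read midpoint.  Same-strand reads add to the sense
    count, opposite-strand reads to the antisense count; midpoints outside
    every CDS are uncounted.  Reads and annotation must share a coordinate
    frame.
    """
    if isinstance(annotation, pd.DataFrame):
        ann = annotation
    else:
        ann = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in annotation],
                "chrom": [g.chrom for g in annotation],
                "strand": [g.strand for g in annotation],
                "cds_start": [g.cds_start for g in annotation],
                "cds_end": [g.cds_end for g in annotation],
            }
        )
    dup = ann.duplicated(subset=["chrom", "cds_start", "cds_end", "strand"])
    if dup.any():
        raise ValueError("annotation contains genes with identical coordinates "
                         "and strand")
    gene_ids = list(ann["gene_id"])
    if samples is None:
        samples = sorted(reads["sample_id"].unique())
    sense = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=np.int64)
    anti = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=np.int64)
    if not len(reads):
        return sense, anti

    mid = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2)
    rchrom = reads["chrom"].to_numpy()
    rstrand = reads["strand"].to_numpy()
    rsample = reads["sample_id"].to_numpy()

    for _, g in ann.iterrows():
        in_cds = (
            (rchrom == g["chrom"]) & (mid >= g["cds_start"]) & (mid <= g["cds_end"])
        )
        if not in_cds.any():
            continue
        same = rstrand[in_cds] == g["strand"]
        samp = rsample[in_cds]
        s_counts = pd.Series(samp[same]).value_counts()
        a_counts = pd.Series(samp[~same]).value_counts()
        for smp, c in s_counts.items():
            sense.at[g["gene_id"], smp] += int(c)
        for smp, c in a_counts.items():
            anti.at[g["gene_id"], smp] += int(c)
    return sense, anti


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _scale_factors(counts: pd.DataFrame,
                   totals: pd.Series | None = None) -> pd.Series:
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.astype(float).reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        bad = totals.index[(totals <= 0) | totals.isna()].tolist()
        raise ValueError(f"samples with zero mapped reads: {bad}")
    return totals.mean() / totals


def _batch_center(
    log_values: pd.DataFrame,
    batches: pd.Series,
    excluded_samples,
) -> pd.DataFrame:
    """Per-gene per-batch mean subtraction; batch means computed excluding
    ``excluded_samples`` but the subtraction is applied to every sample."""
    out = log_values.copy()
    excluded = set(excluded_samples)
    for batch in batches.unique():
        members = [s for s in log_values.columns if batches[s] == batch]
        ref = [s for s in members if s not in excluded] or members
        means = log_values[ref].mean(axis=1, skipna=True)
        out[members] = log_values[members].sub(means, axis=0)
    return out


def normalize_sense(
    counts: pd.DataFrame,
    batches: pd.Series | None = None,
    excluded_samples=(),
    zero_floor: float = 0.1,
    center_before_log: bool = False,
    totals: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """The sense normalization chain.

    (1) drop genes with zero counts in more than half of the samples;
    (2) replace remaining zeros by ``zero_floor``; (3) scale each sample by
    mean(t)/t_i where t_i is its total mapped reads; (4) log2-transform;
    (5) remove batch effects by per-gene per-batch mean-centering, with
    batch means computed excluding ``excluded_samples`` (e.g. deletion-
    strain samples) but applied to all.  Returns the normalized matrix and
    the dropped gene list.  ``center_before_log`` applies the centering on
    the scaled natural-scale values instead (the literal ordering; may
    produce negatives that become NaN under log2).
    """
    if batches is None:
        batches = pd.Series("b0", index=counts.columns)
    sf = _scale_factors(counts, totals)
    zero_frac = (counts == 0).mean(axis=1)
    dropped = list(counts.index[zero_frac > 0.5])
    kept = counts.drop(index=dropped).astype(float)
    kept = kept.where(kept != 0, zero_floor)
    scaled = kept.mul(sf, axis=1)
    if center_before_log:
        centered = _batch_center(scaled, batches, excluded_samples)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.log2(centered.where(centered > 0))
    else:
        out = _batch_center(np.log2(scaled), batches, excluded_samples)
    return out, dropped


def normalize_antisense(
    counts: pd.DataFrame,
    batches: pd.Series | None = None,
    excluded_samples=(),
    center_before_log: bool = False,
    totals: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Antisense normalization: zeros are missing, not floored.

    Same chain as :func:`normalize_sense` except zero counts become missing
    values before scaling (antisense coverage is sparse) and batch centering
    uses available values only.  ``totals`` should carry each sample's total
    mapped reads (usually the sense totals); by default the antisense column
    sums are used.  Gene/batch cells with fewer than two available values
    are centered against whatever is available and reported in the third
    return value.
    """
    if batches is None:
        batches = pd.Series("b0", index=counts.columns)
    sf = _scale_factors(counts, totals)
    zero_frac = (counts == 0).mean(axis=1)
    dropped = list(counts.index[zero_frac > 0.5])
    kept = counts.drop(index=dropped).astype(float)
    kept = kept.where(kept != 0)  # zeros -> NaN
    scaled = kept.mul(sf, axis=1)
    logv = scaled if center_before_log else np.log2(scaled)
    centered = _batch_center(logv, batches, excluded_samples)
    if center_before_log:
        with np.errstate(invalid="ignore", divide="ignore"):
            centered = np.log2(centered.where(centered > 0))

    sparse_rows = []
    for batch in batches.unique():
        members = [s for s in counts.columns if batches[s] == batch]
        n_avail = kept[members].notna().sum(axis=1)
        for gene in kept.index[n_avail < 2]:
            sparse_rows.append({"gene_id": gene, "batch": batch,
                                "n_available": int(n_avail[gene])})
    report = pd.DataFrame(sparse_rows, columns=["gene_id", "batch", "n_available"])
    return centered, dropped, report
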