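"""Genome, annotation and variant containers shared by every pipeline stage.

All coordinates are 1-based inclusive (VCF/GFF convention); BED writers
convert to 0-based half-open on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "VariantSite",
    "GenomeModel",
    "Inversion",
]

#: parental-origin codes used throughout the package
P1, P2, UNKNOWN = 0, 1, -1


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its transcription start site and CDS interval.

    ``tss`` lies upstream of the CDS start on the + strand and downstream of
    the CDS end on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int
    cds_start: int
    cds_end: int
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.gene_id}: CDS start > end")
        if self.strand == "+" and self.tss > self.cds_start:
            raise ValueError(f"{self.gene_id}: TSS downstream of CDS start on + strand")
        if self.strand == "-" and self.tss < self.cds_end:
            raise ValueError(f"{self.gene_id}: TSS upstream of CDS end on - strand")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class VariantSite:
    """A biallelic polymorphism between the two parents.

    ``delta`` is the length change of the alt allele relative to ref:
    0 for SNPs, positive for insertions, negative for deletions.
    ``p1_is_ref`` records which parent carries the reference allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # "SNP" | "insertion" | "deletion"
    delta: int = 0
    p1_is_ref: bool = True

    def __post_init__(self) -> None:
        if self.vtype == "SNP" and self.delta != 0:
            raise ValueError("SNP must have delta 0")
        if self.vtype == "insertion" and self.delta <= 0:
            raise ValueError("insertion must have delta > 0")
        if self.vtype == "deletion" and self.delta >= 0:
            raise ValueError("deletion must have delta < 0")


@dataclass(frozen=True)
class Inversion:
    """A recombination-suppressed interval (e.g. a pericentric inversion)."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom: str, pos) -> np.ndarray | bool:
        return (chrom == self.chrom) & (np.asarray(pos) >= self.start) & (
            np.asarray(pos) <= self.end
        )


@dataclass
class GenomeModel:
    """Chromosomes, gene annotations and variant sites in one coordinate frame."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneAnnotation] = field(default_factory=list)
    variants: list[VariantSite] = field(default_factory=list)
    inversion: Inversion | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_id values must be unique")
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.cds_start < 1 or g.cds_end > lengths[g.chrom]:
                raise ValueError(f"{g.gene_id}: CDS outside chromosome bounds")
        seen: dict[str, int] = {}
        for v in self.variants:
            if v.chrom not in lengths:
                raise ValueError(f"variant at {v.chrom}:{v.pos}: unknown chromosome")
            if v.chrom in seen and v.pos <= seen[v.chrom]:
                raise ValueError(
                    f"variant positions must be strictly increasing within "
                    f"{v.chrom} (at {v.pos})"
                )
            seen[v.chrom] = v.pos

    # -- tabular views --------------------------------------------------
    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
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

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "vtype": [v.vtype for v in self.variants],
                "delta": [v.delta for v in self.variants],
                "p1_is_ref": [v.p1_is_ref for v in self.variants],
            }
        )

    def chrom_length(self, name: str) -> int:
        return dict(self.chromosomes)[name]

    def variant_gene_index(self) -> np.ndarray:
        """Index of the gene whose CDS hosts each variant (-1 if intergenic).

        With overlapping genes the first (leftmost CDS start) wins; a variant
        is only ever expressed through its host transcript.
        """
        out = np.full(len(self.variants), -1, dtype=int)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for gi, g in enumerate(self.genes):
            by_chrom.setdefault(g.chrom, []).append((g.cds_start, g.cds_end, gi))
        for c in by_chrom:
            by_chrom[c].sort()
        for vi, v in enumerate(self.variants):
            for s, e, gi in by_chrom.get(v.chrom, ()):
                if s <= v.pos <= e:
                    out[vi] = gi
                    break
                if s > v.pos:
                    break
        return out
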