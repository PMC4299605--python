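"""Readers and writers for the package's on-disk formats.

Genome models round-trip through GFF3 (genes/CDS) + VCF (variants); read
placements go to BED6; genotype, count and linkage tables are plain TSV.
Internal coordinates are 1-based inclusive; BED output is 0-based
half-open.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomeModel, Inversion, VariantSite
from .genotyping import GenotypeCallMatrix, InheritanceMatrix, MarkerMap

__all__ = [
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "read_vcf_variants",
    "write_fasta",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_reads_bed",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_markers_tsv",
    "write_breakpoints_bed",
]

_INH_LABEL = {0: "P1", 1: "P2", -1: "unknown"}
_INH_CODE = {v: k for k, v in _INH_LABEL.items()}


# ---------------------------------------------------------------------------
# annotation / variants / sequence
# ---------------------------------------------------------------------------

def write_gff3(genome: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        if genome.inversion is not None:
            inv = genome.inversion
            fh.write(
                f"{inv.chrom}\tsegqtl\tinverted_repeat\t{inv.start}\t{inv.end}"
                f"\t.\t+\t.\tID=inversion\n"
            )
        for g in genome.genes:
            biotype = "protein_coding" if g.coding else "ncRNA"
            gene_start = min(g.tss, g.cds_start)
            gene_end = max(g.tss, g.cds_end)
            fh.write(
                f"{g.chrom}\tsegqtl\tgene\t{gene_start}\t{gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={biotype};tss={g.tss}\n"
            )
            fh.write(
                f"{g.chrom}\tsegqtl\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tParent={g.gene_id}\n"
            )


def read_gff3(path: str) -> GenomeModel:
    import gffutils

    chromosomes: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _, length = line.split()
                chromosomes.append((chrom, int(length)))
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    inversion = None
    gene_meta: dict[str, dict] = {}
    cds: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        if feat.featuretype == "inverted_repeat":
            inversion = Inversion(feat.seqid, feat.start, feat.end)
        elif feat.featuretype == "gene":
            gene_meta[feat.attributes["ID"][0]] = {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "tss": int(feat.attributes["tss"][0]),
                "coding": feat.attributes.get("biotype",
                                              ["protein_coding"])[0]
                == "protein_coding",
            }
        elif feat.featuretype == "CDS":
            cds[feat.attributes["Parent"][0]] = (feat.start, feat.end)
    genes = [
        GeneAnnotation(
            gid, m["chrom"], m["strand"], m["tss"], cds[gid][0], cds[gid][1],
            m["coding"],
        )
        for gid, m in gene_meta.items()
    ]
    return GenomeModel(chromosomes, genes, [], inversion)


def write_vcf(genome: GenomeModel, path: str,
              sample_alleles: dict[str, np.ndarray] | None = None) -> None:
    """Write the parental variant table (plus optional per-sample GT columns)."""
    samples = list(sample_alleles) if sample_alleles else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            cols += "\tFORMAT\t" + "\t".join(samples)
        fh.write(cols + "\n")
        for vi, v in enumerate(genome.variants):
            row = (
                f"{v.chrom}\t{v.pos}\tv{vi:04d}\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"TYPE={v.vtype}"
            )
            if samples:
                gts = "\t".join(
                    str(int(sample_alleles[s][vi])) for s in samples
                )
                row += "\tGT\t" + gts
            fh.write(row + "\n")


def read_vcf_variants(path: str) -> list[VariantSite]:
    from cyvcf2 import VCF

    out: list[VariantSite] = []
    for rec in VCF(path):
        alt = rec.ALT[0]
        delta = len(alt) - len(rec.REF)
        vtype = ("SNP" if delta == 0
                 else "insertion" if delta > 0 else "deletion")
        out.append(VariantSite(rec.CHROM, rec.POS, rec.REF, alt, vtype, delta))
    return out


def write_fasta(genome: GenomeModel, path: str, seed: int = 0,
                line_width: int = 70) -> None:
    """Realize a random sequence consistent with the variant ref alleles."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes:
            seq = rng.choice(bases, size=length)
            for v in genome.variants:
                if v.chrom == chrom and v.pos + len(v.ref) - 1 <= length:
                    seq[v.pos - 1: v.pos - 1 + len(v.ref)] = list(v.ref)
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(s[i: i + line_width] + "\n")


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def write_genotypes_tsv(inh: InheritanceMatrix, path: str) -> None:
    """Strains x sites parental-origin table (P1/P2/unknown)."""
    labels = pd.DataFrame(
        np.vectorize(_INH_LABEL.get)(inh.matrix),
        index=pd.Index(inh.strains, name="strain"),
        columns=[f"{c}:{p}" for c, p in
                 zip(inh.sites["chrom"], inh.sites["pos"])],
    )
    labels.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str) -> InheritanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chroms, positions = zip(*(c.rsplit(":", 1) for c in df.columns))
    sites = pd.DataFrame({"chrom": chroms, "pos": [int(p) for p in positions]})
    matrix = np.vectorize(_INH_CODE.get)(df.to_numpy()).astype(np.int8)
    return InheritanceMatrix(list(df.index), sites, matrix)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_reads_bed(reads: pd.DataFrame, path: str) -> None:
    """BED6: 0-based half-open intervals, one line per placement."""
    bed = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"] - 1,
            "end": reads["end"],
            "name": reads["sample_id"].astype(str) + ":" + reads["gene_id"],
            "score": reads["n_errors"],
            "strand": reads["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_calls_tsv(calls: GenotypeCallMatrix, path: str) -> None:
    """Long-format variant calls: strain, chrom, pos, allele, quality."""
    code = {0: "ref", 1: "alt", 2: "het", -1: "missing"}
    rows = []
    for si, strain in enumerate(calls.strains):
        for vi in range(len(calls.sites)):
            a = int(calls.alleles[si, vi])
            if a == GenotypeCallMatrix.MISSING:
                continue
            rows.append(
                {
                    "strain": strain,
                    "chrom": calls.sites["chrom"].iloc[vi],
                    "pos": int(calls.sites["pos"].iloc[vi]),
                    "allele": code[a],
                    "quality": float(calls.quality[si, vi]),
                }
            )
    pd.DataFrame(rows, columns=["strain", "chrom", "pos", "allele", "quality"]
                 ).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str, sites: pd.DataFrame,
                   strains: list[str]) -> GenotypeCallMatrix:
    """Rebuild a call matrix from the long format given the site table."""
    code = {"ref": 0, "alt": 1, "het": 2}
    df = pd.read_csv(path, sep="\t")
    site_idx = {
        (c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))
    }
    strain_idx = {s: i for i, s in enumerate(strains)}
    alleles = np.full((len(strains), len(sites)), GenotypeCallMatrix.MISSING,
                      dtype=np.int8)
    quality = np.zeros((len(strains), len(sites)))
    for row in df.itertuples(index=False):
        si = strain_idx[row.strain]
        vi = site_idx[(row.chrom, row.pos)]
        alleles[si, vi] = code[row.allele]
        quality[si, vi] = row.quality
    return GenotypeCallMatrix(strains, sites, alleles, quality)


def write_markers_tsv(markers: MarkerMap, path: str) -> None:
    meta = markers.markers.copy()
    labels = pd.DataFrame(
        np.vectorize(_INH_LABEL.get)(markers.matrix.T),
        columns=markers.strains,
    )
    pd.concat([meta, labels], axis=1).to_csv(path, sep="\t", index=False)


def write_breakpoints_bed(breakpoints, path: str) -> None:
    table = breakpoints.table
    bed = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["left_pos"] - 1,
            "end": table["right_pos"],
            "name": table["strain"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
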