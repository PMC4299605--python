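"""Genotyping recombinant segregants from expressed-variant calls.

Segregants of a two-parent haploid cross can be genotyped directly from
RNA-seq: variants called at sites polymorphic between the parents reveal the
inherited allele wherever the host gene is expressed.  Sites in silent genes
stay uncalled, but meiotic recombination leaves large haplotype blocks, so
missing genotypes can be imputed from agreeing flanking sites, and fully
linked adjacent sites collapse into unique mapping markers.

The steps implemented here: infer parental origin from calls (quality and
heterozygosity filters), discard suspect sites, correct isolated discordant
calls, impute missing genotypes within 50-kb agreeing blocks, and build the
marker map used as QTL predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import P1, P2, UNKNOWN

__all__ = [
    "GenotypeCallMatrix",
    "InheritanceMatrix",
    "MarkerMap",
    "BreakpointSet",
    "infer_inheritance",
    "filter_sites",
    "correct_isolated_discordant",
    "impute_missing",
    "build_markers",
    "detect_breakpoints",
    "check_replicates",
]


@dataclass
class GenotypeCallMatrix:
    """Per-strain allele calls with qualities at parental polymorphic sites.

    ``alleles`` is strains x sites with codes REF (0), ALT (1), HET (2),
    MISSING (-1); ``sites`` carries chrom/pos and which parent is ref.
    """

    REF, ALT, HET, MISSING = 0, 1, 2, -1

    strains: list[str]
    sites: pd.DataFrame  # chrom, pos, ref, alt, p1_is_ref
    alleles: np.ndarray  # int8
    quality: np.ndarray  # float

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.alleles.shape != (len(self.strains), len(self.sites)):
            raise ValueError("alleles shape must be strains x sites")
        if self.quality.shape != self.alleles.shape:
            raise ValueError("quality shape must match alleles")
        if (self.quality < 0).any():
            raise ValueError("quality must be >= 0")


@dataclass
class InheritanceMatrix:
    """Parental origin (P1/P2/unknown) per strain per polymorphic site."""

    strains: list[str]
    sites: pd.DataFrame  # chrom, pos (sorted within chrom), index-aligned
    matrix: np.ndarray  # int8, strains x sites, values in {P1, P2, UNKNOWN}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        bad = ~np.isin(self.matrix, [P1, P2, UNKNOWN])
        if bad.any():
            raise ValueError("inheritance values must be P1, P2 or unknown")

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def called_fraction(self) -> float:
        return float((self.matrix != UNKNOWN).mean())

    def copy(self) -> "InheritanceMatrix":
        return InheritanceMatrix(
            list(self.strains), self.sites.copy(), self.matrix.copy()
        )

    def chrom_blocks(self):
        """Yield (chrom, column indices) per chromosome, in site order."""
        chroms = self.sites["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            yield chrom, np.flatnonzero(chroms == chrom)


@dataclass
class MarkerMap:
    """Unique mapping markers: runs of adjacent fully linked sites.

    Member sites of one marker share an identical segregation vector over
    the whole strain panel (unknowns included); adjacent markers differ.
    """

    strains: list[str]
    markers: pd.DataFrame  # marker_id, chrom, start, end, n_sites
    matrix: np.ndarray  # int8, strains x markers
    member_positions: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class BreakpointSet:
    """Recombination breakpoints per strain, as flanking-site intervals."""

    table: pd.DataFrame  # strain, chrom, left_pos, right_pos

    @property
    def total(self) -> int:
        return len(self.table)

    def per_strain(self) -> pd.Series:
        return self.table.groupby("strain").size()


# ---------------------------------------------------------------------------
# Step 2: inferring parental origin
# ---------------------------------------------------------------------------

def infer_inheritance(
    calls: GenotypeCallMatrix, min_quality: float = 20.0
) -> InheritanceMatrix:
    """Map called alleles to the parent carrying them.

    Heterozygous calls (impossible in haploids, hence ambiguous) and calls
    with genotype quality below ``min_quality`` become unknown.
    """
    p1_is_ref = calls.sites["p1_is_ref"].to_numpy()
    a = calls.alleles
    out = np.full(a.shape, UNKNOWN, dtype=np.int8)

    ref_parent = np.where(p1_is_ref, P1, P2).astype(np.int8)
    alt_parent = np.where(p1_is_ref, P2, P1).astype(np.int8)
    out[a == GenotypeCallMatrix.REF] = np.broadcast_to(ref_parent, a.shape)[
        a == GenotypeCallMatrix.REF
    ]
    out[a == GenotypeCallMatrix.ALT] = np.broadcast_to(alt_parent, a.shape)[
        a == GenotypeCallMatrix.ALT
    ]
    # HET, MISSING and any unexpected code stay unknown
    out[calls.quality < min_quality] = UNKNOWN
    return InheritanceMatrix(
        list(calls.strains), calls.sites[["chrom", "pos"]].copy(), out
    )


# ---------------------------------------------------------------------------
# Step 3: site filtering and isolated-discordance correction
# ---------------------------------------------------------------------------

def filter_sites(
    inh: InheritanceMatrix,
    parental_check: np.ndarray,
    maf_min: float = 0.10,
    rule: str = "and",
) -> tuple[InheritanceMatrix, pd.DataFrame]:
    """Discard suspect sites.

    The default reading discards a site iff it fails the parental check
    *and* its minor allele frequency (over called strains) is below
    ``maf_min``; ``rule="or"`` switches to the disjunctive reading.  Sites
    with no called strain are always discarded and reported separately.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    parental_check = np.asarray(parental_check, dtype=bool)
    called = inh.matrix != UNKNOWN
    n_called = called.sum(axis=0)
    n_p2 = ((inh.matrix == P2) & called).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(n_called > 0, n_p2 / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(f, 1 - f)

    all_unknown = n_called == 0
    fail_parent = ~parental_check
    low_maf = maf < maf_min
    if rule == "and":
        discard = fail_parent & low_maf
    else:
        discard = fail_parent | low_maf
    discard = discard | all_unknown

    report = inh.sites.loc[discard, ["chrom", "pos"]].copy()
    report["maf"] = maf[discard]
    report["parental_ok"] = parental_check[discard]
    report["reason"] = np.where(
        all_unknown[discard], "all_unknown", "parental_and_maf" if rule == "and"
        else "parental_or_maf"
    )
    keep = ~discard
    kept = InheritanceMatrix(
        list(inh.strains),
        inh.sites.loc[keep].reset_index(drop=True),
        inh.matrix[:, keep],
    )
    return kept, report.reset_index(drop=True)


def correct_isolated_discordant(
    inh: InheritanceMatrix, max_flank_distance: int = 50_000
) -> tuple[InheritanceMatrix, int]:
    """Overwrite single calls disagreeing with both close flanking calls.

    A called site whose two nearest called neighbours (same strain, same
    chromosome) agree with each other, disagree with it, and lie less than
    ``max_flank_distance`` apart is treated as a genotyping error and
    rewritten to the flanking label.  One left-to-right pass; corrections
    become visible to later sites but no re-scan is performed.
    """
    out = inh.copy()
    n_corrected = 0
    for _, cols in out.chrom_blocks():
        pos = out.positions[cols]
        for si in range(len(out.strains)):
            row = out.matrix[si, cols]
            called = np.flatnonzero(row != UNKNOWN)
            for j in range(1, len(called) - 1):
                a, b, c = called[j - 1], called[j], called[j + 1]
                if (
                    row[a] == row[c]
                    and row[b] != row[a]
                    and pos[c] - pos[a] < max_flank_distance
                ):
                    row[b] = row[a]
                    n_corrected += 1
            out.matrix[si, cols] = row
    return out, n_corrected


# ---------------------------------------------------------------------------
# Step 4: imputation within haplotype blocks
# ---------------------------------------------------------------------------

def impute_missing(
    inh: InheritanceMatrix,
    max_flank_distance: int = 50_000,
    fill_runs: bool = True,
) -> InheritanceMatrix:
    """Fill unknown genotypes from agreeing flanking calls within 50 kb.

    An unknown entry takes the shared label of its nearest called flanks iff
    both exist on the same chromosome, agree, and are less than
    ``max_flank_distance`` apart (assuming no recombination between them).
    Disagreeing or distant flanks leave the entry unknown; called entries are
    never touched.  ``fill_runs=False`` restricts the rule to isolated
    single unknowns.
    """
    out = inh.copy()
    for _, cols in out.chrom_blocks():
        pos = out.positions[cols]
        for si in range(len(out.strains)):
            row = out.matrix[si, cols]
            called = np.flatnonzero(row != UNKNOWN)
            if len(called) < 2:
                continue
            unknown = np.flatnonzero(row == UNKNOWN)
            if not len(unknown):
                continue
            right_i = np.searchsorted(called, unknown)
            interior = (right_i > 0) & (right_i < len(called))
            for u, ri in zip(unknown[interior], right_i[interior]):
                left, right = called[ri - 1], called[ri]
                if not fill_runs and right - left != 2:
                    continue
                if (
                    row[left] == row[right]
                    and pos[right] - pos[left] < max_flank_distance
                ):
                    row[u] = row[left]
            out.matrix[si, cols] = row
    return out


# ---------------------------------------------------------------------------
# Step 5: marker assembly
# ---------------------------------------------------------------------------

def build_markers(
    inh: InheritanceMatrix, min_called_fraction: float = 0.5
) -> MarkerMap:
    """Collapse adjacent fully linked sites into unique mapping markers.

    Sites called in fewer than ``min_called_fraction`` of strains are
    discarded; maximal runs of adjacent sites with identical segregation
    vectors (the unknown pattern must match too) become one marker spanning
    their positions.
    """
    called_frac = (inh.matrix != UNKNOWN).mean(axis=0)
    keep = called_frac >= min_called_fraction
    sites = inh.sites.loc[keep].reset_index(drop=True)
    mat = inh.matrix[:, keep]

    marker_rows = []
    columns = []
    members: list[list[int]] = []
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    i = 0
    while i < len(sites):
        j = i + 1
        while (
            j < len(sites)
            and chroms[j] == chroms[i]
            and np.array_equal(mat[:, j], mat[:, i])
        ):
            j += 1
        marker_rows.append(
            {
                "marker_id": f"m{len(marker_rows):04d}",
                "chrom": chroms[i],
                "start": int(positions[i]),
                "end": int(positions[j - 1]),
                "n_sites": j - i,
            }
        )
        columns.append(mat[:, i])
        members.append([int(p) for p in positions[i:j]])
        i = j
    matrix = (
        np.stack(columns, axis=1) if columns
        else np.empty((len(inh.strains), 0), dtype=np.int8)
    )
    return MarkerMap(
        list(inh.strains), pd.DataFrame(marker_rows), matrix, members
    )


# ---------------------------------------------------------------------------
# breakpoints and replicate checks
# ---------------------------------------------------------------------------

def detect_breakpoints(data: InheritanceMatrix | MarkerMap) -> BreakpointSet:
    """One breakpoint per adjacent pair of called sites with opposite labels."""
    if isinstance(data, MarkerMap):
        sites = data.markers.rename(columns={"start": "pos"})[["chrom", "pos"]]
        inh = InheritanceMatrix(list(data.strains), sites.copy(), data.matrix)
    else:
        inh = data
    rows = []
    for chrom, cols in inh.chrom_blocks():
        pos = inh.positions[cols]
        for si, strain in enumerate(inh.strains):
            row = inh.matrix[si, cols]
            called = np.flatnonzero(row != UNKNOWN)
            lab = row[called]
            switches = np.flatnonzero(lab[1:] != lab[:-1])
            for k in switches:
                rows.append(
                    {
                        "strain": strain,
                        "chrom": chrom,
                        "left_pos": int(pos[called[k]]),
                        "right_pos": int(pos[called[k + 1]]),
                    }
                )
    cols = ["strain", "chrom", "left_pos", "right_pos"]
    return BreakpointSet(pd.DataFrame(rows, columns=cols))


def check_replicates(
    replicate_rows: list[np.ndarray], concordance_min: float = 0.9
) -> tuple[bool, pd.DataFrame]:
    """Flag probable sample swaps from replicate genotype concordance.

    Each element of ``replicate_rows`` is one replicate's inheritance vector
    over the same sites.  All pairwise concordances over co-called sites are
    computed; any pair below ``concordance_min`` (or with no co-called
    sites) flags the strain for removal.
    """
    if len(replicate_rows) < 2:
        raise ValueError("need at least two replicates")
    rows = [np.asarray(r, dtype=np.int8) for r in replicate_rows]
    records = []
    ok = True
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            co = (rows[i] != UNKNOWN) & (rows[j] != UNKNOWN)
            n_co = int(co.sum())
            if n_co == 0:
                conc = np.nan
                ok = False
            else:
                conc = float((rows[i][co] == rows[j][co]).mean())
                if conc < concordance_min:
                    ok = False
            records.append({"rep_a": i, "rep_b": j, "n_co_called": n_co,
                            "concordance": conc})
    return ok, pd.DataFrame(records)
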