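"""Random-Forest QTL mapping with permutation-based significance.

Traits (normalized sense/antisense expression, growth parameters) are mapped
to genotypic markers with regression forests.  The engine handles the two
complications of RNA-seq-derived genotypes:

* missing marker genotypes — instead of treating "missing" as a third
  allele (which biases split choices), each missing entry is randomly
  re-assigned one of the two parental alleles, forests are grown for many
  such assignments, and the resulting models are combined;
* population structure — the leading eigenvectors of the strain kinship
  matrix enter the forests as additional (real-valued) covariate predictors.

A marker's linkage score is its *selection frequency*: the fraction of all
split nodes in the combined forest that split on it.  Significance comes
from a shared permutation scheme: the same strain-index shuffles are applied
to every trait (preserving inter-trait correlation), forests are regrown,
and the pooled per-marker null distribution yields empirical p-values.  The
permuted traits' own p-values give a null p-value distribution from which
false discovery rates are estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._random import child_int_seed, substream

__all__ = [
    "PredictorMatrix",
    "KinshipModel",
    "RFConfig",
    "LinkageResult",
    "QTLRegion",
    "QTLGroup",
    "kinship",
    "structure_covariates",
    "rf_selection_frequency",
    "permutation_null",
    "empirical_p_and_fdr",
    "marker_ld",
    "group_qtls",
]


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

@dataclass
class PredictorMatrix:
    """Marker genotypes plus structure covariates, aligned to strains.

    Marker entries are 0 (P1 allele), 1 (P2 allele) or NaN (missing);
    covariates are real-valued and never missing.
    """

    strains: list[str]
    marker_ids: list[str]
    markers: np.ndarray  # float, strains x markers, NaN = missing
    covariates: np.ndarray | None = None  # strains x k
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if not self.covariate_names:
                self.covariate_names = [
                    f"pc{i + 1}" for i in range(self.covariates.shape[1])
                ]

    @classmethod
    def from_marker_map(cls, marker_map, covariates=None, covariate_names=None):
        """Build from a :class:`~segqtl.genotyping.MarkerMap` (unknown -> NaN)."""
        m = marker_map.matrix.astype(float)
        m[marker_map.matrix == -1] = np.nan
        return cls(
            list(marker_map.strains),
            list(marker_map.markers["marker_id"]),
            m,
            covariates,
            covariate_names or [],
        )

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


# ---------------------------------------------------------------------------
# kinship and structure covariates
# ---------------------------------------------------------------------------

@dataclass
class KinshipModel:
    """Allele-sharing strain relatedness with its eigendecomposition."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # sorted descending
    eigenvectors: np.ndarray  # columns aligned to eigenvalues

    def variance_explained(self) -> np.ndarray:
        ev = np.clip(self.eigenvalues, 0, None)
        return np.cumsum(ev) / ev.sum()


def kinship(markers: np.ndarray) -> KinshipModel:
    """Relatedness: fraction of co-called markers with identical alleles.

    ``markers`` is strains x markers with entries 0/1 and NaN for missing;
    a strain pair with no co-called marker is an error.
    """
    m = np.asarray(markers, dtype=float)
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 strains")
    obs = ~np.isnan(m)
    filled = np.nan_to_num(m)
    # co-called counts and identical counts via matrix products
    co = obs.astype(float) @ obs.astype(float).T
    if (co == 0).any():
        raise ValueError("a strain pair shares no co-called marker")
    both_one = (filled * obs) @ (filled * obs).T
    both_zero = ((1 - filled) * obs) @ ((1 - filled) * obs).T
    k = (both_one + both_zero) / co
    np.fill_diagonal(k, 1.0)
    k = (k + k.T) / 2
    vals, vecs = np.linalg.eigh(k)
    order = np.argsort(vals)[::-1]
    return KinshipModel(k, vals[order], vecs[:, order])


def structure_covariates(
    kin: KinshipModel, variance_target: float = 0.80, fixed_k: int | None = None
) -> np.ndarray:
    """Top kinship eigenvectors used as population-structure covariates.

    Returns the smallest k whose eigenvalues explain strictly more than
    ``variance_target`` of the genotype variance, unless ``fixed_k`` pins
    the count (the study profile uses 8).
    """
    if fixed_k is not None:
        return kin.eigenvectors[:, :fixed_k]
    frac = kin.variance_explained()
    k = int(np.searchsorted(frac, variance_target, side="right")) + 1
    k = min(k, len(frac))
    return kin.eigenvectors[:, :k]


# ---------------------------------------------------------------------------
# randomized-forest selection frequency
# ---------------------------------------------------------------------------

@dataclass
class RFConfig:
    """Forest ensemble sizes for one mapping profile.

    The study-scale expression profile is 100 forests x 160 trees with
    1,000 missing-genotype re-assignments; the growth profile grows 2,000
    forests x 25 trees with 10,000 permutations.  Desk-scale defaults are
    far smaller.  Permutation nulls may use a smaller ensemble than the
    observed scan (a conservative economy: smaller null ensembles have
    heavier-tailed score distributions).
    """

    n_forests: int = 50
    trees_per_forest: int = 10
    n_missing_assignments: int = 50
    mtry: float = 1.0 / 3.0
    min_node_size: int = 5  # regression-forest leaf size (R randomForest default)
    score: str = "split_nodes"  # or "tree_presence"
    missing_fill: str = "bernoulli"  # or "frequency"

    @classmethod
    def expression_study(cls) -> "RFConfig":
        return cls(n_forests=100, trees_per_forest=160, n_missing_assignments=1000)

    @classmethod
    def growth_study(cls) -> "RFConfig":
        return cls(n_forests=2000, trees_per_forest=25, n_missing_assignments=1000)


def _fill_missing(
    markers: np.ndarray, rng: np.random.Generator, mode: str
) -> np.ndarray:
    """One random assignment of parental alleles to missing marker entries."""
    miss = np.isnan(markers)
    if not miss.any():
        return markers
    filled = markers.copy()
    if mode == "bernoulli":
        filled[miss] = rng.integers(0, 2, size=miss.sum())
    elif mode == "frequency":
        freq = np.nanmean(markers, axis=0)
        cols = np.where(miss)[1]
        filled[miss] = (rng.random(miss.sum()) < freq[cols]).astype(float)
    else:
        raise ValueError(f"unknown missing_fill {mode!r}")
    return filled


def _forest_split_counts(forest: RandomForestRegressor, p: int, score: str) -> np.ndarray:
    counts = np.zeros(p)
    for est in forest.estimators_:
        feats = est.tree_.feature
        feats = feats[feats >= 0]
        if score == "split_nodes":
            counts += np.bincount(feats, minlength=p)
        else:  # tree_presence: a predictor counts once per tree containing it
            counts[np.unique(feats)] += 1
    return counts


def rf_selection_frequency(
    trait: np.ndarray,
    predictors: PredictorMatrix,
    config: RFConfig | None = None,
    seed: int = 0,
    return_full: bool = False,
):
    """Score every marker by its selection frequency in combined forests.

    Missing marker entries get a fresh random parental-allele assignment per
    forest, cycling through ``config.n_missing_assignments`` distinct
    assignments, and the forests are combined; with no missing entries the
    assignment machinery is skipped entirely (so the result is independent
    of ``n_missing_assignments``).  Strains with a missing trait value are
    dropped for this trait.  Covariates participate as predictors but are
    excluded from the returned marker scores; selection frequencies over all
    predictors of the combined forest sum to 1.
    """
    config = config or RFConfig()
    y = np.asarray(trait, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("trait is constant over non-missing strains")
    m = predictors.markers[keep]
    all_missing = np.isnan(m).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} marker column(s) entirely missing; scored 0"
        )
    m_used = m[:, ~all_missing]
    cov = predictors.covariates[keep] if predictors.covariates is not None else None
    rng = substream(seed, "forest")

    n_fills = min(config.n_forests, max(1, config.n_missing_assignments))
    has_missing = np.isnan(m_used).any()
    fills = (
        [_fill_missing(m_used, rng, config.missing_fill) for _ in range(n_fills)]
        if has_missing
        else [m_used]
    )

    p_total = m_used.shape[1] + (0 if cov is None else cov.shape[1])
    counts = np.zeros(p_total)
    for fi in range(config.n_forests):
        x = fills[fi % len(fills)]
        if cov is not None:
            x = np.hstack([x, cov])
        forest = RandomForestRegressor(
            n_estimators=config.trees_per_forest,
            max_features=config.mtry,
            min_samples_leaf=config.min_node_size,
            random_state=child_int_seed(rng),
        )
        forest.fit(x, y)
        counts += _forest_split_counts(forest, p_total, config.score)
    total = counts.sum()
    full = counts / total if total > 0 else counts
    marker_scores = np.zeros(predictors.n_markers)
    marker_scores[~all_missing] = full[: m_used.shape[1]]
    if return_full:
        full_out = np.zeros(predictors.n_markers + predictors.n_covariates)
        full_out[: predictors.n_markers][~all_missing] = full[: m_used.shape[1]]
        full_out[predictors.n_markers:] = full[m_used.shape[1]:]
        return marker_scores, full_out
    return marker_scores


# ---------------------------------------------------------------------------
# shared permutations and empirical significance
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Selection-frequency null from shared trait permutations.

    ``scores[t, k, m]`` is the score of marker ``m`` for permutation ``k``
    of trait ``t``; the same strain-index shuffle ``k`` is used for every
    trait, and predictor rows (markers and covariates) stay fixed to
    strains.
    """

    permutations: np.ndarray  # n_perm x n_strains index arrays
    scores: np.ndarray  # n_traits x n_perm x n_markers

    def pooled(self) -> np.ndarray:
        """Per-marker null pool over all traits and permutations."""
        return self.scores.reshape(-1, self.scores.shape[2])


def _apply_shared_perm(y: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply a panel-wide shuffle to a trait, respecting its missing strains.

    The shared permutation order is restricted to the trait's non-missing
    strains: the j-th retained position receives the value of the j-th
    retained strain in the shuffled order.
    """
    keep = ~np.isnan(y)
    if keep.all():
        return y[perm]
    kept_idx = np.flatnonzero(keep)
    kept_set = keep[perm]
    order = perm[kept_set]
    out = np.full_like(y, np.nan)
    out[kept_idx] = y[order]
    return out


def permutation_null(
    traits: pd.DataFrame,
    predictors: PredictorMatrix,
    n_perm: int = 1000,
    config: RFConfig | None = None,
    seed: int = 0,
) -> PermutationNull:
    """Grow forests on permuted traits under one shared permutation scheme.

    ``traits`` is traits x strains.  The strain-index shuffles are drawn
    once and reused for every trait (so correlated traits receive identical
    permuted orderings, keeping the null faithful for hotspot counting),
    while marker and covariate rows stay attached to strains.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives unstable null tails")
    config = config or RFConfig()
    rng = substream(seed, "permutations")
    n_strains = len(predictors.strains)
    perms = np.stack([rng.permutation(n_strains) for _ in range(n_perm)])
    values = traits.to_numpy(dtype=float)
    scores = np.zeros((len(traits), n_perm, predictors.n_markers))
    for k in range(n_perm):
        for t in range(len(traits)):
            y = _apply_shared_perm(values[t], perms[k])
            scores[t, k] = rf_selection_frequency(
                y, predictors, config=config, seed=child_int_seed(rng)
            )
    return PermutationNull(perms, scores)


@dataclass
class LinkageResult:
    """Per trait-marker selection frequencies, empirical p and q values."""

    trait_ids: list[str]
    marker_ids: list[str]
    scores: pd.DataFrame  # traits x markers
    p: pd.DataFrame
    q: pd.DataFrame

    def linked(self, fdr: float = 0.10) -> pd.DataFrame:
        """Long-format significant linkages at the given FDR."""
        mask = self.q.to_numpy() <= fdr
        t_idx, m_idx = np.nonzero(mask)
        return pd.DataFrame(
            {
                "trait_id": [self.trait_ids[i] for i in t_idx],
                "marker_id": [self.marker_ids[j] for j in m_idx],
                "score": self.scores.to_numpy()[t_idx, m_idx],
                "p": self.p.to_numpy()[t_idx, m_idx],
                "q": self.q.to_numpy()[t_idx, m_idx],
            }
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for t in self.trait_ids:
            for m in self.marker_ids:
                rows.append(
                    {"trait_id": t, "marker_id": m,
                     "score": self.scores.loc[t, m],
                     "p": self.p.loc[t, m], "q": self.q.loc[t, m]}
                )
        return pd.DataFrame(rows)


def _empirical_p(values: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    """Plus-one upper-tail empirical p of ``values`` against a sorted null."""
    n = len(null_sorted)
    ge = n - np.searchsorted(null_sorted, values, side="left")
    return (1.0 + ge) / (1.0 + n)


def empirical_p_and_fdr(
    observed: pd.DataFrame,
    null: PermutationNull,
) -> LinkageResult:
    """Empirical p-values and permutation-FDR q-values for observed scores.

    p(trait, m) = (1 + #{pooled null scores at m >= observed}) / (1 + N).
    The permuted traits are then scored against the same pooled null and
    q(p0) = mean-over-permutations #{null p <= p0} / #{observed p <= p0},
    clipped to [0, 1] and monotonized.  Null values are scored with their
    own self-exceedance counted but the same (1 + N) denominator as the
    observed scores: a null value that tops its marker's pool then attains
    exactly the minimal observed p, so the estimated FDR stays calibrated
    at the resolution limit of the permutation null instead of collapsing
    to zero whenever an observed score beats the whole pool.
    """
    obs = observed.to_numpy(dtype=float)
    n_traits, n_markers = obs.shape
    pool = null.pooled()  # (T*K) x markers
    n_perm = null.scores.shape[1]

    pool_sorted = np.sort(pool, axis=0)
    p_obs = np.empty_like(obs)
    for m in range(n_markers):
        p_obs[:, m] = _empirical_p(obs[:, m], pool_sorted[:, m])

    # p-values of every permuted trait against the same pooled null; the
    # self-exceedance replaces the plus-one so scales match the observed p
    n_pool = pool.shape[0]
    p_null = np.empty_like(null.scores)
    for m in range(n_markers):
        v = null.scores[:, :, m].ravel()
        ge = n_pool - np.searchsorted(pool_sorted[:, m], v, side="left")
        p_null[:, :, m] = (ge / (1.0 + n_pool)).reshape(n_traits, n_perm)

    flat_obs = np.sort(p_obs.ravel())
    null_per_perm = np.sort(
        p_null.transpose(1, 0, 2).reshape(n_perm, -1), axis=1
    )
    # expected null discoveries at each observed threshold
    v_hat = np.zeros(len(flat_obs))
    for k in range(n_perm):
        v_hat += np.searchsorted(null_per_perm[k], flat_obs, side="right")
    v_hat = v_hat / n_perm
    r = np.arange(1, len(flat_obs) + 1)
    q_at = np.clip(v_hat / r, 0, 1)
    q_at = np.minimum.accumulate(q_at[::-1])[::-1]  # monotone in p

    idx = np.searchsorted(flat_obs, p_obs.ravel(), side="right") - 1
    q = q_at[idx].reshape(p_obs.shape)

    return LinkageResult(
        list(observed.index),
        list(observed.columns),
        observed.copy(),
        pd.DataFrame(p_obs, index=observed.index, columns=observed.columns),
        pd.DataFrame(q, index=observed.index, columns=observed.columns),
    )


# ---------------------------------------------------------------------------
# marker LD and QTL grouping
# ---------------------------------------------------------------------------

def marker_ld(markers: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of allele codes over co-called strains."""
    df = pd.DataFrame(np.asarray(markers, dtype=float))
    return df.corr(min_periods=2).to_numpy()


@dataclass
class QTLRegion:
    chrom: str
    start: int  # interval between first non-linked flanking polymorphisms
    end: int
    members: list[int]  # marker indices, genomic order


@dataclass
class QTLGroup:
    """All linked regions of one trait, counted as a single linkage."""

    trait_id: str
    regions: list[QTLRegion]
    member_markers: list[int]

    @property
    def multi_region(self) -> bool:
        return len(self.regions) > 1

    def contains_position(self, chrom: str, pos: int) -> bool:
        return any(
            r.chrom == chrom and r.start <= pos <= r.end for r in self.regions
        )


def group_qtls(
    linked: list[int],
    markers: pd.DataFrame,
    ld: np.ndarray,
    max_gap: int = 10,
    ld_min: float = 0.8,
    chrom_lengths: dict[str, int] | None = None,
    trait_id: str = "",
) -> QTLGroup | None:
    """Merge a trait's linked markers into regions and one QTL group.

    ``markers`` must be in genomic order with columns chrom/start/end.
    Consecutive linked markers merge into a region; a region absorbs the
    next linked marker (plus intermediate non-linked markers) iff they are
    on the same chromosome, separated by at most ``max_gap`` non-linked
    markers and in LD > ``ld_min`` with every current member.  Remaining
    regions form one multi-region group counted as a single linkage.
    Region intervals span between the first non-linked flanking markers;
    terminal linked markers extend the interval to the chromosome end.
    """
    if not linked:
        return None
    linked = sorted(linked)
    chroms = markers["chrom"].to_numpy()
    starts = markers["start"].to_numpy()
    ends = markers["end"].to_numpy() if "end" in markers else starts

    regions: list[list[int]] = [[linked[0]]]
    for m in linked[1:]:
        cur = regions[-1]
        last = cur[-1]
        same_chrom = chroms[m] == chroms[last]
        gap = m - last - 1
        high_ld = all(
            not np.isnan(ld[m, c]) and ld[m, c] > ld_min for c in cur
        )
        if same_chrom and gap <= max_gap and (gap == 0 or high_ld):
            cur.append(m)
        else:
            regions.append([m])

    out_regions = []
    for members in regions:
        chrom = chroms[members[0]]
        first, last = members[0], members[-1]
        # flanking non-linked markers on the same chromosome
        left = first - 1
        if left >= 0 and chroms[left] == chrom:
            lo = int(starts[left])
        else:
            lo = 1
        right = last + 1
        if right < len(markers) and chroms[right] == chrom:
            hi = int(ends[right])
        else:
            hi = chrom_lengths[chrom] if chrom_lengths else int(ends[last])
        out_regions.append(QTLRegion(str(chrom), lo, hi, members))
    return QTLGroup(trait_id, out_regions, linked)
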