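"""Map planted expression QTLs with the randomized-forest engine.

Uses a reduced study (fewer markers and traits than the validation suite)
so it finishes in about a minute: 44 segregants, ~55 markers, a few
planted cis and trans effects, kinship-eigenvector covariates, shared
permutations and the empirical FDR.  Note the permutation count sets the
smallest attainable p-value (and with it the FDR resolution): with T
traits and K permutations the pooled null holds T*K scores per marker, so
small demos need enough permutations for q-values below the cutoff to be
reachable at all.
"""

import pandas as pd

from segqtl.designs import RF_DESK, qtl_study
from segqtl.qtl import (
    RFConfig,
    empirical_p_and_fdr,
    group_qtls,
    marker_ld,
    permutation_null,
    rf_selection_frequency,
)

study = qtl_study(seed=1, n_variants=60, n_trans=3, n_cis=2)
print(f"{study.predictors.n_markers} markers, "
      f"{len(study.traits)} planted traits")

observed = pd.DataFrame(
    [rf_selection_frequency(study.traits.loc[t].to_numpy(),
                            study.predictors, RF_DESK, seed=i)
     for i, t in enumerate(study.traits.index)],
    index=study.traits.index, columns=study.predictors.marker_ids,
)
null = permutation_null(study.traits, study.predictors, n_perm=200,
                        config=RFConfig(2, 50, 2), seed=1)
result = empirical_p_and_fdr(observed, null)
linked = result.linked(fdr=0.10)
print(f"linkages at FDR 0.10: {len(linked)}")

ld = marker_ld(study.predictors.markers)
ids = study.predictors.marker_ids
for trait_id, sub in linked.groupby("trait_id"):
    members = [ids.index(m) for m in sub["marker_id"]]
    group = group_qtls(members, study.markers.markers, ld,
                       chrom_lengths=dict(study.genome.chromosomes),
                       trait_id=trait_id)
    truth = study.planted.set_index("trait_id").loc[trait_id]
    spans = ", ".join(f"{r.chrom}:{r.start}-{r.end}" for r in group.regions)
    hit = group.contains_position(truth["chrom"], truth["pos"])
    print(f"  {trait_id} ({truth['kind']}): QTL {spans} "
          f"-> causal site {'inside' if hit else 'outside'}")

# A trait's QTL group should span the marker carrying its planted effect;
# the q-values come from the shared-permutation null, so correlated traits
# do not inflate the discovery count.
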