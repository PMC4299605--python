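# segqtl

Expression and growth QTL mapping in two-parent haploid crosses genotyped
directly from RNA-seq.

## The problem

In a recombinant library built from two haploid parents (the classic
fission/budding-yeast design), every strain's genome is a mosaic of the two
parental haplotypes. RNA-seq of each strain can serve double duty: the reads
quantify sense and antisense expression, *and* the alleles they carry at
sites polymorphic between the parents reveal which parent each genomic
segment came from — no separate genotyping assay needed. The catch is that a
variant is only visible where its host gene is expressed, so roughly half
the sites are missing in any one strain, and the missingness is informative
(tied to expression).

`segqtl` implements the full computational pipeline for this design:

* a synthetic-cross simulator (genomes, meioses with a
  recombination-suppressed inversion, NB expression with planted
  cis/trans/hotspot effects, 48-bp read placements with an empirical-style
  error model, expression-tied genotype calls), so every stage is testable
  without any sequencing data;
* genotyping from expressed variants: quality filtering, discordance
  correction, imputation inside 50-kb haplotype blocks, collapse of fully
  linked adjacent sites into unique mapping markers;
* strain-specific annotation liftover, strand-specific CDS counting
  (sense + antisense), and the normalization chain (gene filter, zero
  handling, library scaling, log2, per-batch mean-centering);
* a Random-Forest QTL mapper whose linkage score is the predictor
  **selection frequency** (fraction of split nodes using a marker), with
  random re-assignment of missing genotypes over many forests,
  kinship-eigenvector covariates for population structure, a shared
  permutation scheme across traits, empirical p-values and a
  permutation-based FDR, and LD-aware grouping of linked markers into QTL
  regions and groups;
* downstream statistics: Poisson-bin hotspot detection, cis/trans
  classification by LD with the markers flanking the target gene, effect
  directionality, candidate-regulator prediction by maximal r², and
  gene-pair-orientation (convergent/divergent/tandem x overlap) enrichment;
* growth-curve analysis: LS→OD calibration and extraction of efficiency,
  AUC, μ_max, lag time and doubling time (T_d = ln 2/μ_max) as QTL traits.

The scientific model and every numerical choice are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from segqtl.designs import genotyping_study
from segqtl import infer_inheritance, filter_sites, impute_missing, build_markers
import numpy as np

genome, truth, expr, calls = genotyping_study(seed=1)
inh = infer_inheritance(calls, min_quality=20)
print(f"direct: {inh.called_fraction():.1%}")
inh, _ = filter_sites(inh, np.ones(len(inh.sites), bool))
inh = impute_missing(inh, max_flank_distance=50_000)
print(f"imputed: {inh.called_fraction():.1%}")
print(f"markers: {len(build_markers(inh))}")
```

prints

```
direct: 50.1%
imputed: 93.6%
markers: 155
```

— about half of the polymorphic sites are readable directly from
expression; block-wise imputation lifts the call rate above 90% (the
remainder sits across true recombination breakpoints, where flanking
haplotypes disagree and no honest imputation is possible); the ~500
retained sites collapse into ~155 markers because only a recombination
event can separate adjacent sites.

The `examples/` directory has one short script per capability
(simulation, genotyping, QTL mapping, hotspots and gene pairs, growth
curves, the full pipeline). A pipeline run is also available from the
shell:

```bash
segqtl run --seed 7 --outdir myrun     # simulate -> genotype -> map -> hotspots
segqtl genotype --calls calls.tsv --variants parents.vcf --outdir geno
segqtl map --traits expr.tsv --genotypes geno/genotypes.tsv --out linkages.tsv
```

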