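# Methods

`segqtl` implements a desk-scale but complete analysis pipeline for
expression and growth QTL mapping in a two-parent haploid recombinant
library that is genotyped directly from RNA-seq. This note documents the
models, the synthetic data they are validated on, the numerical choices,
and the known limits of what the validation shows.

## The study design being modeled

Two haploid parental strains differ at a few hundred to a few thousand
SNP/indel sites. Their recombinant offspring (F1 from one meiosis, F2 from
two) are profiled by strand-specific RNA-seq and by growth curves. Because
variants are only visible where the host transcript is expressed, the
genotype of roughly half of the sites can be read directly; the rest must
be imputed from the large haplotype blocks that meiosis leaves behind.
Genotypes then serve as predictors for mapping three trait families: sense
expression, antisense expression over coding CDS regions, and growth
parameters.

## Synthetic cross (module `simulate`)

The generator emulates a fission-yeast-like design scaled down ~6x so that
every stage runs in seconds to minutes on one CPU:

* **Genome** — 2 chromosomes (1.2 Mb + 0.8 Mb), 200 non-overlapping genes
  (CDS 0.5–2 kb; a configurable number of adjacent pairs rewritten as
  convergent overlapping (+,−) pairs), 500 variant sites (85% SNP, 15%
  indel of 1–3 bp), 90% of sites inside CDS. A pericentric inversion
  (chr1:100–400 kb) suppresses recombination.
* **Meiosis** — crossovers per chromosome are Poisson with uniform
  placement, thinned inside the inversion by the suppression factor
  (default 0.1). The default rate of 1.4 crossovers/chromosome/meiosis
  reproduces the empirical density of ~1.4 breakpoints per Mb per
  segregant seen in such libraries; at our 2 Mb scale that is ~2.8
  breakpoints per strain. F2 segregants are composed from two independent
  F1 mosaics recombined by a second crossover process, so they carry more
  breakpoints than F1. There is no crossover interference (fission yeast
  lacks it), so rare close double crossovers occur — see the genotyping
  validation below.
* **Expression** — per gene and sample the true log2 mean is
  `baseline + effects + batch offset`; counts are negative-binomial with
  mean `10 * 2^mean * library factor` and dispersion α (variance
  μ + αμ²). α defaults to 0.05, a typical bulk RNA-seq overdispersion; the
  real study does not state a count-noise model, so α is exposed in
  config, and α = 0 switches noise off exactly (deterministic rounded
  means) so tests can isolate other stages. Baselines are N(2.5, 2.0) in
  log2 units, giving a realistic spread from silent to highly expressed.
* **Effect sizes are in units of the gene's own noise SD.** A planted
  effect of size s shifts the alt-allele group by
  `s * sqrt(α + 1/μ)/ln 2` log2 units, where μ is the gene's baseline mean
  count. This makes "a 1.5 SD trans effect" mean the same detectability
  for a weakly and a strongly expressed gene; with a fixed log2 shift
  instead, low-expression genes would receive effects far below nominal
  size purely through Poisson noise. A fixed global unit is available via
  `EffectConfig.trait_sd`.
* **Reads** — 48-bp placements uniform over the transcript plus a 48-nt
  poly-A tail, strand equal to the gene strand, per-base errors from a
  position-dependent error profile (default rising 0.001→0.01 along the
  read, the shape empirical error models take on real sequencers).
* **Mapping bias** is modeled analytically rather than by running an
  aligner: in reference mode a read's mismatch count is its sequencing
  errors plus one per covered alt SNP, and an alt indel costs the whole
  read (an ungapped aligner cannot span a length change); reads above the
  mismatch budget (default 3) are dropped. Strain-specific mode counts
  sequencing errors only. This isolates the mechanism by which
  reference-based alignment under-counts polymorphic genes, at desk scale.
* **Genotype calls** — a site inside a gene is called with probability
  `1 − exp(−count/θ)` (θ = 70 by default, chosen so that ~50% of sites are
  directly called under the default expression model, matching the
  regime these libraries operate in); θ = 0 means every covered site is
  called. Calls flip parent with a configurable error rate and carry
  N(60, 15) qualities clipped at 0. Sites outside genes are never
  observed.

All randomness flows from one master seed through named substreams
(`cross`, `expression`, `reads`, `calls`, ...), so each stage is
independently reproducible.

## Genotyping (module `genotyping`)

Five steps, operating on a strains x sites matrix over {P1, P2, unknown}:

1. **Inference** — a called allele maps to the parent carrying it;
   heterozygous calls (meaningless in haploids) and calls with quality
   < 20 become unknown.
2. **Site filtering** — a site is discarded iff it fails the parental
   sanity check *and* its minor allele frequency over called strains is
   below 10%. The conjunctive reading follows the rule's grammar; a
   `rule="or"` switch gives the disjunctive alternative. Sites never
   called anywhere are always discarded.
3. **Isolated-discordance correction** — a call disagreeing with both of
   its nearest called neighbours is rewritten to their shared label when
   the two flanking sites lie < 50 kb apart (the flank-to-flank distance,
   not focal-to-flank). One left-to-right pass; corrections become visible
   to later sites but no re-scan occurs.
4. **Imputation** — an unknown entry takes the shared label of its nearest
   called flanks iff they agree and are < 50 kb apart, assuming no
   recombination within the block. Runs of consecutive unknowns are filled
   entry by entry under the same rule (`fill_runs=False` restricts to
   singletons). Called entries are never overwritten, and the
   correct→impute→build chain is idempotent.
5. **Markers** — sites called in < 50% of strains are dropped; maximal
   runs of adjacent sites with *identical* segregation vectors (the
   unknown pattern must match too) collapse into one marker spanning their
   positions. Each marker is a maximal fully-linked block.

Replicate concordance over co-called sites (< 0.9 by default) flags
probable sample swaps.

**Validation.** With full coverage, zero call error and noiseless
qualities, inference + imputation reproduce the true genotypes at 100% of
retained sites. That benchmark deliberately skips step 3: in error-free
complete data an isolated discordant pattern can only be a genuine close
double recombination (the Poisson crossover model allows them), which a
correction built to remove call errors would overwrite. Under
expression-tied missingness (~50% direct calls, 44 segregants), the full
five-step pipeline reaches a post-imputation call rate ≥ 0.9 with accuracy
≥ 0.99; residual unknowns sit where flanking haplotypes disagree (true
breakpoint intervals) or at chromosome ends.

## Strain-specific quantification (module `expression`)

* **Liftover** — indels carried by a strain shift all downstream
  coordinates; annotation intervals are lifted by cumulative offsets, and
  a boundary inside a deleted segment clamps to the deletion edge (with a
  warning). Lift then inverse-lift is the identity for any position not
  deleted.
* **Counting** — strand-specific and CDS-based: a read is assigned to the
  CDS containing its midpoint (midpoint assignment resolves
  boundary-spanning reads without double counting); same-strand reads are
  sense, opposite-strand reads antisense. With convergent overlapping
  pairs a midpoint can lie in two CDSs of opposite strand and counts once
  per strand orientation.
* **Normalization** — genes with zero counts in more than half of the
  samples are dropped; remaining zeros become 0.1 (sense) or missing
  (antisense — their coverage is too sparse for a floor to be honest);
  samples are scaled by `mean(t)/t_i` with t_i the total mapped reads
  (this form preserves count magnitude; for antisense matrices the sense
  totals should be passed as `totals` since they are the library size);
  values are log2-transformed; batch effects are removed by per-gene
  per-batch mean-centering, computing each batch mean without designated
  excluded samples (e.g. deletion-mutant controls) but subtracting it from
  all. Centering is applied after the log because centering raw scaled
  counts can produce negatives; `center_before_log=True` preserves the
  literal order for comparison.

## QTL mapping (module `qtl`)

The mapper is a randomized-forest scan scored by **selection frequency**:
the fraction of all split nodes in a combined forest that split on a given
predictor (an alternative per-tree presence score sits behind a flag).
Regression forests use mtry = p/3 and a minimum leaf size of 5 — the
regression defaults of the classical R randomForest implementation this
method family was built on. Leaf size matters: fully grown trees on 44
samples spend most of their ~43 splits on noise, diluting the causal
marker's share ~5-fold.

* **Missing genotypes** — missing marker entries are randomly assigned one
  of the two parental alleles (Bernoulli(0.5); allele-frequency-weighted
  draws behind a flag), forests are grown per assignment, and all forests
  are combined. The score's run-to-run variance decreases as the number of
  assignments grows. With no missing entries the assignment machinery is
  skipped, so results are independent of that setting.
* **Population structure** — the strain kinship matrix (fraction of
  co-called markers with identical alleles) is eigendecomposed and its
  leading eigenvectors join the predictor matrix as real-valued
  covariates; k is the smallest count explaining strictly more than 80% of
  the genotype variance, or a fixed k (the study profile uses 8).
  Covariates compete for splits but are excluded from returned marker
  scores; frequencies over all predictors sum to 1.
* **Shared permutations** — the same strain-index shuffles are used for
  every trait, with predictor rows (markers and covariates) held fixed to
  strains. This preserves inter-trait correlation in the null, which is
  what makes downstream hotspot counting honest. For a trait with missing
  values (antisense), the shared shuffle is restricted to its non-missing
  strains. Pooling permuted scores over all traits and permutations gives
  a per-marker null distribution and plus-one empirical p-values.
* **FDR** — the permuted traits are themselves scored against the pooled
  null, and `q(p0) = mean-per-permutation #{null p <= p0} / #{observed
  p <= p0}`, monotonized. Null values count their own self-exceedance but
  use the same (1+N) denominator as observed values, so a null value that
  tops its marker's pool attains exactly the minimal observed p. Without
  this, an observed score beating the whole pool would get an estimated
  FDR of exactly 0, and under a 200-trait global null a handful of such
  resolution-limit artifacts appear by chance. Benjamini–Hochberg on the
  empirical p-values is available as an alternative via standard tools.
* **Grouping** — consecutive linked markers form a region; a region
  absorbs the next linked marker (plus intermediate non-linked markers)
  iff same chromosome, gap ≤ 10 non-linked markers, and LD (Pearson r of
  allele codes over co-called strains) > 0.8 with every current member.
  Remaining regions form one multi-region QTL group counted as a single
  linkage (which region holds the causal variant is unknowable from the
  cross). Reported intervals span between the first non-linked flanking
  markers; terminal linked markers extend to the chromosome end.

### Ensemble sizes

The study-scale profiles (100 forests x 160 trees, 1,000 missing
assignments, 1,000 permutations for expression; 2,000 x 25 trees and
10,000 permutations for growth) are available as `RFConfig` presets but
are far beyond desk scale. The validation suite uses 500 trees per
observed trait (50 forests x 10 trees, one fresh missing assignment per
forest) with 200 shared permutations. Null forests use 200 trees
(4 x 50): score noise scales as ~1/sqrt(trees), so a smaller null ensemble
has a heavier-tailed score distribution than the observed statistic and
the resulting p-values are somewhat conservative; 200 trees keeps that
conservatism modest at a quarter of the cost. The global-null calibration
uses matched 50-tree ensembles on both sides, where the estimator is
exactly exchangeable and ensemble size cancels.

### Validation

On the planted study (44 segregants, ~200 markers after collapsing, 10
trans effects of 1.5 SD, 5 cis effects of 2 SD, 5% missing genotypes),
≥ 80% of planted loci fall inside their reported QTL group at FDR 0.10
across seeds, with every recovered cis/trans effect classified correctly.
Recovery hovers near the threshold on some seeds — at n = 44 a 1.5 SD
effect is genuinely near the detection edge, which is the realistic
regime. Under a 200-trait global null the realized false-linkage
proportion at FDR 0.05 is 0 (no discoveries).

## Downstream statistics (module `postqtl`)

* **Hotspots** — each linkage is assigned to a 50-kb bin by its
  peak-marker position (multi-bin membership behind a flag); the expected
  count per bin is uniform, λ = total/bins (chromosome-specific λ behind a
  flag); the p-value is the upper Poisson tail P(X ≥ k), verified against
  direct series summation to 1e-12; bins with p < 8e-4 are kept and
  consecutive significant bins sharing ≥ 1 target merge (identical-set
  merging behind a flag). End-of-chromosome remainders enlarge the last
  bin rather than creating a small one.
* **cis/trans** — a QTL is cis for a trait iff any member marker has
  Pearson r > 0.8 with a marker surrounding the target gene's CDS (its
  nearest flanking markers; a gene past the last marker falls back to the
  single nearest). The classification is invariant to global relabeling of
  the parental alleles.
* **Directionality** — sign of (alt-parent group mean − reference-parent
  group mean), reported relative to the reference parent; ties are 0.
* **Candidate regulators** — among annotated genes with expression data
  inside the QTL interval(s), the one maximizing squared Pearson
  correlation with the target trait (the target itself excluded inside its
  own QTL; coordinate-order tie-break). A hotspot's regulator is the modal
  candidate over its targets.
* **Gene pairs** — coding genes ordered by TSS per chromosome; successive
  pairs are convergent (+,−), divergent (−,+) or tandem, and overlapping
  iff the CDS intervals intersect (UTR-only overlap does not count,
  because antisense is quantified over the CDS). Enrichment of a target
  set uses gene-incidence counting — each picked gene adds 1 to the
  category of every adjacent pair containing it — against random target
  sets of the same size. On a universe where every gene belongs to exactly
  one pair this statistic is an exact hypergeometric draw, which is how
  the permutation p-values are oracle-checked. Both enrichment and
  depletion p-values are reported (plus-one). Note the p-values are
  sub-uniform, not uniform, under the null: the counting statistic is
  discrete, so its p-value distribution has atoms; tests bound
  P(p ≤ α) ≤ α rather than asserting continuous uniformity.

## Growth (module `growth`)

Light-scattering series are mapped to OD by OLS on anchor pairs.
Per curve: efficiency = OD(end) − OD(start); AUC = trapezoidal integral
above the initial-OD baseline (clipped at 0, hence invariant to constant
shifts); μ_max = maximum of d/dt ln OD via the first derivative of a
GCV-smoothed spline (default) or a sliding-window OLS slope (window 7);
lag time by the tangent construction — the tangent at the point of maximal
specific growth rate traced back to the initial log-OD level; doubling
time T_d = ln 2 / μ_max exactly. Curves flat within numerical noise
(μ_max ≤ 1e-9) report the rate-derived parameters as missing. Exact
exponentials recover μ_max to ≪1%; logistic curves recover the maximal
specific rate r(1 − x0/K) within 5%.

## Pipeline (modules `pipeline`, `cli`)

One YAML `RunConfig` drives simulate → genotype → normalize → map →
downstream with per-stage toggles; outputs are plain GFF3/VCF/BED/TSV plus
a JSON manifest carrying a content hash over all output files and the
scientific parameters (not paths or timings), so byte-identical
reproduction is a one-line check. The `segqtl` console command is a thin
layer over these functions.

## What the synthetic validation does and does not show

The generator reproduces the *statistical structure* the method assumes:
haplotype-block genotypes with expression-tied missingness, NB count
noise, batch offsets, planted cis/trans/hotspot architecture, and the
mismatch-budget mapping bias. It does not emulate base-level sequence
evolution, UTR structure, isoform variation, diploid genetics,
fragment-length effects, or a real aligner's heuristics. Passing tests
therefore demonstrate that the pipeline's inference machinery is correct
and calibrated under its own model assumptions — not that those
assumptions capture every property of a real library. Headline counts
from any real study (numbers of markers, breakpoints, eQTLs, hotspots)
depend on its archived sequencing data and are outside what a synthetic
desk-scale study can or should reproduce; the validation targets are
therefore recovery rates, calibration and oracle agreement, not those
counts.
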