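# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the limitations of `doeqtl`. It states how things are
computed; any empirical number it refers to is produced by the test suite or
`scripts/acceptance.py`, not asserted here.

## Genetic model and state space

A Diversity Outbred genome is a mosaic of eight founder haplotypes. At each
marker the unordered pair of founder origins gives 36 diplotype states; the
canonical order used throughout the package (and serialized in file headers)
is the 8 homozygotes in founder order A–H followed by the 28 heterozygote
pairs lexicographically (AB … GH). Diplotype probabilities are an *input*
(upstream haplotype reconstruction from array intensities is out of scope);
the package validates the per-(sample, marker) simplex (sum to 1 within
1e-4 on input, 1e-6 as the declared invariant for generated data) and
collapses to founder dosages `d_f = 2·P(ff) + Σ_{g≠f} P(fg)`, which sum to 2
exactly. Probabilities are not truncated or floored before the collapse.
Markers missing on one genotyping platform take the probability slice of the
nearest measured marker on the same chromosome by base-pair distance; an
exact tie goes to the lower genomic position (the rule must pick one side
deterministically; upstream is arbitrary but fixed). chrX receives no
special treatment: if present it is scanned like an autosome, with no male
hemizygosity model.

## Association scan

Expression (FPKM) is transformed per gene to normal scores
`Φ⁻¹(rank/(n+1))` with average ranks for ties, which makes the scan
invariant to any monotone transformation of expression and robust to the
skewness of FPKM. The full model at a marker is ordinary least squares of
the rankZ phenotype on [covariates | 8 dosages]; the null model is the
covariates alone. Covariates are intercept, sex, diet, sex×diet, generation
and batch indicators for the all-livers dataset; the single-sex scans drop
the sex and sex×diet columns. Constant and aliased covariate columns are
dropped (logged) until the design has full column rank.

Because the eight dosages sum to 2 at every marker they are collinear with
the intercept. The fit is the minimum-norm least-squares solution, and the
founder coefficients are reported centered to a zero sum, which yields
founder-effect tracks without designating a reference strain. The LOD score
is −log10 of the F-test p-value with rank-based degrees of freedom
(df1 = rank(full) − rank(null), df2 = n − rank(full)); perfect fits and
underflowing p-values are capped at LOD 300. A fast scan path residualizes
the dosages against the covariates once and evaluates any number of
phenotype vectors by projection; its residual sums are mathematically
identical to the per-marker fit (verified to 1e-8 in tests), and the
per-marker fit itself is verified against an independent normal-equations
oracle to 1e-10.

**Permutations.** Genome-wide significance permutes the expression vector
across samples — genotype *and* covariate associations are both broken —
with p = (1 + #{permutation max ≥ observed}) / (n_perm + 1), so p is never 0
and lies on a discrete grid. Relatedness is handled only by the generation
covariate; there is no kinship/mixed-model correction. The permutation count
is a parameter (the reference procedure used 1,000; the package defaults to
200, which bounds the smallest achievable p at 1/201 and is adequate for the
FDR < 0.05 decision at the suite's scale).

**Peaks and FDR.** Per gene, the global best marker is always recorded; the
best marker of every other chromosome is kept iff its genome-wide
permutation p < 0.05 (at most one candidate per chromosome). BH FDR is then
applied across all candidate peaks of a dataset — primary and secondary
peaks pooled — and q < 0.05 defines significance.

**Credible interval.** The LOD profile of the peak chromosome is raised to
the 10th power (after rescaling by its maximum so LOD 300 cannot overflow)
and converted to a density by assigning each marker's weight to the bin
between the midpoints to its neighbors. The interval is the central 95%
(quantiles 2.5%–97.5%) of that mass. The midpoint-bin density — rather than
trapezoid interpolation between markers — is what makes a single-marker
spike produce an interval narrower than one marker spacing while a flat
profile yields the exact central quantiles of the chromosome span; both
behaviors are required simultaneously, and interpolation cannot deliver the
first. Central quantiles are used rather than a highest-density region; for
unimodal post-power profiles the two nearly coincide, and the central
interval is always a single segment. The interval is expanded (rarely) to
contain a maximum-LOD marker.

**Regulating strain and cis/trans.** The regulating strain is the founder
with the largest |centered coefficient| at the peak (ties, essentially
impossible with real arithmetic, go to the lower founder index with a
warning), with the coefficient sign recorded as the direction of expression
change. An eQTL is cis iff its credible interval overlaps, by at least 1 bp,
the TAD containing the gene's TSS; a TSS outside every TAD adopts the
nearest TAD on its chromosome; anything else — including a different
chromosome — is trans.

## Sex-bias categorization

An eQTL of a sex-specific gene, significant in at least one single-sex scan,
is characterized by ΔLOD = LOD_male − LOD_female *at its own peak marker*
(using the per-sex argmax markers instead would let the anchor drift between
sexes; a single anchor keeps the comparison interpretable). ΔLOD = 0 is
excluded as ambiguous rather than tie-broken. The category is the triple
(gene sex class, stronger sex, sign of the regulating strain's coefficient
in the stronger sex's scan): categories 1–4 predict decreased sex
specificity in the regulating strain, 5–8 increased. Gain/loss calls then
consult per-strain sex-specificity calls from founder-strain expression
(microarray rule, |FC| > 1.5 at FDR < 0.05): a decrease category is an
outright *loss* iff the regulating strain's call is sex-independent while at
least one other strain retains the gene's sex-specific call; an increase
category is an outright *gain* iff the regulating strain itself carries the
sex-specific call.

The matched-sex enrichment takes all combined eQTLs with nonzero ΔLOD whose
genes are sex-specific, marks each as matched (gene class equals the
stronger sex) or opposite, and compares the top 10% of |ΔLOD| against the
remainder in a 2×2 Fisher exact test. The top stratum is the round(0.1·n)
largest values by rank — a quantile threshold would mis-size the stratum
whenever |ΔLOD| values tie. With an empty opposite cell the odds-ratio fold
is infinite and the Haldane (+0.5) corrected estimate is reported alongside.

## Sex-specificity calls, variability, batch handling

The differential test behind all sex-specificity calls is a Welch t-test on
log2(FPKM + 0.5) with BH adjustment; fold-change is the pseudocounted ratio
of sex means, and the platform threshold is |FC| > 2 (RNA-seq) or > 1.5
(microarray), both at FDR < 0.05. This deliberately replaces count-model
differential expression: the decision surface downstream is only
(fold-change, FDR) thresholds, and the package's inputs are FPKM, not
counts. Strength flags (|FC| > 1.5, > 2, > 4, < 1.2) feed the enrichment
gene sets. Inter-strain variability is the coefficient of variation of the
8 strain means, intra-strain the CV across replicates, both with the sample
(n−1) standard deviation — the denominator convention is not dictated by the
formulas' source and is fixed here; CVs are undefined (NaN) at zero mean.
Batch handling for correlation analyses is per-gene, per-batch mean
centering on log2(FPKM + 1) with the grand mean restored; it removes exactly
the additive batch shifts the generator plants and is a deliberate
simplification of empirical-Bayes batch adjustment, whose scope here is
limited to pre-correlation cleanup.

## Regulatory-element profiles

Strain-specific variants are those whose alt allele is carried by exactly
one founder; missing genotype calls count as reference, which is
conservative for the exactly-one rule (a variant cannot *gain* ownership
through missingness). Only eQTLs with credible intervals narrower than 3 Mb
are profiled, with genes labeled male-/female-specific at |FC| > 4 or
sex-independent at |FC| < 1.2 (the 1.2–4 gap is dropped). For one eQTL and
one factor (DHS, STAT5, BCL6), the elements inside the interval are
restricted to those containing ≥ 1 variant owned by the regulating strain —
elements without such variants are excluded, and the denominator of the
class fractions is the restricted count (an eQTL with no qualifying element
yields an NA profile, excluded from testing). A variant is inside an element
by its leftmost base. Profile distributions are compared across eQTL sets by
two-sided Wilcoxon rank-sum, exact for combined n ≤ 20, normal approximation
with continuity correction above. cis and trans eQTLs are profiled through
the same code path, separated by a flag.

## Co-regulation clusters

Each significant all-livers eQTL (for genes expressed in ≥ 25% of samples)
gets a region spanning the second marker left through the second marker
right of its peak (five markers, truncated at chromosome ends). Regions on
the same chromosome with the same regulating strain that overlap by ≥ 1 bp
are joined; clusters are connected components of that graph, so chains are
clustered by pairwise overlap even when their ends do not mutually overlap
(an empty region intersection is then flagged rather than splitting the
cluster). Cluster summaries report the intersection of member regions and
the merged union of member credible intervals; members split into
subclusters by the sign of the regulating-strain coefficient, with within-
and cross-subcluster Pearson correlations computed on batch-centered log
expression. Enrichment of sex-specific genes per cluster (size ≥ 2;
singletons are emitted but not tested) is an upper hypergeometric tail
against the expressed-gene universe with BH across clusters — the reference
analysis reports significance without naming a test, and the hypergeometric
is the standard choice for set enrichment at fixed universe.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
exercised and tested:

- **Genomes.** Each sample carries two haplotypes per chromosome from a
  stationary Markov mosaic: uniform founder start, switch probability
  1 − exp(−ρ·d/1e8) between markers d bp apart, new founder uniform among
  the other seven. The default ρ = 5 breakpoints/100 Mb per haplotype gives
  founder blocks of a few tens of Mb, matching early-generation DO mosaics.
  DO breeding itself (the funnel, pedigrees) is not simulated: the inference
  uses only marginal mosaic structure, never pedigree. Default genome:
  3 autosomes × 100 Mb × 60 evenly spaced markers; default cohort: 100 mice
  per sex, two diets, two batches, two generations, balanced and assigned
  deterministically.
- **Genotype uncertainty.** Probability `genotype_confidence` (default
  0.97) sits on the true diplotype state, the remainder uniformly on the
  other 35 states. A real HMM produces structured uncertainty concentrated
  on neighboring states; the regression contract only needs calibrated
  dosages, for which the uniform spread is sufficient.
- **Expression.** log-scale linear model: baseline sex effect (±sex_effect/2
  by sex), founder effects times a per-sex multiplier acting on dosage, diet
  shift (default 0.3), batch shifts (default 0 and 0.4), Gaussian noise
  (default SD 1 — effects are specified in noise-SD units), exponentiated
  and scaled (default ×10) to an FPKM-like scale, so rankZ is exercised on
  skewed, strictly positive data. Planted truth records the causal marker,
  effect vector, expected regulating strain (argmax |effect|) and sex-bias
  direction. Founder-strain replicate expression uses dosage 2 of the own
  founder (inbred homozygosity), default 6 replicates per sex per strain.
- **Annotations.** Variants uniform over the genome with a configurable
  strain-private fraction (default 0.7 — founder-private variants dominate
  informative sites); elements of 1 kb with factor labels and sex classes at
  10% male-biased / 10% female-biased / 80% sex-independent (sex-biased open
  chromatin is the minority); TADs tile each chromosome in 2 Mb blocks.
  Planted-element blocks insert elements of a chosen class inside a chosen
  interval, each containing one variant private to a chosen strain, so the
  profile machinery has a recoverable signal.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: read-level noise and mapping bias,
kinship beyond a generation label, structured HMM genotype uncertainty,
linkage between variants and regulatory elements, non-additive (dominance,
epistatic) genetic effects, and count-distributional properties of RNA-seq.
Results on real DO data additionally depend on the upstream haplotype
reconstruction and expression quantification, which are inputs here.

## Acceptance studies and problem sizes

`scripts/acceptance.py` derives all randomness from one master seed via
stable per-stage hashing (so stages are independently reproducible) and
runs: a 100-gene planted-effect recovery study (one ±2 SD founder effect
per gene, n = 200, 200 permutations, 180 markers over 3 chromosomes); a
null calibration at one marker over 2,000 phenotypes (n = 100); and a full
pipeline study on a 76-gene cohort shaped like the sex-bias analyses — a
minority of sex-specific genes with strongly sex-dependent, mostly
concordant eQTLs (stronger in the gene's own sex), a few milder discordant
ones, a majority of sex-specific genes whose eQTLs have no sex-dependence
(their stronger sex is sampling noise), plus sex-independent eQTL genes
(a quarter trans) and null genes. That composition is what makes the
matched-sex decile fold an inference rather than an artifact: the top
|ΔLOD| decile is populated by the concordant minority while the remainder
is class-balanced. These sizes keep the whole script and the test suite
within a desk-scale single-CPU budget; they are the package's chosen study
conditions, and counts reported at this scale are not comparable to results
on a full 64,713-marker, 438-liver dataset.

## Known limitations

- No kinship correction: sibling structure beyond generation/batch labels
  inflates the null at high relatedness.
- Credible intervals are central-quantile, not HPD; for multimodal LOD¹⁰
  profiles (two linked peaks) the interval spans both modes.
- The FDR pools primary and secondary peaks per dataset; treating them
  separately would change borderline q-values.
- Each (gene, chromosome) eQTL is categorized once, using the stronger sex;
  eQTLs significant in both sexes are not double-counted.
- The Wilcoxon "exact" small-sample path ignores ties (the usual exact-rank
  convention); with heavily tied fraction profiles the p-value is
  approximate.
- Fold-changes use one pseudocounted FPKM ratio for all platforms, though
  microarray intensities and FPKM are different scales; the platform
  difference is carried in the threshold (1.5 vs 2), not the statistic.
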