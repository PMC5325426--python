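# Methods

This note documents the models, parameter defaults and numerical choices
behind `allclones`, and what the synthetic-data tests do and do not show
about real cohorts.

## Data model and somatic filtering

A mutation record is one somatic variant in one sample at one timepoint
(diagnosis, first or second relapse), carrying allele fraction, alt/total
read counts and a `called` flag.  Records with `called=False` represent
re-genotyped read support at timepoints where the variant was not called —
the input to the low-AF rescue analysis.  Coordinates are 1-based,
VCF-style; indels are expected left-normalized with an anchor base.

The pipeline starts downstream of variant calling, so quality filtering is
reduced to depth / alt-read / AF thresholds plus two site blacklists
(matched-remission germline variants and a population panel).  Defaults —
`min_depth=20`, `min_alt_reads=4`, `min_af=0.05` — are calling-grade
choices for ~600× panel data and are configurable; they are deliberately
bypassed by rescue genotyping.  Dropped records carry exactly one reason
tag (the first failing check in a fixed order), which makes the filter
idempotent and the kept/dropped partition exact.

Non-silent means protein-altering: missense, nonsense, frameshift,
non-frameshift indel, or splice site.  Annotator consequence strings are
mapped onto this seven-class taxonomy through an explicit lookup table;
unknown strings are an error rather than a silent default.

## Synthetic cohorts

The generator emulates the statistical structure of a deep targeted-panel
leukemia study; it is a stand-in, not a fitted generative model of any real
population.  Defaults:

- **Burden**: per-patient mutation counts are negative binomial with means
  6.4 (T immunophenotype) and 3.5 (B-cell precursor) and dispersion 1.5.
  The negative binomial (rather than Poisson) reflects the wide per-patient
  ranges seen in panel data and lets a hypermutated outlier be spiked.
- **Allele fractions**: blast fractions are uniform on (0.80, 0.95).
  Founder mutations sit at blast/2 (blast on chrX in males and chrM);
  subclonal mutations are assigned to 1–3 per-patient subclones with AF
  levels uniform on (0.02, 0.30 · blast).  The clonal fraction is 0.65 for
  T and 0.40 for BCP patients, reproducing the observation that most T-ALL
  mutations are already in the founding clone.  These choices make the
  cohort-wide AF density bimodal with a valley near 0.3.
- **Reads**: depth is negative binomial around 638× (dispersion 8, floor
  30); alt reads are binomial(depth, AF).  `noise_free=True` replaces the
  binomial draw by rounding, which the exactness tests rely on.
- **Contexts**: SNV trinucleotide contexts are drawn from per-group
  mixtures of the packaged synthetic signature catalogue; all groups get a
  CpG-deamination-like process, and the t(12;21) group additionally gets an
  APOBEC-like C>G-at-TpCpN process.  Emitted strand is randomized so the
  pyrimidine collapse is exercised.
- **Drivers**: per-subtype driver genes are spiked by re-labelling a subset
  of the drawn burden (probability 0.55 per patient) as clonal non-silent
  mutations in subtype-specific genes, so spiking does not inflate the
  burden means.
- **Outcomes**: competing exponential cause-specific hazards — relapse
  0.035/yr (multiplied by 3.0 for carriers of a non-silent mutation in the
  designated pathway, default "Notch") versus 0.008/yr for the pooled
  competing events, with administrative censoring at 10 years.
- **Relapse pairs**: half of relapsed patients get a relapse sample.
  Losses eradicate whole subclones (bounded by the available subclonal
  structure, so realized losses can fall short of the nominal Poisson mean
  3.6); gains are Poisson(5) new mutations in 1–2 new clones; 21% of gained
  mutations are seeded at diagnosis with AF < 2% and ≥2 supporting reads
  (the rescue truth); 9% of lost mutations leave residual support at
  relapse; one surviving subclone per pair doubles its AF (the rising
  truth).  A quarter of pairs get a second relapse handled by the same
  rules against the first relapse.

Every emitted mutation has exactly one truth record (clone assignment, true
AF, driver flag, context), and relapse pairs carry per-mutation
status/rescued/residual/rising labels.  What passing tests show: the
analysis operations invert this generator exactly (noise-free) or within
stated tolerances (noisy).  What they do not show: robustness to mapping
artifacts, copy-number change, contamination, or mis-specified blast
fractions — none of which the generator emulates.

## AF boundary and clonality

The clonal/subclonal boundary is the argmin of a Gaussian-kernel density
(Silverman bandwidth) on a 400-point grid over (0.05, 0.5), between the two
largest local maxima; a unimodal density yields an explicit "no boundary"
result rather than a number.  Classification divides AF by a ploidy factor
(2 for chrX in males and mitochondrial sites, else 1) and labels a mutation
clonal iff adjusted AF ≥ boundary; hemizygous sites are kept and adjusted
rather than excluded (exclusion is available by flag), and the estimator
can be run on raw or ploidy-adjusted AFs — the adjusted mode is the
default used by the pipeline.  Burden comparisons use the two-sided
Wilcoxon rank-sum test, exact when both groups have n ≤ 12 without ties,
normal approximation with mid-rank tie correction otherwise.  The
clonal-fraction comparison is a Pearson chi-square without continuity
correction (configurable).

## Mutational signatures

Context order is fixed: substitution-major (C>A, C>G, C>T, T>A, T>C, T>G),
then the 16 flank pairs lexicographically.  Recurrent SNVs (identical
chrom/pos/ref/alt in more than one patient) are removed before tabulation,
since shared calls are more likely artifacts or germline leakage than
independent somatic events.  Motif correction multiplies each context
count by genome/panel frequency of its central trinucleotide; it is exactly
inverted by swapping the two frequency arguments, and deliberately does not
conserve totals.  Whether corrected counts are additionally row-normalized
before factorization is exposed as a flag (`row_normalize`), default off.

NMF minimizes Frobenius error with multiplicative updates, 50 random
restarts (best by reconstruction error), 10 000 max iterations, tolerance
1e−6, deterministic given the seed; the matrices here are tiny (≤7 × 96) so
restarts cost little and determinism matters more than speed.  Signatures
are row-normalized to sum 1 with exposures rescaled.  Matching reports
cosine-similarity best hits (catalogue order breaks ties) plus a
complete-linkage dendrogram on Euclidean distances of the row-scaled
stacked matrix.  The shipped catalogue
(`data/synthetic_signature_catalogue.tsv`) is a constructed synthetic
stand-in with four parametric processes (CpG deamination, APOBEC-like,
ApCpG-enriched C>T, flat); it exists so matching needs no network access
and is not a published reference set.

## Driver discovery

The three statistics are simplified, dependency-free analogues of the
heavyweight cohort tools, not re-implementations: they keep the three
detection axes while dropping external covariate and score files.

- **Burden**: upper-tail Poisson p with mean = background rate × coding
  length × patients.  The background rate is anchored on silent+noncoding
  calls and scaled by the cohort non-silent/neutral ratio.
- **Impact bias**: one-sided mid-rank-sum p of the gene's effect-severity
  scores against the rest of the cohort, with the null evaluated by
  permutation (2000 draws).  The permutation null matters: with discrete
  score maps the normal approximation is badly anticonservative (an
  observed p of 0.007 versus an exact 0.12 in a typical tie-heavy case).
  Genes with fewer than two scored mutations are not tested (p missing,
  not 1).
- **Clustering**: max sliding-window (default 30 bp) mutation fraction,
  permutation p against uniform positions with +1 smoothing, so
  p ≥ 1/(n_perm+1).

Within each (subgroup, statistic) family p-values get Benjamini–Hochberg
q-values; a subgroup "predicts" a gene when any statistic has q ≤ 0.1
(an all-statistics-agree strict mode is a flag; which convention the
original tools' consensus used is not knowable from outside, so both
exist).  The consensus driver call requires ≥1 predicting subgroup and ≥3
non-silent mutations cohort-wide.  The five default discovery subgroups
are T-ALL, all BCP-ALL, and the three largest BCP subtypes (high
hyperdiploid, t(12;21), normal karyotype).

The subtype summary reports, per subtype: patients, Ras-gene carriers
(KRAS/NRAS/PTPN11/FLT3, configurable), mean driver mutations per patient,
and driver-free patients, with percentages rounded half-up to integers.

## Competing-risks relapse analysis

Relapse competes with death in remission, secondary malignancy and
resistant disease, so relapse probability is the Aalen–Johansen cumulative
incidence (increment = overall survival just before t × cause-specific
hazard at t), with events preceding censorings at tied times
(configurable).  With no competing events it reduces exactly to one minus
the product-limit estimator, which is tested against an independent
implementation.

Gray's K-sample test compares subdistribution hazards with ρ = 0 weighting
(the standard default).  Subjects failing from competing causes stay in
the weighted risk set with inverse-probability-of-censoring weights
G(t−)/G(T_i) from the pooled censoring Kaplan–Meier.  P-values come from
either a chi-square reference (K−1 df, plug-in log-rank-style variance) or
— the default — a permutation null, exact under exchangeable labels, with
automatic exhaustive enumeration for two groups when the assignment count
is small (≤20 000).  The permutation default was chosen because the
plug-in variance omits the correction terms for weight estimation; in
practice the two agree closely (and both agree with the cmprsk
implementation, which one test cross-checks through Rscript), and the
permutation null calibrates to nominal level by construction.

The relapse screen removes infants (< 1 year), keeps non-silent diagnostic
mutations, and tests each gene or pathway mutated in ≥5 patients of the
analyzed subgroup, mutated vs unmutated; the Bonferroni factor m is the
number of units actually tested in that subgroup and unit type.  Pathway
membership collapses to a per-patient flag (≥1 non-silent mutation in any
member gene); unmapped genes are ignored but counted.  Subgroups: all,
T-ALL, BCP-ALL, the three major BCP subtypes, and risk-stratified BCP when
the patient table carries a `risk_group` column.

## Clonal evolution

Status per mutation in paired patients: shared (called at diagnosis and
any relapse), diagnosis-only, or relapse-gained; mutations called only at
a second relapse are judged against the first relapse by the same rules.
A relapse-gained mutation with ≥2 supporting reads at AF < 2% at its
reference timepoint is rescued (pre-existing minor subclone); the
symmetric flag on diagnosis-only mutations is residual.  The read
threshold defaults to 2 because "detectable" needs a floor on integer read
support; it is configurable.  The rising rule — AF at relapse at least
twice the AF at diagnosis, boundary inclusive — applies to shared
mutations only; rescued mutations are rising by construction and are
reported as their own class to avoid ratios against near-zero AFs.

Clone grouping is a deterministic proxy for the manual clustering a
practitioner would do: split by presence pattern across timepoints, then
single-linkage merge trajectories whose AFs agree within 0.05 at every
shared timepoint; fates are eradicated (absent and unrescued at the last
timepoint), expanding (any member rising or rescued), else persisting.
It is order-invariant and labelled as an algorithmic stand-in, not an
inference of the true phylogeny.

A gene is relapse-associated if (1) it has ≥2 non-silent relapse-gained
mutations, or (2) ≥1 relapse-gained mutation plus non-silent diagnostic
mutations in relapsed patients (diagnostic or pooled extension cohort) —
criterion 2 being voided when any same-immunophenotype patient who stayed
in first remission carries a non-silent diagnostic mutation in the gene.
Extension-cohort records may lack AFs (pooled calling); they participate
in the criteria but are excluded from AF-based flags.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen to make the Monte
Carlo bounds tight without waste: 2000 replicates (two groups of 150) for
Gray's-test calibration with 499 permutations per test; 100 random
instances for the product-limit equivalence; 50 000 planted counts over 6
groups for signature recovery; 200 passenger + 10 spiked driver genes over
100 patients for driver recovery; 1000 patients per phenotype for the
burden means.  Wilcoxon power at the default burden dispersion measures
91.5% at p < 0.01 (97.5% at p < 0.05) over 200 replicates at n = 100/100;
the frozen test asserts the corresponding fixed-seed count.  All
simulations are driven by integer seeds; ties, tolerances and tie-break
orders are stated at each operation above.

## Known limitations

- No copy-number awareness: AFs are interpreted under constant ploidy
  (apart from the chrX/chrM factor), so loss-of-heterozygosity events
  (e.g. an indel at AF 0.85) are annotated by their AF but not modelled.
- No per-sample signature exposures (groups only), and no estimation of
  the number of signatures (k is user-set).
- The driver statistics are desk-scale analogues; they share detection
  axes with the cohort-scale tools but not their covariate corrections,
  so gene lists are not comparable across methods.
- Gray's test is implemented with pooled censoring weighting; per-group
  weighting (as in cmprsk) differs slightly in the statistic's scale but
  agreed with it to within a few percent on all checked datasets.
- The generator draws subclones independently per patient; it does not
  emulate nested clone phylogenies, so clone "fates" are only as deep as
  presence patterns plus AF trajectories.
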