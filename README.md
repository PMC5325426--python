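# allclones

Somatic-mutation analysis for deep targeted-panel sequencing of pediatric
acute lymphoblastic leukemia (ALL) cohorts — and, more generally, for any
cancer cohort with per-sample allele fractions, read counts and
competing-risks outcomes.

Deep panel sequencing (~600× coverage) of diagnostic and relapse leukemia
samples makes the mutant allele fraction (AF) of every somatic call precise
enough to reason about clonal structure: a mutation carried by every
leukemic cell of a sample with blast fraction *b* sits near AF = *b*/2
(near *b* on chrX in males and in mitochondrial DNA), while subclonal
mutations sit lower, producing a bimodal cohort-wide AF distribution.
`allclones` implements the downstream analyses that build on this:

- **Clonality & burden** — per-patient mutation burdens compared by
  Wilcoxon rank-sum; kernel-density estimation of the AF valley separating
  clonal from subclonal calls; ploidy-aware clonal/subclonal labels;
  six-class substitution spectra; Spearman burden–age correlation.
- **Mutational signatures** — 96 pyrimidine-centered trinucleotide-context
  counts per patient group; correction of context counts for
  panel-vs-genome motif composition,
  corrected(g,c) = counts(g,c) · f_genome(motif(c)) / f_panel(motif(c));
  rank-*k* non-negative matrix factorization (Frobenius loss, multi-restart)
  and cosine matching against a reference catalogue.
- **Driver discovery** — three per-subgroup statistics along the classic
  axes (burden excess via an upper-tail Poisson test anchored on the
  silent/noncoding background rate; functional-impact bias via a
  permutation rank-sum; positional clustering via a sliding-window
  permutation test), Benjamini–Hochberg within each family, and the
  consensus rule: a gene is a putative driver iff predicted in ≥1 patient
  subgroup **and** carrying ≥3 non-silent mutations.
- **Relapse association** — Aalen–Johansen cumulative incidence and Gray's
  K-sample test for the subdistribution hazard of relapse under the
  competing risks (death in remission, secondary malignancy, resistant
  disease); a gene/pathway screen restricted to units mutated in ≥5
  patients of the analyzed subgroup with per-subgroup Bonferroni
  correction.
- **Clonal evolution** — paired diagnosis/relapse classification
  (shared / diagnosis-only / relapse-gained), rescue of relapse-gained
  mutations detectable at low level (AF < 2%) at diagnosis, the rising-clone
  rule AF_relapse ≥ 2 · AF_diagnosis, deterministic clone grouping, and the
  two-criterion relapse-associated-gene call.
- **Synthetic cohorts** — a generator that emits all of the structure above
  with per-mutation ground truth, so every analysis stage is testable
  end to end.

## Worked example

```python
from allclones import SimConfig
from allclones.simulate import simulate_cohort, simulate_relapse_pairs
from allclones.io import mutations_to_frame
from allclones.clonality import estimate_af_boundary, ploidy_factor, compare_burden
from allclones.evolution import classify_status, rescue_low_af, flag_rising, calls_to_frame

cfg = SimConfig(seed=1)
mutations, patients, truth = simulate_cohort(cfg)
mutations, truth = simulate_relapse_pairs(mutations, patients, truth, cfg)
frame = mutations_to_frame(mutations)

sex = {p.patient_id: p.sex for p in patients}
snvs = frame[(frame.timepoint == "diagnosis") & frame.called
             & (frame.variant_class == "SNV")]
adjusted = [r.af / ploidy_factor(r.chrom, sex[r.patient_id])
            for r in snvs.itertuples(index=False)]
print(f"AF boundary: {estimate_af_boundary(adjusted).boundary:.3f}")

paired = frame[frame.patient_id.isin(
    set(frame.loc[frame.timepoint != 'diagnosis', 'patient_id']))]
calls = calls_to_frame(flag_rising(rescue_low_af(classify_status(paired))))
print(f"statuses: {calls.status.value_counts().to_dict()}")
print(f"rescued: {int(calls.rescued.sum())} of "
      f"{int((calls.status == 'relapse_gained').sum())} gained")
```

prints

```
AF boundary: 0.308
statuses: {'relapse_gained': 105, 'shared': 73, 'diagnosis_only': 13}
rescued: 24 of 105 gained
```

i.e. the cohort-wide AF density has its clonal/subclonal valley near 0.31,
and among the 20 paired patients 105 mutations were gained at relapse, 24
of which were already detectable as low-level read support at diagnosis —
relapse clones frequently pre-exist as minor subclones.

The same pipeline runs from the shell:

```bash
allclones all --seed 1 --outdir out/
```

which writes mutation/patient tables, clonality labels, context matrices
and signatures, driver calls and the subtype summary, the relapse screen,
evolution calls and a plain-text report into `out/`, each TSV stamped with
the tool version and config hash.

## Layout

```
src/allclones/
  io.py          mutation/patient/gene tables, somatic filters, VCF/TSV I/O
  simulate.py    synthetic cohorts, relapse pairs, outcome and spike helpers
  clonality.py   AF boundary, clonal labels, burden and spectrum statistics
  signatures.py  96-context machinery, motif correction, NMF, matching
  drivers.py     burden/impact/clustering statistics and the consensus rule
  survival.py    cumulative incidence, Gray's test, gene/pathway screen
  evolution.py   paired-sample status, rescue, rising clones, clone groups
  cli.py         `allclones` command: simulate → analyse → report
docs/methods.md  model assumptions, parameter defaults, known limitations
```
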