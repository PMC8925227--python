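# Methods

This note states the models and procedures implemented in `stresslnc`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All intervals are 1-based inclusive (GFF3 convention); an interval
`start..end` spans `end − start + 1` bases. GTF and GFF3 are both accepted
on input (dialect auto-detected per line); output is always GFF3. Exons
must carry an explicit strand: the antisense class is defined by
opposite-strand overlap, so silently guessing a strand would corrupt
classification. BED6 known-lncRNA tracks are converted from 0-based
half-open on read.

## Filter cascade

Ordered rules, first failure recorded per transcript:

| rule | default | notes |
|---|---|---|
| `min_length` | 200 nt | spliced length; single-exon transcripts retained (`keep_single_exon`, switchable) |
| `coding_overlap` | — | same-strand exonic overlap with a coding gene model; opposite-strand overlap is never a rejection (it defines the antisense class) |
| known-lncRNA overlap | — | same-strand exon overlap with the known track marks the transcript known and skips the coding-potential step; the expression rule still applies |
| `min_fpkm` | 0.5 | max FPKM over all samples |
| `coding_potential` | — | consensus of three predictors; novel lncRNA only if all three say non-coding |

The three coding-potential predictors are deliberately simple, independent
surrogates for the usual ORF-, composition- and domain-based tools:

* **ORF**: coding iff the longest forward-frame ATG..stop reading reaches
  `orf_min_codons` (default 100, stop excluded). Only stop-terminated ORFs
  count; codons containing N break the reading.
* **Hexamer**: coding iff the mean log₂(f_coding(h)/f_noncoding(h)) over
  all overlapping hexamers is strictly positive. Tables are trained with
  pseudocount 1 on user-supplied sequence sets; the pipeline default trains
  the coding table on the annotation's coding transcripts and uses a
  uniform non-coding table, which makes the score a signed
  Kullback–Leibler-style contrast against coding composition.
* **Domain**: coding iff any peptide motif from a user-supplied list occurs
  in one of the three forward-frame translations.

The unanimity rule (all three non-coding) reproduces the intersection logic
of multi-tool Venn filtering and is monotone: flipping any predictor to
coding can only move the consensus toward coding.

Classification precedence is exactly antisense > intronic > lincRNA.
Intronic requires full containment of the lncRNA span within a *single*
intron of a *same-strand* gene transcript; opposite-strand containment
without exon overlap falls through to lincRNA. These two conventions are
conservative choices, not forced by the definitions. Interval queries use
an interval tree; tests check agreement with an exhaustive all-pairs oracle
on 1,000 random configurations.

## Differential expression

A conditional exact test on a negative-binomial model with a single common
dispersion, chosen as a defensible, fully specified replacement for a
packaged GLM pipeline (three replicates per condition give tagwise
dispersion estimation little to work with):

1. **Normalization** — each sample is scaled by (geometric mean of library
   sizes)/library size and rounded back to integers. Library sizes default
   to column sums. No trimmed-mean normalization is attempted; strongly
   asymmetric DE between conditions will therefore shift log-fold-changes
   of null features (composition effect), a known limitation of total-count
   scaling.
2. **Dispersion** — pooled method of moments. Within-condition variances
   are pooled, and `phi = max(0, Σ(s² − μ̄)/Σμ̄²)` is solved jointly over
   features with grand mean > 5. The joint ratio form matters: per-feature
   moment estimates with 6 samples are extremely noisy and truncated at
   zero, and their median underestimates φ enough to make the exact test
   anticonservative (measured null type-I ≈ 0.074 at nominal 0.05 versus
   0.039–0.049 for the ratio form, true φ = 0.1).
3. **Exact test** — under H₀ the group sums are NB with means proportional
   to replicate counts and sum-dispersion φ/n (sums of i.i.d. NB draws are
   NB with that dispersion). Conditionally on the total, every split (a, b)
   is enumerated and the two-sided p-value sums the probability of all
   splits no more likely than the observed one, with relative tie tolerance
   1 + 10⁻⁷ (the convention of standard exact binomial implementations;
   with φ = 0 and balanced groups the conditional law is exactly
   Binomial(total, ½)). Totals above 100,000 use a normal approximation to
   the conditional distribution (conditional mean n_aμ, variance
   v_a v_b/(v_a+v_b)); at the scales shipped here this path is essentially
   never taken.
4. **Fold change and flags** — log₂((S_H/n_H + ½)/(S_C/n_C + ½)); the ½
   prior count keeps zero groups finite. BH step-up adjustment; flagged
   up/down iff padj ≤ 0.05 and |log₂FC| ≥ 1.

All-zero features get p = 1, log₂FC = 0. Swapping condition labels negates
every fold change and leaves every p-value unchanged (tested).

## Target prediction

*Cis*: gap between the lncRNA span and the gene span
(`later.start − earlier.end − 1`, 0 on overlap) at most 100,000 bp, strand
ignored, boundary included. The window is measured from the transcript
span, not the TSS. *Trans*: Pearson correlation of raw FPKM across all six
samples, |r| ≥ 0.95, both signs accepted; a `log2` switch transforms to
log₂(FPKM+1) first. Zero-variance profiles are skipped with a warning. No
p-value is attached to r — with six samples the |r| ≥ 0.95 cutoff has no
multiplicity control, and spurious trans links are expected and visible in
the synthetic runs; the common-target intersection is what limits them.
`common_targets` defaults to gene-level intersection (`any_lnc`); the
stricter `same_lnc` mode (the cis and trans evidence must come from one
lncRNA) is provided and is always a subset.

## Enrichment

Exact hypergeometric upper tail per term; BH within namespace (so adding
pathway terms never changes GO q-values); GO significant at raw p < 0.05,
pathways at q < 0.05, mirroring the asymmetric convention of the analysis
this package reproduces; both thresholds are flags. Network inclusion of
terms uses p < 0.05 for both namespaces. No length-bias (Wallenius)
correction is applied — the probability-weighting fit it requires is not
parameterized here — and annotations are taken as given (no GO DAG
propagation). The background defaults to genes above the expression floor.

## miRNA-site scoring

Ungapped antiparallel sliding window of miRNA length; miRNA position i
(from its 5′ end) faces window position L−i+1. Penalties: Watson–Crick 0,
G:U wobble 0.5, mismatch 1.0; positions 2–13 (seed) doubled; expectation =
penalty sum; sites reported at ≤ 5.0, best first, ties leftmost. T ≡ U.
Gaps/bulges and target-accessibility energies are deliberately out of
scope, which makes the score a lower bound on duplex disruption: a perfect
site is exactly 0, one non-seed wobble exactly 0.5, one seed mismatch
exactly 2.0 — the planted-site identities the tests assert.

## Synthetic benchmark

The generator emulates the six-library design (control PC1–PC3, heat
PH1–PH3) downstream of assembly. Defaults and rationale:

* **Genome/annotation** — 10 chromosomes × 600 kb; 100 coding genes with
  3–6 exons, real ORFs of 160–300 codons plus a planted peptide motif, and
  a first intron of 1.2–2.6 kb (so intronic lncRNAs have hosts); 210
  planted lncRNAs split 200/5/5 lincRNA/intronic/antisense (≈95/2.4/2.4%,
  echoing the strongly lincRNA-dominated class balance of plant lncRNA
  catalogs); 92% of planted lncRNAs single-exon with short lengths
  (exponential, mostly < 500 nt), matching the structural contrasts the
  `summarize_structure` tables are meant to expose.
* **Decoys** — 200, round-robin over four kinds, each violating exactly one
  cascade rule: < 200 nt; a ≥ 150-codon ORF in otherwise neutral sequence;
  zero expression; same-strand overlap with a coding exon. Antisense
  lncRNAs and overlap decoys hang off the 3′UTR tail of a host exon so
  their (genome-derived) sequence stays compositionally neutral.
* **Sequence content** — i.i.d. uniform nucleotides except coding regions,
  which draw codons from a skewed usage table (GC-ending codons weighted
  6:1) so the hexamer predictor has honest signal. Planted lncRNA sequences
  are rejection-sampled to be ORF-poor, since a few-hundred-nt uniform
  sequence contains a ≥ 100-codon ORF a few percent of the time and planted
  lncRNAs must pass the cascade by construction.
* **Counts** — NB with common dispersion 0.1, baseline means log-uniform
  20–500, per-sample depth factors within ±20%; 25% of features carry a
  planted ±2 log₂ effect on the heat mean. Planted trans pairs instead get
  deterministic integer shared-profile counts (feature constant × sample
  profile, heat × 4) so the pair's FPKM vectors are *exactly* proportional
  (r = 1); NB noise would destroy the planted correlation this recovery
  test needs. The emitted FPKM table equals `compute_fpkm` of the emitted
  counts to 10⁻⁹.
* **miRNA sites** — 9 sites cycling exact/wobble/mismatch, each with a
  fresh 21-nt miRNA, planted into DE lincRNAs (preferring trans-pair
  members so miRNA→lncRNA→gene chains exist in the network).
* **Terms** — ~34 background terms at 8% assignment, plus one GO term and
  one pathway concentrated (80% versus 3%) on the planted common targets.

Everything is a pure function of the configuration including the seed:
identical configs produce byte-identical files, which the end-to-end
determinism check asserts over two full runs.

**What passing does and does not show.** The benchmark demonstrates
correctness of the implemented rules and calibration of the exact test
under the stated generative model. It does not model splice-isoform
complexity, positional read bias, sequence-composition effects on
quantification, real codon usage or real annotation structure, so recovery
rates here do not predict recovery on real libraries; the statistical
guarantees (exactness of the hypergeometric tail, the binomial limit of the
exact test, BH monotonicity) are model-free.

## Numerical choices and degenerate inputs

Hexamer tables carry pseudocount 1 so log-ratios stay finite; windows with
N are skipped. Sequences with symbols outside ACGTN are errors. Zero-length
features and zero library sizes are errors in FPKM; zero-variance profiles
are skipped (correlation) or reported missing (replicate R²). BH clips at
1 and is stable under ties (mergesort). Exact-test ties use the 1 + 10⁻⁷
relative tolerance noted above. Network exports sort nodes and edges so
repeated exports are byte-identical.

## Problem sizes

The shipped default scale (510 transcripts, 6 samples; calibration studies
at 2,000 features) keeps a full pipeline run in a few seconds and the whole
verification suite within a couple of minutes on one core, while leaving
every planted-recovery margin comfortable; all counts scale through
`SimulationConfig`.
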