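# stresslnc

Identification of long non-coding RNAs (lncRNAs) and analysis of their
heat-stress regulatory relationships from plant bulk RNA-seq designs
(2 conditions × 3 replicates), implemented as a tested, reusable Python
pipeline with a synthetic-data generator carrying planted ground truth.

The package is aimed at plant transcriptomics analysts who want the whole
chain — lncRNA discovery filter cascade, positional classification,
differential expression, cis/trans target prediction, enrichment and
regulatory-network export — as auditable, scriptable components rather than
a collection of one-off tools.

## What it computes

**Discovery.** Assembled transcripts are screened by an ordered filter
cascade: spliced length ≥ 200 nt (single-exon transcripts retained);
same-strand exonic overlap with a protein-coding gene → rejected, overlap
with a known-lncRNA track → known lncRNA; max FPKM over all samples ≥ 0.5,
with FPKM<sub>t,s</sub> = counts<sub>t,s</sub> · 10⁹ / (length<sub>t</sub> · N<sub>s</sub>);
and a coding-potential consensus: a transcript is a novel lncRNA only if
*all three* predictors (longest-ORF length, hexamer log-likelihood ratio,
protein-motif scan) call it non-coding. Every transcript gets exactly one
outcome and, if rejected, the first failed rule. Surviving lncRNAs are
classified with precedence antisense > intronic > lincRNA (exon-level
opposite-strand overlap; full containment in a single same-strand intron;
otherwise intergenic).

**Differential expression.** A negative-binomial conditional exact test:
counts are scaled to a common effective library size, a single common
dispersion φ is estimated by pooled method of moments
(φ̂ = Σ(s² − μ̄)/Σμ̄² over well-expressed features), and for each feature
the two group sums are compared conditionally on their total by enumerating
every split. log₂ fold changes use a 0.5 prior count; features with
BH-adjusted p ≤ 0.05 and |log₂FC| ≥ 1 are flagged up/down.

**Targets.** *Cis*: protein-coding genes within 100 kb of the lncRNA span
(gap = later.start − earlier.end − 1; the boundary gap of exactly 100,000 bp
is included; strand ignored). *Trans*: genes whose FPKM profile satisfies
|Pearson r| ≥ 0.95 across all samples. *Common targets* are genes that are
a cis target of some DE lncRNA, a trans target of some DE lncRNA, and
themselves differentially expressed.

**Enrichment.** Exact hypergeometric upper tail per term,
p = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n), BH q-values within namespace; GO terms
significant at p < 0.05, pathways at q < 0.05.

**miRNA targeting.** An ungapped antiparallel expectation score: 0 per
Watson–Crick pair, 0.5 per G:U wobble, 1.0 per mismatch, penalties doubled
in the seed (miRNA positions 2–13), sites reported at expectation ≤ 5.0.

**Network.** Typed, directed regulator→regulated graph
(miRNA → lncRNA → gene → annotation term) exported as SIF, GraphML and
node/edge TSVs; up-regulated nodes carry `color=red`, down-regulated
`color=green`.

## Worked example

```sh
stresslnc run-all --simulate --seed 1 --out run/
```

prints

```
lncRNAs: 209  DElncRNAs: 85  common targets: 49  network: 144 nodes / 1214 edges
```

meaning: of 510 simulated transcripts (100 coding gene models, 210 planted
lncRNAs, 200 decoys), 209 pass the filter cascade as lncRNAs; 85 of them
are differentially expressed between control (PC1–PC3) and heat (PH1–PH3);
49 genes are cis *and* trans targets of DE lncRNAs and themselves DE
(including all 20 planted common targets); and the exported regulatory
network links the DE miRNAs, DE lncRNAs, common targets and significantly
enriched terms. `run/` then contains the GFF3/FASTA/TSV artifacts of every
stage plus `manifest.json` with SHA-256 hashes of all inputs and outputs —
re-running the same seed reproduces every file byte for byte.

The same stages are available as library functions
(`stresslnc.discovery.filter_cascade`, `stresslnc.expression.exact_test_de`,
`stresslnc.targeting.cis_targets` / `trans_targets` / `common_targets`,
`stresslnc.enrichment.hypergeom_enrich`, `stresslnc.mirna.score_sites`,
`stresslnc.network.build_network`) and as individual subcommands
(`stresslnc simulate | identify | de | run-all`).

## Scope notes

Read QC, alignment and transcript assembly are upstream of this package
(inputs are assembled-transcript GTF/GFF3, transcript FASTA and a count
matrix). The DE stage is an in-house NB exact test rather than edgeR, the
enrichment stage is plain hypergeometric rather than GOseq's length-bias
corrected test, and the miRNA scorer is a simplified ungapped expectation
scheme; `docs/methods.md` states these models, their assumptions and their
limitations precisely.
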