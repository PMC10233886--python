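# crypticorf

Proteogenomic discovery of **non-canonical ORFs (ncORFs)** — open reading
frames outside annotated coding sequences — and of the MHC-bound peptides
they produce in cancer.

Conventional MS/MS searches use only canonical protein databases and
therefore miss peptides translated from 5′UTR upstream ORFs (uORFs), 3′UTR
downstream ORFs (dORFs), out-of-frame ORFs overlapping the canonical CDS in
a shifted frame, and ORFs on noncoding RNAs. They likewise discard "silent"
somatic mutations, which can be protein-altering in a shifted reading
frame. `crypticorf` is a tested, reusable pipeline for this analysis,
aimed at computational proteogenomics and immunopeptidomics researchers.
Every stage is exercisable on synthetic data with planted ground truth, so
the whole pipeline is verifiable without any external downloads.

## What it does

1. **Annotation core** — strand-aware transcript models from genome FASTA +
   GTF, with exact genomic↔transcript coordinate maps and frame-aware
   translation (0-based half-open internally; codons containing `N`
   translate to `X`).
2. **ncORF enumeration** — every AUG→stop ORF on the spliced transcript,
   one per (stop codon, frame) keeping the 5′-most AUG, classified as
   `uORF_5utr`, `dORF_3utr`, `out_of_frame`, `ncRNA` or `miscRNA`;
   deduplication to a nonredundant protein set.
3. **Search space** — target-decoy database (ncORF + canonical proteins +
   per-protein reversed decoys, no contaminants), tryptic/semi-tryptic
   in-silico digestion with missed cleavages, and a deterministic
   canonical-overlap filter (substring and shared-peptide tests under I=L
   equivalence, with an external-aligner hook).
4. **PSM filtering** — target-decoy q-values at the PSM level
   (FDR(t) = #decoys/#targets above t, monotonized), per-assay thresholds
   (whole proteome: q ≤ 0.01; immunopeptidome: probability ≥ 0.99 and 8–25
   aa), peptide→ncORF mapping with canonical exclusion, cohort
   pervasiveness (≥ 8 cancers), differential-expression annotation
   (|log2FC| ≥ 1.5, P < 0.01) and Wilcoxon rank-sum comparisons.
5. **Variant re-annotation** — somatic SNVs/indels (MAF or VCF) projected
   through the transcript onto ORF-local codons; consequences called in the
   ncORF frame (missense / silent / frameshift / in-frame indel /
   stop-gain / stop-loss) and cross-classified into three groups:
   canonical-noncoding variants altering an ncORF, canonical-overlap
   variants altering an ncORF, and canonical-only variants. Per-sample
   tumor mutation burden (variants/Mb) in canonical vs ncORF-only scopes.
6. **Neoantigens & epitopes** — per-sample mutated ncORF proteomes from
   eligible variants, exhaustive elimination of wildtype-explainable
   peptides, and a prioritization cascade: binding affinity ≤ 150 nM AND
   (retention-time error < 5 min OR normal-tissue median expression
   < 1 TPM), with neoantigens flagged `mutated`.
7. **Synthetic data** — a deterministic generator that plants ncORFs of all
   categories, PSM score mixtures with known labels, variants constructed
   to realize requested consequence pairs, and epitope evidence tables with
   planted filter outcomes.

## Worked example

```bash
python examples/02_psm_fdr_evidence.py
```

prints (seed 11):

```
PSMs: 10000  accepted at q<=0.01: 873
realized false-target fraction among accepts: 0.0046
retained after per-assay filters: 863
peptide-supported ORFs: 38
pervasive (>= 8 of 10 cohorts): ['tx0001:32:2', 'tx0003:48:0', 'tx0014:620:2', 'tx0026:49:1', 'tx0028:281:2', 'tx0029:219:0']
planted pervasive:                            ['tx0001:32:2', 'tx0003:48:0', 'tx0014:620:2', 'tx0026:49:1', 'tx0028:281:2', 'tx0029:219:0']
```

Of 10,000 simulated PSMs (true targets score ~N(4,1), false targets and
decoys ~N(0,1)), 873 pass the 1% target-decoy FDR with a realized
false-target fraction of 0.46% — the estimator controls what it claims to
control. After mapping retained peptides onto ncORF proteins (discarding
anything contained in a canonical protein under I=L), the six ORFs planted
with true-peptide support in ≥ 8 of 10 cancer cohorts are exactly the six
flagged as pervasively translated. The other examples walk through
enumeration (`01`), variant re-annotation and mutation burden (`03`), and
the neoantigen/epitope cascade (`04`).

The same stages are available as a thin CLI:

```bash
crypticorf simulate --seed 3 --out sim/
crypticorf enumerate --genome sim/genome.fa --gtf sim/annotation.gtf --out ncorfs/
crypticorf builddb --ncorf ncorfs/ncorfs.fa --canonical sim/canonical.fa --out db.fa
crypticorf psms --db db.fa --psms sim/psms.tsv --out evidence/
crypticorf reannotate --maf sim/somatic.maf --genome sim/genome.fa --gtf sim/annotation.gtf --out consequences/
```

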