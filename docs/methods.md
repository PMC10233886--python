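# Methods

## Scope and model

`crypticorf` re-implements, as a self-contained and testable pipeline, the
proteogenomic analysis of non-canonical ORFs: enumeration of ORFs outside
annotated coding sequence, construction of a target-decoy search space,
statistical filtering of peptide-spectrum matches (PSMs), frame-aware
re-annotation of somatic variants, and prioritization of MHC-bound
peptides. External model-based tools that commonly surround this analysis
(search engines, posterior-probability mixture models, aligners, MHC
binding predictors, retention-time predictors, variant effect predictors,
differential-expression fitters) are deliberately *not* re-implemented:
their outputs enter as pluggable input tables, which keeps the pipeline's
own logic — coordinates, frames, set filters, estimators — fully testable.

## Coordinates and translation

All internal coordinates are 0-based half-open; GTF (1-based closed) and
MAF/VCF (1-based) are converted at parse boundaries only. Transcript
coordinates count along the spliced 5′→3′ sequence, so position 0 of a
minus-strand transcript is its rightmost genomic base. The spliced
sequence is the single frame of reference: ORFs, variants and peptides are
all projected onto it, which makes strand handling a property of one
mapping function rather than of every caller.

Translation uses the standard genetic code. Codons containing `N`
translate to `X` and never terminate translation (an ambiguous codon
cannot be treated as a definite stop); peptides containing `X` are dropped
from digestion products because search engines cannot match ambiguous
residues. The stop codon is considered part of the CDS span; when a GTF
dialect excludes it, the parser extends the span by one codon if the next
in-frame codon is a stop, and otherwise rejects the transcript as an
incomplete CDS (how upstream resources handle stop-less CDS annotations is
unspecified, so we refuse to guess).

## ncORF enumeration and classification

An ncORF is an AUG-initiated segment reaching an in-frame stop on the
spliced transcript. One ORF is reported per (stop codon, frame) — the
5′-most AUG, i.e. the longest variant — which matches the
"between start and stop codons" convention without combinatorial blowup;
alternative downstream AUGs and near-cognate starts (CUG/GUG) are
non-goals. The default minimum length is 30 codons (the convention of the
ORF resource this search space mirrors), configurable down to 8 for
immunopeptide-scale ORFs.

Classification relative to the canonical CDS: entirely 5′ → `uORF_5utr`;
entirely 3′ → `dORF_3utr`; overlapping in a shifted frame →
`out_of_frame`; overlapping in the same frame → discarded (canonical or
isoform sequence, not an ncORF). Overlap dominates: an ORF starting in a
UTR and running out-of-frame into the CDS is `out_of_frame`, because
overlap with canonical sequence is the property that matters downstream
(cross-classification of variants, wildtype exclusion). Transcripts
without a CDS yield `ncRNA` (or `miscRNA` for misc_RNA/rRNA biotypes).
Deduplication keeps one representative per distinct protein string
(lexicographically smallest ORF id) with a redundancy map.

## Search space

The database is ncORF proteins + canonical proteome + one whole-sequence
reversed decoy per target (prefix `rev_`), with no contaminant entries.
Digestion follows the trypsin rule (cleave after K/R, not before P) with
configurable missed cleavages; semi-tryptic mode adds every one-sided
truncation of each fully-tryptic product. Digestion is delegated to
`pyteomics.parser.icleave`, which reproduces these semantics exactly
(verified against hand-computed examples and a brute-force truncation
oracle in the tests).

Alignment-based exclusion of ncORFs indistinguishable from canonical
sequence is replaced by a deterministic filter: an ncORF is removed when
(a) its full sequence is a substring of a canonical protein under I=L
equivalence, or (b) more than 90% of its fully-tryptic 0-missed peptides
are also producible from the canonical set. E-values are tool- and
database-size dependent and not reproducible in isolation; the filter
preserves the step's purpose (drop ncORFs whose evidence could never be
discriminating) and is exactly testable. An external aligner's removal
list can be supplied to reproduce alignment behavior verbatim. I and L are
treated as identical in *all* peptide-vs-protein comparisons because they
are isobaric in MS.

## PSM filtering and evidence

The FDR estimator at score threshold t is #decoys(≥t) / max(1,
#targets(≥t)), monotonized into q-values from the bottom of the ranking;
tied scores share the q-value of their worst-ranked member, and ties are
broken deterministically by (score desc, spectrum id asc). The +1 decoy
correction is available as a switch; the default omits it (both variants
are standard, and the upstream tooling does not state which it uses).
Per-assay retention: whole-proteome PSMs at q ≤ 0.01; immunopeptidome PSMs
at posterior probability ≥ 0.99 with peptide length 8–25 aa. The posterior
probability is an input column (the mixture model that produces it is out
of scope); an optional boolean `validated` column represents
peptide-centric re-validation and, when present, retained PSMs must have
it set.

A retained peptide maps to every ncORF protein containing it (I=L);
peptides also contained in any canonical protein are discarded as
non-discriminating. Evidence aggregates peptides, cohorts and assays per
ORF. Pervasiveness flags ORFs supported in ≥ 8 cohorts (of the 9–10 cancer
cohorts a pan-cancer panel provides). Differential-expression classes use
per-gene input tables: over-expressed iff P < 0.01 and log2FC ≥ 1.5,
under-expressed iff P < 0.01 and log2FC ≤ −1.5 (fold-change bounds
inclusive). Group comparisons (conservation strata, burden, lengths) use
the two-sided Wilcoxon rank-sum test from `scipy.stats.mannwhitneyu`.

## Variant re-annotation

Variants are stored trimmed (SNV, pure insertion, pure deletion); complex
substitutions must be normalized upstream, and multi-allelic VCF records
are rejected with instructions. Indels are left-aligned against the genome
before projection so positions are deterministic across input dialects.
The consequence of an SNV is called by before/after codon comparison in
the ORF-local frame (strand-correct); a variant in the stop codon that
yields another stop is silent ("retained stop"), a sense codon there is
stop-loss. Indels are classified by the net exonic length change within
the ORF, mod 3. Indels spanning splice junctions cannot be projected onto
the spliced sequence without re-splicing and are reported unprojectable;
the same applies to intronic variants.

Canonical-frame classes are trusted from the MAF when present and
otherwise computed with the same codon engine on the CDS; exonic non-CDS
positions are UTR classes, intronic positions within 2 nt of an exon
boundary are splice-region. Cross-classification per variant: group 1 —
canonical-noncoding (UTR/flank/intron/splice/RNA) and ncORF-altering;
group 2 — canonical-coding (missense or silent, or any CDS class) and
ncORF-altering; group 3 — overlapping an ncORF without altering any ncORF
protein. Each variant receives exactly one group; when a variant overlaps
several ORFs, each (variant, ORF) pair is emitted but the variant-level
class collapses by a fixed precedence (frameshift > stop-gain > stop-loss
> in-frame > missense > silent) and burden counts the variant once.
Mutation burden divides per-sample counts by a configurable region size
(default 38 Mb, a typical exome target; the denominator is never stated by
upstream tools, so it is explicit here).

## Mutated proteomes and the epitope cascade

Eligible variants for the per-sample mutated ncORF proteome are those that
alter an ncORF protein while being invisible to canonical pipelines:
canonical-silent variants on out-of-frame ORFs, and variants outside the
canonical CDS footprint entirely. All of a sample's eligible variants for
one ORF are applied jointly (3′-most first so offsets stay valid);
frameshifts re-translate to the next stop; overlapping edits in one sample
conflict and reject the record. Candidate peptides must span the changed
interval, and any peptide occurring (I=L) in *any* wildtype protein —
canonical or unmutated ncORF — is eliminated by exhaustive substring scan.

The prioritization cascade: binding affinity ≤ 150 nM (or, alternatively,
predictor percentile rank ≤ 2 when enabled) is the hard gate; support then
requires retention-time error < 5 min (strict) or normal-tissue median
expression < 1 TPM. Candidates lacking an RT measurement neither pass nor
fail on RT — the expression route remains open. Affinities, ranks, RT
predictions and expression medians are input tables; the built-in
hydrophobicity index (additive per-residue retention coefficients from
classical reversed-phase HPLC work, with a multiplicative length
normalization factor defaulting to 1.0) exists only for RT-vs-
hydrophobicity QC and is never a filter; externally predicted values take
precedence when supplied.

## Synthetic data: what it emulates, and what it does not

The generator builds a deterministic miniature of a pan-cancer study from
a single root seed (per-stage child generators use fixed offsets):

* **Reference** — default 40 transcripts (25% noncoding) on 2 contigs,
  1–3 exons each, both strands, intron lengths 40–150 nt. Protein-coding
  transcripts carry 5′UTR/CDS/3′UTR (CDS 120–220 codons); planted ORFs
  (10 uORFs, 10 dORFs, 10 out-of-frame, 8 lncRNA, 2 misc_RNA; 30–45
  codons) are written by explicit sequence design: AUG and stop placed in
  the designated region and frame, interior in-frame stops and upstream
  in-frame AUGs repaired, with edits forbidden from creating stops in the
  canonical frame or touching previously planted constructs. UTRs are
  sized to host ≥30-codon uORFs/dORFs (longer than typical human UTRs;
  a consequence of the 30-codon ORF convention at miniature scale). Every
  plant is verified by running the enumerator and retried on failure, so
  manifest recovery is guaranteed by construction.
* **PSMs** — 10,000 PSMs: true targets N(4,1); false targets and decoys
  share N(0,1), each null PSM a decoy with probability 0.5. Posterior
  probability is a logistic transform of the score (midpoint halfway
  between the components, scale 0.4). Supported ORFs emit discriminating
  peptides (fully-tryptic 8–25-mers unique to one planted ORF under I=L);
  pervasive ORFs (6) in ≥ 8 of 10 cohorts, all others in 1–3 cohorts —
  sparse support typical of singleton detections. Each supported
  (ORF, cohort) pair contributes 5 whole-proteome spectra, emulating the
  redundancy of cohort-level data. Random false-target peptides avoid I/L
  so I=L collisions with real proteins cannot occur.
* **Variants** — requested (canonical-class, ncORF-class) cells are
  realized by randomized search over positions and alleles inside planted
  ORF footprints, each candidate verified with the pipeline's own
  consequence engine (closed loop); unrealizable draws are reported, not
  silently dropped. Canonical-missense background SNVs outside any ORF
  footprint support burden statistics.
* **Epitope tables** — per-candidate affinity and RT outcomes and
  per-gene expression outcomes are planted as pass/fail and then realized
  numerically (e.g. RT error drawn from [0, 4.5) for a pass, [5.5, 15)
  for a fail, around a prediction that is an affine transform of the
  built-in hydrophobicity index).

What the generator does **not** emulate: spectra (no mzML/MGF, no peak
matching), quantification, sequencing reads, splice-disrupting variants,
germline phasing, real score/probability distributions (the two-Gaussian
model is a caricature that makes FDR calibration exactly checkable), and
realistic homology structure between proteins (planted proteins are
random, so peptide-to-ORF mapping is nearly collision-free — real
proteomes share far more sequence). Passing tests therefore demonstrate
the correctness of the pipeline's logic under known truth, not the
biological discovery rates of any real cohort.

## Numerical and testing choices

* Determinism everywhere: fixed seeds, stable sorts, explicit tie-breaks;
  byte-identical generator output per seed is asserted in the tests.
* Dual-route verification: the enumerator is checked against an
  independent brute-force all-AUG scan (200 random transcripts,
  300–3,000 nt, GC 0.30–0.60), and the consequence caller against a naive
  oracle that applies the edit to the contig, re-splices, re-translates
  and diffs proteins (1,000 random SNVs/indels on both strands).
* Empirical FDR control is measured, not assumed: the realized
  false-target fraction among q ≤ 0.01 acceptances averages ≈ 1% over 20
  seeds (bound asserted at ≤ 2%).
* Problem sizes (40 transcripts, 10,000 PSMs, ~240 variants, 20-seed
  repeats) were chosen so the complete suite and the acceptance script
  each run in well under a minute on one CPU while leaving every planted
  structure statistically comfortable; they are configuration, not
  constants, and scale up through `SimulationConfig`.

## Known limitations

* No trans-splicing, selenocysteine recoding, or non-standard genetic
  codes; no ribosome-profiling evidence integration; no Kozak-context
  scoring (an annotation column accepts external scores).
* The canonical-overlap filter's 90% shared-peptide threshold
  parameterizes a gap left open by alignment-based exclusion (no stated
  coverage requirement); it is configurable.
* Splice-region variants are projected only when exonic; re-splicing
  consequences are out of scope.
* The variant-level class precedence for multi-ORF overlaps is a
  convention; per-pair classes are always emitted alongside it.
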