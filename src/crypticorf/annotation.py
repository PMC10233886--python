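"""Genome and transcript-annotation machinery.

Everything downstream (ORF enumeration, variant projection, mutated-proteome
construction) relies on the coordinate conventions fixed here:

* internal coordinates are 0-based, half-open, everywhere;
* GTF input (1-based, closed) and MAF/VCF input (1-based) are converted at
  the parse boundary and nowhere else;
* transcript coordinates count from the transcript 5' end along the spliced
  sequence, so position 0 of a minus-strand transcript is the *rightmost*
  genomic base of its last genomic exon.

The spliced transcript sequence is the single source of truth for reading
frames: ORFs, variants and peptides are all projected onto it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: standard genetic code, with '*' marking stops
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in STOP_CODONS})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "misc_RNA", "rRNA", "other")


class AnnotationError(ValueError):
    """Invalid annotation content (invariant violations, bounds errors)."""


class GTFParseError(AnnotationError):
    """Malformed GTF input; the message names the offending line number."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, offset: int) -> str:
    """Translate ``seq`` from ``offset`` until the first stop codon.

    The stop codon is not included in the output.  Codons containing ``N``
    translate to ``'X'`` (and never terminate translation: a search engine
    cannot treat an ambiguous codon as a definite stop).  A trailing partial
    codon is ignored.

    Parameters
    ----------
    seq : nucleotide sequence over {A,C,G,T,N}
    offset : reading-frame offset, one of 0, 1, 2
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2 (got {offset})")
    out: list[str] = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = CODON_TABLE[codon]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


@dataclass
class GenomeBuild:
    """A set of named contigs holding uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"contig {name!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise AnnotationError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeBuild":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return contig[start:end), raising on out-of-bounds access."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise AnnotationError(f"unknown contig {contig!r}") from None
        if start < 0 or end > len(seq) or start > end:
            raise AnnotationError(
                f"interval [{start},{end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are genomic intervals in genomic order (leftmost first,
    regardless of strand).  ``cds_span`` is in *transcript* coordinates on
    the spliced sequence and, when present, includes the stop codon.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_span: Optional[tuple[int, int]] = None
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-' (got {self.strand!r})")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (0 <= cs < ce <= self.length):
                raise AnnotationError(
                    f"{self.transcript_id}: cds_span {self.cds_span} outside "
                    f"transcript of length {self.length}"
                )
        if self.biotype not in BIOTYPES:
            raise AnnotationError(f"unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint [leftmost, rightmost)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None


def genomic_to_transcript(t: TranscriptModel, gpos: int) -> Optional[int]:
    """Map a 0-based genomic position to a spliced-transcript offset.

    Returns ``None`` for intronic positions or positions outside the
    transcript footprint.
    """
    if t.strand == "+":
        offset = 0
        for s, e in t.exons:
            if s <= gpos < e:
                return offset + (gpos - s)
            offset += e - s
        return None
    offset = 0
    for s, e in reversed(t.exons):
        if s <= gpos < e:
            return offset + (e - 1 - gpos)
        offset += e - s
    return None


def transcript_to_genomic(t: TranscriptModel, tpos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` (exonic positions only)."""
    if not 0 <= tpos < t.length:
        raise AnnotationError(
            f"transcript position {tpos} outside [0,{t.length}) "
            f"for {t.transcript_id}"
        )
    if t.strand == "+":
        remaining = tpos
        for s, e in t.exons:
            if remaining < e - s:
                return s + remaining
            remaining -= e - s
    else:
        remaining = tpos
        for s, e in reversed(t.exons):
            if remaining < e - s:
                return e - 1 - remaining
            remaining -= e - s
    raise AssertionError("unreachable")  # pragma: no cover


def transcript_interval_to_genomic(
    t: TranscriptModel, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Project a transcript interval onto genomic intervals (genomic order)."""
    if not 0 <= t_start <= t_end <= t.length:
        raise AnnotationError(
            f"interval [{t_start},{t_end}) outside transcript {t.transcript_id}"
        )
    if t_start == t_end:
        return []
    intervals: list[tuple[int, int]] = []
    # walk exons in transcript (5'->3') order
    exon_iter = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    offset = 0
    for s, e in exon_iter:
        ln = e - s
        lo = max(t_start, offset)
        hi = min(t_end, offset + ln)
        if lo < hi:
            if t.strand == "+":
                intervals.append((s + (lo - offset), s + (hi - offset)))
            else:
                intervals.append((e - (hi - offset), e - (lo - offset)))
        offset += ln
    intervals.sort()
    return intervals


def spliced_sequence(t: TranscriptModel, genome: GenomeBuild) -> str:
    """Exon sequences concatenated 5'->3' (reverse-complemented on minus)."""
    parts = [genome.fetch(t.contig, s, e) for s, e in t.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if t.strand == "-" else seq


def annotated_protein(t: TranscriptModel, genome: GenomeBuild) -> str:
    """Translation of the annotated CDS (stop codon excluded)."""
    if t.cds_span is None:
        raise AnnotationError(f"{t.transcript_id} has no CDS")
    cs, ce = t.cds_span
    return translate_frame(spliced_sequence(t, genome)[cs:ce], 0)


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "misc_rna": "misc_RNA",
    "rrna": "rRNA",
}


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GTFParseError(
                    f"line {lineno}: non-integer start/end "
                    f"({fields[3]!r}, {fields[4]!r})"
                ) from None
            if start < 1 or end < start:
                raise GTFParseError(
                    f"line {lineno}: invalid interval {start}..{end}"
                )
            if fields[6] not in ("+", "-", "."):
                raise GTFParseError(f"line {lineno}: bad strand {fields[6]!r}")


def parse_transcripts(
    gtf_path: str | Path, genome: GenomeBuild
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Parse a GTF into transcript models; returns (kept, rejected).

    ``rejected`` maps transcript_id -> reason.  Transcripts on contigs absent
    from ``genome`` are skipped with a warning (not listed as rejected: the
    annotation itself may legitimately cover more contigs than the build).
    """
    import gffutils

    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise GTFParseError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks transcript_id"
            )
        rec = per_tx.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "gene_name": feat.attributes.get("gene_name", [""])[0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
                "biotype_raw": (
                    feat.attributes.get("transcript_biotype", [None])[0]
                    or feat.attributes.get("transcript_type", [None])[0]
                    or feat.attributes.get("gene_biotype", [None])[0]
                ),
            },
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        if feat.featuretype == "exon":
            rec["exons"].append(iv)
        else:
            rec["cds"].append(iv)

    kept: list[TranscriptModel] = []
    rejected: dict[str, str] = {}
    for tid, rec in per_tx.items():
        if rec["contig"] not in genome:
            log.warning(
                "transcript %s: contig %s absent from genome build; skipped",
                tid,
                rec["contig"],
            )
            continue
        try:
            kept.append(_assemble_transcript(tid, rec, genome))
        except AnnotationError as exc:
            rejected[tid] = str(exc)
            log.warning("transcript %s rejected: %s", tid, exc)
    return kept, rejected


def _assemble_transcript(
    tid: str, rec: dict, genome: GenomeBuild
) -> TranscriptModel:
    exons = tuple(sorted(rec["exons"]))
    raw = (rec["biotype_raw"] or "").lower()
    biotype = _BIOTYPE_MAP.get(raw, "other")
    cds_span = None
    if rec["cds"]:
        biotype = "protein_coding"
    elif biotype == "other" and not raw:
        biotype = "other"

    t = TranscriptModel(
        transcript_id=tid,
        gene_id=rec["gene_id"],
        gene_name=rec["gene_name"],
        contig=rec["contig"],
        strand=rec["strand"],
        exons=exons,
        cds_span=None,
        biotype=biotype if rec["cds"] else (biotype if biotype != "protein_coding" else "other"),
    )

    if not rec["cds"]:
        return t

    # project CDS intervals to transcript coordinates and require contiguity
    cds = sorted(rec["cds"])
    total = sum(e - s for s, e in cds)
    tpositions = []
    for s, e in cds:
        a = genomic_to_transcript(t, s)
        b = genomic_to_transcript(t, e - 1)
        if a is None or b is None:
            raise AnnotationError(f"{tid}: CDS [{s},{e}) not contained in exons")
        tpositions.extend((a, b))
    cs, ce = min(tpositions), max(tpositions) + 1
    if ce - cs != total:
        raise AnnotationError(f"{tid}: CDS intervals not contiguous on the transcript")
    if total % 3 != 0:
        raise AnnotationError(f"{tid}: CDS length {total} not divisible by 3")

    seq = spliced_sequence(t, genome)
    if seq[ce - 3 : ce] not in STOP_CODONS:
        # GTF dialects that exclude the stop codon: extend when the next
        # in-frame codon is a stop, otherwise the CDS is incomplete.
        nxt = seq[ce : ce + 3]
        if nxt in STOP_CODONS:
            ce += 3
        else:
            raise AnnotationError(
                f"{tid}: CDS has no stop codon (incomplete CDS rejected)"
            )
    inner = seq[cs : ce - 3]
    if any(inner[i : i + 3] in STOP_CODONS for i in range(0, len(inner) - 2, 3)):
        raise AnnotationError(f"{tid}: internal stop codon in annotated CDS")

    return TranscriptModel(
        transcript_id=tid,
        gene_id=rec["gene_id"],
        gene_name=rec["gene_name"],
        contig=rec["contig"],
        strand=rec["strand"],
        exons=exons,
        cds_span=(cs, ce),
        biotype="protein_coding",
    )


def load_annotation(
    gtf_path: str | Path, genome: GenomeBuild
) -> list[TranscriptModel]:
    """Parse a GTF and return the transcripts that satisfy all invariants.

    Rejected transcripts (CDS outside exons, non-contiguous or incomplete
    CDS) are logged; use :func:`parse_transcripts` to obtain the rejection
    report programmatically.
    """
    kept, _rejected = parse_transcripts(gtf_path, genome)
    return kept
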