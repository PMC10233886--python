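"""Enumeration and classification of non-canonical ORFs (ncORFs).

An ncORF is an AUG-initiated reading-frame segment on the spliced transcript
that reaches an in-frame stop and does not coincide with the annotated
canonical CDS.  ORFs on protein-coding transcripts are classified by their
position relative to the canonical CDS:

* ``uORF_5utr``   — entirely 5' of the CDS (upstream ORF);
* ``dORF_3utr``   — entirely 3' of the CDS (downstream ORF);
* ``out_of_frame``— overlapping the CDS in a shifted reading frame;
* same-frame CDS overlaps are canonical/isoform sequence and are discarded.

ORFs on noncoding transcripts are ``ncRNA`` (or ``miscRNA`` for misc_RNA /
rRNA biotypes).  One ORF is reported per (stop codon, frame): the 5'-most
AUG, i.e. the longest variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .annotation import (
    GenomeBuild,
    TranscriptModel,
    spliced_sequence,
    translate_frame,
)

log = logging.getLogger(__name__)

CATEGORIES = ("uORF_5utr", "dORF_3utr", "out_of_frame", "ncRNA", "miscRNA")

START_CODON = "ATG"
_STOPS = ("TAA", "TAG", "TGA")

#: default minimum ORF length in codons (stop excluded); tunable down to 8
#: for immunopeptide-scale ORFs
DEFAULT_MIN_CODONS = 30


@dataclass(frozen=True)
class ORFRecord:
    """One enumerated ncORF on one transcript.

    ``t_start``/``t_end`` span start codon through end of stop codon in
    transcript coordinates (0-based half-open); ``codon_length`` excludes
    the stop.
    """

    orf_id: str
    transcript_id: str
    gene_id: str
    category: Optional[str]
    t_start: int
    t_end: int
    frame_offset: int
    codon_length: int
    protein: str

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != 3 * (self.codon_length + 1):
            raise ValueError(
                f"{self.orf_id}: span {self.t_end - self.t_start} != "
                f"3*({self.codon_length}+1)"
            )
        if not self.protein.startswith("M"):
            raise ValueError(f"{self.orf_id}: protein does not start with M")
        if "*" in self.protein:
            raise ValueError(f"{self.orf_id}: internal stop in protein")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"{self.orf_id}: unknown category {self.category!r}")


def make_orf_id(transcript_id: str, t_start: int, frame_offset: int) -> str:
    return f"{transcript_id}:{t_start}:{frame_offset}"


def enumerate_orfs(
    t: TranscriptModel,
    genome: GenomeBuild,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> list[ORFRecord]:
    """All AUG->stop ORFs of >= ``min_codons`` codons on the spliced transcript.

    One ORF per (stop, frame), keeping the 5'-most AUG.  The annotated
    canonical CDS itself is never returned.  Categories are left unset; see
    :func:`classify_orf` / :func:`enumerate_and_classify`.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    seq = spliced_sequence(t, genome)
    out: list[ORFRecord] = []
    for frame in range(3):
        pending: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if pending is not None:
                    n_codons = (i - pending) // 3
                    start, end = pending, i + 3
                    pending = None
                    if n_codons < min_codons:
                        continue
                    if t.cds_span == (start, end):
                        continue  # the canonical CDS is not an ncORF
                    protein = translate_frame(seq[start:end], 0)
                    out.append(
                        ORFRecord(
                            orf_id=make_orf_id(t.transcript_id, start, start % 3),
                            transcript_id=t.transcript_id,
                            gene_id=t.gene_id,
                            category=None,
                            t_start=start,
                            t_end=end,
                            frame_offset=start % 3,
                            codon_length=n_codons,
                            protein=protein,
                        )
                    )
            elif codon == START_CODON and pending is None:
                pending = i
    out.sort(key=lambda o: (o.t_start, o.frame_offset))
    return out


def classify_orf(orf: ORFRecord, t: TranscriptModel) -> Optional[str]:
    """Category of an enumerated ORF, or ``None`` when it must be discarded.

    Same-frame overlap with the canonical CDS means the ORF is canonical or
    isoform sequence, not an ncORF; those return ``None``.  Overlap with the
    CDS dominates the UTR classes: an ORF starting in a UTR and running
    out-of-frame into the CDS is ``out_of_frame``.
    """
    if t.cds_span is None:
        return "miscRNA" if t.biotype in ("misc_RNA", "rRNA") else "ncRNA"
    cs, ce = t.cds_span
    if orf.t_end <= cs:
        return "uORF_5utr"
    if orf.t_start >= ce:
        return "dORF_3utr"
    # overlapping the CDS: frame decides
    if (orf.t_start - cs) % 3 == 0:
        return None
    return "out_of_frame"


def enumerate_and_classify(
    t: TranscriptModel,
    genome: GenomeBuild,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> list[ORFRecord]:
    """Enumerate ORFs and attach categories, dropping same-frame isoforms."""
    out = []
    for orf in enumerate_orfs(t, genome, min_codons):
        cat = classify_orf(orf, t)
        if cat is not None:
            out.append(replace(orf, category=cat))
    return out


def deduplicate_orfs(
    orfs: Iterable[ORFRecord],
) -> tuple[list[ORFRecord], dict[str, list[str]]]:
    """Collapse ORFs with identical protein sequences.

    Returns one representative per distinct protein (the lexicographically
    smallest ``orf_id``) and a redundancy map representative_orf_id ->
    sorted list of all source orf_ids (the representative included).
    """
    by_protein: dict[str, list[ORFRecord]] = {}
    for orf in orfs:
        by_protein.setdefault(orf.protein, []).append(orf)
    representatives: list[ORFRecord] = []
    redundancy: dict[str, list[str]] = {}
    for members in by_protein.values():
        members.sort(key=lambda o: o.orf_id)
        rep = members[0]
        representatives.append(rep)
        redundancy[rep.orf_id] = [m.orf_id for m in members]
    representatives.sort(key=lambda o: o.orf_id)
    return representatives, redundancy


def category_counts(orfs: Iterable[ORFRecord]) -> dict[str, int]:
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    for orf in orfs:
        if orf.category is None:
            raise ValueError(f"{orf.orf_id} is unclassified")
        counts[orf.category] += 1
    return counts


# ---------------------------------------------------------------------------
# tabular / FASTA output
# ---------------------------------------------------------------------------

def orf_accession(orf: ORFRecord) -> str:
    return f"ncorf|{orf.orf_id}|{orf.category}"


def orfs_to_frame(orfs: Iterable[ORFRecord]) -> pd.DataFrame:
    rows = [
        {
            "orf_id": o.orf_id,
            "transcript_id": o.transcript_id,
            "gene": o.gene_id,
            "category": o.category,
            "t_start": o.t_start,
            "t_end": o.t_end,
            "codon_length": o.codon_length,
        }
        for o in orfs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "transcript_id",
            "gene",
            "category",
            "t_start",
            "t_end",
            "codon_length",
        ],
    )


def write_orf_table(orfs: Iterable[ORFRecord], path: str | Path) -> None:
    orfs_to_frame(orfs).to_csv(path, sep="\t", index=False)


def write_orf_fasta(orfs: Iterable[ORFRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(o.protein), id=orf_accession(o), description="")
        for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")
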