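"""Frame-aware re-annotation of somatic variants in non-canonical ORFs.

A somatic variant annotated as silent, UTR, flank, intronic or RNA in the
canonical reading frame can still alter the protein of an overlapping ncORF
read in a shifted frame.  This module projects variants through the
transcript onto ORF-local codons, calls the ncORF-frame consequence, and
cross-classifies each variant into three groups:

* group 1 — canonical-noncoding variant (UTR/flank/intron/splice/RNA)
  altering an ncORF protein;
* group 2 — variant inside a region shared by the canonical CDS and an
  ncORF (canonical missense or silent) altering the ncORF protein;
* group 3 — variant overlapping an ncORF without changing any ncORF protein
  (silent in the shifted frame, or a retained stop).

Internal variant representation is 0-based with trimmed alleles: SNVs have
single-base ref/alt, deletions have ``alt == ""``, insertions have
``ref == ""`` (the insertion point is *before* ``pos``).  MAF (GDC dialect)
and VCF 4.x are converted at the parse boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import (
    GenomeBuild,
    TranscriptModel,
    genomic_to_transcript,
    reverse_complement,
    spliced_sequence,
    transcript_interval_to_genomic,
    translate_frame,
    CODON_TABLE,
    STOP_CODONS,
)
from .orfs import ORFRecord

log = logging.getLogger(__name__)

CANONICAL_CLASSES = (
    "missense",
    "silent",
    "stop_gained",
    "stop_lost",
    "frameshift",
    "inframe_indel",
    "utr5",
    "utr3",
    "flank5",
    "flank3",
    "intron",
    "splice_region",
    "rna",
    "other",
)

NCORF_CLASSES = (
    "missense",
    "silent",
    "frameshift_ins",
    "frameshift_del",
    "inframe_ins",
    "inframe_del",
    "stop_gained",
    "stop_lost",
    "none",
)

#: ncORF-frame classes that change the translated protein
ALTERING_NCORF = frozenset(
    {
        "missense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "stop_gained",
        "stop_lost",
    }
)

#: canonical-frame classes that change the canonical protein
ALTERING_CANONICAL = frozenset(
    {"missense", "stop_gained", "stop_lost", "frameshift", "inframe_indel"}
)

#: canonical-frame classes outside the canonical protein
NONCODING_CANONICAL = frozenset(
    {"utr5", "utr3", "flank5", "flank3", "intron", "splice_region", "rna", "other"}
)

GROUPS = ("1_utr_derived", "2_overlap_canonical", "3_canonical_only")


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant, 0-based with trimmed alleles."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    cohort: str = ""
    canonical_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VariantError("ref and alt must differ")
        if self.ref and self.alt and len(self.ref) != len(self.alt):
            raise VariantError(
                "complex substitutions are not supported; normalize to "
                "SNV / pure insertion / pure deletion first"
            )
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise VariantError("multi-nucleotide substitutions are not supported")
        if self.canonical_class is not None and self.canonical_class not in CANONICAL_CLASSES:
            raise VariantError(f"unknown canonical class {self.canonical_class!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return self.ref == ""

    @property
    def is_deletion(self) -> bool:
        return self.alt == ""

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref or '-'}>{self.alt or '-'}:{self.sample_id}"


@dataclass(frozen=True)
class NcorfConsequence:
    variant: VariantRecord
    orf_id: str
    ncorf_class: str
    protein_change: str = ""
    figure4a_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ncorf_class not in NCORF_CLASSES:
            raise VariantError(f"unknown ncORF class {self.ncorf_class!r}")
        if self.ncorf_class in ("silent", "none") and self.protein_change:
            raise VariantError("protein_change must be empty for silent/none")


def check_reference(v: VariantRecord, genome: GenomeBuild) -> None:
    """Hard error when the stated reference allele disagrees with the genome."""
    if not v.ref:
        return
    observed = genome.fetch(v.contig, v.pos, v.pos + len(v.ref))
    if observed != v.ref:
        raise VariantError(
            f"{v.key}: reference allele {v.ref!r} does not match genome "
            f"({observed!r}); corrupt input"
        )


def left_normalize(v: VariantRecord, genome: GenomeBuild) -> VariantRecord:
    """Shift a pure indel to its smallest genomic coordinate.

    Standard left-alignment: while the base preceding the event equals the
    last base of the inserted/deleted sequence, rotate the allele one base
    left.  SNVs are returned unchanged.
    """
    if v.is_snv:
        return v
    pos, ref, alt = v.pos, v.ref, v.alt
    seq = genome.contigs[v.contig]
    allele = ref or alt
    while pos > 0 and seq[pos - 1] == allele[-1]:
        allele = seq[pos - 1] + allele[:-1]
        pos -= 1
    if ref:
        ref = allele
    else:
        alt = allele
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# transcript-space edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptEdit:
    """A variant expressed on the spliced transcript (5'->3' strand-correct).

    Apply as ``seq[:t_pos] + t_alt + seq[t_pos + len(t_ref):]``.
    """

    t_pos: int
    t_ref: str
    t_alt: str

    def apply(self, seq: str) -> str:
        return seq[: self.t_pos] + self.t_alt + seq[self.t_pos + len(self.t_ref) :]


def transcript_edit(v: VariantRecord, t: TranscriptModel) -> Optional[TranscriptEdit]:
    """Project a genomic variant into transcript space, or ``None``.

    Returns ``None`` for intronic/outside positions and for indels that are
    not fully exonic (a splice-disrupting edit cannot be projected onto the
    spliced sequence without re-splicing).
    """
    minus = t.strand == "-"
    if v.is_snv:
        tpos = genomic_to_transcript(t, v.pos)
        if tpos is None:
            return None
        ref = reverse_complement(v.ref) if minus else v.ref
        alt = reverse_complement(v.alt) if minus else v.alt
        return TranscriptEdit(tpos, ref, alt)
    if v.is_deletion:
        tpositions = []
        for g in range(v.pos, v.pos + len(v.ref)):
            tp = genomic_to_transcript(t, g)
            if tp is None:
                return None
            tpositions.append(tp)
        lo, hi = min(tpositions), max(tpositions) + 1
        if hi - lo != len(v.ref):
            return None  # deletion spans a splice junction
        ref = reverse_complement(v.ref) if minus else v.ref
        return TranscriptEdit(lo, ref, "")
    # insertion between genomic pos-1 and pos
    if not minus:
        tpos = genomic_to_transcript(t, v.pos)
        if tpos is None:
            return None
        return TranscriptEdit(tpos, "", v.alt)
    tp = genomic_to_transcript(t, v.pos)
    if tp is None:
        return None
    return TranscriptEdit(tp + 1, "", reverse_complement(v.alt))


def project_variant(
    v: VariantRecord, orf: ORFRecord, t: TranscriptModel
) -> Optional[tuple[int, int]]:
    """ORF-local (codon index, within-codon offset) of the first affected
    base, or ``None`` when the variant does not touch the ORF footprint."""
    edit = transcript_edit(v, t)
    if edit is None:
        return None
    first = _first_affected(edit, orf)
    if first is None:
        return None
    rel = first - orf.t_start
    return rel // 3, rel % 3


def _first_affected(edit: TranscriptEdit, orf: ORFRecord) -> Optional[int]:
    """First transcript position inside the ORF touched by the edit."""
    if edit.t_ref:  # SNV or deletion: half-open interval
        lo = max(edit.t_pos, orf.t_start)
        hi = min(edit.t_pos + len(edit.t_ref), orf.t_end)
        return lo if lo < hi else None
    # insertion: alters the ORF only when strictly inside it
    if orf.t_start < edit.t_pos < orf.t_end:
        return edit.t_pos
    return None


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------

def _interval_consequence(
    edit: TranscriptEdit, seq: str, start: int, end: int
) -> tuple[str, str]:
    """(class, protein_change) of an edit on the reading frame [start, end).

    ``end`` includes the stop codon.  SNVs are resolved by before/after
    codon comparison; indels by net length mod 3.  Classes use the ncORF
    vocabulary (frameshift_ins/del, inframe_ins/del).
    """
    first = _first_affected(edit, _span_stub(start, end))
    if first is None:
        return "none", ""
    if edit.t_ref and edit.t_alt:  # SNV
        rel = first - start
        ci, off = rel // 3, rel % 3
        old_codon = seq[start + 3 * ci : start + 3 * ci + 3]
        new_codon = old_codon[:off] + edit.t_alt + old_codon[off + 1 :]
        in_stop = start + 3 * ci >= end - 3
        old_is_stop = old_codon in STOP_CODONS
        new_is_stop = new_codon in STOP_CODONS
        if in_stop or old_is_stop:
            if new_is_stop:
                return "silent", ""  # retained stop
            new_aa = CODON_TABLE.get(new_codon, "X")
            return "stop_lost", f"p.*{ci + 1}{new_aa}ext"
        if new_is_stop:
            old_aa = CODON_TABLE.get(old_codon, "X")
            return "stop_gained", f"p.{old_aa}{ci + 1}*"
        old_aa = CODON_TABLE.get(old_codon, "X")
        new_aa = CODON_TABLE.get(new_codon, "X")
        if old_aa == new_aa:
            return "silent", ""
        return "missense", f"p.{old_aa}{ci + 1}{new_aa}"
    # indel: only the bases falling inside the frame shift it
    if edit.t_ref:  # deletion
        within = min(edit.t_pos + len(edit.t_ref), end) - max(edit.t_pos, start)
        net = -within
    else:
        net = len(edit.t_alt)
    ci = (first - start) // 3
    kind = "ins" if net > 0 else "del"
    if abs(net) % 3 != 0:
        return f"frameshift_{kind}", f"p.X{ci + 1}fs"
    return f"inframe_{kind}", f"p.{ci + 1}{kind}"


class _span_stub:
    """Duck-typed ORF span for :func:`_first_affected`."""

    __slots__ = ("t_start", "t_end")

    def __init__(self, start: int, end: int) -> None:
        self.t_start, self.t_end = start, end


def call_ncorf_consequence(
    v: VariantRecord,
    orf: ORFRecord,
    t: TranscriptModel,
    genome: GenomeBuild,
) -> NcorfConsequence:
    """Consequence of a variant in the reading frame of one ncORF."""
    check_reference(v, genome)
    edit = transcript_edit(v, t)
    if edit is None:
        return NcorfConsequence(v, orf.orf_id, "none")
    seq = spliced_sequence(t, genome)
    if edit.t_ref and seq[edit.t_pos : edit.t_pos + len(edit.t_ref)] != edit.t_ref:
        raise VariantError(
            f"{v.key}: projected reference mismatch on {t.transcript_id}"
        )
    cls, change = _interval_consequence(edit, seq, orf.t_start, orf.t_end)
    return NcorfConsequence(v, orf.orf_id, cls, change)


def compute_canonical_class(
    v: VariantRecord, t: TranscriptModel, genome: GenomeBuild
) -> str:
    """Canonical-frame class of a variant relative to one transcript.

    Used when the MAF does not carry a trusted annotation.  Exonic variants
    in the CDS are classified with the same codon engine used for ncORFs;
    splice-region means within 2 nt of an exon boundary inside an intron.
    """
    edit = transcript_edit(v, t)
    if edit is None:
        lo, hi = t.span
        if lo <= v.pos < hi:
            near_edge = any(
                0 < s - v.pos <= 2 or 0 <= v.pos - e < 2 for s, e in t.exons
            )
            return "splice_region" if near_edge else "intron"
        upstream = v.pos < lo
        if t.strand == "-":
            upstream = not upstream
        return "flank5" if upstream else "flank3"
    if t.cds_span is None:
        return "rna"
    cs, ce = t.cds_span
    seq = spliced_sequence(t, genome)
    cls, _change = _interval_consequence(edit, seq, cs, ce)
    if cls == "none":
        anchor = edit.t_pos if (edit.t_ref or edit.t_alt) else edit.t_pos
        return "utr5" if anchor < cs else "utr3"
    return {
        "missense": "missense",
        "silent": "silent",
        "stop_gained": "stop_gained",
        "stop_lost": "stop_lost",
        "frameshift_ins": "frameshift",
        "frameshift_del": "frameshift",
        "inframe_ins": "inframe_indel",
        "inframe_del": "inframe_indel",
    }[cls]


def cross_classify(canonical_class: str, ncorf_class: str) -> str:
    """Three-way group of one variant given both frame annotations."""
    if canonical_class not in CANONICAL_CLASSES:
        raise VariantError(f"unknown canonical class {canonical_class!r}")
    altered = ncorf_class in ALTERING_NCORF
    if not altered:
        return "3_canonical_only"
    if canonical_class in NONCODING_CANONICAL:
        return "1_utr_derived"
    return "2_overlap_canonical"


# ---------------------------------------------------------------------------
# cohort-level annotation
# ---------------------------------------------------------------------------

#: precedence for collapsing per-ORF classes to one variant-level class
_CLASS_PRIORITY = (
    "frameshift_del",
    "frameshift_ins",
    "stop_gained",
    "stop_lost",
    "inframe_del",
    "inframe_ins",
    "missense",
    "silent",
    "none",
)


def annotate_variants(
    variants: Sequence[VariantRecord],
    orfs: Sequence[ORFRecord],
    transcripts: Mapping[str, TranscriptModel],
    genome: GenomeBuild,
) -> tuple[list[NcorfConsequence], pd.DataFrame]:
    """Call ncORF consequences for every (variant, overlapping ORF) pair.

    Returns the per-pair consequence list and a per-variant summary table
    with one row per variant that overlaps at least one ncORF footprint
    (columns: variant_key, sample_id, cohort, canonical_class, ncorf_class,
    figure4a_group, n_orfs).
    """
    # genomic footprints of every ORF, indexed by contig
    footprints: dict[str, list[tuple[int, int, ORFRecord, TranscriptModel]]] = {}
    for orf in orfs:
        t = transcripts[orf.transcript_id]
        for s, e in transcript_interval_to_genomic(t, orf.t_start, orf.t_end):
            footprints.setdefault(t.contig, []).append((s, e, orf, t))

    pairs: list[NcorfConsequence] = []
    rows: list[dict] = []
    for v in variants:
        v = left_normalize(v, genome)
        check_reference(v, genome)
        span_lo = v.pos - 1
        span_hi = v.pos + max(1, len(v.ref)) + 1
        seen: set[str] = set()
        v_pairs: list[NcorfConsequence] = []
        for s, e, orf, t in footprints.get(v.contig, ()):  # naive scan; fine at study scale
            if e <= span_lo or s >= span_hi or orf.orf_id in seen:
                continue
            seen.add(orf.orf_id)
            v_pairs.append(call_ncorf_consequence(v, orf, t, genome))
        real = [p for p in v_pairs if p.ncorf_class != "none"]
        if not real:
            continue
        canonical = v.canonical_class
        if canonical is None:
            host = transcripts[_orf_transcript(real[0].orf_id)]
            canonical = compute_canonical_class(v, host, genome)
        variant_class = min(
            (p.ncorf_class for p in real), key=_CLASS_PRIORITY.index
        )
        group = cross_classify(canonical, variant_class)
        pairs.extend(
            replace(p, figure4a_group=cross_classify(canonical, p.ncorf_class))
            for p in real
        )
        rows.append(
            {
                "variant_key": v.key,
                "sample_id": v.sample_id,
                "cohort": v.cohort,
                "canonical_class": canonical,
                "ncorf_class": variant_class,
                "figure4a_group": group,
                "n_orfs": len(real),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "sample_id",
            "cohort",
            "canonical_class",
            "ncorf_class",
            "figure4a_group",
            "n_orfs",
        ],
    )
    return pairs, summary


def _orf_transcript(orf_id: str) -> str:
    return orf_id.rsplit(":", 2)[0]


def figure4a_tallies(summary: pd.DataFrame) -> dict[str, int]:
    """Group and class tallies over the per-variant summary table.

    The structural identity: the per-class counts of protein-altering
    variants (missense + frameshift + stop_gained + stop_lost + inframe)
    sum to the total count of ncORF-altering variants.
    """
    altered = summary[summary["ncorf_class"].isin(ALTERING_NCORF)]
    out = {g: int((summary["figure4a_group"] == g).sum()) for g in GROUPS}
    out["n_overlapping"] = len(summary)
    out["n_altering"] = len(altered)
    for cls in ("missense", "stop_gained", "stop_lost"):
        out[cls] = int((altered["ncorf_class"] == cls).sum())
    out["frameshift"] = int(
        altered["ncorf_class"].isin(["frameshift_ins", "frameshift_del"]).sum()
    )
    out["inframe"] = int(
        altered["ncorf_class"].isin(["inframe_ins", "inframe_del"]).sum()
    )
    return out


def mutation_burden(
    summary_all: pd.DataFrame, region_size_mb: float = 38.0
) -> pd.DataFrame:
    """Per-sample variants/Mb in canonical and ncORF-only scopes.

    ``summary_all`` needs columns sample_id, cohort, canonical_class and
    ncorf_class (one row per variant).  Canonical scope counts variants with
    protein-altering canonical classes; ncORF-only scope counts variants
    whose *only* protein-altering consequence is in an ncORF.  The default
    denominator (38 Mb) is a typical exome target size.
    """
    if region_size_mb <= 0:
        raise ValueError("region_size_mb must be > 0")
    df = summary_all.copy()
    df["canonical_altering"] = df["canonical_class"].isin(ALTERING_CANONICAL)
    df["ncorf_altering"] = df["ncorf_class"].isin(ALTERING_NCORF)
    df["ncorf_only"] = df["ncorf_altering"] & ~df["canonical_altering"]
    grouped = df.groupby(["sample_id", "cohort"], sort=True).agg(
        canonical_count=("canonical_altering", "sum"),
        ncorf_only_count=("ncorf_only", "sum"),
    )
    grouped["canonical_per_mb"] = grouped["canonical_count"] / region_size_mb
    grouped["ncorf_only_per_mb"] = grouped["ncorf_only_count"] / region_size_mb
    return grouped.reset_index()


# ---------------------------------------------------------------------------
# MAF / VCF I/O
# ---------------------------------------------------------------------------

_MAF_CLASS = {
    "missense": "Missense_Mutation",
    "silent": "Silent",
    "stop_gained": "Nonsense_Mutation",
    "stop_lost": "Nonstop_Mutation",
    "frameshift": "Frame_Shift_Indel",
    "inframe_indel": "In_Frame_Indel",
    "utr5": "5'UTR",
    "utr3": "3'UTR",
    "flank5": "5'Flank",
    "flank3": "3'Flank",
    "intron": "Intron",
    "splice_region": "Splice_Region",
    "rna": "RNA",
    "other": "Targeted_Region",
}
_MAF_CLASS_INV = {v: k for k, v in _MAF_CLASS.items()}
_MAF_CLASS_INV.update(
    {
        "Frame_Shift_Del": "frameshift",
        "Frame_Shift_Ins": "frameshift",
        "In_Frame_Del": "inframe_indel",
        "In_Frame_Ins": "inframe_indel",
        "Splice_Site": "splice_region",
        "Nonstop_Mutation": "stop_lost",
    }
)

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
    "cohort",
]


def write_maf(
    variants: Sequence[VariantRecord], path: str | Path, genes: Optional[Sequence[str]] = None
) -> None:
    rows = []
    for i, v in enumerate(variants):
        gene = genes[i] if genes else ""
        if v.is_snv:
            start, end, ref, alt, vtype = v.pos + 1, v.pos + 1, v.ref, v.alt, "SNP"
        elif v.is_deletion:
            start, end, ref, alt, vtype = v.pos + 1, v.pos + len(v.ref), v.ref, "-", "DEL"
        else:
            start, end, ref, alt, vtype = v.pos, v.pos + 1, "-", v.alt, "INS"
        rows.append(
            {
                "Hugo_Symbol": gene,
                "Chromosome": v.contig,
                "Start_Position": start,
                "End_Position": end,
                "Reference_Allele": ref,
                "Tumor_Seq_Allele2": alt,
                "Variant_Classification": _MAF_CLASS.get(v.canonical_class or "other", ""),
                "Variant_Type": vtype,
                "Tumor_Sample_Barcode": v.sample_id,
                "cohort": v.cohort,
            }
        )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a GDC-dialect MAF (with our extra ``cohort`` column)."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    out: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        ref = "" if row.Reference_Allele in ("-", "") else str(row.Reference_Allele)
        alt = "" if row.Tumor_Seq_Allele2 in ("-", "") else str(row.Tumor_Seq_Allele2)
        if ref == "":  # insertion: Start_Position is the base before
            pos = int(row.Start_Position)
        else:
            pos = int(row.Start_Position) - 1
        cls = _MAF_CLASS_INV.get(str(row.Variant_Classification))
        out.append(
            VariantRecord(
                contig=str(row.Chromosome),
                pos=pos,
                ref=ref,
                alt=alt,
                sample_id=str(row.Tumor_Sample_Barcode),
                cohort=str(getattr(row, "cohort", "")),
                canonical_class=cls,
            )
        )
    return out


def read_vcf(
    path: str | Path, sample_id: str = "", cohort: str = ""
) -> list[VariantRecord]:
    """Read VCF 4.x; multi-allelic records are an error (normalize first)."""
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise VariantError(
                f"{rec.CHROM}:{rec.POS}: multi-allelic record; split/normalize "
                "with `bcftools norm` first"
            )
        pos, ref, alt = rec.POS - 1, rec.REF, rec.ALT[0]
        # trim shared prefix (VCF anchor base), then shared suffix
        while ref and alt and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        while ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        out.append(
            VariantRecord(
                contig=rec.CHROM,
                pos=pos,
                ref=ref,
                alt=alt,
                sample_id=sample_id,
                cohort=cohort,
            )
        )
    return out


def write_consequence_table(
    pairs: Sequence[NcorfConsequence], path: str | Path
) -> None:
    rows = [
        {
            "variant_key": p.variant.key,
            "sample_id": p.variant.sample_id,
            "cohort": p.variant.cohort,
            "orf_id": p.orf_id,
            "ncorf_class": p.ncorf_class,
            "protein_change": p.protein_change,
            "figure4a_group": p.figure4a_group or "",
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "variant_key",
            "sample_id",
            "cohort",
            "orf_id",
            "ncorf_class",
            "protein_change",
            "figure4a_group",
        ],
    ).to_csv(path, sep="\t", index=False)
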