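"""Mutated proteomes and MHC-I epitope / neoantigen prioritization.

Per-sample mutated non-canonical proteomes are built from eligible somatic
variants (canonical-silent variants hitting out-of-frame ncORFs, and
variants outside the canonical CDS footprint altogether), candidate
peptides are stripped of anything explainable by wildtype sequence, and
surviving MHC-bound candidates pass through a prioritization cascade:

* binding affinity  <= 150 nM  (high-affinity gate, always required);
* retention-time error < 5 min (observed vs predicted), OR
* normal-tissue expression < 1 TPM (GTEx-style median).

Unmutated ncORF peptides passing the gate are "epitopes"; mutated-proteome
peptides are "neoantigens" (the ``mutated`` flag distinguishes them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import (
    GenomeBuild,
    TranscriptModel,
    spliced_sequence,
    translate_frame,
)
from .orfs import ORFRecord
from .searchdb import DigestSpec, ProteinDBEntry, digest, il_collapse
from .variants import (
    ALTERING_NCORF,
    NONCODING_CANONICAL,
    NcorfConsequence,
    TranscriptEdit,
    transcript_edit,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutatedProtein:
    """One ncORF protein re-translated with a sample's eligible variants."""

    orf_id: str
    sample_id: str
    wt_protein: str
    mut_protein: str
    variant_ids: tuple[str, ...]
    changed_interval: tuple[int, int]  # protein coords on mut_protein

    def __post_init__(self) -> None:
        if self.mut_protein == self.wt_protein:
            raise ValueError(f"{self.orf_id}/{self.sample_id}: no protein change")
        lo, hi = self.changed_interval
        if not (0 <= lo < hi <= len(self.mut_protein)):
            raise ValueError(
                f"{self.orf_id}/{self.sample_id}: bad changed_interval "
                f"{self.changed_interval}"
            )


@dataclass
class EpitopeCandidate:
    """A peptide with MHC-binding, RT, and expression evidence."""

    peptide: str
    orf_id: str
    sample_id: str
    hla_allele: str
    affinity_nM: float
    percentile_rank: Optional[float] = None
    rt_observed_min: Optional[float] = None
    rt_predicted_min: Optional[float] = None
    gtex_median_tpm: Optional[float] = None
    mutated: bool = False
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.affinity_nM <= 0:
            raise ValueError("affinity_nM must be positive")

    @property
    def rt_error_min(self) -> Optional[float]:
        if self.rt_observed_min is None or self.rt_predicted_min is None:
            return None
        return retention_time_error(self.rt_observed_min, self.rt_predicted_min)


def is_eligible_for_mutated_proteome(
    cons: NcorfConsequence, orf_category: str
) -> bool:
    """Eligibility rule for the per-sample mutated proteome.

    A variant contributes when it alters the ncORF protein AND either
    (a) it is silent in the canonical frame while the ncORF is out-of-frame
    (the class of variant that canonical pipelines discard), or (b) it lies
    outside the canonical CDS footprint entirely (UTR/flank/intron/RNA).
    """
    if cons.ncorf_class not in ALTERING_NCORF:
        return False
    canonical = cons.variant.canonical_class
    if canonical == "silent" and orf_category == "out_of_frame":
        return True
    return canonical in NONCODING_CANONICAL


def build_mutated_proteome(
    consequences: Sequence[NcorfConsequence],
    orfs: Mapping[str, ORFRecord],
    transcripts: Mapping[str, TranscriptModel],
    genome: GenomeBuild,
) -> list[MutatedProtein]:
    """Apply each sample's eligible variants jointly per ORF and re-translate.

    Variants for one (sample, ORF) are applied in genomic order (via their
    transcript positions, 3'-most first so earlier offsets stay valid);
    frameshifts re-translate to the next stop.  Overlapping edits within one
    sample conflict and the (sample, ORF) record is rejected with a log
    entry.
    """
    groups: dict[tuple[str, str], list[NcorfConsequence]] = {}
    for cons in consequences:
        orf = orfs.get(cons.orf_id)
        if orf is None or orf.category is None:
            continue
        if not is_eligible_for_mutated_proteome(cons, orf.category):
            continue
        groups.setdefault((cons.variant.sample_id, cons.orf_id), []).append(cons)

    out: list[MutatedProtein] = []
    for (sample_id, orf_id), members in sorted(groups.items()):
        orf = orfs[orf_id]
        t = transcripts[orf.transcript_id]
        seq = spliced_sequence(t, genome)
        edits: list[tuple[TranscriptEdit, str]] = []
        for cons in members:
            edit = transcript_edit(cons.variant, t)
            if edit is not None:
                edits.append((edit, cons.variant.key))
        if not edits:
            continue
        edits.sort(key=lambda ev: ev[0].t_pos, reverse=True)
        if _edits_conflict([e for e, _ in edits]):
            log.warning(
                "conflicting overlapping variants for %s in sample %s; rejected",
                orf_id,
                sample_id,
            )
            continue
        mut_seq = seq
        for edit, _key in edits:
            mut_seq = edit.apply(mut_seq)
        mut_protein = translate_frame(mut_seq[orf.t_start :], 0)
        wt_protein = orf.protein
        if mut_protein == wt_protein:
            continue
        out.append(
            MutatedProtein(
                orf_id=orf_id,
                sample_id=sample_id,
                wt_protein=wt_protein,
                mut_protein=mut_protein,
                variant_ids=tuple(sorted(key for _, key in edits)),
                changed_interval=_diff_interval(wt_protein, mut_protein),
            )
        )
    return out


def _edits_conflict(edits: Sequence[TranscriptEdit]) -> bool:
    spans = sorted(
        (e.t_pos, e.t_pos + max(1, len(e.t_ref))) for e in edits
    )
    for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
        if s2 < e1:
            return True
    return False


def _diff_interval(wt: str, mut: str) -> tuple[int, int]:
    """Protein coordinates of the altered region on the mutant sequence."""
    lo = 0
    while lo < min(len(wt), len(mut)) and wt[lo] == mut[lo]:
        lo += 1
    if len(wt) == len(mut):
        hi = len(mut)
        while hi > lo and wt[hi - 1] == mut[hi - 1]:
            hi -= 1
    else:
        hi = len(mut)  # length change: altered through the new C terminus
    if lo == hi:  # pure C-terminal truncation: mark the last mutant residue
        lo, hi = max(0, len(mut) - 1), len(mut)
    return lo, hi


def mutated_accession(mp: MutatedProtein) -> str:
    return f"ncorf|{mp.orf_id}|mut|{mp.sample_id}"


def write_mutated_fasta(
    proteins: Iterable[MutatedProtein], path: str | Path
) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (
            SeqRecord(Seq(mp.mut_protein), id=mutated_accession(mp), description="")
            for mp in proteins
        ),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# wildtype elimination
# ---------------------------------------------------------------------------

def candidate_peptides(
    proteins: Iterable[MutatedProtein], spec: DigestSpec
) -> list[tuple[str, MutatedProtein]]:
    """Digestion products of mutated proteins that span the changed region."""
    out: list[tuple[str, MutatedProtein]] = []
    for mp in proteins:
        lo, hi = mp.changed_interval
        for start, pep in digest(mp.mut_protein, spec):
            if start < hi and start + len(pep) > lo:
                out.append((pep, mp))
    return out


def eliminate_wildtype_matches(
    candidates: Sequence[tuple[str, MutatedProtein]],
    wildtype_db: Sequence[ProteinDBEntry],
) -> list[tuple[str, MutatedProtein]]:
    """Drop candidate peptides explainable by any wildtype protein.

    A peptide is removed when it occurs (I=L equivalent) as a substring of
    any canonical or unmutated ncORF protein; retained peptides must span
    the changed interval of their mutated protein (enforced again here so
    the output is safe regardless of how candidates were produced).
    """
    wt_il = [il_collapse(e.sequence) for e in wildtype_db if e.origin != "decoy"]
    retained: list[tuple[str, MutatedProtein]] = []
    for pep, mp in candidates:
        lo, hi = mp.changed_interval
        start = mp.mut_protein.find(pep)
        spans = False
        while start != -1:
            if start < hi and start + len(pep) > lo:
                spans = True
                break
            start = mp.mut_protein.find(pep, start + 1)
        if not spans:
            continue
        pep_il = il_collapse(pep)
        if any(pep_il in wt for wt in wt_il):
            continue
        retained.append((pep, mp))
    return retained


# ---------------------------------------------------------------------------
# retention time and hydrophobicity
# ---------------------------------------------------------------------------

def retention_time_error(observed_min: float, predicted_min: float) -> float:
    """Absolute difference between observed and predicted RT, in minutes."""
    if not (math.isfinite(observed_min) and math.isfinite(predicted_min)):
        raise ValueError("observed and predicted RT must be finite")
    return abs(observed_min - predicted_min)


#: additive per-residue retention coefficients (reversed-phase HPLC, TFA
#: system; Guo-style values). Units are arbitrary retention units.
RETENTION_COEFFICIENTS: dict[str, float] = {
    "W": 8.8, "F": 8.1, "L": 8.1, "I": 7.4, "M": 5.5, "V": 5.0,
    "Y": 4.5, "C": 2.6, "A": 2.0, "P": 2.0, "E": 1.1, "T": 0.6,
    "D": 0.2, "Q": 0.0, "S": -0.2, "G": -0.2, "R": -0.6, "N": -0.6,
    "H": -2.1, "K": -2.1,
}


def hydrophobicity_index(
    peptide: str,
    coefficients: Optional[Mapping[str, float]] = None,
    length_norm: float = 1.0,
) -> float:
    """Additive hydrophobicity index of a peptide.

    Sum of per-residue retention coefficients scaled by a multiplicative
    length-normalization factor (default 1.0, i.e. the raw sum).  Used only
    for RT-vs-hydrophobicity QC, never as a hard filter; externally
    predicted values take precedence when supplied alongside candidates.
    """
    coeffs = RETENTION_COEFFICIENTS if coefficients is None else coefficients
    total = 0.0
    for aa in peptide:
        if aa not in coeffs:
            raise ValueError(f"unknown residue {aa!r} in peptide")
        total += coeffs[aa]
    return total * length_norm


# ---------------------------------------------------------------------------
# prioritization cascade
# ---------------------------------------------------------------------------

def prioritize_epitopes(
    candidates: Sequence[EpitopeCandidate],
    affinity_max: float = 150.0,
    rt_max: float = 5.0,
    tpm_max: float = 1.0,
    rank_max: Optional[float] = None,
) -> tuple[list[EpitopeCandidate], list[EpitopeCandidate]]:
    """Flag candidates and produce the ranked report.

    Flags: ``affinity_pass`` iff affinity <= ``affinity_max`` nM (or, when
    ``rank_max`` is given, percentile rank <= ``rank_max`` as the
    alternative criterion); ``rt_pass`` iff RT error < ``rt_max`` minutes
    (candidates lacking RT measurements neither pass nor fail — the
    expression route remains open); ``gtex_pass`` iff normal-tissue median
    expression < ``tpm_max`` TPM; ``mutated`` marks neoantigens.

    The report is ``affinity_pass AND (rt_pass OR gtex_pass)``, ranked by
    affinity ascending.  Returns (all candidates with flags set, report).
    """
    for c in candidates:
        c.flags.clear()
        aff_ok = c.affinity_nM <= affinity_max
        if not aff_ok and rank_max is not None and c.percentile_rank is not None:
            aff_ok = c.percentile_rank <= rank_max
        if aff_ok:
            c.flags.add("affinity_pass")
        err = c.rt_error_min
        if err is not None and err < rt_max:
            c.flags.add("rt_pass")
        if c.gtex_median_tpm is not None and c.gtex_median_tpm < tpm_max:
            c.flags.add("gtex_pass")
        if c.mutated:
            c.flags.add("mutated")
    report = [
        c
        for c in candidates
        if "affinity_pass" in c.flags
        and ("rt_pass" in c.flags or "gtex_pass" in c.flags)
    ]
    report.sort(key=lambda c: (c.affinity_nM, c.peptide, c.hla_allele))
    return list(candidates), report


def report_to_frame(report: Sequence[EpitopeCandidate]) -> pd.DataFrame:
    rows = [
        {
            "peptide": c.peptide,
            "orf_id": c.orf_id,
            "sample_id": c.sample_id,
            "hla_allele": c.hla_allele,
            "affinity_nM": c.affinity_nM,
            "percentile_rank": c.percentile_rank,
            "rt_error_min": c.rt_error_min,
            "gtex_median_tpm": c.gtex_median_tpm,
            "mutated": c.mutated,
            "flags": ";".join(sorted(c.flags)),
        }
        for c in report
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "orf_id",
            "sample_id",
            "hla_allele",
            "affinity_nM",
            "percentile_rank",
            "rt_error_min",
            "gtex_median_tpm",
            "mutated",
            "flags",
        ],
    )
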