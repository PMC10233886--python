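"""Proteogenomic search-space construction.

Builds the target-decoy database (ncORF proteins + canonical proteome + one
reversed decoy per target, no contaminants), performs in-silico tryptic
digestion (full or semi-tryptic, configurable missed cleavages), and removes
ncORF proteins that are indistinguishable from canonical sequence space.

The canonical-exclusion step is a deterministic substring / shared-peptide
filter under I=L equivalence (isoleucine and leucine are isobaric and cannot
be distinguished by MS); an external aligner's removal list can be supplied
to reproduce alignment-based exclusion exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pyteomics import parser as _pyt_parser

log = logging.getLogger(__name__)

#: cleave C-terminal of K/R except before P
TRYPSIN_RULE = r"[KR](?!P)"

DECOY_PREFIX = "rev_"

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: I and L are isobaric; all peptide-vs-protein matching collapses them
_IL = str.maketrans("L", "I")


def il_collapse(seq: str) -> str:
    """Map a sequence into I=L-collapsed space (L -> I)."""
    return seq.translate(_IL)


@dataclass(frozen=True)
class ProteinDBEntry:
    accession: str
    sequence: str
    origin: str  # canonical | ncorf | decoy
    source_accession: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ("canonical", "ncorf", "decoy"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.origin == "decoy" and not self.accession.startswith(DECOY_PREFIX):
            raise ValueError(f"decoy accession must start with {DECOY_PREFIX!r}")


@dataclass(frozen=True)
class DigestSpec:
    """In-silico digestion settings.

    Defaults follow common proteogenomic search practice: semi-tryptic
    peptides with two missed cleavage sites.
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    mode: str = "semi"  # full | semi
    min_len: int = 7
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin digestion is supported")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.mode not in ("full", "semi"):
            raise ValueError("mode must be 'full' or 'semi'")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def reverse_decoy(entry: ProteinDBEntry) -> ProteinDBEntry:
    """Character-reversed decoy of a target entry."""
    if entry.origin == "decoy":
        raise ValueError(f"refusing to reverse decoy entry {entry.accession}")
    return ProteinDBEntry(
        accession=DECOY_PREFIX + entry.accession,
        sequence=entry.sequence[::-1],
        origin="decoy",
        source_accession=entry.accession,
    )


def digest(sequence: str, spec: DigestSpec) -> list[tuple[int, str]]:
    """Tryptic digestion products of ``sequence`` with start offsets.

    Full mode returns every product with at most ``spec.missed_cleavages``
    internal cleavage sites; semi mode additionally returns every prefix and
    suffix truncation of each fully-tryptic product (one non-tryptic
    terminus).  Products are filtered to ``[min_len, max_len]``.  Peptides
    containing residues outside the 20-letter alphabet (including 'X') are
    dropped and counted in the log.
    """
    if not sequence or sequence != sequence.strip():
        raise ValueError("sequence must be nonempty with no whitespace")
    products = _pyt_parser.icleave(
        sequence,
        TRYPSIN_RULE,
        missed_cleavages=spec.missed_cleavages,
        min_length=spec.min_len,
        max_length=spec.max_len,
        semi=(spec.mode == "semi"),
        regex=True,
    )
    out: list[tuple[int, str]] = []
    dropped = 0
    seen: set[tuple[int, str]] = set()
    for start, pep in products:
        key = (start, pep)
        if key in seen:
            continue
        seen.add(key)
        if set(pep) - AA20:
            dropped += 1
            continue
        out.append(key)
    if dropped:
        log.debug("digest: dropped %d peptides with non-standard residues", dropped)
    out.sort()
    return out


def peptide_set(
    sequences: Iterable[str], spec: DigestSpec, collapse_il: bool = True
) -> set[str]:
    """Union of digestion products over many proteins (optionally I=L space)."""
    out: set[str] = set()
    for seq in sequences:
        for _, pep in digest(seq, spec):
            out.add(il_collapse(pep) if collapse_il else pep)
    return out


def build_search_database(
    ncorfs: Sequence[ProteinDBEntry],
    canonical: Sequence[ProteinDBEntry],
) -> list[ProteinDBEntry]:
    """Target-decoy database: targets in input order, then their decoys.

    Entry count is exactly twice the target count.  Duplicate accessions
    across the inputs are a hard error.
    """
    targets = list(ncorfs) + list(canonical)
    seen: dict[str, int] = {}
    collisions = []
    for e in targets:
        seen[e.accession] = seen.get(e.accession, 0) + 1
        if seen[e.accession] == 2:
            collisions.append(e.accession)
    if collisions:
        raise ValueError(f"duplicate accessions in search database: {collisions}")
    return targets + [reverse_decoy(e) for e in targets]


def canonical_overlap_filter(
    ncorfs: Sequence[ProteinDBEntry],
    canonical: Sequence[ProteinDBEntry],
    spec: Optional[DigestSpec] = None,
    shared_peptide_threshold: float = 0.9,
    external_removals: Optional[Iterable[str]] = None,
) -> tuple[list[ProteinDBEntry], list[tuple[str, str]]]:
    """Drop ncORF proteins that collapse into canonical sequence space.

    An ncORF is removed when (a) its full sequence occurs as a substring of
    any canonical protein under I=L equivalence, or (b) the fraction of its
    fully-tryptic 0-missed-cleavage peptides also producible from the
    canonical set exceeds ``shared_peptide_threshold`` (strictly greater).
    ``external_removals`` accepts an aligner-derived accession list and
    removes those entries unconditionally (reason ``external``).

    Returns (retained entries, removal report of (accession, reason)).
    """
    if spec is None:
        spec = DigestSpec()
    full_spec = DigestSpec(
        enzyme=spec.enzyme,
        missed_cleavages=0,
        mode="full",
        min_len=spec.min_len,
        max_len=spec.max_len,
    )
    external = set(external_removals or ())
    canon_il = [il_collapse(c.sequence) for c in canonical]
    canon_peps = peptide_set((c.sequence for c in canonical), full_spec)

    retained: list[ProteinDBEntry] = []
    report: list[tuple[str, str]] = []
    for e in ncorfs:
        if e.accession in external:
            report.append((e.accession, "external"))
            continue
        seq_il = il_collapse(e.sequence)
        if any(seq_il in c for c in canon_il):
            report.append((e.accession, "substring"))
            continue
        own = {il_collapse(p) for _, p in digest(e.sequence, full_spec)}
        if own:
            frac = len(own & canon_peps) / len(own)
            if frac > shared_peptide_threshold:
                report.append((e.accession, f"shared_peptides:{frac:.3f}"))
                continue
        retained.append(e)
    return retained, report


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta_entries(path: str | Path, origin: str) -> list[ProteinDBEntry]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if origin != "decoy" and acc.startswith(DECOY_PREFIX):
            raise ValueError(f"{acc}: decoy-prefixed accession in {origin} input")
        out.append(ProteinDBEntry(accession=acc, sequence=str(rec.seq), origin=origin))
    return out


def read_database_fasta(path: str | Path) -> list[ProteinDBEntry]:
    """Read a mixed target-decoy FASTA, deriving origins from accessions
    (``rev_`` -> decoy, ``ncorf|`` -> ncorf, anything else -> canonical)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc.startswith(DECOY_PREFIX):
            origin, source = "decoy", acc[len(DECOY_PREFIX):]
        elif acc.startswith("ncorf|"):
            origin, source = "ncorf", ""
        else:
            origin, source = "canonical", ""
        out.append(
            ProteinDBEntry(
                accession=acc, sequence=str(rec.seq), origin=origin,
                source_accession=source,
            )
        )
    return out


def write_fasta_entries(entries: Iterable[ProteinDBEntry], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        (SeqRecord(Seq(e.sequence), id=e.accession, description="") for e in entries),
        str(path),
        "fasta",
    )


def write_removal_report(report: Iterable[tuple[str, str]], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(report, columns=["accession", "reason"]).to_csv(
        path, sep="\t", index=False
    )
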