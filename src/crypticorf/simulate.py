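"""Synthetic study generator with planted ground truth.

Builds a fully self-contained miniature of a pan-cancer proteogenomic
study: a genome with multi-exon transcripts on both strands, planted ncORFs
of every category, PSM tables with known true/false/decoy labels drawn from
a two-component score model, somatic variants constructed to realize
requested (canonical-frame, ncORF-frame) consequence pairs, and auxiliary
tables (HLA affinity, retention times, normal-tissue expression,
differential expression, ortholog counts).

Every generator is deterministic for a fixed root seed; per-stage child
seeds are derived from the root by fixed offsets so stages can be re-run
independently.  Planted constructs are verified against the pipeline's own
engines during generation (plant, check, retry), so the ground-truth
manifest is guaranteed to be recoverable by construction.  Background
sequence is random, so *unplanted* ORFs exist and are expected: recovery
checks should use superset semantics for enumeration and exact membership
for manifest entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GenomeBuild,
    TranscriptModel,
    annotated_protein,
    reverse_complement,
    spliced_sequence,
    transcript_interval_to_genomic,
    translate_frame,
    CODON_TABLE,
    STOP_CODONS,
)
from .orfs import ORFRecord, enumerate_and_classify, make_orf_id, orf_accession
from .searchdb import DigestSpec, ProteinDBEntry, digest, il_collapse
from .variants import (
    VariantRecord,
    call_ncorf_consequence,
    compute_canonical_class,
    left_normalize,
    transcript_edit,
)
from .epitopes import hydrophobicity_index

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_STOPS = sorted(STOP_CODONS)

COHORT_LABELS = ["BRCA", "OV", "COAD", "LUAD", "UCEC", "KIRC", "HNSC", "LIHC", "PRAD", "GBM"]
HLA_ALLELES = ["HLA-A*02:01", "HLA-A*01:01", "HLA-B*07:02", "HLA-B*08:01", "HLA-C*07:01"]


class PlantingError(RuntimeError):
    """A requested construct cannot be realized on the given sequence."""


@dataclass
class PsmModel:
    """Two-component PSM score model.

    True-target scores are N(true_score_mean, score_sd); false targets and
    decoys share N(null_score_mean, score_sd).  Each null-pool PSM is a
    decoy with probability ``decoy_fraction``, otherwise a false target.
    """

    n_true: int = 1000
    n_false: int = 9000
    true_score_mean: float = 4.0
    null_score_mean: float = 0.0
    score_sd: float = 1.0
    decoy_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_true, self.n_false) < 0:
            raise ValueError("PSM counts must be >= 0")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be > 0")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in [0,1]")


def default_variant_model() -> dict[tuple[str, str], int]:
    """Requested (canonical_class, ncorf_class) cells, missense-dominated."""
    return {
        ("utr5", "missense"): 30,
        ("utr3", "missense"): 30,
        ("silent", "missense"): 25,
        ("missense", "missense"): 15,
        ("rna", "missense"): 10,
        ("utr5", "stop_gained"): 8,
        ("utr3", "stop_gained"): 8,
        ("utr5", "stop_lost"): 4,
        ("utr3", "stop_lost"): 4,
        ("utr5", "frameshift_del"): 6,
        ("utr3", "frameshift_ins"): 6,
        ("utr5", "inframe_del"): 3,
        ("utr3", "inframe_ins"): 3,
        ("silent", "silent"): 15,
        ("missense", "silent"): 10,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000  # minimum; contigs grow to fit transcripts
    n_transcripts: int = 40
    fraction_noncoding: float = 0.25
    planted_orfs_per_category: dict[str, int] = field(
        default_factory=lambda: {
            "uORF_5utr": 10,
            "dORF_3utr": 10,
            "out_of_frame": 10,
            "ncRNA": 8,
            "miscRNA": 2,
        }
    )
    min_codons: int = 30
    orf_codon_range: tuple[int, int] = (30, 45)
    n_cohorts: int = 10
    n_samples_per_cohort: int = 5
    n_pervasive: int = 6
    pervasive_min_cohorts: int = 8
    replicates_per_cohort: int = 5
    immuno_fraction: float = 0.1
    psm_model: PsmModel = field(default_factory=PsmModel)
    variant_model: dict[tuple[str, str], int] = field(
        default_factory=default_variant_model
    )
    n_background_variants: int = 60
    rt_noise_sd_min: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_noncoding <= 1:
            raise ValueError("fraction_noncoding must be in [0,1]")
        if any(v < 0 for v in self.planted_orfs_per_category.values()):
            raise ValueError("planted ORF counts must be >= 0")
        if self.orf_codon_range[0] < self.min_codons:
            raise ValueError("planted ORFs must satisfy min_codons")

    def rng(self, stage: int) -> np.random.Generator:
        """Child generator for one pipeline stage (fixed offsets)."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------------

class _TranscriptBuilder:
    """Mutable spliced-transcript sequence with constraint-checked edits.

    Edits must not create stop codons inside the canonical CDS frame, must
    not touch the canonical start/stop codons, and must not touch the
    footprint of previously planted ORFs (``locked`` intervals).
    """

    def __init__(self, seq: str, cds: Optional[tuple[int, int]], rng) -> None:
        self.seq = list(seq)
        self.cds = cds
        self.rng = rng
        self.locked: list[tuple[int, int]] = []
        if cds is not None:
            cs, ce = cds
            self.locked.append((cs, cs + 3))      # canonical start codon
            self.locked.append((ce - 3, ce))      # canonical stop codon

    def __len__(self) -> int:
        return len(self.seq)

    def _is_locked(self, lo: int, hi: int) -> bool:
        return any(lo < e and s < hi for s, e in self.locked)

    def _cds_frame_ok(self, lo: int, hi: int) -> bool:
        """No stop codon created in the canonical frame over [lo, hi)."""
        if self.cds is None:
            return True
        cs, ce = self.cds
        if hi <= cs or lo >= ce:
            return True
        j = cs + 3 * ((max(lo, cs) - cs) // 3)
        while j < min(hi, ce - 3):
            if "".join(self.seq[j : j + 3]) in STOP_CODONS:
                return False
            j += 3
        return True

    def write_codon(self, i: int, codon: str) -> bool:
        if self._is_locked(i, i + 3):
            return False
        old = self.seq[i : i + 3]
        self.seq[i : i + 3] = list(codon)
        if not self._cds_frame_ok(i, i + 3):
            self.seq[i : i + 3] = old
            return False
        return True

    def _replace_with_sense(self, i: int, forbid_atg: bool) -> bool:
        candidates = list(_SENSE_CODONS)
        self.rng.shuffle(candidates)
        for codon in candidates:
            if forbid_atg and codon == "ATG":
                continue
            if self.write_codon(i, codon):
                return True
        return False

    def plant(self, p: int, n_codons: int) -> bool:
        """Plant an AUG..stop ORF of ``n_codons`` codons starting at ``p``.

        Guarantees after success: ATG at p; the unique in-frame stop of the
        segment at p+3*n_codons; no in-frame ATG between the previous
        in-frame stop and p (so the enumerator's 5'-most-AUG rule recovers
        exactly this ORF).
        """
        q = p + 3 * n_codons
        if q + 3 > len(self.seq):
            return False
        if not self.write_codon(p, "ATG"):
            return False
        stops = list(_STOPS)
        self.rng.shuffle(stops)
        if not any(self.write_codon(q, s) for s in stops):
            return False
        for i in range(p + 3, q, 3):
            if "".join(self.seq[i : i + 3]) in STOP_CODONS:
                if not self._replace_with_sense(i, forbid_atg=False):
                    return False
        # upstream cleanup: no ATG in this frame since the previous stop
        i = p - 3
        while i >= 0:
            codon = "".join(self.seq[i : i + 3])
            if codon in STOP_CODONS:
                break
            if codon == "ATG" and not self._replace_with_sense(i, forbid_atg=True):
                return False
            i -= 3
        self.locked.append((p, q + 3))
        return True


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_cds(rng, n_codons: int) -> str:
    """ATG + random sense codons + stop; translates to n_codons residues."""
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)]
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(body) + stop


@dataclass
class PlantedORF:
    orf_id: str
    transcript_id: str
    gene_id: str
    category: str
    t_start: int
    t_end: int
    protein: str


@dataclass
class SyntheticReference:
    """In-memory synthetic genome + annotation + canonical proteome."""

    config: SimulationConfig
    genome: GenomeBuild
    transcripts: list[TranscriptModel]
    canonical: list[ProteinDBEntry]
    planted: list[PlantedORF]
    gtf_text: str

    @property
    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name in sorted(self.genome.contigs):
                fh.write(f">{name}\n")
                seq = self.genome.contigs[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        (outdir / "annotation.gtf").write_text(self.gtf_text)
        from .searchdb import write_fasta_entries

        write_fasta_entries(self.canonical, outdir / "canonical.fa")
        with open(outdir / "planted_orfs.json", "w") as fh:
            json.dump([asdict(p) for p in self.planted], fh, indent=1)


def _design_transcript(
    rng,
    coding: bool,
    plant_categories: Sequence[str],
    cfg: SimulationConfig,
) -> tuple[str, Optional[tuple[int, int]], list[tuple[str, int, int]]]:
    """One attempt at a designed spliced sequence with planted ORFs.

    Returns (sequence, cds_span, planted list of (category, t_start, t_end));
    raises PlantingError when a plant cannot be realized on this draw.
    """
    lo_c, hi_c = cfg.orf_codon_range

    def orf_codons() -> int:
        return int(rng.integers(lo_c, hi_c + 1))

    if coding:
        n_u = orf_codons() if "uORF_5utr" in plant_categories else 0
        n_d = orf_codons() if "dORF_3utr" in plant_categories else 0
        n_o = orf_codons() if "out_of_frame" in plant_categories else 0
        utr5 = 3 * (n_u + 1) + int(rng.integers(30, 90)) if n_u else int(rng.integers(60, 160))
        utr3 = 3 * (n_d + 1) + int(rng.integers(30, 90)) if n_d else int(rng.integers(60, 160))
        cds_codons = max(int(rng.integers(120, 220)), n_o + 12)
        seq = _random_seq(rng, utr5) + _random_cds(rng, cds_codons) + _random_seq(rng, utr3)
        cds = (utr5, utr5 + 3 * cds_codons + 3)
        b = _TranscriptBuilder(seq, cds, rng)
        planted: list[tuple[str, int, int]] = []
        if n_o:
            cs, ce = cds
            span = 3 * (n_o + 1)
            shift = int(rng.integers(1, 3))  # 1 or 2: out of frame
            last = ce - 3 - span
            starts = [p for p in range(cs + 3 + shift, last + 1, 3)]
            rng.shuffle(starts)
            if not _try_positions(b, starts, n_o, planted, "out_of_frame"):
                raise PlantingError("out_of_frame plant failed")
        if n_u:
            span = 3 * (n_u + 1)
            starts = list(range(0, cds[0] - span + 1))
            rng.shuffle(starts)
            if not _try_positions(b, starts[:40], n_u, planted, "uORF_5utr"):
                raise PlantingError("uORF plant failed")
        if n_d:
            span = 3 * (n_d + 1)
            starts = list(range(cds[1], len(b.seq) - span + 1))
            rng.shuffle(starts)
            if not _try_positions(b, starts[:40], n_d, planted, "dORF_3utr"):
                raise PlantingError("dORF plant failed")
        return "".join(b.seq), cds, planted

    n = orf_codons()
    span = 3 * (n + 1)
    length = span + int(rng.integers(120, 400))
    seq = _random_seq(rng, length)
    b = _TranscriptBuilder(seq, None, rng)
    starts = list(range(0, length - span + 1))
    rng.shuffle(starts)
    planted = []
    category = plant_categories[0] if plant_categories else None
    if category:
        if not _try_positions(b, starts[:40], n, planted, category):
            raise PlantingError("noncoding plant failed")
    return "".join(b.seq), None, planted


def _try_positions(b, starts, n_codons, planted, category) -> bool:
    for p in starts:
        if b.plant(p, n_codons):
            planted.append((category, p, p + 3 * (n_codons + 1)))
            return True
    return False


def _verify_plants(
    seq: str,
    cds: Optional[tuple[int, int]],
    biotype: str,
    planted: Sequence[tuple[str, int, int]],
    min_codons: int,
) -> bool:
    """Closed-loop check: the enumerator recovers every plant exactly."""
    tmp_genome = GenomeBuild({"tmp": seq})
    tmp = TranscriptModel(
        transcript_id="tmp",
        gene_id="tmp",
        gene_name="",
        contig="tmp",
        strand="+",
        exons=((0, len(seq)),),
        cds_span=cds,
        biotype=biotype,
    )
    found = {
        (o.t_start, o.t_end, o.category) for o in enumerate_and_classify(tmp, tmp_genome, min_codons)
    }
    return all((s, e, cat) in found for cat, s, e in planted)


def _embed_transcript(
    rng, seq: str, contig_parts: list[str], cursor: int
) -> tuple[tuple[tuple[int, int], ...], str, int]:
    """Split ``seq`` into exons, add introns, append to a contig buffer.

    Returns (exon intervals in genomic order, strand, new cursor).
    """
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    n_exons = int(rng.integers(1, 4))
    cuts = []
    if n_exons > 1:
        valid = range(30, len(seq) - 30)
        cuts = sorted(rng.choice(list(valid), size=n_exons - 1, replace=False))
        while any(b - a < 30 for a, b in zip(cuts, cuts[1:])):
            cuts = sorted(rng.choice(list(valid), size=n_exons - 1, replace=False))
    bounds = [0, *cuts, len(seq)]
    chunks = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = [_random_seq(rng, int(rng.integers(40, 150))) for _ in range(len(chunks) - 1)]

    gap = _random_seq(rng, int(rng.integers(100, 250)))
    contig_parts.append(gap)
    cursor += len(gap)

    genomic_chunks = chunks if strand == "+" else [reverse_complement(c) for c in reversed(chunks)]
    exons: list[tuple[int, int]] = []
    for i, chunk in enumerate(genomic_chunks):
        start = cursor
        contig_parts.append(chunk)
        cursor += len(chunk)
        exons.append((start, cursor))
        if i < len(introns):
            intron = introns[i]
            contig_parts.append(intron)
            cursor += len(intron)
    return tuple(exons), strand, cursor


def simulate_reference(cfg: SimulationConfig) -> SyntheticReference:
    """Genome FASTA + GTF + canonical proteome + planted-ORF manifest."""
    rng = cfg.rng(1)
    n_noncoding = round(cfg.n_transcripts * cfg.fraction_noncoding)
    n_coding = cfg.n_transcripts - n_noncoding

    want = dict(cfg.planted_orfs_per_category)
    for cat in ("uORF_5utr", "dORF_3utr", "out_of_frame"):
        if want.get(cat, 0) > n_coding:
            raise PlantingError(
                f"cannot plant {want[cat]} {cat} ORFs on {n_coding} coding transcripts"
            )
    if want.get("ncRNA", 0) + want.get("miscRNA", 0) > n_noncoding:
        raise PlantingError("not enough noncoding transcripts for requested plants")

    # assign plant categories per transcript
    coding_assignments: list[list[str]] = [[] for _ in range(n_coding)]
    for cat in ("uORF_5utr", "dORF_3utr", "out_of_frame"):
        idx = rng.permutation(n_coding)[: want.get(cat, 0)]
        for i in idx:
            coding_assignments[int(i)].append(cat)
    noncoding_assignments: list[list[str]] = [[] for _ in range(n_noncoding)]
    slots = rng.permutation(n_noncoding)
    k = 0
    for cat in ("ncRNA", "miscRNA"):
        for _ in range(want.get(cat, 0)):
            noncoding_assignments[int(slots[k])].append(cat)
            k += 1

    contig_parts: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(cfg.n_contigs)}
    cursors = {name: 0 for name in contig_parts}
    transcripts: list[TranscriptModel] = []
    planted: list[PlantedORF] = []
    canonical: list[ProteinDBEntry] = []
    gtf_lines: list[str] = []

    specs = [("protein_coding", a) for a in coding_assignments]
    for i, a in enumerate(noncoding_assignments):
        biotype = "misc_RNA" if "miscRNA" in a else "lncRNA"
        specs.append((biotype, a))

    for i, (biotype, cats) in enumerate(specs):
        tid, gid, gname = f"tx{i:04d}", f"g{i:04d}", f"GENE{i:04d}"
        coding = biotype == "protein_coding"
        for attempt in range(30):
            try:
                seq, cds, plants = _design_transcript(rng, coding, cats, cfg)
            except PlantingError:
                continue
            if _verify_plants(seq, cds, biotype, plants, cfg.min_codons):
                break
        else:
            raise PlantingError(
                f"transcript {tid}: could not realize plants {cats} in 30 attempts"
            )
        contig = f"chr{(i % cfg.n_contigs) + 1}"
        exons, strand, cursors[contig] = _embed_transcript(
            rng, seq, contig_parts[contig], cursors[contig]
        )
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_name=gname,
            contig=contig,
            strand=strand,
            exons=exons,
            cds_span=cds,
            biotype=biotype,
        )
        transcripts.append(t)
        for cat, s, e in plants:
            planted.append(
                PlantedORF(
                    orf_id=make_orf_id(tid, s, s % 3),
                    transcript_id=tid,
                    gene_id=gid,
                    category=cat,
                    t_start=s,
                    t_end=e,
                    protein=translate_frame(seq[s:e], 0),
                )
            )
        gtf_lines.extend(_gtf_features(t))

    # pad contigs to the configured minimum and build the genome
    contigs: dict[str, str] = {}
    for name, parts in contig_parts.items():
        seq = "".join(parts)
        if len(seq) < cfg.contig_length:
            seq += _random_seq(rng, cfg.contig_length - len(seq))
        contigs[name] = seq
    genome = GenomeBuild(contigs)

    # internal consistency: designed sequences survive embedding
    for t, (biotype, cats) in zip(transcripts, specs):
        assert spliced_sequence(t, genome) is not None
    for t in transcripts:
        if t.cds_span is not None:
            canonical.append(
                ProteinDBEntry(
                    accession=f"sp|{t.gene_id}|{t.transcript_id}",
                    sequence=annotated_protein(t, genome),
                    origin="canonical",
                )
            )

    ref = SyntheticReference(
        config=cfg,
        genome=genome,
        transcripts=transcripts,
        canonical=canonical,
        planted=planted,
        gtf_text="".join(gtf_lines),
    )
    _verify_reference(ref)
    return ref


def _gtf_features(t: TranscriptModel) -> list[str]:
    attrs = (
        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
        f'gene_name "{t.gene_name}"; transcript_biotype "{t.biotype}";'
    )
    lines = []
    for s, e in t.exons:
        lines.append(
            f"{t.contig}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
        )
    if t.cds_span is not None:
        for s, e in transcript_interval_to_genomic(t, *t.cds_span):
            lines.append(
                f"{t.contig}\tsynthetic\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
    return lines


def _verify_reference(ref: SyntheticReference) -> None:
    """Every planted ORF is recovered, with matching id/category/protein."""
    by_tx: dict[str, list[PlantedORF]] = {}
    for p in ref.planted:
        by_tx.setdefault(p.transcript_id, []).append(p)
    tx = ref.transcripts_by_id
    for tid, plants in by_tx.items():
        found = {
            o.orf_id: o
            for o in enumerate_and_classify(tx[tid], ref.genome, ref.config.min_codons)
        }
        for p in plants:
            o = found.get(p.orf_id)
            if o is None or o.category != p.category or o.protein != p.protein:
                raise PlantingError(
                    f"planted ORF {p.orf_id} not recovered after embedding"
                )


def planted_orf_records(ref: SyntheticReference) -> list[ORFRecord]:
    """Planted ORFs as first-class ORF records."""
    out = []
    for p in ref.planted:
        out.append(
            ORFRecord(
                orf_id=p.orf_id,
                transcript_id=p.transcript_id,
                gene_id=p.gene_id,
                category=p.category,
                t_start=p.t_start,
                t_end=p.t_end,
                frame_offset=p.t_start % 3,
                codon_length=(p.t_end - p.t_start) // 3 - 1,
                protein=p.protein,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

@dataclass
class PsmTruth:
    """Ground truth for one simulated PSM table."""

    labels: dict[str, str]                      # spectrum_id -> true|false|decoy
    true_peptides_by_cohort: dict[str, list[str]]
    pervasive_orf_ids: list[str]
    support_cohorts: dict[str, list[str]]       # orf_id -> cohorts with true support


def _discriminating_peptides(
    orfs: Sequence[ORFRecord], canonical: Sequence[ProteinDBEntry]
) -> dict[str, list[str]]:
    """Fully-tryptic 8-25 aa peptides unique to one planted ORF.

    Uniqueness is substring-level under I=L against the canonical proteome
    and every other planted ORF, matching the mapper's containment rule.
    """
    spec = DigestSpec(missed_cleavages=0, mode="full", min_len=8, max_len=25)
    canon_il = [il_collapse(e.sequence) for e in canonical]
    orf_il = {o.orf_id: il_collapse(o.protein) for o in orfs}
    out: dict[str, list[str]] = {}
    for o in orfs:
        peps = []
        for _, pep in digest(o.protein, spec):
            pil = il_collapse(pep)
            if any(pil in c for c in canon_il):
                continue
            owners = sum(1 for seq in orf_il.values() if pil in seq)
            if owners == 1:
                peps.append(pep)
        out[o.orf_id] = sorted(set(peps))
    return out


def simulate_psm_tables(
    cfg: SimulationConfig, ref: SyntheticReference
) -> tuple[pd.DataFrame, PsmTruth]:
    """PSM table with known true/false/decoy labels and planted pervasiveness.

    True-target PSMs sample discriminating peptides of planted ORFs with
    scores from the high component; false targets and decoys share the null
    component.  Posterior probabilities are a logistic transform of the
    score.  Pervasive ORFs receive true peptides in >= ``pervasive_min_cohorts``
    cohorts; all other supported ORFs in 1-3 cohorts.  Each supported
    (ORF, cohort) pair contributes ``replicates_per_cohort`` whole-proteome
    spectra, emulating the redundancy of real cohort-level data.
    """
    rng = cfg.rng(2)
    m = cfg.psm_model
    cohorts = COHORT_LABELS[: cfg.n_cohorts]
    orfs = planted_orf_records(ref)
    disc = _discriminating_peptides(orfs, ref.canonical)
    eligible = [o for o in orfs if disc[o.orf_id]]
    if m.n_true == 0:
        eligible = []  # null-only model: no true support anywhere
    elif len(eligible) < cfg.n_pervasive:
        raise PlantingError("not enough ORFs with discriminating peptides")

    perm = rng.permutation(len(eligible))
    n_perv = min(cfg.n_pervasive, len(eligible))
    pervasive = [eligible[int(i)] for i in perm[:n_perv]]
    others = [eligible[int(i)] for i in perm[n_perv:]]

    support: dict[str, list[str]] = {}
    for o in pervasive:
        k = int(rng.integers(cfg.pervasive_min_cohorts, cfg.n_cohorts + 1))
        support[o.orf_id] = sorted(
            str(c) for c in rng.choice(cohorts, size=k, replace=False)
        )
    max_other = min(3, cfg.pervasive_min_cohorts - 1)
    for o in others:
        k = int(rng.integers(1, max_other + 1))
        support[o.orf_id] = sorted(
            str(c) for c in rng.choice(cohorts, size=k, replace=False)
        )

    orf_by_id = {o.orf_id: o for o in eligible}
    rows: list[dict] = []
    labels: dict[str, str] = {}
    true_by_cohort: dict[str, set[str]] = {c: set() for c in cohorts}
    counter = 0

    def sample_of(cohort: str) -> str:
        j = int(rng.integers(0, cfg.n_samples_per_cohort))
        return f"{cohort}-S{j:02d}"

    def emit_true(orf_id: str, cohort: str, assay: str) -> None:
        nonlocal counter
        o = orf_by_id[orf_id]
        pep = disc[orf_id][int(rng.integers(0, len(disc[orf_id])))]
        score = float(rng.normal(m.true_score_mean, m.score_sd))
        sid = f"spec{counter:06d}"
        counter += 1
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": pep,
                "score": score,
                "probability": _prob_from_score(score, m),
                "accessions": orf_accession(o),
                "sample_id": sample_of(cohort),
                "cohort": cohort,
                "assay": assay,
            }
        )
        labels[sid] = "true"
        true_by_cohort[cohort].add(pep)

    # guaranteed support: replicated whole-proteome spectra per (ORF, cohort)
    for orf_id, chs in sorted(support.items()):
        for cohort in chs:
            for _ in range(cfg.replicates_per_cohort):
                emit_true(orf_id, cohort, "proteome")

    n_extra = max(0, m.n_true - sum(len(c) for c in support.values()) * cfg.replicates_per_cohort)
    supported_ids = sorted(support)
    for _ in range(n_extra):
        orf_id = supported_ids[int(rng.integers(0, len(supported_ids)))]
        cohort = support[orf_id][int(rng.integers(0, len(support[orf_id])))]
        assay = "immunopeptidome" if rng.random() < cfg.immuno_fraction else "proteome"
        emit_true(orf_id, cohort, assay)

    canonical_accs = [e.accession for e in ref.canonical]
    forbidden = [il_collapse(o.protein) for o in orfs] + [
        il_collapse(e.sequence) for e in ref.canonical
    ]
    for _ in range(m.n_false):
        is_decoy = rng.random() < m.decoy_fraction
        pep = _random_peptide(rng, forbidden)
        score = float(rng.normal(m.null_score_mean, m.score_sd))
        cohort = cohorts[int(rng.integers(0, len(cohorts)))]
        acc = canonical_accs[int(rng.integers(0, len(canonical_accs)))]
        sid = f"spec{counter:06d}"
        counter += 1
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": pep,
                "score": score,
                "probability": _prob_from_score(score, m),
                "accessions": ("rev_" + acc) if is_decoy else acc,
                "sample_id": sample_of(cohort),
                "cohort": cohort,
                "assay": "immunopeptidome"
                if rng.random() < cfg.immuno_fraction
                else "proteome",
            }
        )
        labels[sid] = "decoy" if is_decoy else "false"

    df = pd.DataFrame(rows)
    df["is_decoy"] = df["accessions"].str.startswith("rev_")
    truth = PsmTruth(
        labels=labels,
        true_peptides_by_cohort={c: sorted(s) for c, s in true_by_cohort.items()},
        pervasive_orf_ids=sorted(o.orf_id for o in pervasive),
        support_cohorts=support,
    )
    return df, truth


def _prob_from_score(score: float, m: PsmModel) -> float:
    mid = 0.5 * (m.true_score_mean + m.null_score_mean)
    return float(1.0 / (1.0 + np.exp(-(score - mid) / 0.4)))


_AA = np.array(list("ACDEFGHKMNPQRSTVWY"))  # no I/L: avoids I=L collisions


def _random_peptide(rng, forbidden_il: Sequence[str]) -> str:
    while True:
        n = int(rng.integers(8, 26))
        pep = "".join(_AA[rng.integers(0, len(_AA), n)])
        pil = il_collapse(pep)
        if not any(pil in seq for seq in forbidden_il):
            return pep


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

@dataclass
class VariantTruth:
    """Intended consequence pair per emitted variant."""

    cells: list[dict]                 # {key, canonical_class, ncorf_class, orf_id}
    skipped: dict[str, int]           # "<canonical>/<ncorf>" -> unrealized count
    background_keys: list[str]


_CELL_HOST = {
    "utr5": "uORF_5utr",
    "utr3": "dORF_3utr",
    "silent": "out_of_frame",
    "missense": "out_of_frame",
    "rna": "ncRNA",
}


def simulate_variants(
    cfg: SimulationConfig, ref: SyntheticReference
) -> tuple[list[VariantRecord], VariantTruth]:
    """Somatic variants realizing requested consequence-pair cells.

    For each requested (canonical_class, ncorf_class) cell, candidate edits
    inside planted ORF footprints are drawn and verified with the
    consequence engine until the cell count is met; unrealizable draws are
    reported in ``skipped``.  Canonical-protein-altering background
    variants outside any ncORF footprint are added for burden statistics.
    """
    rng = cfg.rng(3)
    cohorts = COHORT_LABELS[: cfg.n_cohorts]
    tx = ref.transcripts_by_id
    orfs = planted_orf_records(ref)
    by_cat: dict[str, list[ORFRecord]] = {}
    for o in orfs:
        by_cat.setdefault(o.category, []).append(o)
    by_cat.setdefault("ncRNA", []).extend(by_cat.get("miscRNA", []))

    out: list[VariantRecord] = []
    cells: list[dict] = []
    skipped: dict[str, int] = {}

    def sample_label() -> tuple[str, str]:
        cohort = cohorts[int(rng.integers(0, len(cohorts)))]
        j = int(rng.integers(0, cfg.n_samples_per_cohort))
        return f"{cohort}-S{j:02d}", cohort

    for (canon_cls, nc_cls), count in sorted(cfg.variant_model.items()):
        hosts = by_cat.get(_CELL_HOST.get(canon_cls, "out_of_frame"), [])
        made = 0
        tries = 0
        max_tries = count * 400
        while made < count and tries < max_tries and hosts:
            tries += 1
            orf = hosts[int(rng.integers(0, len(hosts)))]
            t = tx[orf.transcript_id]
            v = _draw_candidate(rng, orf, t, ref.genome, nc_cls)
            if v is None:
                continue
            try:
                v = left_normalize(v, ref.genome)
                got_nc = call_ncorf_consequence(v, orf, t, ref.genome).ncorf_class
                got_canon = compute_canonical_class(v, t, ref.genome)
            except Exception:
                continue
            if (got_canon, got_nc) != (canon_cls, nc_cls):
                continue
            sample_id, cohort = sample_label()
            v = VariantRecord(
                contig=v.contig,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                sample_id=sample_id,
                cohort=cohort,
                canonical_class=canon_cls,
            )
            out.append(v)
            cells.append(
                {
                    "key": v.key,
                    "canonical_class": canon_cls,
                    "ncorf_class": nc_cls,
                    "orf_id": orf.orf_id,
                }
            )
            made += 1
        if made < count:
            skipped[f"{canon_cls}/{nc_cls}"] = count - made
            log.warning(
                "variant cell %s/%s: realized %d of %d", canon_cls, nc_cls, made, count
            )

    background = _background_variants(rng, cfg, ref, orfs, sample_label)
    out.extend(background)
    truth = VariantTruth(
        cells=cells,
        skipped=skipped,
        background_keys=[v.key for v in background],
    )
    return out, truth


def _draw_candidate(rng, orf, t, genome, nc_cls) -> Optional[VariantRecord]:
    """One random edit of the right shape inside the ORF footprint."""
    seq_len = orf.t_end - orf.t_start
    if nc_cls == "stop_lost":
        tpos = orf.t_end - 3 + int(rng.integers(0, 3))
    elif nc_cls == "stop_gained":
        tpos = orf.t_start + 3 + int(rng.integers(0, seq_len - 6))
    else:
        tpos = orf.t_start + int(rng.integers(3, seq_len - 3))
    from .annotation import transcript_to_genomic

    if nc_cls in ("missense", "silent", "stop_gained", "stop_lost"):
        gpos = transcript_to_genomic(t, tpos)
        ref_base = genome.fetch(t.contig, gpos, gpos + 1)
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[int(rng.integers(0, 3))]
        return VariantRecord(contig=t.contig, pos=gpos, ref=ref_base, alt=alt)
    if nc_cls.endswith("_del"):
        ln = 3 if nc_cls.startswith("inframe") else int(rng.choice([1, 2, 4, 5]))
        if tpos + ln > orf.t_end - 3:
            return None
        gps = [transcript_to_genomic(t, tpos + k) for k in range(ln)]
        lo, hi = min(gps), max(gps) + 1
        if hi - lo != ln:
            return None  # spans a splice junction
        ref_seq = genome.fetch(t.contig, lo, hi)
        return VariantRecord(contig=t.contig, pos=lo, ref=ref_seq, alt="")
    if nc_cls.endswith("_ins"):
        ln = 3 if nc_cls.startswith("inframe") else int(rng.choice([1, 2, 4, 5]))
        ins = "".join(_BASES[rng.integers(0, 4, ln)])
        gpos = transcript_to_genomic(t, tpos)
        # candidate insertion points bracketing the mapped base (strand-proof:
        # the engine verifies the realized consequence downstream)
        gp = gpos + int(rng.integers(0, 2))
        if gp <= 0:
            return None
        try:
            return VariantRecord(contig=t.contig, pos=gp, ref="", alt=ins)
        except Exception:
            return None
    return None


def _background_variants(rng, cfg, ref, orfs, sample_label) -> list[VariantRecord]:
    """Canonical-missense SNVs in CDS regions clear of any ORF footprint."""
    from .annotation import transcript_to_genomic
    from .variants import compute_canonical_class

    tx = ref.transcripts_by_id
    footprints: dict[str, list[tuple[int, int]]] = {}
    for o in orfs:
        t = tx[o.transcript_id]
        for s, e in transcript_interval_to_genomic(t, o.t_start, o.t_end):
            footprints.setdefault(t.contig, []).append((s, e))
    coding = [t for t in ref.transcripts if t.cds_span is not None]
    out: list[VariantRecord] = []
    tries = 0
    while len(out) < cfg.n_background_variants and tries < cfg.n_background_variants * 200:
        tries += 1
        t = coding[int(rng.integers(0, len(coding)))]
        cs, ce = t.cds_span
        tpos = cs + 3 + int(rng.integers(0, ce - cs - 6))
        gpos = transcript_to_genomic(t, tpos)
        if any(s <= gpos < e for s, e in footprints.get(t.contig, ())):
            continue
        ref_base = ref.genome.fetch(t.contig, gpos, gpos + 1)
        alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(0, 3))]
        v = VariantRecord(contig=t.contig, pos=gpos, ref=ref_base, alt=alt)
        if compute_canonical_class(v, t, ref.genome) != "missense":
            continue
        sample_id, cohort = sample_label()
        out.append(
            VariantRecord(
                contig=t.contig,
                pos=gpos,
                ref=ref_base,
                alt=alt,
                sample_id=sample_id,
                cohort=cohort,
                canonical_class="missense",
            )
        )
    return out


# ---------------------------------------------------------------------------
# epitope evidence tables
# ---------------------------------------------------------------------------

@dataclass
class EpitopeTruth:
    """Intended filter outcomes per (peptide, sample) candidate."""

    intended: list[dict]  # {peptide, orf_id, sample_id, affinity_pass, rt_pass, gtex_pass, reported}


def simulate_epitope_tables(
    cfg: SimulationConfig,
    candidates: Sequence[tuple[str, str, str, bool]],
    orf_gene: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, EpitopeTruth]:
    """Affinity, retention-time and expression tables with planted outcomes.

    ``candidates`` are (peptide, orf_id, sample_id, mutated) tuples.  Each
    candidate gets an independently planted affinity outcome and RT outcome;
    the expression outcome is planted per *gene* (all candidates of a gene
    share it, as in a median-across-tissues table).  Observed RT is the
    hydrophobicity-derived prediction plus noise scaled to land inside or
    outside the 5-minute window.  Returns (affinity_df, rt_df, expression_df,
    truth).
    """
    rng = cfg.rng(4)
    genes = sorted({orf_gene[orf_id] for _, orf_id, _, _ in candidates})
    gene_low_expr = {g: bool(rng.random() < 0.4) for g in genes}
    expr_rows = [
        {
            "gene_id": g,
            "median_tpm": float(rng.uniform(0.0, 0.9))
            if gene_low_expr[g]
            else float(rng.uniform(1.5, 60.0)),
        }
        for g in genes
    ]

    aff_rows, rt_rows, intended = [], [], []
    for pep, orf_id, sample_id, mutated in candidates:
        allele = HLA_ALLELES[int(rng.integers(0, len(HLA_ALLELES)))]
        aff_pass = bool(rng.random() < 0.5)
        affinity = (
            float(10 ** rng.uniform(0.7, 2.17))
            if aff_pass
            else float(10 ** rng.uniform(2.4, 3.7))
        )
        aff_rows.append(
            {
                "peptide": pep,
                "orf_id": orf_id,
                "sample_id": sample_id,
                "hla_allele": allele,
                "affinity_nM": round(affinity, 2),
                "percentile_rank": round(min(50.0, affinity / 75.0), 3),
            }
        )
        has_rt = rng.random() >= 0.15
        rt_pass: Optional[bool] = None
        if has_rt:
            rt_pass = bool(rng.random() < 0.5)
            predicted = 0.35 * hydrophobicity_index(pep) + 18.0
            err = (
                float(rng.uniform(0.0, 4.5))
                if rt_pass
                else float(rng.uniform(5.5, 15.0))
            )
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rt_rows.append(
                {
                    "peptide": pep,
                    "rt_observed_min": round(predicted + sign * err, 3),
                    "rt_predicted_min": round(predicted, 3),
                }
            )
        gtex_pass = gene_low_expr[orf_gene[orf_id]]
        intended.append(
            {
                "peptide": pep,
                "orf_id": orf_id,
                "sample_id": sample_id,
                "mutated": mutated,
                "affinity_pass": aff_pass,
                "rt_pass": rt_pass,
                "gtex_pass": gtex_pass,
                "reported": aff_pass and (bool(rt_pass) or gtex_pass),
            }
        )
    return (
        pd.DataFrame(aff_rows),
        pd.DataFrame(rt_rows).drop_duplicates("peptide") if rt_rows else pd.DataFrame(columns=["peptide", "rt_observed_min", "rt_predicted_min"]),
        pd.DataFrame(expr_rows),
        EpitopeTruth(intended=intended),
    )


def simulate_aux_tables(
    cfg: SimulationConfig, ref: SyntheticReference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression and ortholog-count tables per gene.

    A random subset of genes is planted as significantly over- or
    under-expressed at the log2FC +/-1.5 / P<0.01 thresholds; ortholog
    counts (0-12 species) are unstructured background.
    """
    rng = cfg.rng(5)
    genes = sorted({t.gene_id for t in ref.transcripts})
    de_rows, ortho_rows = [], []
    for g in genes:
        u = rng.random()
        if u < 0.15:
            lfc = float(rng.uniform(1.5, 4.0))
            p = float(rng.uniform(1e-6, 0.009))
        elif u < 0.25:
            lfc = float(-rng.uniform(1.5, 4.0))
            p = float(rng.uniform(1e-6, 0.009))
        else:
            lfc = float(rng.normal(0.0, 0.7))
            p = float(rng.uniform(0.02, 1.0))
        de_rows.append({"gene_id": g, "log2fc": round(lfc, 4), "pvalue": p})
        ortho_rows.append({"gene_id": g, "n_species": int(rng.integers(0, 13))})
    return pd.DataFrame(de_rows), pd.DataFrame(ortho_rows)


@dataclass
class GroundTruthManifest:
    """Aggregated ground truth across all generators."""

    planted_orfs: list[PlantedORF]
    psm: Optional[PsmTruth] = None
    variants: Optional[VariantTruth] = None
    epitopes: Optional[EpitopeTruth] = None

    def to_json(self, path: str | Path) -> None:
        def enc(obj):
            if hasattr(obj, "__dict__"):
                return obj.__dict__
            raise TypeError(type(obj))

        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_orfs": [asdict(p) for p in self.planted_orfs],
                    "psm": self.psm.__dict__ if self.psm else None,
                    "variants": self.variants.__dict__ if self.variants else None,
                    "epitopes": self.epitopes.__dict__ if self.epitopes else None,
                },
                fh,
                default=enc,
                indent=1,
            )
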