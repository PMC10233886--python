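"""PSM ingestion, target-decoy FDR, filtering, and ncORF evidence.

Peptide-spectrum matches arrive as a TSV table (one row per PSM) emulating a
search-engine/post-processor export.  The flow is:

1. :func:`compute_fdr` — target-decoy q-values at the PSM level;
2. :func:`filter_psms` — per-assay thresholds (whole-cell proteome: q-value;
   immunopeptidome: posterior probability and 8-25 aa length window);
3. :func:`map_peptides_to_ncorfs` — peptide-to-protein assignment under I=L
   equivalence with canonical exclusion (a peptide also contained in any
   canonical protein cannot discriminate an ncORF and is discarded);
4. cohort-level evidence: pervasiveness across cancer cohorts, differential-
   expression annotation, and rank-sum comparisons between strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .searchdb import DECOY_PREFIX, ProteinDBEntry, il_collapse

log = logging.getLogger(__name__)

ASSAYS = ("proteome", "immunopeptidome")

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "score",
    "probability",
    "accessions",
    "sample_id",
    "cohort",
    "assay",
]


@dataclass(frozen=True)
class PSMRecord:
    spectrum_id: str
    peptide: str
    score: float
    probability: Optional[float]
    accession_hits: tuple[str, ...]
    is_decoy: bool
    sample_id: str
    cohort: str
    assay: str


@dataclass
class NcorfEvidence:
    """Aggregated peptide support for one ncORF."""

    orf_id: str
    peptides: set[str] = field(default_factory=set)
    cohorts_supported: set[str] = field(default_factory=set)
    assay_support: set[str] = field(default_factory=set)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV; derives ``is_decoy`` from accession prefixes.

    A PSM is a decoy match when every accession it hits is ``rev_``-prefixed
    (a peptide shared with any target is a target match).
    """
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns and c != "probability"]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    if "probability" not in df.columns:
        df["probability"] = np.nan
    df["accessions"] = df["accessions"].astype(str)
    if "is_decoy" not in df.columns:
        df["is_decoy"] = df["accessions"].map(
            lambda a: all(x.startswith(DECOY_PREFIX) for x in a.split(";"))
        )
    bad = ~df["assay"].isin(ASSAYS)
    if bad.any():
        raise ValueError(f"unknown assay labels: {sorted(df.loc[bad, 'assay'].unique())}")
    return df


def compute_fdr(psms: pd.DataFrame, plus_one: bool = False) -> pd.DataFrame:
    """Target-decoy q-values at the PSM level.

    At each score threshold t, FDR(t) = #decoys(score>=t) / max(1,
    #targets(score>=t)) (the ``plus_one`` switch adds the conventional +1 to
    the decoy count); the q-value is the running minimum of FDR over
    thresholds at or below each PSM's score, so q is monotone non-decreasing
    with rank and tied scores share one q-value.

    Returns a copy of the table with a ``q_value`` column, original order
    preserved.
    """
    if psms.empty:
        out = psms.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    if psms["score"].isna().any():
        raise ValueError("every PSM must have a score")
    df = psms.copy()
    order = df.sort_values(
        ["score", "spectrum_id"], ascending=[False, True], kind="mergesort"
    ).index
    is_decoy = df.loc[order, "is_decoy"].to_numpy(dtype=bool)
    scores = df.loc[order, "score"].to_numpy()
    n_decoy = np.cumsum(is_decoy)
    n_target = np.cumsum(~is_decoy)
    if n_target[-1] == 0:
        log.warning("compute_fdr: all-decoy input; q-values degenerate at 1")
    fdr = (n_decoy + (1 if plus_one else 0)) / np.maximum(1, n_target)
    fdr = np.minimum(fdr, 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    # tied scores share the q-value of the last (worst-ranked) tie member
    qs = pd.Series(q, index=order)
    tie_q = qs.groupby(scores).transform("max")
    df.loc[order, "q_value"] = tie_q.to_numpy()
    return df


def filter_psms(
    psms: pd.DataFrame,
    q_max: float = 0.01,
    p_min: float = 0.99,
    len_range: tuple[int, int] = (8, 25),
    require_validated: bool = True,
) -> pd.DataFrame:
    """Apply per-assay retention thresholds; decoys are always removed.

    Whole-cell proteome PSMs are kept at q <= ``q_max``; immunopeptidome
    PSMs are kept at probability >= ``p_min`` with peptide length inside
    ``len_range`` (inclusive).  When a ``validated`` column is present
    (peptide-centric re-validation), retained PSMs must have it true unless
    ``require_validated`` is disabled.
    """
    if "q_value" not in psms.columns:
        raise ValueError("run compute_fdr before filter_psms")
    df = psms[~psms["is_decoy"]].copy()
    plen = df["peptide"].str.len()
    is_prot = df["assay"] == "proteome"
    keep = np.where(
        is_prot,
        df["q_value"] <= q_max,
        (df["probability"] >= p_min)
        & (plen >= len_range[0])
        & (plen <= len_range[1]),
    )
    df = df[keep]
    if require_validated and "validated" in df.columns:
        df = df[df["validated"].fillna(False).astype(bool)]
    return df


def map_peptides_to_ncorfs(
    retained: pd.DataFrame,
    db: Sequence[ProteinDBEntry],
) -> tuple[dict[str, NcorfEvidence], dict[str, list[str]]]:
    """Assign retained peptides to ncORF proteins under I=L equivalence.

    A peptide is assigned to every ncORF protein containing it as a
    substring; peptides also contained in any canonical protein are
    discarded as non-discriminating.  Returns (evidence keyed by orf_id,
    report with ``discarded_canonical`` and ``orphan`` peptide lists).

    ncORF accessions follow ``ncorf|<orf_id>|<category>``; the orf_id is
    recovered from the accession.
    """
    ncorf_entries = [(e, il_collapse(e.sequence)) for e in db if e.origin == "ncorf"]
    canon_il = [il_collapse(e.sequence) for e in db if e.origin == "canonical"]

    evidence: dict[str, NcorfEvidence] = {}
    discarded: list[str] = []
    orphans: list[str] = []

    groups = retained.groupby("peptide", sort=True)
    for peptide, rows in groups:
        pep_il = il_collapse(str(peptide))
        if any(pep_il in c for c in canon_il):
            discarded.append(str(peptide))
            continue
        hit = False
        for entry, seq_il in ncorf_entries:
            if pep_il in seq_il:
                hit = True
                orf_id = _orf_id_from_accession(entry.accession)
                ev = evidence.setdefault(orf_id, NcorfEvidence(orf_id=orf_id))
                ev.peptides.add(str(peptide))
                ev.cohorts_supported.update(rows["cohort"].astype(str))
                ev.assay_support.update(rows["assay"].astype(str))
        if not hit:
            orphans.append(str(peptide))
    return evidence, {"discarded_canonical": discarded, "orphan": orphans}


def _orf_id_from_accession(accession: str) -> str:
    parts = accession.split("|")
    if len(parts) >= 2 and parts[0] == "ncorf":
        return parts[1]
    return accession


def cohort_pervasiveness(
    evidence: Mapping[str, NcorfEvidence], min_cohorts: int = 8
) -> list[str]:
    """ORFs supported in at least ``min_cohorts`` cohorts.

    Default 8 targets pervasive translation across most of a 9-10 cancer
    panel.  Sorted by cohort count descending, then orf_id.
    """
    flagged = [
        ev for ev in evidence.values() if len(ev.cohorts_supported) >= min_cohorts
    ]
    flagged.sort(key=lambda ev: (-len(ev.cohorts_supported), ev.orf_id))
    return [ev.orf_id for ev in flagged]


def annotate_differential_expression(
    evidence: Mapping[str, NcorfEvidence],
    orf_gene: Mapping[str, str],
    de_table: pd.DataFrame,
    lfc: float = 1.5,
    p: float = 0.01,
) -> dict[str, str]:
    """DE class per ORF from a per-gene log2FC/p-value table.

    ``over`` iff p-value < ``p`` and log2FC >= ``lfc``; ``under`` iff
    p-value < ``p`` and log2FC <= -``lfc`` (both bounds inclusive on the
    fold change, strict on the p-value); genes absent from the table are
    ``none``.
    """
    required = {"gene_id", "log2fc", "pvalue"}
    if not required <= set(de_table.columns):
        raise ValueError(f"de_table must have columns {sorted(required)}")
    idx = de_table.set_index("gene_id")
    out: dict[str, str] = {}
    for orf_id in evidence:
        gene = orf_gene.get(orf_id)
        if gene is None or gene not in idx.index:
            out[orf_id] = "none"
            continue
        row = idx.loc[gene]
        if row["pvalue"] < p and row["log2fc"] >= lfc:
            out[orf_id] = "over"
        elif row["pvalue"] < p and row["log2fc"] <= -lfc:
            out[orf_id] = "under"
        else:
            out[orf_id] = "none"
    return out


def stratified_rank_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two strata.

    Used for conservation strata (orthologs in >=6 vs <=5 species),
    peptide-length comparisons, and tumor-mutation-burden comparisons.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(group_a, group_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def write_evidence_table(
    evidence: Mapping[str, NcorfEvidence], path: str | Path
) -> None:
    rows = [
        {
            "orf_id": ev.orf_id,
            "n_peptides": ev.n_peptides,
            "peptides": ";".join(sorted(ev.peptides)),
            "cohorts": ";".join(sorted(ev.cohorts_supported)),
            "assays": ";".join(sorted(ev.assay_support)),
        }
        for ev in sorted(evidence.values(), key=lambda e: e.orf_id)
    ]
    pd.DataFrame(
        rows, columns=["orf_id", "n_peptides", "peptides", "cohorts", "assays"]
    ).to_csv(path, sep="\t", index=False)
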