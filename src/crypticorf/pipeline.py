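"""End-to-end orchestration of the synthetic proteogenomic study.

Runs every stage against a generated reference with planted ground truth:
ORF enumeration -> search-database construction -> PSM FDR/filtering ->
peptide-to-ORF evidence -> pervasiveness/DE annotation -> variant
re-annotation -> mutated proteomes -> epitope/neoantigen prioritization.
Primarily a convenience layer for scripts and examples; each stage is
usable on its own through the module APIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .annotation import GenomeBuild, TranscriptModel
from .orfs import (
    ORFRecord,
    category_counts,
    deduplicate_orfs,
    enumerate_and_classify,
    orf_accession,
)
from .searchdb import (
    DigestSpec,
    ProteinDBEntry,
    build_search_database,
    canonical_overlap_filter,
)
from .psms import (
    NcorfEvidence,
    annotate_differential_expression,
    cohort_pervasiveness,
    compute_fdr,
    filter_psms,
    map_peptides_to_ncorfs,
)
from .variants import (
    NcorfConsequence,
    VariantRecord,
    annotate_variants,
    figure4a_tallies,
    mutation_burden,
)
from .epitopes import (
    EpitopeCandidate,
    MutatedProtein,
    build_mutated_proteome,
    candidate_peptides,
    eliminate_wildtype_matches,
    prioritize_epitopes,
)
from .simulate import (
    EpitopeTruth,
    GroundTruthManifest,
    PsmTruth,
    SimulationConfig,
    SyntheticReference,
    VariantTruth,
    simulate_aux_tables,
    simulate_epitope_tables,
    simulate_psm_tables,
    simulate_reference,
    simulate_variants,
)


@dataclass
class StudyResult:
    """All artifacts of one synthetic study run."""

    config: SimulationConfig
    reference: SyntheticReference
    orfs: list[ORFRecord]                      # enumerated + classified, all transcripts
    orf_representatives: list[ORFRecord]       # nonredundant by protein
    redundancy: dict[str, list[str]]
    db: list[ProteinDBEntry]                   # targets + decoys
    removal_report: list[tuple[str, str]]
    psms: pd.DataFrame                         # with q_value
    psm_truth: PsmTruth
    retained: pd.DataFrame
    evidence: dict[str, NcorfEvidence]
    mapping_report: dict[str, list[str]]
    pervasive: list[str]
    de_class: dict[str, str]
    variants: list[VariantRecord]
    variant_truth: VariantTruth
    consequences: list[NcorfConsequence]
    variant_summary: pd.DataFrame
    variant_table: pd.DataFrame                # one row per variant (incl. non-overlapping)
    tallies: dict[str, int]
    burden: pd.DataFrame
    mutated: list[MutatedProtein]
    neo_peptides: list[tuple[str, MutatedProtein]]
    epitope_truth: EpitopeTruth
    candidates: list[EpitopeCandidate]
    report: list[EpitopeCandidate]

    @property
    def manifest(self) -> GroundTruthManifest:
        return GroundTruthManifest(
            planted_orfs=self.reference.planted,
            psm=self.psm_truth,
            variants=self.variant_truth,
            epitopes=self.epitope_truth,
        )


def assemble_candidates(
    affinity: pd.DataFrame,
    rt: pd.DataFrame,
    expression: pd.DataFrame,
    orf_gene: dict[str, str],
    mutated_keys: set[tuple[str, str]],
) -> list[EpitopeCandidate]:
    """Join affinity, RT and expression tables into epitope candidates.

    ``mutated_keys`` holds (peptide, sample_id) pairs originating from
    mutated proteomes (neoantigens).
    """
    rt_idx = rt.set_index("peptide") if len(rt) else None
    expr_idx = expression.set_index("gene_id")["median_tpm"] if len(expression) else None
    out: list[EpitopeCandidate] = []
    for row in affinity.itertuples(index=False):
        rt_obs = rt_pred = None
        if rt_idx is not None and row.peptide in rt_idx.index:
            rt_obs = float(rt_idx.loc[row.peptide, "rt_observed_min"])
            rt_pred = float(rt_idx.loc[row.peptide, "rt_predicted_min"])
        gene = orf_gene.get(row.orf_id)
        tpm = None
        if expr_idx is not None and gene in expr_idx.index:
            tpm = float(expr_idx.loc[gene])
        out.append(
            EpitopeCandidate(
                peptide=row.peptide,
                orf_id=row.orf_id,
                sample_id=row.sample_id,
                hla_allele=row.hla_allele,
                affinity_nM=float(row.affinity_nM),
                percentile_rank=float(row.percentile_rank),
                rt_observed_min=rt_obs,
                rt_predicted_min=rt_pred,
                gtex_median_tpm=tpm,
                mutated=(row.peptide, row.sample_id) in mutated_keys,
            )
        )
    return out


def full_variant_table(
    variants: list[VariantRecord], summary: pd.DataFrame
) -> pd.DataFrame:
    """One row per variant: ORF-overlapping rows from ``summary``, plus
    non-overlapping variants with ncorf_class 'none'."""
    seen = set(summary["variant_key"]) if len(summary) else set()
    rows = []
    for v in variants:
        if v.key in seen:
            continue
        rows.append(
            {
                "variant_key": v.key,
                "sample_id": v.sample_id,
                "cohort": v.cohort,
                "canonical_class": v.canonical_class or "other",
                "ncorf_class": "none",
                "figure4a_group": "",
                "n_orfs": 0,
            }
        )
    extra = pd.DataFrame(rows, columns=summary.columns)
    return pd.concat([summary, extra], ignore_index=True) if rows else summary.copy()


def run_study(
    seed: int = 0,
    cfg: Optional[SimulationConfig] = None,
    digest_spec: Optional[DigestSpec] = None,
) -> StudyResult:
    """Generate a synthetic study and run the full pipeline over it."""
    if cfg is None:
        cfg = SimulationConfig(seed=seed)
    if digest_spec is None:
        digest_spec = DigestSpec(missed_cleavages=2, mode="semi", min_len=8, max_len=25)

    ref = simulate_reference(cfg)
    tx = ref.transcripts_by_id

    orfs: list[ORFRecord] = []
    for t in ref.transcripts:
        orfs.extend(enumerate_and_classify(t, ref.genome, cfg.min_codons))
    representatives, redundancy = deduplicate_orfs(orfs)

    ncorf_entries = [
        ProteinDBEntry(accession=orf_accession(o), sequence=o.protein, origin="ncorf")
        for o in representatives
    ]
    ncorf_entries, removal_report = canonical_overlap_filter(
        ncorf_entries, ref.canonical, digest_spec
    )
    db = build_search_database(ncorf_entries, ref.canonical)

    psms, psm_truth = simulate_psm_tables(cfg, ref)
    psms = compute_fdr(psms)
    retained = filter_psms(psms)
    evidence, mapping_report = map_peptides_to_ncorfs(retained, db)
    pervasive = cohort_pervasiveness(evidence, cfg.pervasive_min_cohorts)

    orf_gene = {o.orf_id: o.gene_id for o in orfs}
    de_table, _ortho = simulate_aux_tables(cfg, ref)
    de_class = annotate_differential_expression(evidence, orf_gene, de_table)

    variants, variant_truth = simulate_variants(cfg, ref)
    consequences, variant_summary = annotate_variants(
        variants, orfs, tx, ref.genome
    )
    tallies = figure4a_tallies(variant_summary)
    variant_table = full_variant_table(variants, variant_summary)
    burden = mutation_burden(variant_table)

    orfs_by_id = {o.orf_id: o for o in orfs}
    mutated = build_mutated_proteome(consequences, orfs_by_id, tx, ref.genome)
    neo_candidates = candidate_peptides(mutated, digest_spec)
    wildtype_db = list(ref.canonical) + [
        e for e in db if e.origin == "ncorf"
    ]
    neo_peptides = eliminate_wildtype_matches(neo_candidates, wildtype_db)

    tuples: list[tuple[str, str, str, bool]] = []
    seen_t: set[tuple[str, str, str, bool]] = set()
    for ev in sorted(evidence.values(), key=lambda e: e.orf_id):
        for pep in sorted(ev.peptides):
            tup = (pep, ev.orf_id, "pooled", False)
            if tup not in seen_t:
                seen_t.add(tup)
                tuples.append(tup)
    for pep, mp in neo_peptides:
        tup = (pep, mp.orf_id, mp.sample_id, True)
        if tup not in seen_t:
            seen_t.add(tup)
            tuples.append(tup)

    affinity, rt, expression, epitope_truth = simulate_epitope_tables(
        cfg, tuples, orf_gene
    )
    mutated_keys = {(pep, sid) for pep, _orf, sid, mut in tuples if mut}
    candidates = assemble_candidates(affinity, rt, expression, orf_gene, mutated_keys)
    candidates, report = prioritize_epitopes(candidates)

    return StudyResult(
        config=cfg,
        reference=ref,
        orfs=orfs,
        orf_representatives=representatives,
        redundancy=redundancy,
        db=db,
        removal_report=removal_report,
        psms=psms,
        psm_truth=psm_truth,
        retained=retained,
        evidence=evidence,
        mapping_report=mapping_report,
        pervasive=pervasive,
        de_class=de_class,
        variants=variants,
        variant_truth=variant_truth,
        consequences=consequences,
        variant_summary=variant_summary,
        variant_table=variant_table,
        tallies=tallies,
        burden=burden,
        mutated=mutated,
        neo_peptides=neo_peptides,
        epitope_truth=epitope_truth,
        candidates=candidates,
        report=report,
    )


def summary_statistics(res: StudyResult) -> dict[str, float | int]:
    """Headline numbers of one study run (all computed, nothing cached)."""
    counts = category_counts(res.orfs)
    planted_ids = {p.orf_id for p in res.reference.planted}
    enumerated_ids = {o.orf_id for o in res.orfs}
    recovered = len(planted_ids & enumerated_ids)
    labels = res.psm_truth.labels
    accepted = res.psms[(res.psms["q_value"] <= 0.01) & (~res.psms["is_decoy"])]
    n_false = sum(labels[s] == "false" for s in accepted["spectrum_id"])
    fdp = n_false / max(1, len(accepted))
    return {
        "n_transcripts": len(res.reference.transcripts),
        "n_orfs_enumerated": len(res.orfs),
        "n_orfs_nonredundant": len(res.orf_representatives),
        "planted_orf_recovery_rate_pct": 100.0 * recovered / max(1, len(planted_ids)),
        **{f"n_{k}": v for k, v in counts.items()},
        "n_psms": len(res.psms),
        "realized_psm_fdp_pct": 100.0 * fdp,
        "n_supported_orfs": len(res.evidence),
        "n_pervasive_flagged": len(res.pervasive),
        "n_pervasive_planted": len(res.psm_truth.pervasive_orf_ids),
        "n_variants": len(res.variants),
        "n_variants_ncorf_altering": res.tallies["n_altering"],
        "n_missense": res.tallies["missense"],
        "n_frameshift": res.tallies["frameshift"],
        "n_stop_gained": res.tallies["stop_gained"],
        "n_stop_lost": res.tallies["stop_lost"],
        "n_mutated_proteins": len(res.mutated),
        "n_neo_peptides": len(res.neo_peptides),
        "n_epitope_candidates": len(res.candidates),
        "n_reported": len(res.report),
        "n_reported_neoantigens": sum(1 for c in res.report if c.mutated),
        "n_reported_epitopes": sum(1 for c in res.report if not c.mutated),
    }
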