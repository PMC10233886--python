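"""Frame-aware variant consequences, cross-classification, burden."""

import numpy as np
import pandas as pd
import pytest

from crypticorf.annotation import (
    GenomeBuild,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
    transcript_to_genomic,
    translate_frame,
)
from crypticorf.orfs import ORFRecord, enumerate_orfs
from crypticorf.variants import (
    ALTERING_NCORF,
    GROUPS,
    VariantError,
    VariantRecord,
    call_ncorf_consequence,
    compute_canonical_class,
    cross_classify,
    figure4a_tallies,
    left_normalize,
    mutation_burden,
    project_variant,
    read_maf,
    write_maf,
)

# ---------------------------------------------------------------------------
# independent oracle: apply the edit to the contig, re-splice, re-translate
# ---------------------------------------------------------------------------

def oracle_consequence(v, orf, t, genome):
    """Naive re-translation oracle, independent of the codon-level caller.

    Applies the genomic edit to the contig, shifts exon coordinates past the
    edit, rebuilds the spliced sequence, re-translates from the ORF start
    and derives the class from the protein diff (SNVs) or net exonic length
    change (indels).  Returns 'none' for edits outside the ORF footprint.
    """
    contig = genome.contigs[t.contig]
    net = len(v.alt) - len(v.ref)
    if v.ref:
        mut_contig = contig[: v.pos] + v.alt + contig[v.pos + len(v.ref) :]
    else:
        mut_contig = contig[: v.pos] + v.alt + contig[v.pos :]

    new_exons = []
    for s, e in t.exons:
        if v.ref == "":  # insertion before v.pos
            s2 = s + net if s >= v.pos else s
            e2 = e + net if e > v.pos else e  # insertion strictly inside or left
            if s < v.pos <= e:
                e2 = e + net
                s2 = s
        else:
            lo, hi = v.pos, v.pos + len(v.ref)
            if hi <= s:
                s2, e2 = s + net, e + net
            elif lo >= e:
                s2, e2 = s, e
            else:  # edit inside this exon (fully, for this oracle)
                assert s <= lo and hi <= e, "oracle requires fully-exonic edits"
                s2, e2 = s, e + net
        new_exons.append((s2, e2))
    t2 = TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        gene_name=t.gene_name,
        contig=t.contig,
        strand=t.strand,
        exons=tuple(new_exons),
        cds_span=None,
        biotype="other",
    )
    mut_spliced = spliced_sequence(t2, GenomeBuild({t.contig: mut_contig}))
    wt = orf.protein
    mut = translate_frame(mut_spliced[orf.t_start :], 0)

    # does the edit touch the ORF footprint on the spliced transcript?
    from crypticorf.variants import transcript_edit, _first_affected

    edit = transcript_edit(v, t)
    if edit is None or _first_affected(edit, orf) is None:
        return "none"

    if len(v.ref) == 1 and len(v.alt) == 1:
        if mut == wt:
            return "silent"
        if len(mut) < len(wt) and wt.startswith(mut):
            return "stop_gained"
        if len(mut) > len(wt) and mut.startswith(wt):
            return "stop_lost"
        return "missense"
    kind = "ins" if net > 0 else "del"
    # bases of the edit that fall inside the ORF decide the frame shift
    if v.ref:
        lo = max(edit.t_pos, orf.t_start)
        hi = min(edit.t_pos + len(edit.t_ref), orf.t_end)
        within = hi - lo
    else:
        within = len(edit.t_alt)
    if within % 3 != 0:
        assert mut != wt
        return f"frameshift_{kind}"
    return f"inframe_{kind}"


def toy_orf_setup():
    """Plus-strand single-exon transcript with one clean ORF."""
    seq = "GG" + "ATG" + "AAA" + "TAC" + "CAC" + "TAA" + "CCCGG"
    genome = GenomeBuild({"c": seq})
    t = TranscriptModel("t", "g", "", "c", "+", ((0, len(seq)),), None, "lncRNA")
    (orf,) = [o for o in enumerate_orfs(t, genome, 2) if o.t_start == 2]
    return genome, t, orf


class TestProjection:
    def test_first_base_of_start_codon(self):
        genome, t, orf = toy_orf_setup()
        v = VariantRecord("c", 2, "A", "C")
        assert project_variant(v, orf, t) == (0, 0)

    def test_one_nt_upstream_is_none(self):
        genome, t, orf = toy_orf_setup()
        v = VariantRecord("c", 1, "G", "C")
        assert project_variant(v, orf, t) is None

    def test_minus_strand_matches_oracle(self, study):
        """Codon index from projection equals the index of the first residue
        changed by the re-translation oracle on minus-strand transcripts."""
        ref = study.reference
        tx = ref.transcripts_by_id
        rng = np.random.default_rng(0)
        checked = 0
        for p in ref.planted:
            t = tx[p.transcript_id]
            if t.strand != "-":
                continue
            orf = next(o for o in study.orfs if o.orf_id == p.orf_id)
            for _ in range(5):
                tpos = p.t_start + int(rng.integers(3, p.t_end - p.t_start - 3))
                g = transcript_to_genomic(t, tpos)
                base = ref.genome.fetch(t.contig, g, g + 1)
                alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
                v = VariantRecord(t.contig, g, base, alt)
                ci, off = project_variant(v, orf, t)
                assert ci == (tpos - p.t_start) // 3
                cons = call_ncorf_consequence(v, orf, t, ref.genome)
                if cons.ncorf_class == "missense":
                    changed = int(cons.protein_change[3:-1].rstrip("*"))
                    assert changed == ci + 1
                checked += 1
        assert checked > 0


class TestConsequences:
    def test_stop_gained_tac_to_taa(self):
        genome, t, orf = toy_orf_setup()
        # codon 2 is TAC at positions 8..11; TAC->TAA via C->A at pos 10
        v = VariantRecord("c", 10, "C", "A")
        cons = call_ncorf_consequence(v, orf, t, genome)
        assert cons.ncorf_class == "stop_gained"
        assert cons.protein_change == "p.Y3*"

    def test_two_nt_deletion_frameshift(self):
        genome, t, orf = toy_orf_setup()
        v = VariantRecord("c", 6, "AA", "")
        v = left_normalize(v, genome)
        cons = call_ncorf_consequence(v, orf, t, genome)
        assert cons.ncorf_class == "frameshift_del"

    def test_inframe_insertion(self):
        genome, t, orf = toy_orf_setup()
        v = VariantRecord("c", 8, "", "GGG")
        cons = call_ncorf_consequence(v, orf, t, genome)
        assert cons.ncorf_class == "inframe_ins"

    def test_retained_stop_is_silent(self):
        genome, t, orf = toy_orf_setup()
        # stop codon TAA at 14..17; TAA->TAG via A->G at pos 16
        v = VariantRecord("c", 16, "A", "G")
        cons = call_ncorf_consequence(v, orf, t, genome)
        assert cons.ncorf_class == "silent"

    def test_stop_lost(self):
        genome, t, orf = toy_orf_setup()
        # TAA->CAA at pos 14: reads through into CCC GG...
        v = VariantRecord("c", 14, "T", "C")
        cons = call_ncorf_consequence(v, orf, t, genome)
        assert cons.ncorf_class == "stop_lost"

    def test_ref_mismatch_is_hard_error(self):
        genome, t, orf = toy_orf_setup()
        with pytest.raises(VariantError, match="reference"):
            call_ncorf_consequence(VariantRecord("c", 2, "T", "C"), orf, t, genome)

    def test_oracle_equivalence_small(self, study):
        """Random SNVs/indels on planted ORFs: caller matches the naive
        re-translation oracle (full sweep lives in the acceptance suite)."""
        mismatches = run_oracle_sweep(study, n=150, seed=5)
        assert mismatches == []


def run_oracle_sweep(study, n, seed):
    ref = study.reference
    tx = ref.transcripts_by_id
    orf_by_id = {o.orf_id: o for o in study.orfs}
    planted = [p for p in ref.planted if p.orf_id in orf_by_id]
    rng = np.random.default_rng(seed)
    mismatches = []
    made = 0
    while made < n:
        p = planted[int(rng.integers(0, len(planted)))]
        t = tx[p.transcript_id]
        orf = orf_by_id[p.orf_id]
        span = p.t_end - p.t_start
        tpos = p.t_start + int(rng.integers(0, span))
        g = transcript_to_genomic(t, tpos)
        kind = rng.random()
        if kind < 0.6:  # SNV
            base = ref.genome.fetch(t.contig, g, g + 1)
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == base:
                continue
            v = VariantRecord(t.contig, g, base, alt)
        elif kind < 0.8:  # deletion 1-6 nt, fully exonic
            ln = int(rng.integers(1, 7))
            gps = []
            ok = True
            for k in range(ln):
                if tpos + k >= t.length:
                    ok = False
                    break
                gps.append(transcript_to_genomic(t, tpos + k))
            if not ok:
                continue
            lo, hi = min(gps), max(gps) + 1
            if hi - lo != ln:
                continue
            v = VariantRecord(t.contig, lo, ref.genome.fetch(t.contig, lo, hi), "")
        else:  # insertion 1-6 nt
            ln = int(rng.integers(1, 7))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, ln))
            v = VariantRecord(t.contig, g, "", ins)
        v = left_normalize(v, ref.genome)
        from crypticorf.variants import transcript_edit

        if transcript_edit(v, t) is None:
            continue
        got = call_ncorf_consequence(v, orf, t, ref.genome).ncorf_class
        try:
            want = oracle_consequence(v, orf, t, ref.genome)
        except AssertionError:
            continue  # edit not fully exonic after normalization
        made += 1
        if got != want:
            mismatches.append((v.key, orf.orf_id, got, want))
    return mismatches


class TestCrossClassification:
    @pytest.mark.parametrize(
        "canonical,ncorf,group",
        [
            ("utr5", "missense", "1_utr_derived"),
            ("intron", "frameshift_del", "1_utr_derived"),
            ("rna", "stop_gained", "1_utr_derived"),
            ("silent", "missense", "2_overlap_canonical"),
            ("missense", "stop_lost", "2_overlap_canonical"),
            ("silent", "silent", "3_canonical_only"),
            ("missense", "none", "3_canonical_only"),
        ],
    )
    def test_group_rules(self, canonical, ncorf, group):
        assert cross_classify(canonical, ncorf) == group

    def test_exactly_one_group_and_tally_identity(self, study):
        summary = study.variant_summary
        assert summary["figure4a_group"].isin(GROUPS).all()
        tallies = study.tallies
        class_sum = (
            tallies["missense"]
            + tallies["frameshift"]
            + tallies["stop_gained"]
            + tallies["stop_lost"]
            + tallies["inframe"]
        )
        assert class_sum == tallies["n_altering"]
        assert sum(tallies[g] for g in GROUPS) == tallies["n_overlapping"]

    def test_silent_canonical_means_unchanged_protein(self, study):
        """Variants annotated canonical-silent leave the canonical protein
        intact when re-translated."""
        ref = study.reference
        tx = ref.transcripts_by_id
        checked = 0
        for cell in study.variant_truth.cells:
            if cell["canonical_class"] != "silent":
                continue
            v = next(v for v in study.variants if v.key == cell["key"])
            t = tx[cell["orf_id"].rsplit(":", 2)[0]]
            cs, ce = t.cds_span
            seq = spliced_sequence(t, ref.genome)
            from crypticorf.variants import transcript_edit

            edit = transcript_edit(v, t)
            mut = edit.apply(seq)
            assert translate_frame(mut[cs:ce], 0) == translate_frame(seq[cs:ce], 0)
            checked += 1
        assert checked > 0


class TestBurden:
    def make_table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant_key", "sample_id", "cohort", "canonical_class",
                     "ncorf_class", "figure4a_group", "n_orfs"],
        )

    def test_counts_per_mb(self):
        rows = [(f"v{i}", "s1", "BRCA", "missense", "none", "", 0) for i in range(38)]
        burden = mutation_burden(self.make_table(rows), region_size_mb=38.0)
        assert burden.loc[0, "canonical_per_mb"] == pytest.approx(1.0)
        assert burden.loc[0, "ncorf_only_per_mb"] == 0.0

    def test_zero_variants(self):
        rows = [("v0", "s1", "BRCA", "utr5", "none", "", 0)]
        burden = mutation_burden(self.make_table(rows))
        assert burden.loc[0, "canonical_per_mb"] == 0.0

    def test_ncorf_only_excludes_canonical_altering(self):
        rows = [
            ("v1", "s1", "BRCA", "silent", "missense", "2_overlap_canonical", 1),
            ("v2", "s1", "BRCA", "missense", "missense", "2_overlap_canonical", 1),
        ]
        burden = mutation_burden(self.make_table(rows))
        assert burden.loc[0, "ncorf_only_count"] == 1
        assert burden.loc[0, "canonical_count"] == 1

    def test_half_rate_shift_detected_by_rank_test(self):
        """Planted ncORF-only burden at half the canonical rate is detected
        (p<0.01) in >=90% of 50 seeds."""
        from crypticorf.psms import stratified_rank_test

        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            canonical = rng.poisson(20, 40) / 38.0
            ncorf_only = rng.poisson(10, 40) / 38.0
            _, p = stratified_rank_test(canonical, ncorf_only)
            hits += p < 0.01
        assert hits >= 45


class TestMafIO:
    def test_round_trip(self, tmp_path, study):
        path = tmp_path / "m.maf"
        write_maf(study.variants, path)
        back = read_maf(path)
        assert len(back) == len(study.variants)
        for a, b in zip(study.variants, back):
            assert (a.contig, a.pos, a.ref, a.alt, a.sample_id, a.cohort) == (
                b.contig, b.pos, b.ref, b.alt, b.sample_id, b.cohort,
            )

    def test_left_normalization(self):
        genome = GenomeBuild({"c": "GGAAAATCC"})
        v = VariantRecord("c", 5, "A", "")  # delete one A of the run
        nv = left_normalize(v, genome)
        assert (nv.pos, nv.ref) == (2, "A")

    def test_multiallelic_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=c,length=100>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c\t5\t.\tA\tC,G\t.\t.\t.\n"
        )
        from crypticorf.variants import read_vcf

        with pytest.raises(VariantError, match="multi-allelic"):
            read_vcf(vcf)
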